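# cavloop

Closed-loop cavitation-level control for focused-ultrasound blood–brain-barrier
opening, as a tested software package. It simulates the full treatment loop
against a configurable synthetic microbubble-emission plant and quantifies the
outcomes:

- **`cavloop.plant`** — synthetic emission plant: harmonics with power-law
  pressure growth, ultra/sub-harmonics above an onset pressure, broadband
  (inertial) emission above a second onset, a band-limited zero-phase receiver
  (2.25 MHz center, 600 kHz −6 dB bandwidth), electronic noise, and optional
  pulse-to-pulse variability. Seeded and bit-reproducible; HDF5 fixture
  archives.
- **`cavloop.spectral`** — per-pulse FFT magnitude spectra, band-sum levels for
  the stable-cavitation band (4th harmonic ± 0.02 MHz) and inertial-cavitation
  band (2.1 ± 0.02 MHz), baseline calibration over the dummy pulses, and dB
  conversion (20·log10 by default, configurable).
- **`cavloop.control`** — the two-phase controller: a 5 s dummy sonication at
  0.3 MPa calibrates the baseline, a ramp phase raises the pressure pulse by
  pulse until the SC level reaches the target cavitation level (TCL, dB above
  baseline), and a maintain phase steps the pressure down/up whenever a pulse
  lands above/below TCL ± tolerance. Characterization: good pulse rate, IC
  probability, per-session summaries.
- **`cavloop.imaging`** — outcome quantifiers: opening volume from a
  contrast-enhanced volume (treated-ROI voxels above control-ROI mean + 3·SD,
  counted per slice, max slice reported in mm³) and red-hue pixel area from
  RGB histology sections; seeded synthetic generators for both.
- **`cavloop.io` / `cavloop.cli`** — YAML/JSON configs, lossless CSV pulse
  logs, session manifests, group summaries, and the `cavloop` command line.

## CLI

```sh
# run a closed-loop session against the synthetic plant
cavloop simulate-treatment --config cfg.yaml --plant plant.yaml \
    --tcl 0.5 --seed 7 --out log.csv --summary summary.json

# generate / analyze trace archives
cavloop make-fixtures --pressures 0.3,0.4 --seeds 1,2 --out traces.h5
cavloop analyze-pcd --archive traces.h5 --baseline-n 5 --out metrics.csv

# outcome quantification
cavloop quantify-mri --volume post.nii --rois rois.yaml --out opening.json
cavloop quantify-histology --image section.png --pixel-size 0.01 --out red.json

# group statistics over per-session summaries
cavloop summarize s1.json s2.json s3.json --out groups.json
```

`rois.yaml` holds `treated:` and `control:` mappings with `center` (mm),
optional `major_axis`/`minor_axis` (default 19/8 mm), `orientation` (deg)
and `slices` (index range).

## Reproducibility

Every stochastic path (plant emission, jitter, synthetic MRI) flows through a
single seeded `numpy` generator; identical seeds give byte-identical pulse
logs and fixture archives. `cavloop simulate-treatment --manifest m.json`
records config hashes, seed and package version for exact reruns.
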