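"""Synthetic microbubble-emission plant.

Maps an applied peak-negative pressure to a per-pulse passive-cavitation-
detector (PCD) voltage trace: integer harmonics of the drive with power-law
pressure growth, ultra/sub-harmonics above an onset pressure, broadband noise
above an inertial-cavitation onset, all seen through a band-limited receiver
with additive electronic noise.  Stands in for a live subject when testing
the feedback controller end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import h5py
import numpy as np
from scipy import signal

__all__ = ["PlantParams", "Plant", "emit", "receiver_filter", "n_samples",
           "make_fixture_set", "load_fixture_set"]

_DEFAULT_HARM_AMP = (1.0, 0.5, 0.3, 0.2, 0.1, 0.05, 0.02, 0.01)
_DEFAULT_UH_AMP = (0.02, 0.03, 0.04, 0.05, 0.05, 0.04)


@dataclass(frozen=True)
class PlantParams:
    """Parameters of the synthetic emission model.

    Amplitudes are arbitrary voltage units; only ratios and dB quantities are
    physically meaningful.  ``jitter_sigma`` sets a per-pulse log-normal
    multiplicative factor on the harmonic amplitudes; ``jitter_growth``
    makes its effective sigma grow as ``(p / jitter_pref) ** jitter_growth``
    so that controllability can degrade at higher drive pressure.
    """

    f0: float = 5.0e5
    fs: float = 4.0e7
    pulse_len: float = 0.010
    n_harmonics: int = 8
    harm_amp: tuple[float, ...] = _DEFAULT_HARM_AMP
    gamma: float = 1.5
    uh_amp: tuple[float, ...] = _DEFAULT_UH_AMP
    p_uh: float = 0.32
    p_ic: float = 0.50
    bb_gain: float = 0.05
    noise_sigma: float = 1.0e-3
    jitter_sigma: float = 0.0
    jitter_growth: float = 0.0
    jitter_pref: float = 0.3
    rx_center: float = 2.25e6
    rx_bw: float = 6.0e5
    rx_order: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2.0 * self.n_harmonics * self.f0:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest harmonic "
                f"({self.n_harmonics} * {self.f0} Hz)")
        if self.p_uh > self.p_ic:
            raise ValueError("p_uh must not exceed p_ic")
        if len(self.harm_amp) != self.n_harmonics:
            raise ValueError("harm_amp length must equal n_harmonics")
        if any(a < 0 for a in self.harm_amp) or any(a < 0 for a in self.uh_amp):
            raise ValueError("amplitudes must be non-negative")
        if self.bb_gain < 0 or self.noise_sigma < 0 or self.jitter_sigma < 0:
            raise ValueError("gains and sigmas must be non-negative")
        n = self.fs * self.pulse_len
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"pulse_len*fs = {n} is not an integer sample count")
        if self.rx_bw >= 2.0 * self.rx_center:
            raise ValueError("rx_bw must be below 2*rx_center")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["harm_amp"] = list(self.harm_amp)
        d["uh_amp"] = list(self.uh_amp)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlantParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown plant parameter(s): {sorted(unknown)}")
        d = dict(d)
        for k in ("harm_amp", "uh_amp"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def n_samples(params: PlantParams) -> int:
    """Exact sample count of one pulse: round(fs * pulse_len)."""
    return int(round(params.fs * params.pulse_len))


def _sos(params: PlantParams) -> np.ndarray:
    # Butterworth corners are -3 dB; zero-phase forward-backward filtering
    # doubles the attenuation, landing the -6 dB points at center +/- bw/2.
    lo = params.rx_center - params.rx_bw / 2.0
    hi = params.rx_center + params.rx_bw / 2.0
    return signal.butter(params.rx_order, [lo, hi], btype="bandpass",
                         fs=params.fs, output="sos")


def receiver_filter(trace: np.ndarray, params: PlantParams) -> np.ndarray:
    """Zero-phase band-pass modelling the PCD receiver.

    -6 dB corners sit at ``rx_center +/- rx_bw/2``: a tone at the center
    passes at unit gain, a tone at either corner emerges at half amplitude.
    """
    trace = np.asarray(trace, dtype=np.float64)
    return signal.sosfiltfilt(_sos(params), trace)


def _zero_phase_gain(freqs: np.ndarray, params: PlantParams) -> np.ndarray:
    # Forward-backward filtering has zero phase and squared magnitude response.
    _, h = signal.sosfreqz(_sos(params), worN=np.atleast_1d(freqs),
                           fs=params.fs)
    return np.abs(h) ** 2


def emit(p: float, params: PlantParams,
         rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthesize one PCD voltage trace for peak-negative pressure ``p`` (MPa).

    Harmonic components grow as ``p**gamma``; ultra/sub-harmonics switch on
    above ``p_uh`` growing as ``(p - p_uh)**gamma``; broadband emission above
    ``p_ic`` with amplitude ``bb_gain * (p - p_ic)``.  Tonal components are
    emitted in receiver steady state (the zero-phase band-pass gain applied
    analytically, avoiding edge transients that would alias into the
    measurement bands); the broadband component passes through the actual
    filter.  Electronic noise is added last.  With a given generator (or the
    params seed) the trace is bit-reproducible.
    """
    if p < 0:
        raise ValueError(f"pressure must be non-negative, got {p}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = n_samples(params)
    t = np.arange(n) / params.fs

    jitter = 1.0
    if params.jitter_sigma > 0:
        sig = params.jitter_sigma * (p / params.jitter_pref) ** params.jitter_growth
        jitter = float(np.exp(sig * rng.standard_normal() - 0.5 * sig * sig))

    out = np.zeros(n)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=params.n_harmonics)
    harm_f = params.f0 * np.arange(1, params.n_harmonics + 1)
    harm_g = _zero_phase_gain(harm_f, params)
    if p > 0:
        amp_p = p ** params.gamma
        for a, f, g, phi in zip(params.harm_amp, harm_f, harm_g, phases):
            if a > 0:
                out += (jitter * a * amp_p * g) * np.sin(
                    2.0 * np.pi * f * t + phi)

    uh_phases = rng.uniform(0.0, 2.0 * np.pi, size=len(params.uh_amp))
    uh_f = params.f0 * (np.arange(1, len(params.uh_amp) + 1) - 0.5)
    if p > params.p_uh:
        uh_g = _zero_phase_gain(uh_f, params)
        amp_uh = (p - params.p_uh) ** params.gamma
        for a, f, g, psi in zip(params.uh_amp, uh_f, uh_g, uh_phases):
            if a > 0:
                out += (jitter * a * amp_uh * g) * np.sin(
                    2.0 * np.pi * f * t + psi)

    if p >= params.p_ic:
        bb = params.bb_gain * (p - params.p_ic) * rng.standard_normal(n)
        out += receiver_filter(bb, params)

    if params.noise_sigma > 0:
        out = out + params.noise_sigma * rng.standard_normal(n)
    return out


class Plant:
    """Stateful pulse source: successive calls draw from one seeded stream.

    ``Plant(params, seed)(p)`` returns the next pulse's trace at pressure
    ``p``.  Identical (params, seed, pressure sequence) gives identical
    traces, which is what makes closed-loop runs reproducible.
    """

    def __init__(self, params: PlantParams, seed: int | None = None):
        self.params = params
        self.seed = params.seed if seed is None else int(seed)
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    @property
    def fs(self) -> float:
        return self.params.fs

    def __call__(self, p: float) -> np.ndarray:
        return emit(p, self.params, self._rng)


def _fixture_key(pressure: float, seed: int) -> str:
    return f"p{pressure:.6f}_s{seed}"


def make_fixture_set(params: PlantParams, pressures, seeds, path) -> None:
    """Write an HDF5 archive with one trace per (pressure, seed) pair.

    Each dataset carries the pressure, seed and full plant parameters as
    attributes; regenerating with the same arguments is bit-identical.
    """
    pressures = list(pressures)
    seeds = list(seeds)
    if not pressures or not seeds:
        raise ValueError("pressures and seeds must be non-empty")
    pairs = [(p, s) for p in pressures for s in seeds]
    keys = [_fixture_key(p, s) for p, s in pairs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (pressure, seed) keys in fixture request")
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format"] = "cavloop-fixtures-v1"
        for k, v in params.to_dict().items():
            f.attrs[f"plant_{k}"] = v
        for (p, s), key in zip(pairs, keys):
            trace = emit(p, params, np.random.default_rng(s))
            ds = f.create_dataset(key, data=trace, track_times=False)
            ds.attrs["pressure_MPa"] = p
            ds.attrs["seed"] = s


def load_fixture_set(path) -> list[dict]:
    """Read a fixture archive back as [{pressure_MPa, seed, trace}, ...]."""
    out = []
    with h5py.File(path, "r") as f:
        for key in f:
            ds = f[key]
            out.append({
                "pressure_MPa": float(ds.attrs["pressure_MPa"]),
                "seed": int(ds.attrs["seed"]),
                "trace": ds[...],
            })
        fs = float(f.attrs.get("plant_fs", 0.0)) or None
    for rec in out:
        rec["fs"] = fs
    return out
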