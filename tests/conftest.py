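"""Shared fixtures: scaled-down plant/session parameters for fast tests.

The scaled plant keeps the 500 kHz drive and the 2.25 MHz receiver but uses
fs = 10 MHz and 2 ms pulses (20 000 samples, 500 Hz bin spacing) so a full
closed-loop session runs in about a second.  All measurement bands stay
exactly on FFT bins, as they do at the full 40 MHz / 10 ms scale.
"""

import numpy as np
import pytest

from cavloop import PlantParams, SonicationConfig


SMALL_FS = 1.0e7
SMALL_PULSE = 2.0e-3


@pytest.fixture
def small_params() -> PlantParams:
    return PlantParams(fs=SMALL_FS, pulse_len=SMALL_PULSE)


@pytest.fixture
def noiseless_params() -> PlantParams:
    """Noise off, onsets out of reach: pure power-law harmonic response."""
    return PlantParams(fs=SMALL_FS, pulse_len=SMALL_PULSE, noise_sigma=0.0,
                       p_uh=10.0, p_ic=10.0)


@pytest.fixture
def linear_params() -> PlantParams:
    """gamma=1 so the SC level is exactly proportional to pressure and
    sc_db(p) = 20*log10(p / dummy_pressure); tiny noise keeps the IC
    baseline positive without perturbing the SC path."""
    return PlantParams(fs=SMALL_FS, pulse_len=SMALL_PULSE, gamma=1.0,
                       noise_sigma=1e-9, p_uh=10.0, p_ic=10.0)


@pytest.fixture
def default_cfg() -> SonicationConfig:
    return SonicationConfig(tcl_db=1.0)


def dft_oracle(trace: np.ndarray) -> np.ndarray:
    """Direct O(N^2) one-sided DFT magnitude oracle."""
    trace = np.asarray(trace, dtype=np.float64)
    n = trace.size
    ks = np.arange(n // 2 + 1)
    mags = np.empty(ks.size)
    for i, k in enumerate(ks):
        w = np.exp(-2j * np.pi * k * np.arange(n) / n)
        mags[i] = abs(np.sum(trace * w))
    return mags


def band_sum_oracle(freqs, mags, lo, hi) -> float:
    """Explicit loop-and-sum over bins inside the closed interval."""
    total = 0.0
    for f, m in zip(freqs, mags):
        if lo <= f <= hi:
            total += m
    return total
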