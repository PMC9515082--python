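"""Two-phase closed-loop pressure controller and its characterization stats.

A treatment session starts with a short dummy sonication at low, fixed
pressure to calibrate the baseline SC/IC levels, then ramps the drive
pressure pulse by pulse until the SC level reaches the target cavitation
level (TCL, in dB above baseline), and finally holds the SC level inside
``TCL +/- tol`` by stepping the pressure down/up whenever a pulse lands
above/below the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import spectral
from .spectral import Band, BaselineCalibration

__all__ = ["SonicationConfig", "PulseRecord", "TreatmentLog",
           "ControllerState", "duty_cycle", "next_pressure", "run_treatment",
           "good_pulse_rate", "ic_probability", "summarize_log",
           "PULSE_LOG_COLUMNS"]

PHASE_DUMMY = "dummy"
PHASE_RAMP = "ramp"
PHASE_MAINTAIN = "maintain"

PULSE_LOG_COLUMNS = ("index", "phase", "pressure_MPa", "sc_linear",
                     "ic_linear", "sc_db", "ic_db", "in_band", "ic_event")


@dataclass(frozen=True)
class SonicationConfig:
    """Acoustic, timing and control parameters of one session.

    ``ramp_entry`` selects what "the SC level reached the TCL" means:
    ``"at_or_above"`` (default) switches to the maintain phase on the first
    pulse with sc_db >= tcl_db; ``"within_band"`` additionally accepts a
    pulse already inside the tolerance band.
    """

    f0: float = 5.0e5
    prf: float = 1.0
    pulse_len: float = 0.010
    dummy_pressure: float = 0.3
    dummy_duration: float = 5.0
    treat_duration: float = 180.0
    tcl_db: float = 0.5
    tol_db: float = 0.125
    ramp_step: float = 0.01
    maintain_step: float = 0.005
    p_max: float = 1.0
    p_min: float = 0.0
    ic_event_db: float = 1.0
    sc_harmonic: int = 4
    band_half_width: float = 0.02e6
    ic_center: float = 2.1e6
    db_convention: str = "amplitude"
    ramp_entry: str = "at_or_above"
    stop_on_ic: bool = False

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError("prf must be positive")
        dc = self.pulse_len * self.prf
        if not (0 < dc <= 1):
            raise ValueError(f"duty cycle {100 * dc}% outside (0, 100]%")
        if self.dummy_pressure > self.p_max:
            raise ValueError("dummy_pressure must not exceed p_max")
        if self.p_min < 0 or self.p_min > self.p_max:
            raise ValueError("require 0 <= p_min <= p_max")
        if self.tol_db <= 0:
            raise ValueError("tol_db must be positive")
        if self.ramp_step <= 0 or self.maintain_step <= 0:
            raise ValueError("pressure steps must be positive")
        if self.dummy_duration <= 0 or self.treat_duration <= 0:
            raise ValueError("durations must be positive")
        if self.ramp_entry not in ("at_or_above", "within_band"):
            raise ValueError(f"unknown ramp_entry: {self.ramp_entry!r}")
        if self.db_convention not in ("amplitude", "power"):
            raise ValueError(f"unknown db_convention: {self.db_convention!r}")

    @property
    def n_dummy(self) -> int:
        return int(round(self.dummy_duration * self.prf))

    @property
    def n_treat(self) -> int:
        return int(round(self.treat_duration * self.prf))

    def sc_band(self) -> Band:
        return spectral.sc_band(self.f0, self.sc_harmonic,
                                self.band_half_width)

    def ic_band(self) -> Band:
        return spectral.ic_band(self.ic_center, self.band_half_width)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SonicationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def duty_cycle(cfg: SonicationConfig) -> float:
    """Duty cycle in percent: 100 * pulse_len * prf."""
    return 100.0 * cfg.pulse_len * cfg.prf


@dataclass(frozen=True)
class PulseRecord:
    index: int
    phase: str
    pressure: float
    sc_linear: float
    ic_linear: float
    sc_db: float
    ic_db: float
    in_band: bool
    ic_event: bool


@dataclass
class TreatmentLog:
    config: SonicationConfig
    baseline: BaselineCalibration
    records: list[PulseRecord] = field(default_factory=list)
    saturated: bool = False

    def maintain_records(self) -> list[PulseRecord]:
        return [r for r in self.records if r.phase == PHASE_MAINTAIN]

    def n_ramp(self) -> int:
        return sum(1 for r in self.records if r.phase == PHASE_RAMP)


@dataclass
class ControllerState:
    """Controller memory between pulses: current phase and drive pressure."""

    phase: str
    pressure: float
    saturated: bool = False


def _clamp(p: float, cfg: SonicationConfig, state: ControllerState) -> float:
    if p > cfg.p_max:
        state.saturated = True
        return cfg.p_max
    return max(p, cfg.p_min)


def next_pressure(state: ControllerState, sc_db_latest: float,
                  cfg: SonicationConfig) -> ControllerState:
    """Advance the controller one pulse given the latest SC level (dB).

    Ramp phase: step the pressure up by ``ramp_step`` until the target is
    reached, then hand over to the maintain phase at unchanged pressure.
    Maintain phase: bang-bang with a dead band — step down if above
    ``tcl + tol``, up if below ``tcl - tol``, hold otherwise.  The output is
    always clamped to ``[p_min, p_max]``; hitting the cap raises the
    saturation flag instead of aborting.
    """
    if state.phase not in (PHASE_RAMP, PHASE_MAINTAIN):
        raise ValueError(f"next_pressure undefined in phase {state.phase!r}")
    st = ControllerState(state.phase, state.pressure, state.saturated)
    if st.phase == PHASE_RAMP:
        reached = sc_db_latest >= cfg.tcl_db
        if cfg.ramp_entry == "within_band":
            reached = reached or abs(sc_db_latest - cfg.tcl_db) <= cfg.tol_db
        if reached:
            st.phase = PHASE_MAINTAIN
        else:
            st.pressure = _clamp(st.pressure + cfg.ramp_step, cfg, st)
        return st
    if sc_db_latest > cfg.tcl_db + cfg.tol_db:
        st.pressure = _clamp(st.pressure - cfg.maintain_step, cfg, st)
    elif sc_db_latest < cfg.tcl_db - cfg.tol_db:
        st.pressure = _clamp(st.pressure + cfg.maintain_step, cfg, st)
    return st


def run_treatment(plant, cfg: SonicationConfig, seed: int | None = None,
                  fs: float | None = None) -> TreatmentLog:
    """Run a full closed-loop session against a plant and log every pulse.

    ``plant`` is either a `cavloop.plant.Plant` (its sampling rate is used)
    or any callable mapping pressure (MPa) to a voltage trace, in which case
    ``fs`` must be given.  ``seed`` reseeds a stateful plant so the whole
    session is reproducible.
    """
    from .plant import Plant  # local import to keep module deps acyclic

    if isinstance(plant, Plant):
        if seed is not None:
            plant = Plant(plant.params, seed)
        else:
            plant.reset()
        fs = plant.fs
    if fs is None:
        raise ValueError("fs is required when plant is a bare callable")

    sc = cfg.sc_band()
    ic = cfg.ic_band()

    dummy_traces = [plant(cfg.dummy_pressure) for _ in range(cfg.n_dummy)]
    baseline = spectral.calibrate_baseline(dummy_traces, fs, sc, ic)

    log = TreatmentLog(config=cfg, baseline=baseline)

    def record(i: int, phase: str, pressure: float, trace) -> PulseRecord:
        lv = spectral.pulse_levels(trace, fs, sc, ic, baseline,
                                   cfg.db_convention)
        rec = PulseRecord(
            index=i, phase=phase, pressure=pressure,
            sc_linear=lv.sc_linear, ic_linear=lv.ic_linear,
            sc_db=lv.sc_db, ic_db=lv.ic_db,
            in_band=abs(lv.sc_db - cfg.tcl_db) <= cfg.tol_db,
            ic_event=lv.ic_db > cfg.ic_event_db)
        log.records.append(rec)
        return rec

    for i, tr in enumerate(dummy_traces):
        record(i, PHASE_DUMMY, cfg.dummy_pressure, tr)

    state = ControllerState(PHASE_RAMP,
                            min(cfg.dummy_pressure + cfg.ramp_step, cfg.p_max))
    for j in range(cfg.n_treat):
        trace = plant(state.pressure)
        rec = record(cfg.n_dummy + j, state.phase, state.pressure, trace)
        if cfg.stop_on_ic and rec.ic_event:
            break
        state = next_pressure(state, rec.sc_db, cfg)
    log.saturated = state.saturated
    return log


def _maintain(log: TreatmentLog) -> list[PulseRecord]:
    recs = log.maintain_records()
    if not recs:
        raise ValueError("log has no maintain-phase pulses")
    return recs


def good_pulse_rate(log: TreatmentLog) -> float:
    """Percent of maintain-phase pulses whose SC level is inside the band."""
    recs = _maintain(log)
    return 100.0 * sum(r.in_band for r in recs) / len(recs)


def ic_probability(log: TreatmentLog) -> float:
    """Percent of maintain-phase pulses flagged as IC events."""
    recs = _maintain(log)
    return 100.0 * sum(r.ic_event for r in recs) / len(recs)


def summarize_log(log: TreatmentLog) -> dict:
    """One-session summary mirroring the controller characterization stats."""
    maintain = log.maintain_records()
    return {
        "tcl_db": log.config.tcl_db,
        "good_pulse_rate_pct": good_pulse_rate(log),
        "ic_probability_pct": ic_probability(log),
        "n_ramp": log.n_ramp(),
        "mean_maintain_pressure_MPa":
            float(np.mean([r.pressure for r in maintain])),
        "saturated": log.saturated,
    }
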