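"""Synthetic continuous flow-cytometry event streams.

Emulates the continuous staining/incubation/measurement chain: the sample is
drawn from the reactor, diluted 1:1 with stain, held for the staining delay,
and measured at the cytometer flow rate with events recorded in 100 ms
acquisition windows. Event arrivals are Poisson with rate proportional to the
(delay-shifted) true concentration; fluorescence per event is drawn from
log-normal cluster kernels (LNA / HNA / PI-positive damaged / background).

Two staining modes are modelled:

* ``"SG"`` — SYBR Green only: every cell (intact or membrane-damaged) is
  stained and counted; the stream reflects TCC.
* ``"SG+PI"`` — SYBR Green + propidium iodide: intact cells appear in the
  normal clusters, membrane-damaged cells take up PI and shift to high red
  fluorescence (outside the intact gate); gated counts reflect ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import InstrumentModel, PopulationModel
from .reactor import Trajectory

__all__ = [
    "EventStream",
    "STAINING_MODES",
    "expected_events_per_window",
    "sample_fluorescence",
    "generate_event_stream",
]

STAINING_MODES = ("SG", "SG+PI")

_SUBPOPULATIONS = ("lna_intact", "hna_intact", "damaged_pi", "background")


@dataclass
class EventStream:
    """Ordered time-tagged fluorescence events from one staining channel."""

    staining_mode: str
    time_ms: np.ndarray
    fl1: np.ndarray
    fl3: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.staining_mode not in STAINING_MODES:
            raise ValueError(f"unknown staining mode {self.staining_mode!r}")
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.fl1 = np.asarray(self.fl1, dtype=float)
        self.fl3 = np.asarray(self.fl3, dtype=float)
        if not (len(self.time_ms) == len(self.fl1) == len(self.fl3)):
            raise ValueError("time_ms, fl1 and fl3 must have equal length")
        if np.any(np.diff(self.time_ms) < 0):
            raise ValueError("event time tags must be non-decreasing")

    def __len__(self) -> int:
        return len(self.time_ms)


def expected_events_per_window(concentration: float,
                               instrument: InstrumentModel | None = None,
                               window_ms: float = 100.0) -> float:
    """Expected cell-event count in one acquisition window (no background).

    The reactor concentration is halved by the 1:1 stain dilution and
    converted through the cytometer flow rate:
    ``conc / dilution * flow_rate[ul/min] * window[min]``.
    """
    inst = instrument if instrument is not None else InstrumentModel()
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if window_ms <= 0:
        raise ValueError("window must be positive")
    return (concentration / inst.staining_dilution_factor
            * inst.cytometer_flow_rate * window_ms / 60000.0)


def sample_fluorescence(populations: PopulationModel, subpopulation: str,
                        n: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (fl1, fl3) pairs from one subpopulation's log-normal kernel.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if subpopulation not in _SUBPOPULATIONS:
        raise ValueError(
            f"unknown subpopulation {subpopulation!r}; "
            f"expected one of {_SUBPOPULATIONS}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dist = getattr(populations, subpopulation if subpopulation != "damaged_pi"
                   else "damaged_pi")
    fl1 = 10.0 ** rng.normal(dist.fl1_mean, dist.fl1_sd, size=n)
    fl3 = 10.0 ** rng.normal(dist.fl3_mean, dist.fl3_sd, size=n)
    return fl1, fl3


def _blend_pct_lna(populations: PopulationModel, ww_fraction: np.ndarray,
                   mode: str) -> np.ndarray:
    """Origin-weighted LNA percentage of the stained community."""
    tap = (populations.tap_pct_lna_tcc if mode == "SG"
           else populations.tap_pct_lna_icc)
    ww = 100.0 - populations.wastewater_pct_hna
    return (1.0 - ww_fraction) * tap + ww_fraction * ww


def generate_event_stream(trajectory: Trajectory,
                          instrument: InstrumentModel | None = None,
                          populations: PopulationModel | None = None,
                          staining_mode: str = "SG",
                          seed: int | None = 0,
                          *, duration_min: float | None = None) -> EventStream:
    """Generate one staining channel's event stream from a true trajectory.

    Acquisition starts at reactor time zero (the instrument runs
    continuously); an event recorded at acquisition time ``t`` reflects the
    reactor state at ``t - staining_delay`` (plug-flow incubation loop).
    Before the delay has elapsed the loop still holds pre-experiment
    baseline water, i.e. the trajectory's initial state.

    ``duration_min`` defaults to trajectory end + staining delay, so the full
    trajectory is observed; longer spans raise, since the trajectory would
    have to extend beyond its last time point.
    """
    inst = instrument if instrument is not None else InstrumentModel()
    pops = populations if populations is not None else PopulationModel()
    if staining_mode not in STAINING_MODES:
        raise ValueError(f"unknown staining mode {staining_mode!r}")

    t_end = trajectory.span[1]
    if duration_min is None:
        duration_min = t_end + inst.staining_delay_min
    if duration_min - inst.staining_delay_min > t_end + 1e-9:
        raise ValueError(
            "trajectory too short for the requested acquisition span: "
            f"need reactor state up to {duration_min - inst.staining_delay_min:g} min, "
            f"trajectory ends at {t_end:g} min")

    window_ms = inst.acquisition_resolution_ms
    n_windows = int(round(duration_min * 60000.0 / window_ms))
    starts_ms = np.arange(n_windows) * window_ms
    centers_min = (starts_ms + window_ms / 2) / 60000.0
    # reactor time each window's sample left the reactor (clamped to start)
    reactor_t = np.maximum(centers_min - inst.staining_delay_min, 0.0)

    tcc = trajectory.at(reactor_t, "tcc")
    icc = trajectory.at(reactor_t, "icc")
    ww = trajectory.at(reactor_t, "wastewater_fraction")
    chlorine = trajectory.at(reactor_t, "chlorine")

    pct_lna = _blend_pct_lna(pops, ww, staining_mode) / 100.0

    if staining_mode == "SG":
        countable = tcc.copy()
        if pops.chlorine_fl1_drift > 0:
            # cumulative signal loss while chlorine is present: a growing
            # share of stained cells drifts below the detection threshold
            dt_min = window_ms / 60000.0
            exposed = np.cumsum((chlorine > 0.05) * dt_min)
            loss = np.minimum(pops.chlorine_fl1_drift * exposed, tcc)
            countable = tcc - loss
        rates = {
            "lna_intact": countable * pct_lna,
            "hna_intact": countable * (1 - pct_lna),
        }
        if pops.chlorine_fl1_drift > 0:
            rates["background"] = tcc - countable  # dimmed, sub-threshold
    else:
        rates = {
            "lna_intact": icc * pct_lna,
            "hna_intact": icc * (1 - pct_lna),
            "damaged_pi": np.maximum(tcc - icc, 0.0),
        }

    per_window_factor = (inst.cytometer_flow_rate
                         / inst.staining_dilution_factor
                         * window_ms / 60000.0)
    bg_rate = inst.background_event_rate * window_ms / 1000.0

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    times, fl1s, fl3s = [], [], []
    order = ["lna_intact", "hna_intact", "damaged_pi", "background"]
    for sub in order:
        if sub == "background":
            lam = np.full(n_windows, bg_rate)
            if "background" in rates:
                lam = lam + rates["background"] * per_window_factor
        elif sub in rates:
            lam = rates[sub] * per_window_factor
        else:
            continue
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        win = np.repeat(starts_ms, counts)
        t = win + rng.uniform(0, window_ms, size=total)
        f1, f3 = sample_fluorescence(pops, sub, total, rng)
        times.append(t)
        fl1s.append(f1)
        fl3s.append(f3)

    if times:
        t = np.concatenate(times)
        f1 = np.concatenate(fl1s)
        f3 = np.concatenate(fl3s)
        order_ix = np.argsort(t, kind="stable")
        t, f1, f3 = t[order_ix], f1[order_ix], f3[order_ix]
    else:
        t = np.array([])
        f1 = np.array([])
        f3 = np.array([])

    meta = {
        "staining_mode": staining_mode,
        "seed": seed,
        "duration_min": float(duration_min),
        "instrument": inst.model_dump(),
    }
    return EventStream(staining_mode=staining_mode, time_ms=t,
                       fl1=f1, fl3=f3, metadata=meta)
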