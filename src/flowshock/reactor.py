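"""Perfect-mixing (CSTR) mass-balance model of the stirred reactor.

The 80-min experiment has four phases: (1) tap-water baseline in batch mode,
(2) a 5-min syringe-pump pulse of pre-diluted wastewater followed by mixing,
(3) a 5-min pulse of hypochlorite followed by reaction, (4) flow-through
flushing with fresh tap water. Two levels of model are provided:

* :func:`predict_series` — the simple piecewise prediction that assumes no
  chlorine effect on cell counts: constant baseline, batch mixing during the
  contaminant pulse, constant plateau, and exponential washout at the
  dilution rate ``D = Q / V``.
* :func:`simulate_experiment` — a full state simulation (RK4) that adds
  first-order inactivation of intact cells by free chlorine, an empirical
  linear decline of total counts during chlorination, first-order chlorine
  demand, and origin-labelled cell balances (tap vs wastewater).

Units: volumes ml, flows ml/min, cell concentrations cells/ul, chlorine
mg/l, times min. Cell *amounts* are carried internally as
concentration x volume (cells/ul x ml == 1000 cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ExperimentConfig, KineticParams

__all__ = [
    "Trajectory",
    "volume_fraction_added",
    "washout_concentration",
    "chlorine_dose_concentration",
    "predict_series",
    "predict_tcc_series",
    "simulate_experiment",
]


class DegenerateInputError(ValueError):
    """Raised when an operation is evaluated on a degenerate input."""


@dataclass
class Trajectory:
    """Time-indexed true state of the reactor on a regular grid."""

    time: np.ndarray                 # min
    volume: np.ndarray               # ml
    tcc: np.ndarray                  # cells/ul
    icc: np.ndarray                  # cells/ul
    chlorine: np.ndarray             # mg/l free chlorine
    wastewater_fraction: np.ndarray  # of cells, in [0, 1]
    dilution_rate: np.ndarray        # 1/min (0 in batch mode)
    tcc_washed_out: np.ndarray = field(default=None)  # cumulative, cells/ul*ml

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.tcc_washed_out is None:
            self.tcc_washed_out = np.zeros(n)
        for name in ("volume", "tcc", "icc", "chlorine",
                     "wastewater_fraction", "dilution_rate", "tcc_washed_out"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must match the time grid length {n}")
            setattr(self, name, arr)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.icc > self.tcc * (1 + 1e-9) + 1e-9):
            raise ValueError("ICC must not exceed TCC")

    def at(self, t, column: str = "tcc"):
        """Linear interpolation of one state column at time(s) ``t`` (min).

        Values outside the grid are clamped to the end points (the reactor
        is assumed to sit at its initial/final state beyond the simulated
        span).
        """
        return np.interp(t, self.time, getattr(self, column))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.time,
            "volume_ml": self.volume,
            "tcc": self.tcc,
            "icc": self.icc,
            "chlorine_mg_l": self.chlorine,
            "wastewater_fraction": self.wastewater_fraction,
            "dilution_rate": self.dilution_rate,
            "tcc_washed_out": self.tcc_washed_out,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(
            time=df["time_min"].to_numpy(float),
            volume=df["volume_ml"].to_numpy(float),
            tcc=df["tcc"].to_numpy(float),
            icc=df["icc"].to_numpy(float),
            chlorine=df["chlorine_mg_l"].to_numpy(float),
            wastewater_fraction=df["wastewater_fraction"].to_numpy(float),
            dilution_rate=df["dilution_rate"].to_numpy(float),
            tcc_washed_out=df["tcc_washed_out"].to_numpy(float)
            if "tcc_washed_out" in df else None,
        )


def volume_fraction_added(rate: float, elapsed: float,
                          initial_volume: float) -> float:
    """Volume fraction (v/v) the injected stream occupies after ``elapsed`` min.

    ``rate * elapsed`` ml added to ``initial_volume`` ml under perfect mixing.
    """
    if rate < 0 or elapsed < 0 or initial_volume < 0:
        raise ValueError("rate, elapsed and initial_volume must be >= 0")
    added = rate * elapsed
    total = initial_volume + added
    if total <= 0:
        raise DegenerateInputError("total volume is zero")
    return added / total


def washout_concentration(c0: float, c_in: float, dilution_rate: float,
                          t) -> float:
    """CSTR washout: ``c_in + (c0 - c_in) * exp(-D * t)``."""
    if dilution_rate < 0:
        raise ValueError("dilution_rate must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = c_in + (c0 - c_in) * np.exp(-dilution_rate * t)
    return float(out) if out.ndim == 0 else out


def chlorine_dose_concentration(stock: float, rate: float, duration: float,
                                reference_volume: float) -> float:
    """Nominal free-chlorine concentration after a dosing pulse.

    Total dosed mass (``stock * rate * duration``) over the reference
    volume, ignoring demand: mg/l * ml/min * min / ml -> mg/l.
    """
    if min(stock, rate, duration, reference_volume) < 0:
        raise ValueError("all arguments must be >= 0")
    if reference_volume <= 0:
        raise DegenerateInputError("reference volume must be positive")
    return stock * rate * duration / reference_volume


def _batch_mix(c0: float, c_in: float, rate: float, elapsed,
               initial_volume: float):
    """Concentration while a stream at ``c_in`` is injected into a batch.

    Cell conservation with growing volume:
    ``(V0*c0 + r*t*c_in) / (V0 + r*t)``.
    """
    elapsed = np.asarray(elapsed, dtype=float)
    num = initial_volume * c0 + rate * elapsed * c_in
    den = initial_volume + rate * elapsed
    return num / den


def predict_series(config: ExperimentConfig | None = None, *,
                   dilution_volume: str = "nominal") -> Trajectory:
    """Piecewise no-chlorine-effect prediction of TCC/ICC at 1-min resolution.

    Phase 1 is constant at the tap-water level; phase 2 follows the batch
    mixing mass balance of the contaminant pulse and then holds the plateau;
    phase 3 assumes no effect of chlorine on cell counts; phase 4 relaxes
    exponentially back to the tap level at the dilution rate.

    ``dilution_volume`` selects the washout denominator: ``"nominal"`` uses
    the initial reactor volume (D = 100/500 = 0.2/min with defaults);
    ``"tracked"`` uses the volume including both injected pulses.
    """
    cfg = config if config is not None else ExperimentConfig()
    if dilution_volume not in ("nominal", "tracked"):
        raise ValueError("dilution_volume must be 'nominal' or 'tracked'")

    t = np.arange(0.0, cfg.total_duration + 1e-9, cfg.time_step)
    v0 = cfg.initial_volume
    added_c = cfg.contaminant_rate * cfg.contaminant_duration
    added_cl = cfg.chlorine_rate * cfg.chlorine_duration
    v_full = v0 + added_c + added_cl
    d = cfg.flowthrough_rate / (v0 if dilution_volume == "nominal" else v_full)

    t1, t2, t3 = cfg.contamination_start, cfg.chlorination_start, cfg.flowthrough_start
    t1e = t1 + cfg.contaminant_duration
    t2e = t2 + cfg.chlorine_duration

    def cells(tap: float, cont: float) -> tuple[np.ndarray, float, np.ndarray]:
        plateau = float(_batch_mix(tap, cont, cfg.contaminant_rate,
                                   cfg.contaminant_duration, v0))
        ww_plateau = float(_batch_mix(0.0, cont, cfg.contaminant_rate,
                                      cfg.contaminant_duration, v0))
        c = np.full_like(t, float(tap))
        ww = np.zeros_like(t)
        mix = (t > t1) & (t <= t1e)
        c[mix] = _batch_mix(tap, cont, cfg.contaminant_rate, t[mix] - t1, v0)
        ww[mix] = _batch_mix(0.0, cont, cfg.contaminant_rate, t[mix] - t1, v0)
        hold = (t > t1e) & (t <= t3)
        c[hold] = plateau
        ww[hold] = ww_plateau
        if dilution_volume == "tracked":
            # the chlorine pulse dilutes the cell pools by ~2.4% (v/v)
            ramp = (t > t2) & (t <= t2e)
            c[ramp] = _batch_mix(plateau, 0.0, cfg.chlorine_rate,
                                 t[ramp] - t2, v0 + added_c)
            ww[ramp] = _batch_mix(ww_plateau, 0.0, cfg.chlorine_rate,
                                  t[ramp] - t2, v0 + added_c)
            plateau = float(_batch_mix(plateau, 0.0, cfg.chlorine_rate,
                                       cfg.chlorine_duration, v0 + added_c))
            ww_plateau = float(_batch_mix(ww_plateau, 0.0, cfg.chlorine_rate,
                                          cfg.chlorine_duration, v0 + added_c))
            c[(t > t2e) & (t <= t3)] = plateau
            ww[(t > t2e) & (t <= t3)] = ww_plateau
        wash = t > t3
        c[wash] = washout_concentration(plateau, tap, d, t[wash] - t3)
        ww[wash] = washout_concentration(ww_plateau, 0.0, d, t[wash] - t3)
        return c, plateau, ww

    tcc, _, ww_tcc = cells(cfg.tap_tcc, cfg.contaminant_tcc)
    icc, _, _ = cells(cfg.tap_icc, cfg.contaminant_icc)

    dose = chlorine_dose_concentration(
        cfg.chlorine_stock, cfg.chlorine_rate, cfg.chlorine_duration,
        v0 if dilution_volume == "nominal" else v0 + added_c + added_cl)
    chlorine = np.zeros_like(t)
    ramp = (t > t2) & (t <= t2e)
    if dilution_volume == "tracked":
        chlorine[ramp] = _batch_mix(0.0, cfg.chlorine_stock,
                                    cfg.chlorine_rate, t[ramp] - t2,
                                    v0 + added_c)
    else:
        chlorine[ramp] = dose * (t[ramp] - t2) / cfg.chlorine_duration
    chlorine[(t > t2e) & (t <= t3)] = dose
    wash = t > t3
    chlorine[wash] = washout_concentration(dose, 0.0, d, t[wash] - t3)

    if dilution_volume == "nominal":
        volume = np.full_like(t, v0)
    else:
        volume = np.full_like(t, v0)
        volume[(t > t1) & (t <= t1e)] = v0 + cfg.contaminant_rate * (
            t[(t > t1) & (t <= t1e)] - t1)
        volume[(t > t1e) & (t <= t2)] = v0 + added_c
        volume[(t > t2) & (t <= t2e)] = v0 + added_c + cfg.chlorine_rate * (
            t[(t > t2) & (t <= t2e)] - t2)
        volume[t > t2e] = v_full

    dil = np.where(t >= t3, d, 0.0)
    frac = np.divide(ww_tcc, tcc, out=np.zeros_like(t), where=tcc > 0)
    return Trajectory(time=t, volume=volume, tcc=tcc, icc=icc,
                      chlorine=chlorine, wastewater_fraction=frac,
                      dilution_rate=dil)


def predict_tcc_series(config: ExperimentConfig | None = None,
                       **kwargs) -> Trajectory:
    """Alias of :func:`predict_series` (TCC is its headline column)."""
    return predict_series(config, **kwargs)


def simulate_experiment(config: ExperimentConfig | None = None,
                        kinetics: KineticParams | None = None,
                        *, step: float = 0.01) -> Trajectory:
    """Full kinetic state simulation of the experiment (fixed-step RK4).

    State: reactor volume, origin-labelled total-cell pools (tap /
    wastewater), origin-labelled intact pools split into chlorine-susceptible
    and resistant fractions, free chlorine, and cumulative washed-out total
    cells. While free chlorine exceeds ``kill_threshold``, susceptible intact
    cells die first order at ``icc_kill_rate``; while it exceeds
    ``tcc_decay_threshold``, total counts decline linearly at
    ``tcc_decay_rate`` (an empirical fluorescence-loss term). Chlorine is
    consumed first order at ``chlorine_demand_rate``.

    With all kinetic rates zero the result reduces to the pure mixing model.
    ``step`` is the internal RK4 step (min); output is on the config's
    ``time_step`` grid. Phase boundaries should be multiples of ``step``.
    """
    cfg = config if config is not None else ExperimentConfig()
    kin = kinetics if kinetics is not None else KineticParams()
    if step <= 0 or step > cfg.time_step + 1e-12:
        raise ValueError("step must be in (0, time_step]")

    fr = kin.icc_resistant_fraction
    t1, t2, t3 = cfg.contamination_start, cfg.chlorination_start, cfg.flowthrough_start
    t1e, t2e = t1 + cfg.contaminant_duration, t2 + cfg.chlorine_duration
    v0 = cfg.initial_volume

    # state vector: V, Ttap, Tww, Itap_s, Itap_r, Iww_s, Iww_r, Cl, out_T
    y0 = np.array([
        v0, cfg.tap_tcc, 0.0,
        cfg.tap_icc * (1 - fr), cfg.tap_icc * fr, 0.0, 0.0,
        0.0, 0.0,
    ])

    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        # t is the step midpoint: the injection regime is frozen per RK4
        # step so phase boundaries aligned to the step grid are exact
        V, Ttap, Tww, Is_t, Ir_t, Is_w, Ir_w, Cl, _ = y
        veff = V if cfg.track_volume else v0
        d = np.zeros_like(y)

        streams = []  # (flow ml/min, conc dict, grows_volume)
        if t1 <= t < t1e and cfg.contaminant_rate > 0:
            streams.append((cfg.contaminant_rate, {
                "Tww": cfg.contaminant_tcc,
                "Iww_s": cfg.contaminant_icc * (1 - fr),
                "Iww_r": cfg.contaminant_icc * fr,
            }, True))
        if t2 <= t < t2e and cfg.chlorine_rate > 0:
            streams.append((cfg.chlorine_rate, {"Cl": cfg.chlorine_stock}, True))
        flowthrough = t >= t3
        if flowthrough and cfg.flowthrough_rate > 0:
            streams.append((cfg.flowthrough_rate, {
                "Ttap": cfg.tap_tcc,
                "Itap_s": cfg.tap_icc * (1 - fr),
                "Itap_r": cfg.tap_icc * fr,
            }, False))

        idx = {"Ttap": 1, "Tww": 2, "Itap_s": 3, "Itap_r": 4,
               "Iww_s": 5, "Iww_r": 6, "Cl": 7}
        for q, conc, grows in streams:
            if grows and cfg.track_volume:
                d[0] += q
            for name, i in idx.items():
                cin = conc.get(name, 0.0)
                d[i] += q * (cin - y[i]) / veff

        # cumulative total cells leaving via the outflow (flow-through only)
        if flowthrough:
            d[8] = cfg.flowthrough_rate * (Ttap + Tww)

        d[7] -= kin.chlorine_demand_rate * Cl
        if Cl > kin.kill_threshold:
            d[3] -= kin.icc_kill_rate * Is_t
            d[5] -= kin.icc_kill_rate * Is_w
        if Cl > kin.tcc_decay_threshold and kin.tcc_decay_rate > 0:
            total = Ttap + Tww
            if total > 0:
                d[1] -= kin.tcc_decay_rate * Ttap / total
                d[2] -= kin.tcc_decay_rate * Tww / total
        return d

    n_steps = int(round(cfg.total_duration / step))
    every = max(1, int(round(cfg.time_step / step)))
    if abs(every * step - cfg.time_step) > 1e-9:
        raise ValueError("time_step must be a multiple of step")

    times = [0.0]
    states = [y0.copy()]
    y = y0.copy()
    for i in range(n_steps):
        tm = (i + 0.5) * step
        k1 = deriv(tm, y)
        k2 = deriv(tm, y + step / 2 * k1)
        k3 = deriv(tm, y + step / 2 * k2)
        k4 = deriv(tm, y + step * k3)
        y = y + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        y[1:8] = np.maximum(y[1:8], 0.0)  # floor concentrations at 0
        if (i + 1) % every == 0:
            times.append((i + 1) * step)
            states.append(y.copy())

    arr = np.array(states)
    time = np.array(times)
    volume = arr[:, 0] if cfg.track_volume else np.full_like(time, v0)
    tcc = arr[:, 1] + arr[:, 2]
    icc = np.minimum(arr[:, 3] + arr[:, 4] + arr[:, 5] + arr[:, 6], tcc)
    chlorine = arr[:, 7]
    frac = np.divide(arr[:, 2], tcc, out=np.zeros_like(tcc), where=tcc > 0)
    dil = np.where(time >= t3,
                   cfg.flowthrough_rate / volume, 0.0)
    return Trajectory(time=time, volume=volume, tcc=tcc, icc=icc,
                      chlorine=chlorine, wastewater_fraction=frac,
                      dilution_rate=dil, tcc_washed_out=arr[:, 8] / 1.0)
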