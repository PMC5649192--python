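"""Configuration models for the reactor, instrument, populations and gates.

All models are strict pydantic models: unknown keys are rejected so that a
typo in a YAML file fails loudly instead of silently falling back to a
default. Units are embedded in field names or documented per field; times
are minutes from experiment start (reactor frame) unless stated otherwise.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ExperimentConfig",
    "KineticParams",
    "InstrumentModel",
    "FluorescenceDistribution",
    "PopulationModel",
    "GateSet",
    "RunConfig",
    "load_config",
    "default_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ExperimentConfig(_StrictModel):
    """Reactor geometry, phase schedule and injection parameters.

    Defaults describe a 500 ml stirred drinking-water reactor that receives
    a 5-min pulse of 10-fold pre-diluted wastewater, a 5-min pulse of
    hypochlorite solution, and is finally flushed with fresh tap water in
    flow-through mode.
    """

    initial_volume: float = Field(500.0, ge=0, description="ml")
    tap_tcc: float = Field(130.6, ge=0, description="cells/ul in tap water")
    tap_icc: float = Field(99.6, ge=0, description="cells/ul in tap water")
    contaminant_tcc: float = Field(14700.0, ge=0, description="cells/ul")
    contaminant_icc_fraction: float = Field(
        0.67, ge=0, le=1,
        description="intact fraction of contaminant cells (plateau-implied)",
    )
    contaminant_rate: float = Field(3.0, ge=0, description="ml/min")
    contaminant_duration: float = Field(5.0, ge=0, description="min")
    chlorine_stock: float = Field(72.0, ge=0, description="mg/l free chlorine")
    chlorine_rate: float = Field(2.5, ge=0, description="ml/min")
    chlorine_duration: float = Field(5.0, ge=0, description="min")
    flowthrough_rate: float = Field(100.0, ge=0, description="ml/min")
    phase_start_times: tuple[float, float, float, float] = Field(
        (0.0, 15.0, 30.0, 45.0),
        description="min: baseline, contamination, chlorination, flow-through",
    )
    total_duration: float = Field(80.0, gt=0, description="min")
    time_step: float = Field(1.0, gt=0, description="min, output grid")
    track_volume: bool = Field(
        True,
        description=(
            "If True, injections grow the reactor volume and the flow-through "
            "dilution rate uses the true volume; if False the nominal initial "
            "volume is used throughout (the published approximation)."
        ),
    )

    @model_validator(mode="after")
    def _check_schedule(self) -> "ExperimentConfig":
        t = self.phase_start_times
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("phase_start_times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("phase start times must be >= 0")
        if self.total_duration <= t[-1]:
            raise ValueError("total_duration must exceed the last phase start")
        if self.contaminant_icc > self.contaminant_tcc:
            raise ValueError("contaminant ICC cannot exceed contaminant TCC")
        if self.tap_icc > self.tap_tcc:
            raise ValueError("tap ICC cannot exceed tap TCC")
        return self

    @property
    def contaminant_icc(self) -> float:
        """Intact cell concentration of the contaminant, cells/ul."""
        return self.contaminant_tcc * self.contaminant_icc_fraction

    @property
    def contamination_start(self) -> float:
        return self.phase_start_times[1]

    @property
    def chlorination_start(self) -> float:
        return self.phase_start_times[2]

    @property
    def flowthrough_start(self) -> float:
        return self.phase_start_times[3]

    @property
    def nominal_dilution_rate(self) -> float:
        """Flow-through dilution rate over the nominal reactor volume, 1/min."""
        return self.flowthrough_rate / self.initial_volume


class KineticParams(_StrictModel):
    """Empirical chlorination kinetics layered on top of the mixing model.

    The intact population is split into a susceptible and a small resistant
    pool; free chlorine above ``kill_threshold`` removes susceptible intact
    cells at ``icc_kill_rate`` (first order). Total counts decline linearly at
    ``tcc_decay_rate`` while chlorine exceeds ``tcc_decay_threshold`` —
    an empirical stand-in for progressive DNA damage weakening the green
    fluorescence signal, not physical cell removal. Chlorine itself decays
    first order at ``chlorine_demand_rate`` in addition to washout.
    """

    icc_kill_rate: float = Field(1.5, ge=0, description="1/min")
    icc_resistant_fraction: float = Field(0.051, ge=0, le=1)
    tcc_decay_rate: float = Field(10.6, ge=0, description="cells/ul/min")
    tcc_decay_threshold: float = Field(0.5, ge=0, description="mg/l")
    chlorine_demand_rate: float = Field(0.04, ge=0, description="1/min")
    kill_threshold: float = Field(0.05, ge=0, description="mg/l free chlorine")

    @classmethod
    def zero(cls) -> "KineticParams":
        """Pure-mixing kinetics: no kill, no decay, no chlorine demand."""
        return cls(icc_kill_rate=0.0, tcc_decay_rate=0.0,
                   chlorine_demand_rate=0.0)


class InstrumentModel(_StrictModel):
    """Continuous-staining flow cytometer front end.

    The sample is drawn continuously, mixed 1:1 with stain
    (``staining_dilution_factor`` 2), incubated for ``staining_delay_min``
    minutes in a flow loop, and measured at ``cytometer_flow_rate`` with
    events recorded in ``acquisition_resolution_ms`` windows. Events whose
    green fluorescence falls below ``detection_threshold_fl1`` are not
    counted as cells.
    """

    cytometer_flow_rate: float = Field(14.0, gt=0, description="ul/min")
    acquisition_resolution_ms: float = Field(100.0, gt=0)
    staining_dilution_factor: float = Field(2.0, ge=1)
    staining_delay_min: float = Field(10.0, ge=0)
    detection_threshold_fl1: float = Field(1000.0, ge=0)
    background_event_rate: float = Field(2.0, ge=0, description="events/s")


class FluorescenceDistribution(_StrictModel):
    """Log-normal fluorescence kernel for one subpopulation (log10 space)."""

    fl1_mean: float  # log10 green fluorescence
    fl1_sd: float = Field(gt=0)
    fl3_mean: float  # log10 red fluorescence
    fl3_sd: float = Field(gt=0)


class PopulationModel(_StrictModel):
    """Fluorescence clusters and community composition for the generator.

    LNA (low nucleic-acid) and HNA (high nucleic-acid) clusters differ in
    green fluorescence; membrane-damaged cells stained with SYBR Green +
    propidium iodide acquire strong red fluorescence. Composition over time
    is an origin-weighted blend of the tap-water and wastewater fingerprints.
    """

    lna_intact: FluorescenceDistribution = FluorescenceDistribution(
        fl1_mean=3.4, fl1_sd=0.15, fl3_mean=2.6, fl3_sd=0.2)
    hna_intact: FluorescenceDistribution = FluorescenceDistribution(
        fl1_mean=4.25, fl1_sd=0.16, fl3_mean=2.7, fl3_sd=0.2)
    damaged_pi: FluorescenceDistribution = FluorescenceDistribution(
        fl1_mean=3.3, fl1_sd=0.2, fl3_mean=4.3, fl3_sd=0.2)
    background: FluorescenceDistribution = FluorescenceDistribution(
        fl1_mean=2.3, fl1_sd=0.25, fl3_mean=1.8, fl3_sd=0.3)
    tap_pct_lna_tcc: float = Field(65.0, ge=0, le=100)
    tap_pct_lna_icc: float = Field(71.0, ge=0, le=100)
    wastewater_pct_hna: float = Field(61.3, ge=0, le=100)
    chlorine_fl1_drift: float = Field(
        0.0, ge=0,
        description=(
            "cells/ul/min pushed below the detection threshold while chlorine "
            "is present; use only with a trajectory whose TCC does not "
            "already carry the chlorination decline"
        ),
    )

    @model_validator(mode="after")
    def _check_clusters(self) -> "PopulationModel":
        if not self.lna_intact.fl1_mean < self.hna_intact.fl1_mean:
            raise ValueError("LNA cluster must sit below HNA on FL1")
        if not self.damaged_pi.fl3_mean > self.lna_intact.fl3_mean:
            raise ValueError("PI-positive cluster must sit above intact on FL3")
        return self


class GateSet(_StrictModel):
    """Fixed gates in (log10 FL1, log10 FL3) space.

    ``fl1_threshold`` is applied first (instrument detection threshold, linear
    units); ``bacteria_gate`` separates cells from background; in SG+PI mode
    ``intact_gate`` additionally excludes PI-positive (membrane-damaged)
    events. ``lna_hna_boundary`` (linear FL1 units) splits the bacterial gate
    into LNA (below) and HNA (at or above).
    """

    fl1_threshold: float = Field(1000.0, ge=0)
    bacteria_gate: list[tuple[float, float]] = Field(
        default=[(3.0, 1.0), (5.5, 1.0), (5.5, 5.0), (3.0, 5.0)])
    intact_gate: list[tuple[float, float]] = Field(
        default=[(3.0, 1.0), (5.5, 1.0), (5.5, 3.5), (3.0, 3.5)])
    lna_hna_boundary: float = Field(10.0 ** 3.8, gt=0)

    @model_validator(mode="after")
    def _check_polygons(self) -> "GateSet":
        from shapely.geometry import Polygon

        for name in ("bacteria_gate", "intact_gate"):
            pts = getattr(self, name)
            if len(pts) < 3:
                raise ValueError(f"{name} needs at least 3 vertices")
            poly = Polygon(pts)
            if not poly.is_valid or not poly.is_simple:
                raise ValueError(f"{name} polygon must be simple (non-self-intersecting)")
        lo = min(p[0] for p in self.bacteria_gate)
        hi = max(p[0] for p in self.bacteria_gate)
        import math

        b = math.log10(self.lna_hna_boundary)
        if not (lo <= b <= hi):
            raise ValueError("lna_hna_boundary must lie within the bacteria gate FL1 extent")
        return self


class RunConfig(_StrictModel):
    """Complete parameterization of one in-silico experiment replay."""

    experiment: ExperimentConfig = ExperimentConfig()
    kinetics: KineticParams = KineticParams()
    instrument: InstrumentModel = InstrumentModel()
    populations: PopulationModel = PopulationModel()
    gates: GateSet = GateSet()


def default_config() -> RunConfig:
    """The packaged default run: the published 80-min experiment."""
    return load_config(Path(__file__).parent / "data" / "default_run.yaml")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration from YAML (or JSON).

    An empty file yields all defaults; unknown keys raise a validation
    error naming the offending key.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)
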