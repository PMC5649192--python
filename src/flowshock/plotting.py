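"""Standard views of a replay: concentration time series and prediction overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .config import ExperimentConfig
from .gating import BinnedSeries
from .reactor import Trajectory

__all__ = ["plot_series", "plot_comparison"]


def _shade_phases(ax, config: ExperimentConfig) -> None:
    c = config
    ax.axvspan(c.contamination_start,
               c.contamination_start + c.contaminant_duration,
               color="purple", alpha=0.25, lw=0)
    ax.axvspan(c.contamination_start + c.contaminant_duration,
               c.chlorination_start, color="purple", alpha=0.08, lw=0)
    ax.axvspan(c.chlorination_start,
               c.chlorination_start + c.chlorine_duration,
               color="orange", alpha=0.25, lw=0)
    ax.axvspan(c.chlorination_start + c.chlorine_duration,
               c.flowthrough_start, color="orange", alpha=0.08, lw=0)


def plot_series(series: BinnedSeries, config: ExperimentConfig | None = None,
                ax=None, label: str | None = None, color=None):
    """1-min concentration series with injection phases shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    cfg = config if config is not None else ExperimentConfig()
    _shade_phases(ax, cfg)
    ax.plot(series.bin_center_min, series.concentration, "o-", ms=3,
            label=label or series.staining_mode, color=color)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cells / µl")
    ax.legend()
    return ax


def plot_comparison(measured: BinnedSeries, predicted: Trajectory,
                    column: str = "tcc", ax=None):
    """Measured 1-min values against the mixing-model prediction."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.plot(predicted.time, getattr(predicted, column), "k.-", ms=4,
            label="calculated")
    ax.plot(measured.bin_center_min, measured.concentration, "o", ms=4,
            color="tab:green", label="measured")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cells / µl")
    ax.legend()
    return ax
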