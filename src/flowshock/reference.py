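"""Benchmark measurements from the reference laboratory experiment.

The package replays, in silico, a published laboratory shock-chlorination
experiment for which no raw data were deposited; what survives are the
summary numbers printed in the report. This module carries those numbers as
a typed, citable-in-code table so tests, docs and the acceptance script all
draw on a single source, each value labelled with what was measured and when.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ReferenceValue", "reported_values", "get", "ChlorineSamples",
           "chlorine_samples", "DETECTION_LIMIT_MG_L"]

DETECTION_LIMIT_MG_L = 0.05  # DPD colorimetric kit, linear range 0.05-2 mg/l


@dataclass(frozen=True)
class ReferenceValue:
    value: float
    units: str
    context: str


_VALUES: dict[str, ReferenceValue] = {
    "tap_tcc_mean": ReferenceValue(130.6, "cells/ul",
                                   "baseline tap-water TCC, minutes 1-15 (n=15)"),
    "tap_tcc_sd": ReferenceValue(8.3, "cells/ul", "baseline TCC sample SD"),
    "tap_icc_mean": ReferenceValue(99.6, "cells/ul",
                                   "baseline tap-water ICC, minutes 1-15 (n=15)"),
    "tap_icc_sd": ReferenceValue(5.9, "cells/ul", "baseline ICC sample SD"),
    "baseline_n": ReferenceValue(15, "bins", "baseline bins used for the stats"),
    "contaminant_tcc": ReferenceValue(
        14700.0, "cells/ul",
        "offline TCC of the 10-fold pre-diluted wastewater"),
    "tcc_peak": ReferenceValue(679.4, "cells/ul",
                               "maximum measured TCC, 30 min"),
    "icc_plateau_mean": ReferenceValue(
        383.3, "cells/ul", "post-contamination ICC plateau (8 min window)"),
    "icc_plateau_sd": ReferenceValue(10.6, "cells/ul", "ICC plateau SD"),
    "icc_postchlorination_mean": ReferenceValue(
        19.6, "cells/ul", "ICC floor held for 25 min after chlorination"),
    "icc_postchlorination_sd": ReferenceValue(3.7, "cells/ul",
                                              "ICC floor SD"),
    "tcc_decline_rate": ReferenceValue(
        10.6, "cells/ul/min",
        "linear TCC decline during chlorination, minutes 31-46"),
    "chlorine_dose": ReferenceValue(
        1.8, "mg/l", "calculated initial free-chlorine concentration"),
    "chlorine_t35": ReferenceValue(
        1.46, "mg/l", "grab sample 35 min (5 min after dosing finished)"),
    "chlorine_t45": ReferenceValue(1.09, "mg/l", "grab sample 45 min"),
    "chlorine_t55": ReferenceValue(
        0.138, "mg/l", "grab sample 55 min (10 min into washout)"),
    "chlorine_consumption_5min": ReferenceValue(
        0.34, "mg/l", "dose minus the 35-min grab sample"),
    "pct_lna_tap_tcc": ReferenceValue(65.0, "%",
                                      "LNA share of tap-water TCC, 10 min"),
    "pct_lna_contaminated_tcc": ReferenceValue(
        29.0, "%", "LNA share of contaminated-mixture TCC, 25 min"),
    "pct_lna_tap_icc": ReferenceValue(71.0, "%",
                                      "LNA share of tap-water ICC, 10 min"),
    "pct_lna_contaminated_icc": ReferenceValue(
        37.0, "%", "LNA share of contaminated-mixture ICC, 25 min"),
    "wastewater_pct_hna": ReferenceValue(
        61.3, "%", "HNA share of the raw wastewater community"),
    "dilution_rate": ReferenceValue(
        0.2, "1/min", "flow-through rate over the nominal reactor volume"),
    "tcc_return_level": ReferenceValue(
        140.0, "cells/ul", "approximate TCC after washout"),
    "icc_return_level": ReferenceValue(
        95.0, "cells/ul", "approximate ICC after washout"),
    "onset_minute_tcc": ReferenceValue(
        16.0, "min", "TCC deviation detectable 1 min after addition began"),
    "icc_collapse_within_min": ReferenceValue(
        4.0, "min", "ICC fell from >380 to <30 cells/ul within this span"),
}


def reported_values() -> dict[str, ReferenceValue]:
    """All printed benchmark values, keyed by short name."""
    return dict(_VALUES)


def get(key: str) -> float:
    """Value of one benchmark quantity; unknown keys raise ``KeyError``."""
    try:
        return _VALUES[key].value
    except KeyError:
        raise KeyError(
            f"unknown reference key {key!r}; known keys: "
            f"{sorted(_VALUES)}") from None


@dataclass(frozen=True)
class ChlorineSamples:
    """Grab-sample chlorine measurements (DPD colorimetric assay).

    ``below_detection`` flags samples under the kit's detection limit; their
    ``concentration`` entries are NaN, never 0 — "below detection" is a
    distinct observation from "zero".
    """

    sample_times: tuple[float, ...]        # min after experiment start
    concentration: tuple[float, ...]       # mg/l, NaN where flagged
    below_detection: tuple[bool, ...]
    detection_limit: float = DETECTION_LIMIT_MG_L

    def __post_init__(self) -> None:
        if list(self.sample_times) != sorted(self.sample_times):
            raise ValueError("sample times must be sorted")
        if not (len(self.sample_times) == len(self.concentration)
                == len(self.below_detection)):
            raise ValueError("fields must have equal length")
        for c, bd in zip(self.concentration, self.below_detection):
            if bd and not math.isnan(c):
                raise ValueError("below-detection samples must carry NaN")
            if not bd and not c >= 0:
                raise ValueError("concentrations must be >= 0")


def chlorine_samples() -> ChlorineSamples:
    """The experiment's grab-sample series (printed values only).

    Samples at 40 and 50 min were taken but their numbers were not printed;
    they are omitted here rather than guessed.
    """
    nan = float("nan")
    return ChlorineSamples(
        sample_times=(10.0, 20.0, 35.0, 45.0, 55.0, 60.0),
        concentration=(nan, nan, 1.46, 1.09, 0.138, nan),
        below_detection=(True, True, False, False, False, True),
    )
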