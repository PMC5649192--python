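# Methods

This note records the models behind `flowshock`, the parameter choices that
matter, what the synthetic data generator does and does not emulate, and the
numerical conventions. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Reactor model

The reactor is treated as perfectly mixed at all times. Two model levels are
provided on purpose.

**Prediction (`predict_series`).** The simple calculation an operator would
make before the experiment: baseline constant at the measured tap level
(TCC 130.6, ICC 99.6 cells µl⁻¹); cell-conserving batch mixing during the
contaminant pulse, giving the plateau (500·130.6 + 15·14,700)/515 ≈ 555
cells µl⁻¹; no chlorine effect on counts; exponential washout at
D = Q/V₀ = 100/500 = 0.2 min⁻¹. Two volume conventions are exposed because
the original calculation's choice is ambiguous: `dilution_volume="nominal"`
(default) uses the initial 500 ml for the washout denominator and the
chlorine dose; `"tracked"` uses the true volume including both pulses
(527.5 ml, D ≈ 0.19 min⁻¹) and additionally accounts for the ~2.4% (v/v)
dilution of the cell pools by the chlorine pulse. The tracked prediction is
exactly the zero-kinetics limit of the simulator (tested to machine
precision).

**Simulator (`simulate_experiment`).** A fixed-step RK4 integration
(default 0.01 min) of volume, origin-labelled cell pools, free chlorine, and
cumulative outflow. The injection regime is frozen per step at the step
midpoint so phase boundaries that coincide with the step grid are handled
exactly; phase times should be multiples of the step. Kinetic terms, all
empirical:

| parameter | default | units | why |
|---|---|---|---|
| `icc_kill_rate` | 1.5 | min⁻¹ | susceptible intact cells must fall from ≈383 to <30 cells µl⁻¹ within 4 min of chlorine arrival, requiring k ≥ ln(383/30)/4 ≈ 0.64; 1.5 makes the collapse complete within ~2–3 min as observed |
| `icc_resistant_fraction` | 0.051 | — | pure first-order kill drives ICC to 0, but the observed post-chlorination ICC holds a stable floor of ≈19.6 cells µl⁻¹ (≈5.1% of the plateau) for 25 min; a two-pool susceptible/resistant population reproduces both collapse and floor |
| `tcc_decay_rate` | 10.6 | cells µl⁻¹ min⁻¹ | observed linear TCC decline during chlorination; modelled as a zero-order loss (progressive DNA damage reducing stain binding), not physical cell removal |
| `tcc_decay_threshold` | 0.5 | mg l⁻¹ | the linear decline is observed only while chlorine is high (roughly the dosing + reaction window); without a cutoff the zero-order term would keep draining TCC far below tap level throughout washout |
| `chlorine_demand_rate` | 0.04 | min⁻¹ | first-order demand; reproduces the 45-min grab sample (1.09 mg l⁻¹) from the 1.8 mg l⁻¹ dose. A single first-order term cannot also capture the fast initial consumption (0.34 mg l⁻¹ within 5 min of dosing); that mismatch is accepted and documented |
| `kill_threshold` | 0.05 | mg l⁻¹ | the DPD kit's detection limit. A threshold of exactly 0 would prevent ICC from ever recovering (the simulated chlorine trace is strictly positive); 0.05 puts the simulated ICC recovery at ≈58–59 min, i.e. after roughly three reactor volume changes, matching the observed behaviour |

Contaminant ICC is not directly known; its intact fraction defaults to 0.67,
back-solved so the predicted ICC plateau matches the measured 383.3
cells µl⁻¹.

The measured TCC decline over minutes 31–45 is slightly steeper (≈11
cells µl⁻¹ min⁻¹) than the configured 10.6, because the chlorine pulse
itself dilutes the cell pools during minutes 30–35 in the volume-tracked
simulation; this is physical, not an artifact.

## Synthetic event streams

Event arrivals per 100 ms acquisition window are Poisson with mean
`C/2 × 14 µl min⁻¹ × window`, where the factor 2 is the 1:1 staining
dilution (applied in generation and inverted in the pipeline — both sides
read the same configured value). The 10-min staining/incubation delay is a
pure time shift (plug flow); before one delay has elapsed the incubation
loop holds pre-experiment baseline water. An optional Gaussian smearing of
the delay is *not* implemented; the delay ambiguity at phase edges is below
the 1-min bin width.

Fluorescence kernels are log-normal per channel per subpopulation, chosen
so the FL1 detection threshold (1000) excludes background (log₁₀ mean 2.3)
but clips <0.5% of the dimmest bacterial cluster (LNA, log₁₀ mean 3.4,
sd 0.15); HNA sits at log₁₀ 4.25; PI-positive membrane-damaged cells under
SG+PI staining at log₁₀ FL3 4.3, well above the intact gate's 3.5 ceiling.
Community composition over time is an origin-weighted blend of the tap
fingerprint (65% LNA for TCC, 71% for ICC) and the wastewater fingerprint
(61.3% HNA). The generator supports an optional `chlorine_fl1_drift`
(cells µl⁻¹ min⁻¹ pushed below threshold while chlorine is present) for
users who drive it with a pure-mixing trajectory; it defaults to 0 because
the default replay's trajectory already carries the chlorination TCC
decline, and applying both would double-count the effect.

What the generator does **not** emulate: scatter channels, doublets and cell
aggregates (which bias real counts low), fluidics noise, gradual stain or
laser drift, axial dispersion in the incubation loop, and the unexplained
TCC overshoot to 679 cells µl⁻¹ the real experiment recorded above the
mixing plateau of 555. It also blends fingerprints strictly by cell origin,
giving ≈45% LNA for the contaminated mixture where the real measurement
showed 29% — the real wastewater community shifted the fingerprint more
than proportionally. Passing tests therefore demonstrate correctness of the
event-processing chain and the statistics under an idealised instrument,
not robustness to these real-data effects.

## Event pipeline conventions

- Gating is threshold-first: FL1 < 1000 is background regardless of any
  polygon. Gates are simple polygons in (log₁₀FL1, log₁₀FL3); the bacteria
  gate spans FL3 up to 10⁵ so that, under SG-only staining, every stained
  cell is counted, while the intact gate caps FL3 at 10³·⁵ so PI-positive
  events are background in SG+PI mode. Events exactly on the LNA/HNA
  boundary (10³·⁸) count as HNA.
- Bins are half-open `[k·60 s, (k+1)·60 s)`, left-anchored at acquisition
  time zero; bin timestamps are the bin start. Alignment subtracts the
  staining delay so series refer to reactor sampling time.
- Empty bins get concentration 0 and an undefined-fingerprint flag (never
  0/0). Events with non-positive or non-finite fluorescence are rejected and
  counted.
- The concentration estimator `count/(14 µl min⁻¹ × 1 min) × 2` is the exact
  algebraic inverse of the generator's rate model (property-tested).

## Analysis choices

- Baseline: mean and sample SD over the 15 bins of minutes 0–15. The
  simulated baseline SD (~3.8 cells µl⁻¹ for TCC) is pure Poisson counting
  noise; the real instrument's was larger (8.3), since real noise includes
  staining and fluidics variability the generator does not model.
- Onset: first of `min_consecutive = 2` consecutive bins beyond
  mean ± 3·SD. With SD = 0 any deviation triggers (documented edge case).
  The rule is this package's own; detection timing is reported as the bin
  in which the deviation begins.
- Chlorination decline: OLS on bin centers over reactor minutes 31–45. The
  window ends at the flow-through switch because a bin straddling the regime
  change would mix the washout plunge into the linear fit; the window is an
  argument, not a constant.
- Washout: `c(t) = a + b·e^(−rt)` by Levenberg–Marquardt (scipy
  `curve_fit`), rate bounded ≥ 0; failure (non-convergence, constant input,
  or rate variance > 10× the rate) is an explicit status, never a silent
  number.
- Comparison vs prediction: prediction interpolated at bin centers;
  RMSE/max-residual computed outside the chlorination-affected window,
  defined a priori as [chlorine start, flow-through start + 3/D] = minutes
  [30, 60] — the prediction assumes no chlorine effect, and any
  chlorine-induced deviation decays at the dilution rate once flow-through
  begins, reaching <5% of its initial size after three volume changes. Lag
  is the argmax of the cross-correlation over integer bin shifts (±5).

## Problem sizes

The default replay simulates 80 reactor minutes at 0.01-min RK4 steps,
generates two 90-min event streams (≈150,000 events each at 100 ms
resolution), and reduces them to 80 aligned 1-min bins per staining mode;
one replay takes about a second. The washout-recovery study refits 35-bin
Poisson-noise series across 100 seeds. These sizes match the original
experiment's design rather than shrinking it.

## Known limitations

- Chlorine chemistry is a single first-order demand; no speciation, pH
  dependence, or CT (concentration × time) dose–response modelling.
- The TCC fluorescence-loss term is zero-order with a hard chlorine
  threshold; a concentration-proportional damage model would be smoother but
  is not what the observations constrain.
- No FCS 3.x import/export; event streams are CSV with a JSON metadata
  sidecar (TIME/FL1/FL3 columns map one-to-one onto instrument exports).
- Gate coordinates ship as editable defaults matched to the generator's
  clusters; they are not calibrated to any physical instrument.
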