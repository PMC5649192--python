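# flowshock

An in-silico replay of a laboratory-scale drinking-water contamination and
shock-chlorination experiment, tracked by continuous real-time flow
cytometry.

## The problem

Wastewater ingress can contaminate a drinking-water reservoir within
minutes, and emergency shock-chlorination must be monitored just as fast.
Continuous flow cytometry (FCM) with automated staining can deliver total
(TCC) and intact (ICC) cell concentrations at 1-min resolution: a sample
stream is drawn continuously from the reactor, mixed 1:1 with SYBR Green
(TCC) or SYBR Green + propidium iodide (ICC), incubated for 10 min in a flow
loop, and measured event-by-event at 100 ms resolution. This package
reproduces, end to end and in software, an 80-min bench experiment of that
design: a 500 ml stirred reactor receives 15 min of tap-water baseline, a
5-min pulse of pre-diluted wastewater (3 ml min⁻¹ at 14,700 cells µl⁻¹), a
5-min pulse of hypochlorite (2.5 ml min⁻¹ at 72 mg l⁻¹, ≈1.8 mg l⁻¹ in the
reactor), and finally 35 min of tap-water flow-through at 100 ml min⁻¹.

It is intended for people developing or validating event-stream analysis for
online microbial water-quality monitoring: every stage downstream of the
physical instrument is testable against known ground truth.

## The model

Four composable stages:

1. **Reactor** (`flowshock.reactor`) — perfect-mixing (CSTR) mass balances.
   The pure prediction is piecewise analytic: constant baseline; batch
   mixing `C(t) = (V₀C₀ + rt·C_in)/(V₀ + rt)` during injection; constant
   plateau ("no chlorine effect"); exponential washout
   `C(t) = C_tap + (C_peak − C_tap)·e^(−Dt)` at dilution rate
   `D = Q/V = 100/500 = 0.2 min⁻¹`. The full simulator adds first-order
   inactivation of chlorine-susceptible intact cells (with a small resistant
   pool), an empirical linear TCC decline of 10.6 cells µl⁻¹ min⁻¹ while
   free chlorine is high (fluorescence loss from DNA damage), first-order
   chlorine demand, and origin-labelled (tap vs wastewater) cell balances.
2. **Instrument** (`flowshock.instrument`) — Poisson event arrivals at
   `λ = C/2 × 14 µl min⁻¹` per unit time (1:1 stain dilution, 14 µl min⁻¹
   cytometer flow), 100 ms acquisition windows, a 10-min plug-flow staining
   delay, log-normal fluorescence clusters (LNA/HNA on green FL1,
   PI-positive membrane-damaged cells on red FL3), and sub-threshold
   background events.
3. **Pipeline** (`flowshock.gating`) — threshold-first fixed gating (FL1 ≥
   1000), bacteria/intact polygons in (log₁₀FL1, log₁₀FL3) space, LNA/HNA
   split at FL1 = 10³·⁸, half-open 60-s binning by event time tag,
   concentration = count/(14 µl min⁻¹ × 1 min) × 2, and delay alignment.
4. **Analysis** (`flowshock.analysis`) — baseline mean ± SD, k-sigma onset
   detection, OLS decline rate, nonlinear washout fit
   `c(t) = a + b·e^(−rt)`, percent reduction / fold increase / volume
   changes, and residual/RMSE/lag comparison against the prediction.

## Worked example

```python
from flowshock import RunConfig, run_replay

result = run_replay(RunConfig(), seed=1)
r = result.report
print(f"baseline TCC  {r['baseline_tcc']['mean']:.1f} ± "
      f"{r['baseline_tcc']['sd']:.1f} cells/ul (n={r['baseline_tcc']['n']})")
print(f"TCC onset at minute {r['onset_tcc_min']:.0f} bin")
print(f"chlorination TCC slope {r['chlorination_slope']:.1f} cells/ul/min")
print(f"ICC reduction {r['icc_reduction_pct']:.1f} %")
print(f"washout rate  {r['washout_rate']:.3f} /min")
```

prints

```
baseline TCC  130.7 ± 3.8 cells/ul (n=15)
TCC onset at minute 15 bin
chlorination TCC slope -10.8 cells/ul/min
ICC reduction 94.9 %
washout rate  0.202 /min
```

Reading these numbers: the 15 baseline bins recover the configured tap-water
TCC of 130.6 cells µl⁻¹ within Poisson noise; the contamination is flagged in
the bin spanning minutes 15–16, i.e. one minute after the wastewater pump
starts; during chlorination the total count declines at ≈10.6 cells µl⁻¹
min⁻¹ (the configured fluorescence-loss rate, plus a small dilution
contribution from the dosing pulse itself); intact cells drop by ≈95% from
the 383 cells µl⁻¹ plateau to a ≈20 cells µl⁻¹ resistant floor; and the
fitted washout rate recovers the dilution rate of 0.2 min⁻¹.

The same replay is available from the shell, writing every intermediate file
(trajectory, prediction, raw event CSVs, binned series, JSON report,
checksummed manifest) plus optional figures:

```bash
flowshock replay --seed 1 --out-dir run1 --plots
flowshock simulate --out traj.csv            # reactor only
flowshock generate traj.csv --mode SG --seed 2 --out events.csv
flowshock bin events.csv --out binned.csv
flowshock analyze binned.csv
```

## Layout

- `src/flowshock/config.py` — validated configuration (reactor, kinetics,
  instrument, populations, gates); packaged defaults in
  `src/flowshock/data/default_run.yaml`
- `src/flowshock/reactor.py` — mixing model, prediction, kinetic simulator
- `src/flowshock/instrument.py` — synthetic event-stream generator
- `src/flowshock/gating.py` — gating, binning, concentrations, fingerprints
- `src/flowshock/analysis.py` — baseline/onset/rates/comparison
- `src/flowshock/reference.py` — reference experiment's printed measurements
- `src/flowshock/replay.py`, `io.py`, `plotting.py`, `cli.py` — orchestration
- `docs/methods.md` — model assumptions, parameter choices, limitations
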