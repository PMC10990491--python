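# osmopulse

Quantification of budding-yeast growth, death and stress-reporter dynamics
under periodic dual environmental perturbations (hyperosmotic stress ×
glucose availability) in microfluidic chambers — from tracked-nuclei
tables, not images.

Time-lapse experiments of this kind produce, per field of view, a CSV with
one row per detected nucleus per frame (object id, parental id, centroid,
nucleus area, optional curated death flag). `osmopulse` is the analysis
layer downstream of segmentation/tracking, for experimentalists who need
per-capita rates and reporter curves out of those tables, plus a fully
synthetic test bed so that every estimator can be validated against known
ground truth without any imaging data.

## What it computes

**Eulerian per-capita rates.** Inside a fixed tracking window (default
1928×1928 px centered in the 2048×2048 field) the living-nucleus count
obeys, between consecutive frames,

    N_window(t+1) − N_window(t) = N_new(t) + N_in(t) − N_out(t) − N_death(t)

with N_new the divisions in the window, N_in/N_out boundary crossings and
N_death newly dead residents. The average division rate over [t₀, t₁] is
the OLS slope of the cumulative sum Σ N_new(t)/N_window(t) against time
(min⁻¹); the death rate is the same construction on death events. Counting
events in a fixed window instead of following lineages makes the estimate
robust to occasional tracking errors and to crowding. Derived quantities:
population growth rate (division − death), doubling time ln 2/rate,
sliding-window "instantaneous" rates (36-min windows every 6 min), and
phase-folded profiles over the stimulus period with half-period means,
replicate confidence intervals and Welch t-tests between conditions.

**Reporter quantification.** Per-cell fold change
(F_i(t) − F̄(t₀))/F̄(t₀) of a transcriptional reporter; nuclear enrichment
(nucleus mean / whole-cell mean) of a translocating kinase; and the
fluorescein relative-fluorescence normalization
RF_t = (F_t − F_min)/(F_max − F_min) used to calibrate medium switching in
the chip — each with population means and 95% CIs.

**Stimulus schedules.** Piecewise-constant glucose/sorbitol programs:
constant, single pulse, periodic osmotic stress, periodic glucose
deprivation, and the two dual regimes — in-phase stresses (IPS: starvation
and 1 M sorbitol together for half of each period) and alternating stresses
(AS: glucose with sorbitol, then starvation without) — all preceded by a
60-min acclimation that is excluded from analysis.

**Synthetic chambers.** An agent-based generator emulating the tracking
output: environment-dependent Bernoulli division with a lag, random-walk
motility and window crossings, crowding washout, persistent dead nuclei,
glycerol-loading-dependent lysis clustered at hypo-osmotic down-shifts
(so the IPS/AS death asymmetry emerges from stress phasing), reporter
traces, and a tracking-error injector (identity swaps, detection drops,
frame drops). Every run is deterministic per seed and logs ground-truth
events for recovery tests.

## Worked example

Simulate one wild-type-like chamber under alternating stresses (2% glucose
+ 1 M sorbitol alternating with plain starvation, period 24 min, 11 h) and
estimate its rates:

```python
import osmopulse as op

schedule = op.make_schedule("AS", period=24, total_duration=660)
cfg = op.SimConfig(initial_cells=150, seed=1)
table, truth = op.simulate_chamber(cfg, schedule)

counts = op.frame_counts(table)
division = op.mean_rate(counts, "division", schedule=schedule)
death = op.mean_rate(counts, "death", schedule=schedule)

print(f"division rate : {division.rate:.2e} /min")
print(f"death rate    : {death.rate:.2e} /min")
print(f"growth rate   : {op.population_growth_rate(division, death):.2e} /min")
t_div, t_death = op.true_rates(truth, division.t0, division.t1)
print(f"true rates    : division {t_div:.2e}, death {t_death:.2e} /min")
print(f"conservation violations: {counts.conservation_violations()}")
```

prints

```
division rate : 1.86e-03 /min
death rate    : 2.09e-03 /min
growth rate   : -2.30e-04 /min
true rates    : division 1.97e-03, death 2.16e-03 /min
conservation violations: 0
```

Cells die faster than they divide under this regime — the population
shrinks (negative growth rate), and both estimates sit within a few percent
of the simulator's event-log ground truth, with the window conservation
identity holding exactly. Running the same seed under IPS instead gives a
death rate of 7.8e-4 /min: phasing sorbitol *with* glucose loads cells with
more glycerol and makes the hypo-osmotic shock on sorbitol removal more
lethal, even though both regimes apply each stress for exactly half the
time.

A command-line layer wraps the same functions:

```bash
osmopulse simulate --config cfg.yaml --out sim/
osmopulse rates --tables sim/tracking_seed1.csv --config cfg.yaml --out rates.csv
osmopulse recover --config cfg.yaml --out report.json
osmopulse demo --config cfg.yaml --out demo/
```

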