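# Methods

## Problem setting

Yeast cells growing in a microfluidic chamber are exposed to periodic
switches of two environmental components — glucose (carbon source, 0/0.1/2 %
wt/vol) and sorbitol (osmotic agent, 0/1 M) — and imaged every 6 minutes.
Upstream segmentation and tracking (outside this package) produce, per field
of view (FOV), a table with one row per detected nucleus per frame: object
id, parental id when the object arose by division, centroid, area, and an
optional manually curated `dead` flag. This package quantifies per-capita
division and death rates, phase-resolved rate profiles, and fluorescent
reporter dynamics from such tables, and ships an agent-based generator that
emulates them with known ground truth.

## Environment schedules

A schedule is piecewise constant with half-open `[start, end)` segments;
the state at a switch instant is the new state. Every experiment begins with
60 min of acclimation in the default medium (glucose, no sorbitol), excluded
from all analyses. Periodic regimes alternate two states with half-period
T/2 each: `periodic_osmo` (sorbitol on/off at constant glucose),
`periodic_glucose` (glucose on/off, no sorbitol), `IPS` (glucose alone,
then starvation *with* sorbitol) and `AS` (glucose *with* sorbitol, then
starvation alone). The phase-0 convention — IPS starts stress-free, AS
starts with glucose+sorbitol — makes IPS and AS share identical glucose
timing, so the two regimes differ only in sorbitol phasing; over any whole
number of periods each spends exactly half the time in sorbitol. Valve
switching in the real device completes well under one imaging interval, so
transitions are idealized as steps.

## Eulerian rate estimation

All counting happens inside a fixed tracking window, by default 1928×1928 px
centered in the 2048×2048 frame (60 px margins), membership decided by the
nucleus centroid with half-open bounds. Between consecutive frames the
living-resident count obeys, exactly,

    N_window(t+1) − N_window(t) = N_new + N_in − N_out − N_death_removed.

Classification of a nucleus living-in-window at t+1 but not at t: it is a
division (`N_new`) iff its *first appearance in the whole table* is frame
t+1, its parent id is set, and the parent was a living window resident at
frame t; every other gain is an entry (`N_in`), with unparented interior
appearances additionally logged as anomalies. Losses are deaths if the
object is flagged dead at t+1, otherwise exits. Because the gain/loss sets
partition the symmetric difference of the two resident sets, the identity
holds exactly on any valid table. Defining "first seen" as first appearance
ever (rather than absence from the previous frame) is what makes the
estimator robust to dropped detections: a track with a one-frame gap is an
entry on reappearance, never a second division.

The average per-capita rate over [t0, t1] is the OLS slope (free intercept,
`scipy.stats.linregress`) of the cumulative sum of N_event(t)/N_window(t)
against interval end time, in min⁻¹. The denominator is the start-of-interval
living count by default (`end` and `mid` are config switches; the choice is
not fixed by the estimator's definition and matters at the <1% level in our
simulations). Zero-denominator intervals are skipped and reported. When a
periodic schedule is supplied, the acclimation hour and any incomplete final
period are excluded. Death rates use the same construction on death events,
with the same living-only denominator (symmetric exclusion of dead nuclei).

Two finer-grained series derive from the same bookkeeping: a sliding-window
"instantaneous" rate (the cumulative-sum slope over 36-min windows every
6 min, edge windows truncated and flagged) and a per-interval rate
N_event/(N_window·Δt) used for phase folding, where each 6-min observation
is assigned to the phase bin of its interval start; bins report across-FOV,
across-period means with t-based 95% CIs, plus half-period means. Derived
quantities: population growth rate = division − death; doubling time
= ln 2 / rate; period = 1/frequency. Replicate summaries are means with
t-distribution 95% CIs over chambers; condition comparisons use Welch's
t-test by default (Student's available) on per-chamber means.

Note one estimator subtlety: with events strongly clustered in time (lysis
bursts at down-shifts), the cumulative-sum slope and the total-events /
cell-minutes ratio are different statistics and can differ by ~20% over
windows containing partial bursts; at constant rates they agree to ~2%.

## Synthetic chamber generator

The generator is first-class, tested code and defines the conditions under
which the estimators are validated.

* **Division** — per living cell per frame, Bernoulli with
  p = 1 − exp(−rΔt), r taken from an (glucose-presence, sorbitol-presence)
  → rate table evaluated at the environment `division_lag` minutes earlier
  (default 12 min, reflecting the delayed growth arrest after glucose
  removal). Default rates: 0.0066 (glucose), 0.0033 (glucose+sorbitol),
  0.0005 (starved), 0.0002 (starved+sorbitol) min⁻¹, spanning the measured
  range. Daughters appear 12 px from the mother with `parent_id` set.
  The realized per-frame event rate is (1 − exp(−rΔt))/Δt, ~1.8% below r at
  r = 0.0066; recovery tests compare against the event-log oracle, which
  measures the realized rate.
* **Spontaneous death** — an analogous per-capita rate table (default zero),
  used to validate death-rate recovery at controlled constant rates.
* **Lysis** — an explicit synthetic osmolyte model, not a fit: glycerol g
  obeys dg/dt = gain·[sorbitol]·(1 + κ·[glucose]) − decay·g (gain 0.02 a.u./min,
  κ = 2, decay 0.01 min⁻¹, integrated exactly per segment), and at each
  sorbitol down-shift every living cell lyses with probability
  min(1, 0.08·g); survivors then dump their glycerol (a configurable
  retention fraction, default 0, reflecting the fast opening of the export
  channel on hypo-osmotic shock — without this, glycerol accumulates across
  periods and per-shock lethality climbs far beyond the measured death
  rates). Phasing sorbitol with glucose (AS-style) loads more
  glycerol at the down-shift than phasing it with starvation (IPS-style), so
  the higher AS death rate is emergent from the schedule, never hard-coded.
  Dead nuclei stay in the table, motionless and flagged, for 999 frames by
  default (they remain trackable for hours in the real data).
* **Motility and crowding** — reflected Gaussian random walk (σ = 4 px/frame)
  inside the 2048×2048 frame generates window boundary crossings; above
  `crowding_capacity` (default 1500) the excess cells nearest the chamber
  edge are washed out of the field, bounding the population the way flow
  does in the device.
* **Tracking-error injection** — identity swaps between nearest spatial
  neighbours (per-object probability), individual detection drops, and
  whole-frame drops with preserved timestamps; deterministic per seed.
* **Reporters** — nuclear enrichment of the stress kinase jumps to
  `hog1_peak` (2.5) at each hyperosmotic up-shift and relaxes exponentially
  toward 1 with half-life 6 min when glucose is present, 45 min under
  starvation, and 4 min once stress is released; the transcriptional
  reporter integrates dm/dt = txn·[enrichment > 1.5 AND glucose] − dilution·m
  with a 20-min maturation delay. Traces carry multiplicative lognormal
  noise (CV 5%). The peak value 2.5 makes the glucose-fed decay fall below
  5% of baseline 30 min post-shock, matching the observed "undetectable by
  30 min" behaviour. All reporter parameters are qualitative synthetic
  defaults — configuration, not estimates.

Identical (config, schedule, seed) gives byte-identical tables and event
logs. Ground-truth rates are computed from the event log as window-resident
events divided by living-cell·minutes in the window.

What the generator does **not** emulate: cell-cycle structure (budding
index, mother/daughter asymmetry), mechanical cell–cell forces, pixel-level
segmentation noise, spatially correlated tracking failures, bleaching, and
the <2-min transient kinase peaks on glucose re-addition that 6-min
sampling cannot resolve. Passing recovery tests therefore demonstrate
correctness of the estimators under the assumed statistical structure, not
performance on any particular real dataset.

## Reporter quantification

Fold change: FC_i(t) = (F_i(t) − F̄(t₀))/F̄(t₀) with F̄(t₀) the across-cell
mean at the baseline frame — by default the first frame after acclimation
exclusion (the natural reading of "first frame" given that the first hour
is excluded; configurable). Nuclear enrichment: nucleus mean over whole-cell
mean, the whole-cell mean including nuclear pixels, hence exactly 1 for
uniform fluorescence and invariant under global intensity rescaling.
Fluorescein relative fluorescence: RF_t = (F_t − F_min)/(F_max − F_min)
with F_min/F_max means over configured calibration window unions (defaults
30–40 & 70–80 min and 10–20 & 50–60 min for the 20-min on/off valve
program); RF is affine-invariant and is flagged, not clipped, outside
[0, 1]. Population curves are across-cell means with t-based 95% CIs; cells
absent at a time point are omitted, and a minimum-track-length filter
(default off, 360 min typical) is available. Adaptation half-lives are
recovered from population enrichment curves by log-linear regression of
(mean − 1) from the peak.

## Numerical and design choices

* Time is carried explicitly in minutes, so dropped frames leave gaps in
  the regression abscissae rather than shifting them.
* Window membership uses centroids (whole-nucleus overlap would need masks
  the tables do not carry); declared and testable.
* Multiple death annotations for one object resolve to the earliest frame;
  annotation is idempotent and irreversible.
* Simultaneous division-and-exit within one interval counts once in each
  category, preserving the identity.
* Problem sizes in the validation suite: 150-cell chambers over 720 min for
  rate recovery (10 seeds × 4 rate combinations), 100 randomized small
  chambers for the conservation property, 3 chambers × 5 periods for phase
  folding, 200 repetitions for t-test calibration — sizes chosen to match
  the study's per-FOV scale while keeping the full suite fast.

## Known limitations

* The estimator assumes the `dead` flag is monotone (no resurrection) and
  validates this at read time.
* Death-rate estimation under strongly clustered lysis inherits the
  slope-vs-ratio discrepancy noted above; report rates over whole periods.
* `fold_by_phase` requires all series to share one sampling grid; it does
  not resample.
* The generator's crowding washout is a simple edge-distance rule; it
  bounds density but does not reproduce the spatial structure of a packed
  chamber.
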