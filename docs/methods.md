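# Methods

This note documents the models implemented in `ktcc`, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions that make every result reproducible.

## The knapsack decision problem and its constrainedness

An instance is `N` items with integer values `v_i` (dollars) and weights
`w_i` (grams), an integer capacity `c` and target profit `p`. The decision
question asks whether a subset exists with `Σw ≤ c` and `Σv ≥ p`. The
constrainedness parameters are

    α_p = p / Σ v_i        α_c = c / Σ w_i ,

computed in exact rational arithmetic (`fractions.Fraction`) and rendered to
float only at the interface. Integer payloads plus rational ratios mean
there is never floating-point ambiguity about band membership or
satisfiability.

Degenerate inputs are legal: `p > Σv` is simply unsatisfiable and `c ≥ Σw`
reduces the problem to the value test; the region classifier labels them
over-/under-constrained respectively. `target_profit ≥ 1` is enforced for
generated instances; `verify_witness` treats a hypothetical `p = 0` as
vacuously satisfied.

## Solvers and the effort measure

`solve_decision` is a depth-first branch and bound over include/exclude
decisions. Items are visited in value-density (`v/w`) descending order,
ties broken by original index, include branch first; density comparisons use
exact rationals so the ordering is platform-independent. A child node is
created only if it passes the weight bound (accumulated weight ≤ `c`) and
the remaining-value bound (accumulated value plus all remaining values can
still reach `p`). Two counters are exposed: `effort_nodes` (nodes visited)
and `effort_checks` (bound evaluations). Because the ordering and pruning
are fixed, the counters are a deterministic, algorithm-specific ex-post
measure of solving cost — the package's stand-in for an external solver's
propagation count, applied to the decision form of the problem only.
Counting only surviving children keeps trivially pruned work out of the
measure (an instance whose every item is overweight costs at most `N + 1`
nodes).

`brute_force_decision` enumerates all `2^N` subsets (vectorized, chunked,
guarded at `N ≤ 25`) and is used as the verdict oracle in tests; its
canonical witness is the first qualifying subset by index bitmask.
`solve_optimization` is the standard dynamic program over weight states with
backtracked subset reconstruction; `best_value ≥ p` iff the matching
decision instance is satisfiable, which the test suite checks on random
instances.

## Instance generator and the phase transition

`SamplingConfig` defaults encode the study conditions: `N = 6`, values and
weights i.i.d. uniform integers on `[1, 100]`, `α_c ∈ [0.40, 0.45]`. The
uniform item distribution is a deliberate, configurable choice — the band
logic is distribution-agnostic, and whether values and weights should be
correlated is left to the user (independent uniforms are the simplest
exchangeable default). Sampling draws target `α` values uniformly in their
bands, sets `c = round(α_c·Σw)` and `p = round(α_p·Σv)` with round-half-up,
then recomputes the realized ratios from the rounded integers and accepts
only if both still lie in their bands (rejection sampling; an
infeasible-band error after 10^4 consecutive rejections). Rounding half-up
keeps the printed bands true of the emitted integers.

`estimate_phase_transition` measures, per grid value of `α_p`, the
satisfiable proportion and mean `effort_nodes` over `n_per_point` instances
drawn in a ±0.01 band. `locate_threshold` finds `α_s` by stochastic
bisection: P(sat) is estimated from 400 fresh instances at the bracket
midpoint (default bracket `[0.35, 0.90]`, precondition-checked to straddle
0.5) and the bracket is halved until its width is ≤ 0.01. Bisection was
preferred over a parametric fit because it makes no assumption about the
transition's shape; a logistic-fit variant (`method="logistic"`) is exposed
for users who want the smoother estimate. Under the defaults `α_s` lands
near 0.65 — inside the high-TCC band `[0.60, 0.65]` used by the factorial
design — and mean solver effort peaks at the grid point nearest `α_s`
(easy–hard–easy).

TCC is a binary band label, exactly as the experimental design uses it:
`[0.35, 0.40]` under-constrained / low TCC, `[0.60, 0.65]` near-threshold /
high TCC, `[0.85, 0.90]` over-constrained / low TCC, closed intervals,
anything else explicitly "unclassified" (with no TCC label, since the notion
is band-relative). The continuous diagnostic `|α_p − α_s|` is available as
`tcc_distance`.

## Factorial stimulus ensemble and scheduling

`build_full_ensemble` fills four cells (TCC × satisfiability) with 18
instances each. Satisfiability labels are never assumed from the region:
every candidate is solved exactly, and a candidate whose verdict disagrees
with its cell's label is rejected (this is what makes the low-TCC cells a
*balanced* design: the under-constrained band essentially only yields
satisfiable instances, the over-constrained band unsatisfiable ones, and
both high-TCC cells draw from the same near-threshold band where the two
labels are roughly equiprobable). Within each high-TCC cell, instances are
median-split on `effort_nodes` into bottom/top strata; the split is a stable
sort, so ties (and the odd middle element) land in the bottom stratum — a
convention that matters only because it makes the strata reproducible.

`subsample_balanced` takes `n_total / 4` entries per cell uniformly without
replacement, and splits the quota evenly over effort strata in high-TCC
cells (odd quotas give the extra entry to a randomly chosen stratum).
Reloading a stored ensemble re-verifies every label and band membership.

`schedule_session` permutes the stimuli into 7 blocks of 8 trials. Each
trial is 3 s items + 22 s solving + 2 s response = 27 s, followed by an
inter-trial rest drawn uniformly from {8, 10, 12} s; onsets therefore step
by 35/37/39 s. The 'YES' button side is randomized per trial. Stimulus
identity, subsampling and scheduling consume independent seeds so each can
be varied while holding the others fixed.

## Design matrices

All regressors live on a TR = 0.8 s grid with `floor(run_length / TR)`
frames. Boxcar-family events are sampled by fractional overlap (a frame's
value is the fraction of its TR covered by the event) — deterministic,
alias-free, and exact for the partition identities below. FIR tents are
evaluated pointwise at frame times, which preserves their partition of
unity exactly.

**Boxcar model.** Per level of the chosen dichotomy: four solving-period
boxcars of 22/4 = 5.5 s (S1..S4) and one 2-s response boxcar; shared 3-s
items boxcar; optional left/right button regressors when trials carry a
button label. The four solving boxcars of a level sum exactly to that
level's full 22-s solving indicator. Convolution (`hrf_mode="canonical"`)
uses a double-gamma kernel (gamma-density peak near 5–6 s, undershoot at
16 s, 1:6 ratio, unit peak) sampled at the TR; `hrf_mode="none"` returns the
raw indicators. The kernel choice is a documented package default — FIR is
the model of choice when the response shape itself is in question.

**FIR model.** Conditions are the full crossing of the labeling factors
(checked; a missing cell is an error). Tents have knots every 2 s from
trial onset to trial end plus a 5-s hemodynamic lag: span 27 + 5 = 32 s,
hence 17 tents. Tent `j` peaks at `2j` s post-onset and estimates task time
`2j − 5` s; the map is stored in the design metadata. Non-commensurate
spans round the knot count down with a warning.

**PPI periods.** The combined items + solving window (25 s) is split into
two equal 12.5-s boxcars (early/late), disjoint and tiling the window.

## Fitting, contrasts, inference, synthetic BOLD

`fit_glm` appends Legendre drift columns P0..P2 by default (P0 is the run
intercept), optionally applies a row censoring mask, verifies full column
rank (naming the dependent columns otherwise), and solves per-voxel OLS by
`lstsq`. The ROI summary at each basis is the arithmetic mean of per-voxel
coefficients. On noiseless data recovery is exact to numerical tolerance
for any full-rank design.

Contrasts are linear combinations over condition selectors; a selector
matching several conditions contributes their *mean* (so the TCC main
effect averages over satisfiability). Built-ins: `tcc` (high − low), `sat`
(unsat − sat), `interaction` ((high,unsat − high,sat) − (low,unsat −
low,sat)), `accuracy` (correct − incorrect). Differential weights must sum
to zero.

`group_timepoint_test` is a per-basis one-sample two-sided t test of
participant contrast values against zero at `α = 0.05`, *uncorrected* —
matching how per-timepoint significance is usually displayed; users who
need familywise control should correct downstream. Zero-variance inputs are
flagged `degenerate` rather than erroring: a nonzero constant is reported
significant, a zero constant not.

`simulate_bold` produces `design × β` plus stationary AR(1) Gaussian noise
per voxel (lag-1 correlation `φ`, marginal SD `σ`, innovation SD
`σ√(1−φ²)`, stationary initial draw). It emulates condition-dependent ROI
responses with temporally autocorrelated noise; it does **not** emulate
motion, physiological confounds, spatial correlation between voxels, scanner
drift beyond what the Legendre columns absorb, or inter-regional coupling.
Passing parameter-recovery tests on this generator validates the estimator
algebra and the design construction, not robustness to real-data artifacts.

## Behavioral simulator

Accuracy follows a mixed logistic model: `P(correct) = logistic(b0 + u_i +
b_tcc·1[high TCC] + b_sat·1[satisfiable] + b_trial·t)` with participant
intercepts `u_i ~ N(0, sd)`; the yes/no choice is derived from correctness
and the ground-truth label. Defaults: `b_tcc = −1.1`, `b_sat = 0.02`,
`b_trial = 0.009` (log-odds), and — since link-scale intercept and
random-intercept SD are not published quantities — `b0 = 1.8`,
`sd = 0.8`, *plausible* values chosen so simulated cohorts land near a mean
accuracy of ~0.78 with a realistic participant spread (~0.5–0.95). These
two are labeled plausible, not empirical.

Recovery (`fit_logistic`) is plain maximum likelihood via Newton–Raphson
(statsmodels `Logit`), with optional per-participant indicator columns
standing in for the random intercepts. Participants with constant outcomes
are dropped when indicators are requested — their indicator coefficient
diverges and they carry no information about within-participant slopes (the
standard fixed-effects-logit degeneracy); the count is reported on the fit.
Perfect or quasi-separation raises a dedicated error. Full mixed-model
integration (adaptive quadrature, Bayesian posteriors) is intentionally out
of scope; the simulator preserves the generative structure so any external
mixed-model tool can be applied to its output.

## Problem sizes used in validation

The shipped validation suite uses: 10^3 random instances (N ≤ 12) for
solver equivalence; 500 instances per grid point / band for phase-transition
shape; 400 instances per bisection step and 2,000 fresh instances for the
threshold probe; 16 simulated participants × 20 voxels for FIR
parameter recovery; 2,000 replicates for the group test's type-I rate; and
200 replicates × 100 participants × 56 trials for logistic coverage. These
sizes give binomial/Monte-Carlo standard errors comfortably inside the
asserted tolerances while keeping a full run to a couple of minutes on one
core.

## Known limitations

- The effort measure is solver-specific; absolute node counts are not
  comparable to other algorithms' cost measures, though the easy–hard–easy
  shape is.
- `α_s` depends on the item distribution; the default uniform generator is
  one choice among many, and the threshold must be re-located whenever the
  generator changes.
- The original 72-instance experimental set is regenerated by
  specification (bands, quotas, balance rules), not reproduced item for
  item.
- Whole-brain spatial inference, preprocessing, empirical PPI/effective
  connectivity and Bayesian mixed-model estimation are out of scope; the
  package operates on ROI/voxel-set series and synthetic data only.
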