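# Methods

## Stimulus model

A stimulus is a map outline partitioned into regions (default 10) by the
Voronoi cells of uniformly sampled interior points, clipped to the
outline. Adjacency is the shared-border relation of the clean cells
(positive intersection length); the cosmetic border jitter applied
afterwards displaces each interior boundary vertex by a hash of its
coordinates (amplitude ≤ 1% of the outline diameter), so vertices shared
by neighboring regions move together and the partition is preserved
exactly. If jitter ever produced an invalid ring the clean cells are kept
instead — adjacency and analysis never depend on the jitter.

Values are keyframes at integer seconds (61 for a 60-s stimulus, 31 for
30 s); higher-frame-rate rendering is interpolation between keyframes and
is outside the analysis, which bins behavior at 1 s. Three dynamics:

* **Semi-random trend (design 1, 60 s).** The global value starts at 0 and
  each second advances by the current slope, drawn uniformly from [-1, 1];
  the slope changes 5–10 times (count uniform, change seconds drawn
  without replacement from the interior, sorted). The global series is
  min-max rescaled to [0, 1]; each region adds i.i.d. per-second Gaussian
  noise (sd 0.1) and the full matrix is min-max rescaled again, so every
  stimulus attains exactly 0 and 1.
* **Whole-map linear trend (design 2, 30 s).** Trend from the 8-point grid
  (-1.00 … 1.00, equally spaced, 2 decimals); the start value is uniform
  on the feasible interval [max(0, −trend), min(1, 1 − trend)] so the
  noise-free series stays in [0, 1]. Region noise (sd 0.1) is *truncated*
  (clipped) to [0, 1], never rescaled, so the nominal trend is preserved;
  with sd 0 the realized trend is exact, and a 10,000-seed Monte-Carlo in
  the test suite bounds the clipping bias of the realized trend at < 0.02
  for a mid-grid slope.
* **Subset trend (design 3, 30 s).** Trend ∈ {−1, −0.5, 0.5, 1} applied to
  3 or 4 regions selected by spatial pattern — *clustered*: grow from one
  uniformly random region through adjacent regions (an error names the
  stranded step if the graph makes that impossible); *distributed*: pick
  non-adjacent regions, falling back to a uniformly random region when
  none qualifies. The remaining regions hold one stable level drawn
  uniformly from [0.2, 0.8] per stimulus (a package choice: unspecified
  upstream; it keeps truncation rare). Noise and truncation as design 2.

Every generator derives independent sub-streams (geometry, starts, noise,
selection) from one root seed via `numpy` seed sequences; identical
inputs give bit-identical outputs.

Whether region noise should be per-second i.i.d., temporally smoothed, or
a static offset is not determinable from the study description; the
generator defaults to per-second i.i.d. and exposes a moving-average
smoothing width (`noise_smoothing_s`, default off) rather than guessing.

## Response simulator

No participant model is published for this task, so the simulator is an
artifact convention chosen for transparency, not a behavioral estimate.
The per-second hazard is linear-clipped:

    hazard_t = clip(base_rate + s·(change_gain·|Δg_t| + congruence_gain·c_t), 0, 1)

with Δg_t the one-second change of the global series, c_t = |Δg_t| when
the trend direction matches the framing expectation (invasive → increase,
endangered → decrease) and 0 otherwise, and s the salience multiplier
(default 0.5 for hue color scales and distributed patterns, 1 otherwise).
The multiplier scales *both* gain terms: a multiplier on the change term
alone would make the congruence effect salience-independent and could not
produce the trend × framing × salience interaction the simulator exists
to exercise. Participants get a lognormal hazard multiplier
exp(N(0, participant_sd)); presses are per-second Bernoulli draws placed
uniformly within their second and thinned greedily to a 0.5-s refractory
gap. Defaults (base 0.06/s, gains 2.0, participant sd 0.4) give press
counts and agreement levels in the range reported for real cohorts, but
passing tests on this simulator demonstrates properties of the *measure*,
not of human viewers: real data have temporally structured individual
strategies, fatigue, and attention lapses the simulator does not emulate.

Fixtures with the published trial bookkeeping (117 × 31 trials with
exactly 267 empty and 11 post-end logs; 176 × 32 with 395 and 13) are
constructed by reconciling the simulated cohort to those exact counts:
surplus natural empties receive one injected press, shortfalls are
cleared, and post-end contaminants replace the presses of randomly chosen
trials. The counts are exact by construction, not in expectation.

## Agreement measure

Debouncing retains a press iff it is ≥ 0.5 s after the last *retained*
press (greedy chaining). Bins are 0-based and half-open [b, b+1); a press
at exactly the stimulus end clamps into the last bin. Norms are
proportions (correlation is scale-invariant). The correlation of a
k-ones indicator with a norm is monotone in the selected-norm sum, so
r_max/r_min come from the k largest/smallest norm values (ties broken by
earliest bin — any tie-break gives the same bounds; this one is
deterministic); the test suite proves equality with exhaustive
enumeration over all C(n, k) placements for n ≤ 12. Trials with k = 0
(empty after filtering cannot occur; all-bins-set can), post-end presses,
or degenerate bounds are excluded *and counted* at each stage; agreement
is computed within experimental group throughout, with the group an
explicit column.

The permutation null independently permutes every trial's binned vector
per iteration (press counts invariant), recomputes all leave-one-out
agreements from the permuted data, and records the sample mean; the
default is 10,000 iterations. The two-tailed p is the symmetric tail mass
around the null mean with add-one smoothing per tail, so an observation
beyond every sample reports 2/(iterations + 1) rather than 0. (The
printed tail formula in the source study evaluates near 1 as written; the
symmetric-tail reading is adopted here and the discrepancy documented,
not resolved.) Cross-stimulus baselines score each trial against every
other stimulus's norm; whether the focal participant's own response to
the *other* stimulus should be excluded there is unspecified upstream, so
leave-one-out is applied uniformly.

## Mixed models

`fit_lmm` is a purpose-built profiled-REML fitter (no installed Python
library provides REML linear mixed models with Satterthwaite degrees of
freedom, and the power loop needs ~millisecond fits). It uses the
relative-Cholesky parameterization G = σ²ΛΛ′ with β and σ² profiled out;
per-group Woodbury identities reduce each deviance evaluation to
sufficient statistics, and when every participant shares the same design
block (balanced factorials) the cost per evaluation is independent of the
number of observations. Crossed random intercepts (contrast, time-unit
and descriptor models) use indicator-matrix Woodbury with group sums.
Optimization is L-BFGS-B with non-negative diagonal bounds; boundary
(zero-variance) estimates are reported, never hidden; non-convergence
raises an error carrying the optimizer diagnostics. Satterthwaite dfs
follow the lmerTest construction — the covariance of the variance
parameters from the numeric Hessian of the un-profiled REML deviance, and
the gradient of Var(c′β̂) by central differences. The engine matches
`lme4`/`lmerTest` to ~1e-6 on estimates and SEs and ~1% on dfs in the
test suite, which keeps the R fit as an independent oracle rather than
the implementation.

Treatment coding throughout, references endangered / hue / distributed /
cross-stimuli; trend stays numeric on [-1, 1]. AMEs of trend are
coefficient sums over the active interaction terms with delta-method SEs
and normal (z) tests, and equal averaged per-observation derivatives
exactly for these linear models. The standardized effect d is
β / √(Σ random-effect variances + residual variance) — a documented
convention; the source analyses do not define their d.

`power_simulation` simulates one agreement value per trial from the
mixed-model data-generating process (all fixed effects 0 except the
three-way interaction), refits the full factorial model per replicate,
and reports the rejection fraction with a Wilson interval. Default
variance components are the published fitted values of the color-scale
experiment (intercept/trend/framing/salience variances 8.29e-3, 9.63e-4,
7.81e-6, 2.01e-4; correlations 0.61, −0.32, −0.74, −0.20, −0.69, 0.99 —
a positive-definite matrix as printed; residual 0.0316). Inside the power
loop the interaction test uses residual dfs (n − p ≈ 4000–5600, where the
t and z tests are numerically indistinguishable) because a Satterthwaite
Hessian per replicate would cost more than the fit; `fit_lmm` defaults to
Satterthwaite elsewhere. Non-converged replicates count as non-rejections
and are reported separately. Type-I calibration at effect 0 is verified
in the tests.

## Problem sizes and reproducibility

Monte-Carlo sizes are package defaults chosen to make every distributional
check stable under a fixed seed: 200 replicates for power runs (binomial
SE ≈ 0.03), 100 replicate cohorts × 1000 permutation iterations for null
calibration, 500 (coverage) and 10,000 (clipping bias) draws where noted.
All randomness flows from explicit integer seeds through named
sub-streams, so every table in a pipeline run directory can be
regenerated from its audit file alone.

## Known limitations

* The simulator's hazard is memoryless given the stimulus; it cannot
  represent hierarchical or anticipatory segmentation strategies.
* The power analysis inherits whatever the assumed variance components
  miss (e.g., stimulus-level random effects, non-normal residuals).
* Agreement is undefined for trials whose press count saturates the bins
  or whose group norm is constant; these are excluded with accounting
  rather than imputed.
* Coarse/fine segmentation grains and time-warped agreement measures are
  out of scope.
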