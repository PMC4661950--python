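# Methods

## Model

An outcome S (a FIM score) is approximated as a sparse sum of M basis
functions of individual biomarkers,

    S = Σ_{m=1..M} a_m p_m(n) + e(n),      n = 1..N subjects,

where each p_m is either the constant or a univariate transform of one
min-max-normalized metric z ∈ [0, 1]: identity, z², z³, sin z, cos z, or
ln(z + ε). The model is cross-sectional — subjects are exchangeable
samples, there are no lagged terms — and deliberately additive: no
interaction terms by default (a config switch exists but is off, since
univariate transforms are the design's contract).

Normalization uses the observed minimum and maximum of each metric,
z(x) = (x − x_min)/(x_max − x_min), applied uniformly to robotic and
clinical candidate columns so every transform sees the same bounded
domain. At prediction time, values outside the training range clip to
[0, 1], keeping the log and trig domains valid. Bounds are computed
once on the full sample by default (`norm_scope="global"`); a
`train_fold` scope refits them inside each CV training fold for
leakage-free evaluation, and a test verifies that with that scope a test
fold's values cannot influence its training fit.

## Fast Orthogonal Search

Term selection is greedy forward selection by largest mean-squared-error
reduction. The implementation keeps deflated (orthogonalized) copies of
all candidate columns: after each selection the chosen direction is
projected out of the residual and the remaining pool (modified
Gram-Schmidt), so each candidate's potential MSE reduction is
(q_j · r)² / (q_j · q_j), one dot product per candidate per step.
Coefficients are always the OLS solution on the selected columns, so the
stored MSE path equals the OLS residual MSE of every prefix model and is
non-increasing by construction.

Two numerical rules make the search well-posed:

* **Collinearity**: a candidate is skipped when its orthogonalized
  squared norm falls below 1e-10 × its raw squared norm (an exact
  duplicate of a selected column has orthogonal norm ~0).
* **Tie-break**: MSE reductions within 1e-12 (relative) of the best are
  ties, resolved to the lowest candidate index; a selected candidate
  leaves the pool.

The contract is defined by oracle equivalence: `greedy_forward_ols`
refits a full OLS model for every remaining candidate at every step
(O(N·P) least-squares solves) and must produce the identical selection
sequence, MSE path and coefficients. The equivalence holds because a
candidate's orthogonalized explained variance equals the drop in
residual sum of squares when it joins a full refit. 200 randomized
instances (10–50 subjects, 5–40 candidates, orders 1–6, with planted
duplicate columns) are checked in the acceptance suite.

A caveat worth knowing: on [0, 1] several transforms of the *same*
metric are nearly collinear (cos z ≈ 1 − z²/2 given a constant term;
sin z ≈ z), with pairwise correlations above 0.999. Greedy selection
therefore identifies the underlying *metric* reliably, but the specific
transform it picks can be an impostor from the same metric at realistic
sample sizes. Repeat rates are accordingly reported per metric
(transform-collapsed), with per-transform detail in diagnostics; the
exact-recovery validation uses incoherent candidate pools where the
selection problem is identifiable.

## Evaluation and order selection

Performance is the mean, over 10 random CV folds, of the Pearson
correlation R between actual and predicted outcomes on held-out
subjects, with predictions first clipped into the target's valid range
(18–126 for FIM-Total, 13–91 for FIM-Motor; clipping can only reduce
absolute error against in-range actuals). R is reported on [0, 1]:
negative correlations clamp to 0 and constant predictions score 0; the
signed raw r is kept in diagnostics. Folds are a seeded uniform random
partition, unstratified.

Orders 1–15 are scored from a single search at the maximum order, since
greedy selection paths are nested; coefficients are refit per prefix.
The default order rule is the **one-standard-error parsimony rule**:
the smallest order whose mean held-out R is within one fold-standard
error of the best mean. Rationale: beyond the true model size the
mean-R curve sits on a flat plateau whose argmax is decided by fold
noise; in simulation (n = 500, 3 true terms, generative R 0.8) strict
argmax scattered the chosen order over 4–13 while the 1-SE rule
recovered the true order in 50/50 seeds. Strict argmax (ties to the
smaller order) remains available as `order_rule="max"`. A per-fold
order-selection variant was considered and rejected as the default: it
yields no single model to report.

Two pools predicting the same target on the same subjects are compared
with Steiger's z-test for dependent overlapping correlations, using the
correlation between the two pooled held-out prediction vectors; the
independent-samples Fisher z-test is available for disjoint cohorts.
The method used is stamped into every report.

## Repeat rates

Stability of biomarker selection is measured by refitting the model at
the chosen order on 100 random 90 % subject subsets (without
replacement — subsampling, not bootstrap) and counting, per rank
position, how often each metric carries the selected term. Per rank the
counts sum to exactly the number of repeats. By default the order is
fixed from the full-data CV; `reselect_order` reruns the CV sweep
inside every repeat. Note that because subsamples share 90 % of the
subjects, repeat rates measure the stability of selection *given the
cohort*, not across independent cohorts: a metric with a strong chance
correlation in one fixed sample will be stably re-selected (see the
null-control limitation below).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at the scale
of the motivating study (85 subjects; 13 reaching metrics per arm plus
13 interlimb, 9 matching, 14 object-hit, small clinical panels;
FIM-Total mean ≈ 96, sd ≈ 24):

* a latent severity factor s drives group factors
  f_g = λ·s + √(1−λ²)·e_g (λ = 0.7), and each metric is
  √ρ·f_g + √(1−ρ)·ε, so metrics within a group are equicorrelated at
  exactly ρ (default 0.3) and groups correlate more weakly through
  severity; a heavy-tailed (t₄) switch exists for robustness checks;
* metrics map affinely to plausible measurement scales; clinical
  columns are binned at standard-normal cut points into ordinal levels
  (Chedoke-like 1–7), preserving monotone association with severity;
* the target is intercept + Σ coefficient × transform(normalized
  metric) + Gaussian noise, affinely rescaled to the configured moments
  and clipped into the FIM range. The default true model — square(M3),
  identity(M5), cube(OH11) — mirrors the kind of sparse model the
  motivating study reported (two proprioceptive-matching terms plus an
  object-hit interlimb term). Noise defaults to the level giving
  generative R 0.8 (the closed form sd_noise = sd_signal·√(1/R² − 1)),
  matching the held-out R range reported for such cohorts.

The ground-truth record (rescaled terms, intercept, noise vector,
normalization bounds) reconstructs the targets exactly from the table;
recovery tests rely on this round trip.

What the generator does **not** emulate: real robotic metric
distributions (skew, floors/ceilings), any direct clinical-to-outcome
pathway (clinical columns influence targets only through the severity
factor, so synthetic clinical pools predict worse than robotic ones —
unlike the motivating study), longitudinal change between assessment
points, and missing data. Passing recovery tests therefore shows the
*pipeline* is sound, not that real cohorts satisfy its assumptions.

## Validation summary and known limitations

The acceptance suite checks: oracle equivalence (200/200 instances);
exact recovery of noise-free sparse targets on incoherent pools
(k = 1..4, residual MSE < 1e-12 × var); metric- and order-recovery on
50 cohorts at n = 500 (both ≥ 90 %, measured 100 %); a pure-noise null
control at n = 200 (across-seed mean held-out R < 0.25 at every order,
measured ≈ 0.10 at the worst order); and end-to-end report plumbing.

Known limitations:

* **Null repeat rates are not calibrated against chance.** On a fixed
  pure-noise cohort the best spurious correlate (|r| ≈ 0.2–0.3 at
  n = 200 across ~60 metrics) is re-selected in nearly all 90 %
  subsample refits — rank-1 repeat rates near 100/100 under the null.
  High repeat rates therefore certify stability of selection, not
  evidence against chance; a chance-calibrated reference would need
  target permutation, which is out of scope here.
* Transform identity within a metric is weakly identifiable (above).
* With `norm_scope="global"` the min/max bounds see the test folds; the
  effect is small (two order statistics) but `train_fold` is the
  leakage-free choice.
* Simulation sizes (50 seeds; n = 500/200) were chosen as the package's
  standard validation workload; rates near the 90 % thresholds have
  binomial noise of about ±4 points.
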