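# Methods

This note documents the models, the estimation procedures, the synthetic
data generator, and the numerical conventions behind `rakenorm`, in the
order the pipeline runs.

## Population model

A latent cognitive ability for children aged 0–6 is generated as

x₁ = −1.5·E − 0.25·T − 0.1·R − 0.05·T·R + 1.2·a − 0.06·a² + 0.0001·a⁴ + z,

where a is continuous age (Uniform[0, 6); six 1-year cohorts, cohort =
⌊a⌋), z ~ N(0, 1), and E, T, R ∈ {1, 2, 3} code education, ethnicity and
region. Codes are ordered by ability direction: 1 = the above-average
category (high education, non-native ethnicity, northwest region), 3 = the
below-average one (low education, native, south). With the reference
marginals — education 40/20/40, ethnicity 30/40/30, region 60/20/20,
crossed independently into 27 joint cells — this coding yields a partial
education–ability correlation of −.78 (age trend controlled), verified in
the tests against a covariance-algebra oracle. The ethnicity and region
coefficients are an order of magnitude smaller; their within-age
correlations with ability are about −.17 and −.10.

Standardization: θ_pop = (x₁ − μ)/σ with μ, σ always taken from the
**reference** population (empirically; a quadrature closed form — mixture
over cells and uniform age, plus unit within-cell variance — serves as the
test oracle, σ ≈ 2.27). Standardizing the distorted populations by the
reference moments is deliberate: the standardized scale then carries the
bias that non-representative sampling induces.

### Population scenarios

1. **Reference** — the outer-product table above, identical in all cohorts.
2. **Mild education bias** — education marginal 52/20/28 (low/medium/high).
3. **Moderate education bias** — 60/20/20.
4. **Mid-heavy education** — 30/40/30 (both tails underrepresented;
   variance shrinks, mean unchanged).
5. **Biased joint cells, intact marginals** — additive perturbation
   c·f(E)·f(T)·f(R) percentage points with f = (+1, −2, +1) and c = 0.15.
   Because f sums to zero over each variable, every marginal is preserved
   exactly; extreme-ability corner cells are overrepresented, raising the
   variance slightly. c = 0.15 is close to the largest value (0.2) that
   keeps the smallest joint cell (1.6%) non-negative.
6. **Clustered sampling** — per cohort only 9 of the 27 cells are active
   (blocks by (E+T+R) mod 3, rotating over cohorts so each block serves two
   cohorts). Active cells keep their reference proportions, renormalized to
   sum to 100. Exact tripling is arithmetically impossible — every
   reference cell is a multiple of 0.4%, so no 9-cell block carries exactly
   one third of the mass — hence the pooled six-cohort table matches the
   reference to within 2% relative rather than exactly.

## Test simulator

A fixed bank of 31 item difficulties δ_i ~ Uniform(−3, 3) is drawn **once
per experiment** and shared by every population, replicate and the
benchmark computation; per-replicate banks would confound the error
comparisons. Item responses are Bernoulli with the 1-PL probability
P(correct) = logistic(θ_pop − δ_i); the raw score is the number of correct
items (0–31).

## Raking

Weights start at 1 and are multiplied, variable by variable, by
target/current weighted share for each category, repeating until the
largest absolute marginal discrepancy falls below `tol` (default 1e-6,
`max_iter` 50 — on a 3×3×3 problem convergence takes a handful of
iterations; the result is invariant to the variable processing order at
convergence). Raking is applied once to the whole 600-person sample, not
per cohort: per-cohort raking would chase sampling noise in cells of a few
persons. Weights are then standardized by dividing by the minimum, so the
most overrepresented group has weight exactly 1; this preserves every
weighted proportion and every weighted fit. The raking API accepts
arbitrary categorical variables, so joint margins can be raked by recoding
a cross-classification into one dummy variable. Missing target categories
raise immediately with the category named. No weight trimming is applied.

## Continuous norming

Ranking is performed within the six 1-year cohorts: percentile of raw value
x = (W_below + ½·W_equal)/W_total using weight sums, which reduces exactly
to the mid-rank RankIt rule (rank − ½)/n with tie averaging under unit
weights. Locations are ℓ = 100 + 15·Φ⁻¹(p). The age predictor attached to
each person is the weighted mean age of their cohort in the sample (the
polynomial is continuous in age, so predictions interpolate between and
extrapolate slightly beyond the six cohort centers).

The norm model is a polynomial raw ≈ b₀ + Σ b_ij ℓ^i a^j over all
0 ≤ i, j ≤ 4, (i, j) ≠ (0, 0) (24 candidate terms), estimated by weighted
least squares with the raking weights (unit weights for the unweighted
method — with equal weights the two paths are bit-identical). Term
selection is best-subset per model size: sizes whose candidate count is at
most 50,000 are searched exhaustively (all sizes up to 5 of 24), larger
sizes by a deterministic beam search (width 40) seeded with the best
smaller subsets. The search operates on the Gram matrix of the
centered-and-scaled design (intercept always included; centering and
scaling leave every subset's span unchanged but keep the 8th-power columns
well conditioned), so each candidate costs one small linear solve, batched
across candidates. The selected model is the smallest size whose adjusted
R² reaches 0.99 **and** whose predicted raw score is non-decreasing in ℓ on
a 200 × 60 (location × age) grid over the calibration ranges; per size, the
best few candidates by residual sum of squares are audited for
monotonicity. If no size qualifies, the monotone candidate with the highest
adjusted R² is returned flagged. In the simulation, selected models
typically carry 3–6 terms with adjusted R² ≈ 0.99.

**Inversion.** Norm scores solve predict_raw(ℓ, a) = raw by bisection over
IQ 40–160 to a tolerance of 1e-4 IQ points. A fitted quartic is audited as
monotone over its calibration range but routinely bends outside it, so the
search is restricted per age to the widest interval containing IQ 100 on
which the profile is non-decreasing (detected on a 241-point grid); raw
scores outside the attainable range at that age are clamped to the interval
endpoint and flagged. A profile that decreases materially (more than 1e-3
raw-score units cumulatively) **inside** the calibration region raises an
error instead. Norm scores are never rounded internally; rounding to
integer IQs happens only in exported norm tables.

## Benchmark norms

IQ_best is computed from a large generated reference population with raw
scores: within each cohort, persons are ordered by age and split into 365
contiguous equal-sized groups (2,190 groups total); within each group every
raw value receives 100 + 15·Φ⁻¹(mid-rank percentile). No smoothing across
groups is applied — the benchmark is deliberately empirical. An exact
oracle computes the same quantity from the generative model (mixture over
the 27 cells, Gauss–Hermite integration over the latent normal,
Poisson-binomial raw-score distribution); the empirical benchmark converges
to it as the reference grows, and the tests verify agreement within 0.5 IQ
points for non-rare raw scores. The finite reference adds rank noise to
IQ_best of roughly 15·√(p(1−p)/m)/φ(z) per group of size m, which inflates
measured RMSE — at the default experiment scale (1.6 M per cohort, m ≈
4,400) by only a few hundredths of an IQ point at the center and ~0.1 at
the tail bins.

## Evaluation

Models are scored on a fixed evaluation set: a seed-controlled random
subsample (default 20,000) of the reference population, shared across all
populations, methods and replicates, each evaluee carrying age, raw score
and IQ_best. Reference-distributed evaluees are used because the error
profile is reported across the full ability range; evaluating on the biased
samples themselves would depopulate the tails the analysis reports on.
RMSE = √mean((IQ_method − IQ_best)²) and MSD = mean(IQ_method − IQ_best)
are computed overall and within 11 bins of 7.5 IQ points centered at
62.5, 70, …, 137.5 (bin membership by IQ_best; values outside contribute to
"overall" only). Replicate-level summaries average the 11 bins with equal
weight; cell means over replicates carry bootstrap 95% CIs (2,000
resamples) instead of ANOVA F-tests. Contrasts can be flagged against a
1-IQ-point practical-relevance threshold, the smallest difference visible
in integer-rounded norm tables.

The experiment driver runs, per population × replicate, one sample draw,
one raking, and two model fits (weighted and unweighted), evaluating both
on the shared evaluation set; per-replicate failures are logged, counted
and excluded, never silently dropped. A single master seed spawns named
child streams (population, item bank, reference raw scores, evaluation set,
one per scenario × replicate), so any component can be re-run independently
and every run is exactly reproducible.

## Problem sizes

The default profiles are 24 M reference persons and 100 replicates
(full scale) and 0.6 M / 20 replicates (the CLI's reduced default). The
acceptance script and the replication test use 9.6 M reference persons,
30 replicates of 600, and 20,000 evaluees — large enough that benchmark
rank noise is negligible against the ~2-IQ-point sampling floor of norming
at n = 600, while a full six-population run completes in about two minutes.

## What the generator does and does not emulate

The synthetic populations reproduce the structural features that matter for
weighting: demographic effects of realistic relative size (education
dominant), independence of the three variables in the reference, pure
marginal distortions, pure joint distortions, and clustered sampling. They
do not emulate measurement non-invariance across groups (the 1-PL item
parameters are identical for everyone), age-varying demographic effects,
within-cell heteroscedasticity, or missing data. Passing tests therefore
show that weighting corrects *sampling* bias under a correctly specified
demographic model; they say nothing about bias from differential item
functioning or from demographic variables that are unobserved or
miscoded.

## Known limitations

- With strong marginal bias, the unweighted method's error is dominated by
  a location shift that peaks mid-scale; per-bin RMSE is then center-peaked
  rather than tail-peaked. Weighting restores the usual parabolic profile.
- Raking corrects marginal non-representativeness only; scenarios 5 and 6
  are included precisely to show that joint-distribution distortions with
  intact marginals are neither helped nor harmed.
- Norm scores outside roughly ±2.6 SD of a 100-per-cohort sample rest on
  polynomial extrapolation; clamping at the monotone-segment edge bounds
  but does not remove the resulting tail error.
- The group-mean-age convention makes the fitted age trend exact only at
  the cohort centers; ages near 0 and 6 are extrapolated by up to half a
  year.
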