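# Methods

## Score construction

The bioage score treats biological age as the conditional expectation
of chronological age given a marker vector, `B~ = E[A | M]`, and
approximates that conditional expectation within the space of affine
functions of the markers — i.e. a multiple linear regression of age on
the z-scored panel.  Markers are z-scored against the training
population (mean `x̄_i`, sample SD `σ_i`, divisor `n−1`) so the fitted
weights `b_i` (years per z-unit) are comparable across assays with
different units.

Because OLS fitted values are shrunk toward the mean response — the
regression slope of `B~` on `A` equals the multiple `r²`, and
`corr(B~, A) = +√r²` — the raw score under-disperses: an even-aged
group of 70-year-olds would average a raw bioage well below 70.  The
correction

    B = (B~ − mean(a)) / r² + mean(a)

divides the centred raw score by `r²`, restoring a unit slope of `B`
on `A` and a zero mean age difference on the training set.  It is
strictly monotone, so the biologically-younger-than ordering induced by
`B~` is preserved.  These identities (`mean(AD) = 0`, slope of `B` on
`A` = 1, `Cov(AD, A) = 0`) are exact OLS algebra and are asserted to
1e-8 in the test suite.  `r` is taken as the non-negative root of the
stored `r²` (a multiple correlation is non-negative by construction).

Scaling parameters, weights, intercept, `r²` and the training mean age
are frozen at fit time; scoring external subjects never refits
anything.  Subjects missing a model marker are flagged and left
unscored rather than dropped, so incompleteness stays reportable.

## Data hygiene

Two outlier rules coexist deliberately.  The IQR fence with `k = 1.3`
(value outside `[Q1 − 1.3·IQR, Q3 + 1.3·IQR]`) is univariate QC
reporting.  Subject exclusion before fitting uses the per-marker
`[0.01, 0.99]` empirical-quantile rule: a subject is excluded if any
panel marker falls strictly outside the closed quantile interval of
that marker in the training table.  Quantiles use linear interpolation
over the sorted sample (type-7, the numpy default); the convention is
recorded in the filter report.  The filter order is fixed — subgroup
restriction, complete-case on the panel, then quantile exclusion with
bounds computed on the complete-case training table and frozen for any
later reuse.  Training excludes all female hormone users regardless of
age (the conservative reading of the training-set rule); missing values
are never imputed.

A consequence worth knowing: the quantile rule excludes roughly
`1 − 0.98^p` of subjects when applied over `p` candidate markers, about
half the sample at the default 32-marker candidate panel.  This is the
literal rule at desk scale; the surviving training sets (~120–180 per
sex at the default cohort size) are ample for a 10-marker fit.

## Marker screening and subset selection

Each candidate is summarised by Pearson `rp`, Spearman `rnp`
(mid-ranks), and the least-squares line of the marker on age.
Preselection ranks by `|rnp|` (configurable to `|rp|`; the choice is
genuinely open — rank correlation is robust to the monotone-but-
nonlinear trajectories common in ageing markers), keeping the top 30 by
default.  Ties break by larger `n`, then lexical name, for determinism.

The 10-marker subset maximises the OLS `R²` against age at fixed size —
no penalised criterion, since subset size is fixed a priori.  The
branch-and-bound search uses the monotonicity bound (any subset's
attainable `R²` is at most its superset's), a greedy-forward warm
start, and strongest-marginal-correlation-first ordering; it provably
returns the global optimum and is validated against exhaustive
enumeration on random instances.  Equal-`R²` ties (within 1e-12)
resolve to the lexically smallest name set.  Rank deficiency is
detected via near-zero Cholesky pivots (relative threshold 1e-10) and
reported with the offending column names.  `auto` dispatch: exhaustive
when the subset count is ≤ 20000, branch and bound up to 40
candidates, greedy forward (documented heuristic, no optimality
guarantee) beyond.

## Group contrasts

Effect sizes are Hodges–Lehmann estimates: the median of all pairwise
differences (two-sample) or Walsh averages (one-sample).  Confidence
intervals are the distribution-free order-statistic construction: the
endpoints are the difference-set order statistics at the critical ranks
of the exact Mann–Whitney (resp. signed-rank) null distribution.  The
exact null distributions are built from the generating polynomials
(the Gaussian binomial for rank sums; `Π(1 + q^i)` for signed ranks) in
float64 — counts reach ~1e40 but only relative accuracy matters — and
are used whenever the smaller sample has ≤ 50 observations, with the
standard normal approximation beyond.  The construction reproduces R's
`wilcox.test(conf.int = TRUE)` intervals exactly on tie-free data
(frozen cross-check fixtures in the test suite).  Ties are handled by
mid-ranks in the tests' p-values but the CI construction assumes
continuous data, as here.

Every contrast reports the HL shift with CI, a two-sided unpaired
t-test (pooled variance) and a Mann–Whitney test; α = 0.05, no
multiplicity correction (raw p-values are the convention for these
confirmatory contrasts).  Age matching restricts both groups to their
common observed age range before comparison — no 1:1 matching, which
would require inventing a pairing algorithm.  The hormone contrast is
split at 50 years (under-50 users are presumed contraceptive users,
over-50 users hormone-replacement users); an empty stratum yields a
warning, not a failure.  Smoking dose–response is the OLS of age
difference on cumulative packs among current smokers.

## Dichotomy screen

For each external marker and sex, two independent simple regressions
are fitted with the marker as response: on chronological age (CA) and
on age difference (AD).  The regression direction follows the
convention of plotting the marker against the age axis; the zero-slope
p-value is direction-invariant in any case.  Classification at
α = 0.05: `AD` if only the AD slope is significant, `CA` if only the CA
slope, `both`/`neither` otherwise — a pure function of the two
p-values.  HOMA-IR uses the Matthews formula
`glucose [mg/dL] × insulin [µU/mL] / 405` (an assumption; the index is
named but not defined in the source analyses this mirrors), and
subjects with glucose strictly above 250 mg/dL (severe hyperglycaemia)
are excluded beforehand; a value exactly at 250 is retained.

## Synthetic cohort generator

The generator emulates an age-stratified cross-sectional recruitment:
eight 5-year strata spanning 35–74 years, ages uniform within stratum,
110 subjects per stratum per sex by default.  Every subject carries a
latent pace-of-ageing deviation `P ~ N(0, pace_sd²)`, independent of
age, with `pace_sd = 5` years (chosen to give an age-difference spread
comparable to what a score with `r ≈ 0.9` implies).  Panel markers
follow

    marker_i = baseline_i + age_slope_i·(A + shift) + pace_loading_i·P_eff + ε_i

with independent Gaussian noise.  Subgroup shifts enter the marker
equation only (the recorded chronological age is untouched): the
DS-like progeroid group at +5 latent years, hormone users older than 50
at −2 years (users under 50 get no shift — the contraceptive-use
regime), GO/SGO at 0 (null comparison groups).  Smoking adds to the
pace, `P_eff = P + 0.002·packs`, with cumulative packs zero-inflated
lognormal (30% smokers, median ~500 packs), giving a median smoker
about +1 year of age advancement and heavy smokers several years.
Under this construction the population expectation of a shifted
subgroup's age difference equals the injected shift exactly, which is
what makes the recovery tests sharp.

The default candidate panel holds 32 generic Gaussian markers with
age correlations spanning ~0.08–0.80 (mixed signs), mirroring the
spread of a realistic candidate panel; most markers track latent
biological age (`pace_loading = age_slope`), a few are pure
chronological trackers or doubly pace-sensitive.  External markers
carry the driver/bystander dichotomy by construction: drivers (HDL-,
vitamin-D- and CD4-ratio-like) load on the pace only, bystanders
(glucose-, HbA1c-like) on age only, insulin-like on both, each tuned to
a marginal correlation of ~0.2 with its driving variable — the
weak-effect regime reported for such associations.  Missingness is
completely at random (2% per marker cell); injected outliers replace a
value by `Q3 + 10·IQR` of its column so that both outlier rules fire.

What the generator does **not** emulate: assay-specific distributions
(methylation betas, glycan ratios), inter-marker residual correlation
beyond what age and pace induce (markers are conditionally independent
given `(A, P)`), informative missingness, batch or centre effects.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated generative model, not robustness
to real-data pathologies.

`inject_subgroup` applies a latent-age shift to existing rows as a
deterministic affine marker adjustment (`age_slope·shift` per marker,
keeping the original noise draw) rather than resampling: a zero shift
is then an exact identity and, noise-free, a shifted subject's markers
equal those of an unshifted subject `shift` years older.

## Problem sizes and numerical tolerances

Unit tests run at n of tens to hundreds; the deeper recovery studies
use 800 subjects per sex and 100 seeds (weight recovery within 3 SE;
driver/bystander classification), and the injected-shift study uses 30
shifted subjects against ~400 reference subjects over 100 seeds.  The
whole suite completes in well under a minute on one core.  Calibration
identities are asserted to 1e-8; oracle equalities (brute-force HL,
exhaustive subsets) to 1e-10; Monte-Carlo rate assertions carry
explicit binomial tolerances.

## Known limitations

- The correction divides by the in-sample `r²`, which is upward-biased
  by roughly `p/n`; recovered subgroup shifts are correspondingly
  attenuated by a few percent at `n ≈ 400` (the +5-year injection is
  recovered as ≈ 4.88 on average).  This is a property of the method,
  not a bug, and vanishes as the training set grows.
- The HL confidence interval treats subjects as independent; shared
  model-estimation error adds a small between-cohort variance component
  when scoring and training share data, slightly reducing coverage
  below nominal (measured ≈ 0.94 at the study-like sizes against a
  nominal 0.95).
- Best-subset optimality is guaranteed only up to 40 candidates; beyond
  that the forward heuristic engages and is labelled as such in the
  result.
- No uncertainty is attached to an individual's bioage; the score is a
  point prediction.
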