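# Methods

## Model and assumptions

`sbcc` works in a Balding–Nichols world.  Per SNP `j` an ancestral
reference-allele frequency `p_j` is drawn uniformly from a common-SNP band
(default `[0.05, 0.5]`, configurable); each of `m` subpopulations receives a
drifted frequency `p_ij ~ Beta` with mean `p_j` and variance `F_i p_j(1-p_j)`;
subjects carry two independent alleles from their subpopulation's frequency
(Hardy–Weinberg within subpopulation), additively coded `G = X1 + X2 ∈
{0,1,2}`.  SNPs are independent — `o` is always interpreted as an
*equivalent number of independent markers*, and no linkage disequilibrium is
modeled.  Case/control labels are pure bookkeeping: none of the simulated
markers is associated with phenotype, because the membership signal under
study is sampling covariance between a subject and the published
frequencies, not association.  Each subject belongs to exactly one
subpopulation (no admixture).

The theory only requires the first two moments — `Var(G) = 2p(1-p)(1+F)`
and `Cov = 4p(1-p)F` within a subpopulation, zero across — and the Beta
construction realizes them exactly.  The distributional family is otherwise
a modeling choice; any law with those moments would give the same closed
forms.

## Closed forms

`cgr_exact` assembles `Cor(G, p_hat)` term-by-term from the pairwise
moments for an arbitrary design (per-subpopulation case/control counts
`n_i, n'_i`, reporting weight `omega`, subject in or out of the cohort).
The common factor `2p(1-p)` cancels, which the test suite asserts against
an O(n²) pairwise-sum oracle evaluated at several explicit `p`.  The
equal-design large-sample form, the `omega = 1` special case
`rho(F) = (1+2nF/m)/sqrt((1+F)(n+2n²F/m))` and its first-order Taylor form
`1/sqrt(n) + sqrt(n)F/m` are separate functions so each printed
approximation can be checked against the exact moments.

Two facts discovered in validation are worth recording:

* the Taylor form is only usable while `nF/m` is small; by `nF/m ≈ 4` it
  overshoots the closed form by ~70%.  Tests exercise it in its validity
  region and check the slope `sqrt(n)/m` by numerical differentiation;
* an out-of-cohort subject from a sampled subpopulation has expected
  correlation `≈ 2·sqrt(n)F/m` for small `nF/m` (exactly the `cgr_exact`
  out-of-cohort moments), i.e. roughly *twice* the bias that the standard
  first-order correction subtracts.  The residual is second-order and
  shifts the null Z by about +0.1 at the default validation configuration;
  the package keeps the standard correction and documents the shift rather
  than invent a different statistic.

## Power machinery

`detection_power(alpha, n, n_s, panel_size, o)` evaluates
`m = max(round(n/n_s), 2)` (nearest integer, ties away from zero — `n_s` is
the average number of cases per contributing study), `k = n/panel_size`,
`mu = (1/sqrt(n))/sqrt(1/o + k/m²)` and `q = Phi(mu - Phi^{-1}(1-alpha))`.
`o = inf` (the default for headline numbers) is the conservative bound;
`o = 50,000` is a realistic genome-wide value.  With `o = inf` the expected
Z simplifies to `m·sqrt(n'')/n`, which makes the power surface's shape
transparent: `q` falls with cohort size until `n ≈ 2 n_s` and then plateaus
near `Phi(sqrt(n'')/n_s - tau_alpha)`.  Because `m` is integer-valued the
exact sequence wiggles by `O(1/2m)` around this monotone envelope; shape
assertions in the tests allow for that discreteness.

## The membership test and its calibration

The test statistic is `z = (rho_hat - (sqrt(n)/m)·F_tilde) / sqrt(1/o + k/m²)`,
one-sided.  `rho_hat` is the Pearson correlation across SNPs between the
standardized deviations `(G_j - 2p_j)/sqrt(2p_j(1-p_j))` and
`(p_hat_j - p_j)/sqrt(2p_j(1-p_j))`.  The reference frequencies `p_j` here
are the attacker's *assumed population frequencies* — the premise of the
entire derivation.  In simulation they are the true ancestral frequencies
(carried in the RAF table's `p_ref` column); a pooled estimate from a
perfectly matching panel is selectable (`ref_source="panel"`) but changes
the statistic's distribution, because a panel drawn from the same realized
subpopulations shares their drift and cancels the very signal the bias
correction is built for.

The variance term `k/m²` is the budget for estimating `F` from a panel of
`n'' = n/k` subjects, and it is consistent with an estimator whose sampling
variance is `1/n''` — the variance of a correlation coefficient computed
from `n''` paired observations.  This pins down the estimator design:

* `estimate_fst` (ANOVA): sample-size-weighted between-subpopulation
  variance of panel frequencies, corrected for binomial sampling noise in
  both numerator and denominator, combined over SNPs as a ratio of
  averages.  Averaging over thousands of SNPs makes its standard error
  ~10⁻⁴ — ideal for parameter recovery (tests recover `F ∈ {0, 0.002,
  0.006, 0.01}` within 4 SE at `n''=2,000`, `o=5,000`), and far *smaller*
  than `1/n''`.
* `estimate_fst_pairing`: each panel subject contributes the product of its
  two standardized alleles at a single deterministically assigned SNP
  (subject `s` reads SNP `s mod o`; computable from the dosage alone as
  `1[G=2] - pG + p²`).  Unbiased for the panel-share-weighted mean `F`,
  variance `≈ 1/n''` by construction, and deliberately not floored at zero.

The membership test defaults to the pairing estimator because the statistic
is only *calibrated* when the claimed null variance matches the actual one.
Plugging the precise ANOVA estimate into a statistic standardized by
`sqrt(1/o + k/m²)` yields a test whose actual null scatter is a tenth of
its claimed scatter — empirical type-I error collapses to zero and
empirical power falls far below the analytic `q`.  With the pairing
estimator the null Z is ~N(0.05–0.1, 1) (the small mean shift is the
second-order Taylor residual above): empirical type-I error sits inside the
binomial band of the nominal 5% at the default validation configuration
(`n=200, m=2, F=0.005, o=5,000, n''=2,000`), and empirical power (~0.10)
agrees with the analytic bound (0.115) to within Monte-Carlo error.  Note
the flooring asymmetry is intentional: the recovery-oriented ANOVA estimate
is floored into `[0, 1)`, the attacker-grade pairing estimate is not, since
its negative excursions are exactly what realizes the test's nominal
false-positive rate.

An `oracle` mode (true `F`, true `p`) separates estimation noise from model
error in the validation suite.

## Replicate harness

`evaluate_error_rates` simulates, per replicate, a fresh cohort and
matching panel and tests one in-cohort case (power) and one out-of-cohort
same-subpopulation subject (type-I), with exact binomial confidence
intervals.  It never materializes subject-by-SNP matrices: per-stratum
allele counts are binomial sufficient statistics for every
frequency-based quantity, the tested subjects' dosage vectors are drawn
directly, and the pairing estimator needs one dosage per panel subject.
The count-level code paths are the same functions the matrix interface
reduces to (`GenotypeMatrix.stratum_counts` → `fst_from_counts`, etc.), so
the fast harness is distributionally exact, not an approximation — a unit
test asserts the reduction equality.  Replicates draw from spawned child
seeds, so extending a run preserves earlier replicates.

Default validation scales — `o = 5,000` SNPs, 200 replicates per
configuration (1,000 for type-I calibration) — keep the full suite around a
minute while leaving Monte-Carlo standard errors small enough for the 3–4
SE acceptance bands used throughout.

## Worked-example gap

Strict evaluation of the power pipeline at the 30,000-case configuration
(`n_s=700`, `n''=12,000`, `alpha=0.05`, `o=inf`) gives 6.84%, slightly
above the commonly quoted ~6.6% for this scenario; the difference (~0.24
percentage points) is within rounding of the inputs (e.g. whether `n/n_s`
is rounded before or after the panel ratio), and the package reports what
the printed formulas produce rather than reverse-engineering unstated
inputs.

## What the simulator does not capture

Real cohorts have linkage disequilibrium (so `o` must be estimated, not
counted), genotyping error, imputation uncertainty, ascertained
disease-associated SNPs, admixed individuals, per-locus variation in `F`,
and reference panels whose ethnic composition only approximately matches
the cohort.  Passing tests therefore demonstrate internal consistency of
theory and generator — that the closed forms, the test and the power bound
are correct *under the stated model* — not that the specific numeric power
values transfer to any particular real data set.  The qualitative
conclusion (stratification noise overwhelms the membership signal for
cohorts beyond ~1,000 cases) is driven by the `k/m²` term, which only grows
with the realism gaps above.

## Degenerate inputs and numerical choices

Drawn subpopulation frequencies are clamped to `[1e-6, 1-1e-6]` (the theory
assumes polymorphic markers).  `empirical_cgr` requires ≥ 30 SNPs and
rejects zero-variance deviation vectors.  `rho0_variance` accepts `o = inf`
but rejects the doubly degenerate `o = inf, k = 0`.  A single-subpopulation
panel returns `F = 0` by convention; ANOVA estimation requires ≥ 2 subjects
per labeled subpopulation.  All stochastic entry points take explicit seeds
and are bit-reproducible; writers are byte-deterministic; readers reject
rather than coerce.
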