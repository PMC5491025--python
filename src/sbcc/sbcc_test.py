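"""The cohort-membership test: bias correction, Z-statistic, error rates.

Pipeline: the attacker computes the empirical genotype/RAF correlation
``rho_hat`` of a target subject against the published frequencies, subtracts
the stratification bias ``(sqrt(n)/m) * F_tilde`` estimated from a matching
reference panel, and standardizes by ``sqrt(1/o + k/m^2)``.  One-sided test
of "subject not in cohort" (corrected correlation 0) against membership.

Two fixation-index estimators are provided, with different jobs:

* :func:`estimate_fst` — sample-size-weighted, noise-corrected ANOVA ratio
  of between-subpopulation frequency variance to total allele variance,
  averaged over SNPs (ratio-of-averages).  Precise parameter recovery; its
  sampling error at genome scale is orders of magnitude below ``1/n''``.
* :func:`estimate_fst_pairing` — one standardized allele-pair observation
  per panel subject (F is the within-subpopulation allele correlation, and a
  correlation estimated from ``n''`` observations has variance ``~ 1/n''``).
  This is the estimator whose uncertainty the test's ``k/m^2`` variance term
  budgets for, so it is the attacker-grade default inside the test: with it
  the Z-statistic's claimed null variance matches its actual null variance
  and the test is calibrated.  It is deliberately not floored at zero — the
  statistic's null rejections come from the estimator's symmetric noise.

See docs/methods.md for why mixing the precise estimator with the
``1/o + k/m^2`` standardization would make the test far too conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, norm

from .cgr_analytic import rho0_variance
from .simulator import (
    GenotypeMatrix,
    RafTable,
    draw_snp_frequencies,
    empirical_cgr,
    stratum_allele_counts,
)
from .strat_model import CohortDesign, PanelSpec, PopulationStructure

__all__ = [
    "SbccResult",
    "estimate_fst",
    "estimate_fst_pairing",
    "sbcc_statistic",
    "run_membership_test",
    "evaluate_error_rates",
]


@dataclass(frozen=True)
class SbccResult:
    """Outcome of one membership test."""

    rho_hat: float
    f_tilde: float
    rho0_hat: float
    se: float
    z: float
    p_value: float
    reject: bool
    alpha: float
    n: int
    m: int
    o: float
    k: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def fst_from_counts(
    allele_counts: np.ndarray,
    subjects_per_subpop: np.ndarray,
    floor: bool = True,
) -> tuple[float, float]:
    """ANOVA fixation-index estimate from per-subpopulation allele counts.

    ``allele_counts`` is ``m x o`` reference-allele sums; per SNP the
    between-subpopulation variance of frequencies (noise-corrected, weighted
    by subpopulation share) is ratioed against the total allele variance,
    and SNPs are combined as a ratio of averages.  Returns ``(fst, se)``
    where ``se`` is the delta-method standard error across SNPs.
    """
    counts = np.asarray(allele_counts, dtype=float)
    c = np.asarray(subjects_per_subpop, dtype=float)
    m, o = counts.shape
    if c.size != m:
        raise ValueError("subject count vector must match the stratum count")
    if m == 1:
        return 0.0, 0.0
    if np.any(c < 2):
        raise ValueError("need at least 2 subjects per labeled subpopulation")
    w = c / c.sum()
    ph = counts / (2.0 * c)[:, None]  # m x o subpopulation frequencies
    pbar = w @ ph
    between = (w[:, None] * (ph - pbar) ** 2).sum(axis=0)
    # unbiased within-stratum p(1-p), then remove its leakage into `between`
    d_hat = ph * (1.0 - ph) / (2.0 * c - 1.0)[:, None]
    w2 = float((w**2).sum())
    num = (between - ((w * (1 - w))[:, None] * d_hat).sum(axis=0)) / (1.0 - w2)
    # total variance: p(1-p) with the variance of pbar added back
    den = pbar * (1.0 - pbar) + ((w**2)[:, None] * d_hat).sum(axis=0) + w2 * num
    den_sum = float(den.sum())
    if den_sum <= 0:
        raise ValueError("degenerate panel: zero total allele variance")
    fst = float(num.sum()) / den_sum
    resid = num - fst * den
    se = float(np.sqrt(resid.var(ddof=1) / o) / den.mean()) if o > 1 else np.inf
    if floor:
        fst = min(max(fst, 0.0), 1.0 - 1e-12)
    return fst, se


def estimate_fst(panel: GenotypeMatrix, return_se: bool = False):
    """Panel fixation index by the weighted, noise-corrected ANOVA estimator.

    Requires subpopulation labels with at least two subjects per labeled
    subpopulation; a single-subpopulation panel returns 0 by convention.
    """
    ca, cn, co, un = panel.stratum_counts()
    counts = ca + co
    subjects = cn + un
    keep = subjects > 0
    fst, se = fst_from_counts(counts[keep], subjects[keep])
    return (fst, se) if return_se else fst


def pairing_fst_from_obs(dosages: np.ndarray, ref_freqs: np.ndarray) -> float:
    """Mean standardized allele-pair product, one observation per subject.

    For an additive dosage ``G`` at a SNP with assumed frequency ``p`` the
    product of its two centered alleles is ``1[G=2] - p G + p^2``, so the
    estimate needs no phase information.  Unfloored by design.
    """
    g = np.asarray(dosages, dtype=float)
    p = np.asarray(ref_freqs, dtype=float)
    prod = (g == 2).astype(float) - p * g + p**2
    return float(np.mean(prod / (p * (1.0 - p))))


def estimate_fst_pairing(panel: GenotypeMatrix, ref_freqs: np.ndarray) -> float:
    """Attacker-grade fixation index: variance ``~ 1/n''`` by construction.

    Each panel subject contributes the correlation product of its two
    alleles at a single deterministically assigned SNP (subject ``s`` reads
    SNP ``s mod o``), standardized by the assumed population frequency.
    The estimate is unbiased for the panel-share-weighted mean fixation
    index, and its sampling noise is exactly what the membership test's
    ``k/m^2`` variance term describes.
    """
    p = np.asarray(ref_freqs, dtype=float)
    if p.size != panel.n_snps:
        raise ValueError("reference frequencies must align with panel SNPs")
    idx = np.arange(panel.n_subjects) % panel.n_snps
    g = panel.dosages[np.arange(panel.n_subjects), idx]
    return pairing_fst_from_obs(g, p[idx])


def sbcc_statistic(
    rho_hat: float,
    n: int,
    m: int,
    f_tilde: float,
    o: float,
    k: float,
    alpha: float = 0.05,
) -> SbccResult:
    """Bias-corrected membership Z-test.

    ``rho0_hat = rho_hat - (sqrt(n)/m) f_tilde``;
    ``z = rho0_hat / sqrt(1/o + k/m^2)``; one-sided p-value ``1 - Phi(z)``.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    var = rho0_variance(o, k, m)
    if var == 0.0:
        raise ValueError("zero variance: need finite o or a finite panel (k > 0)")
    rho0 = rho_hat - np.sqrt(n) / m * f_tilde
    se = float(np.sqrt(var))
    z = float(rho0 / se)
    p_value = float(1.0 - norm.cdf(z))
    tau = norm.ppf(1 - alpha)
    return SbccResult(
        rho_hat=float(rho_hat),
        f_tilde=float(f_tilde),
        rho0_hat=float(rho0),
        se=se,
        z=z,
        p_value=p_value,
        reject=bool(z > tau),
        alpha=alpha,
        n=int(n),
        m=int(m),
        o=float(o),
        k=float(k),
    )


def _aligned(raf: RafTable, panel: GenotypeMatrix) -> None:
    if raf.n_snps != panel.n_snps or np.any(raf.snp_ids != panel.snp_ids):
        a = set(map(str, raf.snp_ids))
        b = set(map(str, panel.snp_ids))
        off = sorted(a.symmetric_difference(b))[:10]
        raise ValueError(
            "RAF table and panel SNP ids are not aligned; offending ids "
            f"(up to 10): {off if off else 'same set, different order'}"
        )


def run_membership_test(
    subject_dosages: np.ndarray,
    raf: RafTable,
    panel: GenotypeMatrix,
    design: CohortDesign,
    alpha: float = 0.05,
    o: float | None = None,
    ref_source: str | np.ndarray = "raf",
    fst_method: str = "pairing",
    f_true: float | None = None,
) -> SbccResult:
    """End-to-end membership test for one subject.

    ``ref_source`` selects the assumed population frequencies: ``"raf"``
    (the table's ``p_ref`` column, default), ``"panel"`` (pooled panel
    frequencies — note a matching panel's pooled frequency absorbs the
    drift signal and changes the test's operating characteristics), or an
    explicit array.  ``fst_method`` is ``"pairing"`` (attacker-grade,
    calibrated default), ``"anova"`` (precise), or ``"oracle"`` (use
    ``f_true``).  Deterministic given its inputs.
    """
    _aligned(raf, panel)
    if isinstance(ref_source, str):
        if ref_source == "raf":
            if raf.p_ref is None:
                raise ValueError("RAF table has no p_ref column; pass frequencies explicitly")
            ref = raf.p_ref
        elif ref_source == "panel":
            ref = panel.dosages.mean(axis=0) / 2.0
            ref = np.clip(ref, 1e-6, 1 - 1e-6)
        else:
            raise ValueError(f"unknown ref_source {ref_source!r}")
    else:
        ref = np.asarray(ref_source, dtype=float)

    rho = empirical_cgr(subject_dosages, raf, ref)
    if fst_method == "pairing":
        f_tilde = estimate_fst_pairing(panel, ref)
    elif fst_method == "anova":
        f_tilde = estimate_fst(panel)
    elif fst_method == "oracle":
        if f_true is None:
            raise ValueError("oracle mode requires f_true")
        f_tilde = float(f_true)
    else:
        raise ValueError(f"unknown fst_method {fst_method!r}")

    n = design.n_cases
    m = design.m
    k = n / panel.n_subjects
    if o is None:
        o = float(raf.n_snps)
    return sbcc_statistic(rho, n, m, f_tilde, o, k, alpha=alpha)


def _binom_ci(successes: int, trials: int) -> tuple[float, float]:
    ci = binomtest(successes, trials).proportion_ci(confidence_level=0.95, method="exact")
    return float(ci.low), float(ci.high)


def evaluate_error_rates(
    design: CohortDesign,
    structure: PopulationStructure,
    panel: PanelSpec,
    o: int,
    alpha: float = 0.05,
    replicates: int = 200,
    seed: int | None = 0,
    fst_method: str = "pairing",
    ref_source: str = "true",
    subject_subpop: int = 0,
    details: bool = False,
):
    """Empirical power and type-I error of the full membership test.

    Each replicate simulates a fresh stratified cohort and matching panel
    (shared realized subpopulation frequencies), tests one in-cohort case
    (power) and one out-of-cohort subject from the same subpopulation
    (type-I), both from ``subject_subpop``.  Replicates use per-subpopulation
    allele counts and single-subject dosage draws — the binomial sufficient
    statistics of the full subject-level simulation — through the same
    estimator code as the matrix path.  Child seed ``r`` drives replicate
    ``r``, so extending ``replicates`` preserves earlier outcomes.

    ``ref_source="true"`` uses the simulated ancestral frequencies as the
    attacker's assumed population frequencies (the theory's premise);
    ``"panel"`` uses pooled panel estimates.  ``fst_method`` as in
    :func:`run_membership_test`, plus ``"oracle"`` (true common F).
    With ``details=True`` also returns a per-replicate frame of statistics.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if design.m != structure.m or panel.composition.size != structure.m:
        raise ValueError("design, structure and panel disagree on subpopulation count")
    if design.cases_per_subpop[subject_subpop] < 1:
        raise ValueError("subject's subpopulation has no cases")
    children = np.random.SeedSequence(seed).spawn(replicates)

    n = design.n_cases
    n_ctrl = design.n_controls
    m = design.m
    omega = design.omega
    n_panel = panel.panel_size
    k = n / n_panel
    f_common = float(structure.fixation.mean())
    pairing_idx = np.arange(n_panel) % o
    pairing_sub = np.repeat(np.arange(m), panel.composition)

    rej_in = rej_out = 0
    z_in = np.empty(replicates)
    z_out = np.empty(replicates)
    rho_in = np.empty(replicates)
    rho_out = np.empty(replicates)
    f_tildes = np.empty(replicates)
    for r in range(replicates):
        rng = np.random.default_rng(children[r])
        p, pf = draw_snp_frequencies(structure, o, rng)
        i0 = subject_subpop
        g_in = rng.binomial(2, pf[i0], size=o)
        case_counts = stratum_allele_counts(design.cases_per_subpop, pf, rng)
        rest = rng.binomial(2 * (design.cases_per_subpop[i0] - 1), pf[i0], size=o)
        case_counts[i0] = rest + g_in
        p_hat = omega * case_counts.sum(axis=0) / (2.0 * n) if omega > 0 else 0.0
        if omega < 1:
            ctrl_counts = stratum_allele_counts(design.controls_per_subpop, pf, rng)
            p_hat = p_hat + (1 - omega) * ctrl_counts.sum(axis=0) / (2.0 * n_ctrl)
        g_out = rng.binomial(2, pf[i0], size=o)

        panel_counts = None
        if ref_source == "panel" or fst_method == "anova":
            panel_counts = stratum_allele_counts(panel.composition, pf, rng)
        if ref_source == "true":
            ref = p
        elif ref_source == "panel":
            ref = np.clip(panel_counts.sum(axis=0) / (2.0 * n_panel), 1e-6, 1 - 1e-6)
        else:
            raise ValueError(f"unknown ref_source {ref_source!r}")

        if fst_method == "pairing":
            g_pair = rng.binomial(2, pf[pairing_sub, pairing_idx])
            f_tilde = pairing_fst_from_obs(g_pair, ref[pairing_idx])
        elif fst_method == "anova":
            f_tilde, _ = fst_from_counts(panel_counts, panel.composition)
        elif fst_method == "oracle":
            f_tilde = f_common
        else:
            raise ValueError(f"unknown fst_method {fst_method!r}")
        f_tildes[r] = f_tilde

        for g, z_arr, rho_arr, which in (
            (g_in, z_in, rho_in, "in"),
            (g_out, z_out, rho_out, "out"),
        ):
            rho = empirical_cgr(g, p_hat, ref)
            res = sbcc_statistic(rho, n, m, f_tilde, float(o), k, alpha=alpha)
            z_arr[r] = res.z
            rho_arr[r] = rho
            if res.reject:
                if which == "in":
                    rej_in += 1
                else:
                    rej_out += 1

    lo_p, hi_p = _binom_ci(rej_in, replicates)
    lo_t, hi_t = _binom_ci(rej_out, replicates)
    summary = pd.DataFrame(
        [
            {
                "n": n,
                "n_controls": n_ctrl,
                "m": m,
                "omega": omega,
                "F": f_common,
                "o": o,
                "panel_size": n_panel,
                "k": k,
                "alpha": alpha,
                "replicates": replicates,
                "fst_method": fst_method,
                "ref_source": ref_source,
                "power": rej_in / replicates,
                "power_ci_low": lo_p,
                "power_ci_high": hi_p,
                "type1": rej_out / replicates,
                "type1_ci_low": lo_t,
                "type1_ci_high": hi_t,
                "mean_z_in": float(z_in.mean()),
                "mean_z_out": float(z_out.mean()),
                "sd_z_out": float(z_out.std(ddof=1)) if replicates > 1 else np.nan,
                "mean_rho_in": float(rho_in.mean()),
                "mean_rho_out": float(rho_out.mean()),
                "sd_rho_in": float(rho_in.std(ddof=1)) if replicates > 1 else np.nan,
                "sd_rho_out": float(rho_out.std(ddof=1)) if replicates > 1 else np.nan,
                "mean_f_tilde": float(f_tildes.mean()),
                "sd_f_tilde": float(f_tildes.std(ddof=1)) if replicates > 1 else np.nan,
            }
        ]
    )
    if details:
        per_rep = pd.DataFrame(
            {
                "replicate": np.arange(replicates),
                "z_in": z_in,
                "z_out": z_out,
                "rho_in": rho_in,
                "rho_out": rho_out,
                "f_tilde": f_tildes,
            }
        )
        return summary, per_rep
    return summary
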