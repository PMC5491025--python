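"""Closed-form genotype/RAF correlation and analytic membership-test power.

The correlation between one case's additive genotype ``G`` and the published
per-SNP frequency ``p_hat`` (the CGR) measures how much a shared frequency
table leaks about cohort membership.  For an unstratified cohort of ``n``
cases it equals ``1/sqrt(n)``; under stratification the within-subpopulation
allele correlation ``F`` adds a bias that grows with cohort size.  For a
cohort with equal subpopulations reporting case frequencies::

    rho(F) = (1 + 2 n F / m) / sqrt((1 + F) (n + 2 n^2 F / m))
           ~ 1/sqrt(n) + sqrt(n) F / m        (first-order Taylor)

The membership test subtracts the panel-estimated bias and standardizes by
``sqrt(1/o + k/m^2)`` where ``o`` is the equivalent number of independent
SNPs and ``k = n / n''`` the cohort-to-panel ratio; the expected Z-score for
a true cohort member is ``mu = (1/sqrt(n)) / sqrt(1/o + k/m^2)``, reducing
to the likelihood-ratio noncentrality ``mu^2 = o/n`` without stratification.
The one-sided detection power at type-I error ``alpha`` is
``q = Phi(mu - tau_alpha)``.

All formulas here are exact algebra over the second moments of
:mod:`sbcc.strat_model`; the simulator validates them empirically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .strat_model import CohortDesign, PopulationStructure

__all__ = [
    "CgrQuery",
    "cgr_exact",
    "cgr_moments",
    "cgr_equal_approx",
    "cgr_case",
    "cgr_taylor",
    "rho0_variance",
    "expected_z",
    "noncentrality",
    "detection_power",
    "subpop_count",
    "power_point",
    "power_grid",
    "plot_power_curves",
]


@dataclass(frozen=True)
class CgrQuery:
    """A subject whose genotype/RAF correlation is requested.

    ``subject_subpop`` indexes the subject's subpopulation (0-based);
    ``subject_in_cases`` says which stratum the subject was sampled into and
    ``in_cohort`` whether the subject actually contributed to the published
    frequencies (the out-of-cohort variant is the test's null case).
    """

    design: CohortDesign
    structure: PopulationStructure
    subject_subpop: int = 0
    subject_in_cases: bool = True
    in_cohort: bool = True

    def __post_init__(self) -> None:
        if self.design.m != self.structure.m:
            raise ValueError("design and structure disagree on subpopulation count")
        if not (0 <= self.subject_subpop < self.structure.m):
            raise ValueError("subject_subpop out of range")
        if self.in_cohort:
            counts = (
                self.design.cases_per_subpop
                if self.subject_in_cases
                else self.design.controls_per_subpop
            )
            if counts[self.subject_subpop] < 1:
                raise ValueError("subject's stratum is empty in this design")


def cgr_moments(query: CgrQuery) -> tuple[float, float, float]:
    """Second moments behind the CGR, in units of ``2 p (1-p)``.

    Returns ``(cov, var_g, var_phat)`` where ``cov = Cov(G, p_hat)``,
    ``var_g = Var(G)`` and ``var_phat = Var(p_hat)``, all divided by the
    common factor ``2 p (1-p)`` — the ancestral frequency cancels exactly,
    which is what makes the closed form usable without knowing ``p``.
    """
    d, s = query.design, query.structure
    F = s.fixation
    ncs = d.cases_per_subpop.astype(float)
    nco = d.controls_per_subpop.astype(float)
    n, np_ = float(d.n_cases), float(d.n_controls)
    w, i = d.omega, query.subject_subpop
    Fi = F[i]

    # Var(sum of stratum genotypes) / 2p(1-p) = sum n_i (1 + F_i) + 2 sum n_i (n_i - 1) F_i
    var_a = np.sum(ncs * (1 + F)) + 2 * np.sum(ncs * (ncs - 1) * F)
    var_u = np.sum(nco * (1 + F)) + 2 * np.sum(nco * (nco - 1) * F)
    # Cov(sum cases, sum controls) / 2p(1-p) = 2 sum n_i n'_i F_i
    cov_au = 2 * np.sum(ncs * nco * F)

    var_phat = 0.0
    if w > 0:
        var_phat += w**2 / (4 * n**2) * var_a
    if w < 1:
        var_phat += (1 - w) ** 2 / (4 * np_**2) * var_u
    if 0 < w < 1:
        var_phat += 2 * w * (1 - w) / (4 * n * np_) * cov_au

    # Cov(G, p_hat) / 2p(1-p): the subject pairs with every cohort member in
    # its subpopulation (2F each) and, if in the cohort, with itself (1+F).
    n_same_cases, n_same_controls = ncs[i], nco[i]
    cov = 0.0
    if query.in_cohort:
        if query.subject_in_cases:
            n_same_cases -= 1
        else:
            n_same_controls -= 1
    if w > 0 and n > 0:
        cov += w / (2 * n) * 2 * n_same_cases * Fi
    if w < 1 and np_ > 0:
        cov += (1 - w) / (2 * np_) * 2 * n_same_controls * Fi
    if query.in_cohort:
        self_weight = (w / (2 * n)) if query.subject_in_cases else ((1 - w) / (2 * np_))
        cov += self_weight * (1 + Fi)

    var_g = 1 + Fi
    return float(cov), float(var_g), float(var_phat)


def cgr_exact(query: CgrQuery) -> float:
    """Exact correlation between the subject's genotype and the published RAF.

    Assembled term-by-term from the genotype variance/covariance identities
    for an arbitrary (unequal-subpopulation, arbitrary-omega) design.  The
    ancestral frequency cancels, so the result depends only on counts,
    fixation indices and omega.
    """
    cov, var_g, var_phat = cgr_moments(query)
    denom = math.sqrt(var_g * var_phat)
    if denom == 0.0:
        raise ValueError("degenerate design: published frequency has zero variance")
    return cov / denom


def cgr_equal_approx(n: int, m: int, F: float, omega: float = 1.0) -> float:
    """Large-sample CGR for equal subpopulations and a common fixation index.

    Assumes ``F_i = F`` and ``n_i = n'_i = n/m``; for ``omega = 1`` this is
    exactly the case-frequency closed form.  ``omega = 0`` (controls-only
    reporting) is handled by case/control symmetry: swap the roles and call
    with ``omega = 1``.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if not (0 <= F < 1):
        raise ValueError("F must lie in [0, 1)")
    if not (0 < omega <= 1):
        raise ValueError("omega must lie in (0, 1] for this form; for controls-only "
                         "reporting use the case/control swap (omega = 1)")
    r = (1 - omega) / omega
    num = 1 + 2 * (1 + r) * n * F / m
    den = (1 + F) * ((1 + r**2) * n + (1 + r) ** 2 * 2 * n**2 * F / m)
    return num / math.sqrt(den)


def cgr_case(n: int, m: int, F: float) -> float:
    """CGR of a case against the published case frequencies (omega = 1)."""
    return cgr_equal_approx(n, m, F, omega=1.0)


def cgr_taylor(n: int, m: int, F: float) -> float:
    """First-order Taylor form ``1/sqrt(n) + (sqrt(n)/m) F``."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if not (0 <= F < 1):
        raise ValueError("F must lie in [0, 1)")
    return 1.0 / math.sqrt(n) + math.sqrt(n) / m * F


def rho0_variance(o: float, k: float, m: int) -> float:
    """Variance of the bias-corrected correlation: ``1/o + k/m^2``.

    ``1/o`` is the finite-marker noise; ``k/m^2`` the cost of estimating the
    stratification bias from a panel ``1/k`` times the cohort's size.  ``o``
    may be ``inf`` (conservative infinite-marker bound).
    """
    if not (o >= 1):
        raise ValueError("o must be >= 1 (may be inf)")
    if k < 0:
        raise ValueError("k must be non-negative")
    if m < 1:
        raise ValueError("m must be >= 1")
    inv_o = 0.0 if math.isinf(o) else 1.0 / o
    return inv_o + k / m**2


def expected_z(n: int, o: float, k: float, m: int) -> float:
    """Expected membership Z-score ``mu = (1/sqrt(n)) / sqrt(1/o + k/m^2)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    var = rho0_variance(o, k, m)
    if var == 0.0:
        raise ValueError("zero variance: need finite o or a finite panel (k > 0)")
    return (1.0 / math.sqrt(n)) / math.sqrt(var)


def noncentrality(n: int, o: float) -> float:
    """Chi-square noncentrality ``lambda = mu^2 = o/n`` of the unstratified test.

    This is the likelihood-ratio figure of merit: detectability is governed by
    the ratio of independent markers to cohort size.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (o >= 1) or math.isinf(o):
        raise ValueError("o must be finite and >= 1")
    return o / n


def subpop_count(n: int, n_s: int) -> int:
    """Number of subpopulations ``m = max(round(n/n_s), 2)``.

    ``n_s`` is the average number of cases contributed per study; ties round
    half away from zero.
    """
    if n < 1 or n_s < 1:
        raise ValueError("n and n_s must be >= 1")
    ratio = n / n_s
    nearest = math.floor(ratio + 0.5)  # half away from zero (ratio > 0)
    return max(nearest, 2)


def detection_power(
    alpha: float,
    n: int,
    n_s: int,
    panel_size: int,
    o: float = math.inf,
) -> float:
    """One-sided power ``q = Phi(mu - tau_alpha)`` to detect a cohort member.

    ``m`` is derived from the cases-per-study average, ``k = n/panel_size``,
    and ``o = inf`` gives the conservative upper bound used for headline
    numbers.  ``q`` equals ``alpha`` exactly when ``mu = 0``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    m = subpop_count(n, n_s)
    k = n / panel_size
    mu = expected_z(n, o, k, m)
    tau = norm.ppf(1 - alpha)
    return float(norm.cdf(mu - tau))


def power_point(alpha: float, n: int, n_s: int, panel_size: int, o: float = math.inf) -> dict:
    """One row of the power table, with all derived quantities."""
    m = subpop_count(n, n_s)
    k = n / panel_size
    mu = expected_z(n, o, k, m)
    q = detection_power(alpha, n, n_s, panel_size, o)
    return {
        "alpha": alpha,
        "n": n,
        "n_s": n_s,
        "m": m,
        "panel_size": panel_size,
        "k": k,
        "o": o,
        "mu": mu,
        "q": q,
    }


def power_grid(
    alphas,
    n_range,
    n_s_set,
    panel_sizes,
    o: float = math.inf,
) -> pd.DataFrame:
    """Long-format power table over the Cartesian scenario grid."""
    rows = [
        power_point(a, int(n), int(ns), int(ps), o)
        for a in alphas
        for n in n_range
        for ns in n_s_set
        for ps in panel_sizes
    ]
    if not rows:
        raise ValueError("empty grid")
    return pd.DataFrame(rows)


def plot_power_curves(grid: pd.DataFrame, out_path: str) -> None:
    """Render power-vs-cohort-size curves, one panel per n_s.

    Reference lines mark q = 0.05 (the type-I error floor) and q = 0.1.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_s_values = sorted(grid["n_s"].unique())
    fig, axes = plt.subplots(
        1, len(n_s_values), figsize=(4 * len(n_s_values), 3.2), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, ns in zip(axes, n_s_values):
        sub = grid[grid["n_s"] == ns]
        for ps, curve in sub.groupby("panel_size"):
            curve = curve.sort_values("n")
            ax.plot(curve["n"], curve["q"], marker="o", ms=3, label=f"n''={ps:,}")
        ax.axhline(0.05, ls=":", color="grey")
        ax.axhline(0.10, ls="--", color="grey")
        ax.set_xscale("log")
        ax.set_xlabel("cohort size n")
        ax.set_title(f"n_s = {ns}")
    axes[0].set_ylabel("detection power q")
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
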