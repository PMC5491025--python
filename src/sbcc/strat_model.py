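"""Population-structure model and genotype second moments.

A cohort samples ``m`` subpopulations whose reference-allele frequencies have
drifted from a shared ancestral frequency ``p``.  The degree of divergence is
Wright's fixation index ``F_st``: the ratio of the variance of subpopulation
frequencies to ``p(1-p)``, equivalently the apparent correlation of two
alleles sampled within the same subpopulation.  Everything downstream (the
genotype/RAF correlation, the membership test, the power bound) is built on
the two second-moment identities implemented here:

* ``Var(G) = 2p(1-p)(1+F)`` for an additively coded genotype ``G = X1 + X2``;
* ``Cov(G1, G2) = 4p(1-p)F`` for two subjects of the same subpopulation and
  ``0`` otherwise.

Subpopulation frequencies are realized by the Balding-Nichols construction:
a Beta law with mean ``p`` and variance ``F p(1-p)``, which satisfies the
moment conditions exactly and is the field-standard choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationStructure",
    "CohortDesign",
    "PanelSpec",
    "genotype_variance",
    "genotype_covariance",
    "draw_subpop_freqs",
]

#: drawn subpopulation frequencies are clamped to [EPS, 1-EPS]; the theory
#: assumes polymorphic markers (0 < p < 1).
FREQ_EPS = 1e-6


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class PopulationStructure:
    """``m`` subpopulations with per-subpopulation fixation indices.

    Parameters
    ----------
    fixation
        Vector of fixation indices ``F_i``, one per subpopulation, each in
        ``[0, 1)``.  A scalar is promoted to a common value.
    maf_low, maf_high
        Bounds of the uniform law for the ancestral reference-allele
        frequency used in simulation.  Defaults target common SNPs.
    """

    fixation: np.ndarray
    maf_low: float = 0.05
    maf_high: float = 0.5

    def __post_init__(self) -> None:
        fx = _as_1d_float(self.fixation, "fixation")
        if fx.size < 1:
            raise ValueError("need at least one subpopulation")
        if np.any(fx < 0) or np.any(fx >= 1):
            raise ValueError("fixation indices must lie in [0, 1)")
        if not (0 < self.maf_low <= self.maf_high < 1):
            raise ValueError("require 0 < maf_low <= maf_high < 1")
        object.__setattr__(self, "fixation", fx)

    @classmethod
    def uniform(cls, m: int, fst: float, **kw) -> "PopulationStructure":
        """Structure with a common fixation index across ``m`` subpopulations."""
        if m < 1:
            raise ValueError("m must be >= 1")
        return cls(fixation=np.full(int(m), float(fst)), **kw)

    @property
    def m(self) -> int:
        return self.fixation.size

    def to_dict(self) -> dict:
        return {
            "fixation": [float(f) for f in self.fixation],
            "maf_low": self.maf_low,
            "maf_high": self.maf_high,
        }


@dataclass(frozen=True)
class CohortDesign:
    """Per-subpopulation case/control counts and the RAF reporting weight.

    The study publishes per-SNP frequencies ``p_hat = omega * p_hat_case +
    (1 - omega) * p_hat_control``; ``omega = 1`` is the worst case of sharing
    case RAFs.
    """

    cases_per_subpop: np.ndarray
    controls_per_subpop: np.ndarray | None = None
    omega: float = 1.0

    def __post_init__(self) -> None:
        ca = np.atleast_1d(np.asarray(self.cases_per_subpop, dtype=int))
        co = (
            np.zeros_like(ca)
            if self.controls_per_subpop is None
            else np.atleast_1d(np.asarray(self.controls_per_subpop, dtype=int))
        )
        if ca.size != co.size:
            raise ValueError("case and control count vectors must have equal length")
        if np.any(ca < 0) or np.any(co < 0):
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError("omega must lie in [0, 1]")
        if self.omega > 0 and ca.sum() < 1:
            raise ValueError("omega > 0 requires at least one case")
        if self.omega < 1 and co.sum() < 1:
            raise ValueError("omega < 1 requires at least one control")
        object.__setattr__(self, "cases_per_subpop", ca)
        object.__setattr__(self, "controls_per_subpop", co)

    @classmethod
    def balanced(cls, n: int, m: int, omega: float = 1.0) -> "CohortDesign":
        """Equal split of ``n`` cases (and ``n`` controls when omega < 1)."""
        if n % m:
            raise ValueError("balanced design requires m to divide n")
        per = np.full(m, n // m)
        controls = None if omega == 1.0 else per.copy()
        return cls(per, controls, omega)

    @property
    def m(self) -> int:
        return self.cases_per_subpop.size

    @property
    def n_cases(self) -> int:
        return int(self.cases_per_subpop.sum())

    @property
    def n_controls(self) -> int:
        return int(self.controls_per_subpop.sum())

    def to_dict(self) -> dict:
        return {
            "cases_per_subpop": [int(c) for c in self.cases_per_subpop],
            "controls_per_subpop": [int(c) for c in self.controls_per_subpop],
            "omega": self.omega,
        }


@dataclass(frozen=True)
class PanelSpec:
    """External reference panel: total size and per-subpopulation composition."""

    composition: np.ndarray = field(default_factory=lambda: np.array([1000]))

    def __post_init__(self) -> None:
        comp = np.atleast_1d(np.asarray(self.composition, dtype=int))
        if np.any(comp < 0) or comp.sum() < 1:
            raise ValueError("panel composition must be non-negative and sum to >= 1")
        object.__setattr__(self, "composition", comp)

    @classmethod
    def balanced(cls, panel_size: int, m: int) -> "PanelSpec":
        if panel_size % m:
            raise ValueError("balanced panel requires m to divide panel_size")
        return cls(np.full(m, panel_size // m))

    @property
    def panel_size(self) -> int:
        return int(self.composition.sum())

    def ratio(self, n_cases: int) -> float:
        """Cohort-to-panel ratio ``k = n / n''``."""
        return n_cases / self.panel_size

    def to_dict(self) -> dict:
        return {"composition": [int(c) for c in self.composition]}


def _check_pf(p: float, F: float) -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(f"allele frequency must lie in (0, 1), got {p}")
    if not (0.0 <= F < 1.0):
        raise ValueError(f"fixation index must lie in [0, 1), got {F}")


def genotype_variance(p: float, F: float) -> float:
    """Variance of an additive genotype under within-subpopulation correlation F.

    ``Var(G) = Var(X1) + Var(X2) + 2 Cov(X1, X2) = 2 p (1-p) (1 + F)``.
    """
    _check_pf(p, F)
    return 2.0 * p * (1.0 - p) * (1.0 + F)


def genotype_covariance(p: float, F: float, same_subpop: bool) -> float:
    """Covariance of two subjects' genotypes.

    Each of the four allele pairs between two subjects of the same
    subpopulation carries correlation ``F``, giving ``4 p (1-p) F``; alleles
    from different subpopulations are uncorrelated.
    """
    _check_pf(p, F)
    if not same_subpop:
        return 0.0
    return 4.0 * p * (1.0 - p) * F


def beta_shapes(p: float, F: float) -> tuple[float, float]:
    """Balding-Nichols Beta shape parameters for mean p, variance F p(1-p)."""
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    if a <= 0 or b <= 0:
        raise ValueError("fixation index too large for a valid Beta law")
    return a, b


def draw_subpop_freqs(
    p: float,
    F: float,
    m: int,
    rng: np.random.Generator | int | None = None,
    eps: float = FREQ_EPS,
) -> np.ndarray:
    """Draw ``m`` subpopulation frequencies drifted from ancestral ``p``.

    For ``F > 0`` the draw is Beta with mean ``p`` and variance ``F p(1-p)``
    (shapes ``p(1-F)/F`` and ``(1-p)(1-F)/F``); ``F = 0`` returns ``m``
    copies of ``p``.  Results are clamped to ``[eps, 1-eps]`` so that no
    simulated marker is monomorphic.
    """
    _check_pf(p, F)
    if m < 1:
        raise ValueError("m must be >= 1")
    if F == 0.0:
        return np.full(m, p)
    a, b = beta_shapes(p, F)
    rng = np.random.default_rng(rng)
    return np.clip(rng.beta(a, b, size=m), eps, 1.0 - eps)
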