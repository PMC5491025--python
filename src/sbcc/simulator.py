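"""Synthetic stratified case-control cohorts, RAF tables and reference panels.

The generator realizes exactly the moment structure the closed forms assume:
per SNP an ancestral frequency ``p_j`` is drawn uniformly from the common-SNP
band, drifted into ``m`` subpopulation frequencies by the Balding-Nichols
Beta law (mean ``p_j``, variance ``F p_j(1-p_j)``), and each subject's two
alleles are then drawn independently from their subpopulation frequency
(Hardy-Weinberg within subpopulation).  SNPs are mutually independent and
case/control status is pure labeling — the membership signal is sampling
covariance, not genotype-phenotype association.

Reference panels reuse the cohort's realized subpopulation frequencies by
default: the panel represents the *same* populations, which is what a
"perfectly matching" panel means.  Fresh drift draws are available as a
mismatch stress test.

For replicate-heavy validation the module also exposes count-level
equivalents (per-stratum allele counts are binomial sufficient statistics),
so harnesses never need to materialize subject-by-SNP matrices; both paths
share the same estimator code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strat_model import (
    FREQ_EPS,
    CohortDesign,
    PanelSpec,
    PopulationStructure,
    beta_shapes,
)

__all__ = [
    "GenotypeMatrix",
    "RafTable",
    "draw_snp_frequencies",
    "simulate_cohort",
    "simulate_panel",
    "compute_raf",
    "empirical_cgr",
    "stratum_allele_counts",
]

MIN_SNPS = 30


@dataclass
class GenotypeMatrix:
    """Subjects-by-SNPs additive dosage matrix with ancestry bookkeeping.

    ``dosages`` holds reference-allele counts in {0, 1, 2}; ``subpop`` and
    ``is_case`` label each subject; ``ancestral_freqs`` (length o) and
    ``subpop_freqs`` (m x o) record the simulated truth for auditability.
    """

    dosages: np.ndarray
    subpop: np.ndarray
    is_case: np.ndarray
    snp_ids: np.ndarray
    ancestral_freqs: np.ndarray | None = None
    subpop_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.subpop = np.asarray(self.subpop, dtype=int)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        self.snp_ids = np.asarray(self.snp_ids)
        ns, o = self.dosages.shape
        if o < 1:
            raise ValueError("need at least one SNP")
        if self.subpop.size != ns or self.is_case.size != ns:
            raise ValueError("subject label vectors must match the dosage row count")
        if self.snp_ids.size != o:
            raise ValueError("snp_ids must match the dosage column count")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def m(self) -> int:
        return int(self.subpop.max()) + 1 if self.subpop.size else 0

    def stratum_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Reduce to per-subpopulation allele counts and subject counts.

        Returns ``(case_alleles, case_n, control_alleles, control_n)`` where
        the allele arrays are ``m x o`` sums of dosages — the sufficient
        statistics every frequency-based estimator in the package consumes.
        """
        m = self.m
        o = self.n_snps
        ca = np.zeros((m, o), dtype=np.int64)
        co = np.zeros((m, o), dtype=np.int64)
        cn = np.zeros(m, dtype=np.int64)
        un = np.zeros(m, dtype=np.int64)
        for i in range(m):
            sel_case = (self.subpop == i) & self.is_case
            sel_ctrl = (self.subpop == i) & ~self.is_case
            ca[i] = self.dosages[sel_case].sum(axis=0)
            co[i] = self.dosages[sel_ctrl].sum(axis=0)
            cn[i] = sel_case.sum()
            un[i] = sel_ctrl.sum()
        return ca, cn, co, un


@dataclass
class RafTable:
    """Published per-SNP frequencies: case, control, the omega mix, and the
    attacker's assumed population frequency ``p_ref``."""

    snp_ids: np.ndarray
    p_case: np.ndarray
    p_control: np.ndarray
    p_hat: np.ndarray
    p_ref: np.ndarray | None = None
    omega: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_case", "p_control", "p_hat", "p_ref"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            setattr(self, name, v)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        self.snp_ids = np.asarray(self.snp_ids)

    @property
    def n_snps(self) -> int:
        return self.snp_ids.size


def _snp_ids(o: int) -> np.ndarray:
    return np.array([f"snp{j:06d}" for j in range(o)])


def draw_snp_frequencies(
    structure: PopulationStructure,
    o: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral frequencies (o,) and drifted subpopulation frequencies (m, o).

    Vectorized Balding-Nichols: each subpopulation's Beta shapes vary per SNP
    with the ancestral draw; ``F_i = 0`` rows copy the ancestral frequency.
    """
    if o < 1:
        raise ValueError("o must be >= 1")
    p = rng.uniform(structure.maf_low, structure.maf_high, size=o)
    m = structure.m
    pf = np.empty((m, o))
    for i, F in enumerate(structure.fixation):
        if F == 0.0:
            pf[i] = p
        else:
            a, b = beta_shapes(0.5, F)  # validate F once
            a = p * (1.0 - F) / F
            b = (1.0 - p) * (1.0 - F) / F
            pf[i] = np.clip(rng.beta(a, b), FREQ_EPS, 1.0 - FREQ_EPS)
    return p, pf


def _draw_dosages(
    counts: np.ndarray, subpop_freqs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw HWE dosages for ``counts[i]`` subjects per subpopulation."""
    rows = []
    labels = []
    for i, c in enumerate(counts):
        if c == 0:
            continue
        rows.append(rng.binomial(2, subpop_freqs[i], size=(int(c), subpop_freqs.shape[1])))
        labels.append(np.full(int(c), i))
    if not rows:
        raise ValueError("no subjects requested")
    return np.vstack(rows).astype(np.int8), np.concatenate(labels)


def simulate_cohort(
    design: CohortDesign,
    structure: PopulationStructure,
    o: int,
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Simulate a stratified case-control cohort of ``o`` independent SNPs."""
    if design.m != structure.m:
        raise ValueError("design and structure disagree on subpopulation count")
    rng = np.random.default_rng(seed)
    p, pf = draw_snp_frequencies(structure, o, rng)
    case_d, case_l = _draw_dosages(design.cases_per_subpop, pf, rng)
    if design.n_controls > 0:
        ctrl_d, ctrl_l = _draw_dosages(design.controls_per_subpop, pf, rng)
        dosages = np.vstack([case_d, ctrl_d])
        subpop = np.concatenate([case_l, ctrl_l])
        is_case = np.concatenate(
            [np.ones(case_l.size, dtype=bool), np.zeros(ctrl_l.size, dtype=bool)]
        )
    else:
        dosages, subpop = case_d, case_l
        is_case = np.ones(case_l.size, dtype=bool)
    return GenotypeMatrix(
        dosages=dosages,
        subpop=subpop,
        is_case=is_case,
        snp_ids=_snp_ids(o),
        ancestral_freqs=p,
        subpop_freqs=pf,
    )


def simulate_panel(
    structure: PopulationStructure,
    composition: PanelSpec | np.ndarray,
    seed: int | np.random.Generator | None = None,
    subpop_freqs: np.ndarray | None = None,
    ancestral_freqs: np.ndarray | None = None,
    o: int | None = None,
) -> GenotypeMatrix:
    """Simulate an external reference panel.

    Pass the cohort's ``subpop_freqs`` (and ``ancestral_freqs``) to draw a
    perfectly matching panel — independent subjects from the same realized
    subpopulations.  Omitting them draws fresh drift (a structure-level match
    only), the mismatch stress mode.
    """
    spec = composition if isinstance(composition, PanelSpec) else PanelSpec(composition)
    if spec.composition.size != structure.m:
        raise ValueError("panel composition length must equal the subpopulation count")
    rng = np.random.default_rng(seed)
    if subpop_freqs is None:
        if o is None:
            raise ValueError("need o when drawing fresh panel frequencies")
        ancestral_freqs, subpop_freqs = draw_snp_frequencies(structure, o, rng)
    else:
        subpop_freqs = np.asarray(subpop_freqs, dtype=float)
    dosages, labels = _draw_dosages(spec.composition, subpop_freqs, rng)
    return GenotypeMatrix(
        dosages=dosages,
        subpop=labels,
        is_case=np.zeros(labels.size, dtype=bool),
        snp_ids=_snp_ids(subpop_freqs.shape[1]),
        ancestral_freqs=None if ancestral_freqs is None else np.asarray(ancestral_freqs),
        subpop_freqs=subpop_freqs,
    )


def compute_raf(genotypes: GenotypeMatrix, omega: float = 1.0) -> RafTable:
    """Exact sample reference-allele frequencies and their omega mix.

    The table's ``p_ref`` column carries the simulated ancestral frequencies
    when the matrix records them — the "assumed population frequency" an
    attacker would bring from outside the study.
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError("omega must lie in [0, 1]")
    n_cases = int(genotypes.is_case.sum())
    n_controls = genotypes.n_subjects - n_cases
    if omega > 0 and n_cases == 0:
        raise ValueError("omega > 0 requires at least one case")
    if omega < 1 and n_controls == 0:
        raise ValueError("omega < 1 requires at least one control")
    o = genotypes.n_snps
    p_case = (
        genotypes.dosages[genotypes.is_case].sum(axis=0) / (2.0 * n_cases)
        if n_cases
        else np.zeros(o)
    )
    p_control = (
        genotypes.dosages[~genotypes.is_case].sum(axis=0) / (2.0 * n_controls)
        if n_controls
        else np.zeros(o)
    )
    p_hat = omega * p_case + (1.0 - omega) * p_control
    return RafTable(
        snp_ids=genotypes.snp_ids,
        p_case=p_case,
        p_control=p_control,
        p_hat=p_hat,
        p_ref=None if genotypes.ancestral_freqs is None else genotypes.ancestral_freqs.copy(),
        omega=omega,
    )


def empirical_cgr(
    subject_dosages: np.ndarray,
    raf: RafTable | np.ndarray,
    ref_freqs: np.ndarray | None = None,
) -> float:
    """Empirical genotype/RAF correlation across SNPs.

    Pearson correlation between the standardized deviations
    ``(G_j - 2 p_j) / sqrt(2 p_j (1-p_j))`` and
    ``(p_hat_j - p_j) / sqrt(2 p_j (1-p_j))``, where ``p_j`` are the assumed
    population frequencies (``ref_freqs``, defaulting to the table's
    ``p_ref``).  Standardizing puts SNPs of different frequency on the scale
    on which the closed forms are derived.
    """
    g = np.asarray(subject_dosages, dtype=float)
    if isinstance(raf, RafTable):
        p_hat = raf.p_hat
        if ref_freqs is None:
            ref_freqs = raf.p_ref
    else:
        p_hat = np.asarray(raf, dtype=float)
    if ref_freqs is None:
        raise ValueError("no reference frequencies: pass ref_freqs or a RafTable with p_ref")
    p = np.asarray(ref_freqs, dtype=float)
    if not (g.shape == p_hat.shape == p.shape):
        raise ValueError("subject dosages, RAFs and reference frequencies must align")
    if g.size < MIN_SNPS:
        raise ValueError(f"need at least {MIN_SNPS} SNPs, got {g.size}")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("reference frequencies must lie strictly in (0, 1)")
    s = np.sqrt(2.0 * p * (1.0 - p))
    x = (g - 2.0 * p) / s
    y = (p_hat - p) / s
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("degenerate input: a deviation vector has zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def stratum_allele_counts(
    subjects_per_subpop: np.ndarray,
    subpop_freqs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-subpopulation reference-allele counts, ``m x o``.

    Binomial(2 c_i, p_ij) per stratum and SNP — the sufficient statistic of a
    full HWE dosage matrix, used by replicate harnesses in place of
    subject-level simulation.
    """
    c = np.asarray(subjects_per_subpop, dtype=int)
    return rng.binomial(2 * c[:, None], subpop_freqs)
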