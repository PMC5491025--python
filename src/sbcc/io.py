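"""TSV / YAML / VCF interchange for genotype matrices, RAF tables, configs.

Canonical interchange is TSV: desk-scale matrices stay inspectable, which
matters when auditing a privacy method.  Schemas:

* genotype TSV — header ``subject_id  subpop  status  <snp ids...>``, one row
  per subject, dosages in {0, 1, 2} (status ``case``/``control``);
* RAF TSV — ``snp_id  p_hat_case  p_hat_control  p_hat  p_ref`` preceded by a
  ``# omega=<w>`` comment line; frequencies carry >= 6 significant digits.

VCF is export-first (one biallelic record per SNP, unphased GT, INFO carrying
the simulated ancestral and subpopulation frequencies); re-import recovers
identical dosages.  Readers reject invalid values rather than coerce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import GenotypeMatrix, RafTable
from .strat_model import CohortDesign, PanelSpec, PopulationStructure

__all__ = [
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_raf_tsv",
    "write_raf_tsv",
    "RunConfig",
    "read_config",
    "write_config",
    "export_vcf",
    "import_vcf",
]

_FMT = "%.8g"
_META = ["subject_id", "subpop", "status"]


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    status = np.where(gm.is_case, "case", "control")
    ids = [f"s{idx:05d}" for idx in range(gm.n_subjects)]
    df = pd.DataFrame(gm.dosages, columns=gm.snp_ids)
    df.insert(0, "status", status)
    df.insert(0, "subpop", gm.subpop)
    df.insert(0, "subject_id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    snp_cols = [c for c in df.columns if c not in _META]
    if not snp_cols:
        raise ValueError(f"{path}: no SNP columns — empty marker set is not allowed")
    bad_status = ~df["status"].isin(["case", "control"])
    if bad_status.any():
        line = int(df.index[bad_status][0]) + 2
        raise ValueError(f"{path}: line {line}: status must be 'case' or 'control'")
    dosages = np.empty((len(df), len(snp_cols)), dtype=np.int8)
    for jcol, col in enumerate(snp_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~vals.isin([0, 1, 2])
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(
                f"{path}: line {line}: column {col!r}: dosage must be 0, 1 or 2 "
                f"(got {df[col][bad].iloc[0]!r})"
            )
        dosages[:, jcol] = vals.to_numpy(dtype=np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        subpop=df["subpop"].astype(int).to_numpy(),
        is_case=(df["status"] == "case").to_numpy(),
        snp_ids=np.asarray(snp_cols),
    )


def write_raf_tsv(raf: RafTable, path: str | Path) -> None:
    p_ref = raf.p_ref if raf.p_ref is not None else np.full(raf.n_snps, np.nan)
    df = pd.DataFrame(
        {
            "snp_id": raf.snp_ids,
            "p_hat_case": raf.p_case,
            "p_hat_control": raf.p_control,
            "p_hat": raf.p_hat,
            "p_ref": p_ref,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# omega={raf.omega!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FMT)


def read_raf_tsv(path: str | Path) -> RafTable:
    omega = 1.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# omega="):
        omega = float(first.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["snp_id", "p_hat_case", "p_hat_control", "p_hat", "p_ref"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in required[1:]:
        v = df[col].to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"{path}: column {col!r}: frequency outside [0, 1]")
    p_ref = df["p_ref"].to_numpy(dtype=float)
    return RafTable(
        snp_ids=df["snp_id"].to_numpy(),
        p_case=df["p_hat_case"].to_numpy(dtype=float),
        p_control=df["p_hat_control"].to_numpy(dtype=float),
        p_hat=df["p_hat"].to_numpy(dtype=float),
        p_ref=None if np.all(np.isnan(p_ref)) else p_ref,
        omega=omega,
    )


# ---------------------------------------------------------------- run config

_ALLOWED = {
    "structure": {"m", "fst", "fixation", "maf_low", "maf_high"},
    "design": {"n_cases", "n_controls", "m", "omega", "cases_per_subpop", "controls_per_subpop"},
    "panel": {"panel_size", "composition"},
    "test": {"alpha", "o", "fst_method", "ref_source"},
    "simulation": {"o", "replicates", "seed"},
    "output": {"prefix", "verbosity"},
}


@dataclass
class RunConfig:
    """Validated flat configuration for simulate/validate runs.

    Sections mirror the pipeline: population ``structure``, cohort
    ``design``, reference ``panel``, ``test`` settings (alpha, o), and
    ``simulation`` scale (o, replicates, seed).  Unknown keys are rejected.
    """

    structure: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)
    test: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_ALLOWED)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, keys in raw.items():
            extra = set(keys) - _ALLOWED[section]
            if extra:
                raise ValueError(
                    f"unknown keys in config section {section!r}: {sorted(extra)}"
                )
        cfg = cls(**{k: dict(v) for k, v in raw.items()})
        alpha = cfg.test.get("alpha")
        if alpha is not None and not (0 < alpha < 1):
            raise ValueError(f"test.alpha must lie in (0, 1), got {alpha}")
        omega = cfg.design.get("omega")
        if omega is not None and not (0 <= omega <= 1):
            raise ValueError(f"design.omega must lie in [0, 1], got {omega}")
        return cfg

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in _ALLOWED
            if getattr(self, k)
        }

    def build_structure(self) -> PopulationStructure:
        s = self.structure
        kw = {k: s[k] for k in ("maf_low", "maf_high") if k in s}
        if "fixation" in s:
            return PopulationStructure(np.asarray(s["fixation"], dtype=float), **kw)
        return PopulationStructure.uniform(int(s.get("m", 1)), float(s.get("fst", 0.0)), **kw)

    def build_design(self) -> CohortDesign:
        d = self.design
        omega = float(d.get("omega", 1.0))
        if "cases_per_subpop" in d:
            return CohortDesign(
                np.asarray(d["cases_per_subpop"], dtype=int),
                np.asarray(d["controls_per_subpop"], dtype=int)
                if "controls_per_subpop" in d
                else None,
                omega,
            )
        m = int(d.get("m", self.structure.get("m", 1)))
        n = int(d["n_cases"])
        per = np.full(m, n // m)
        per[: n % m] += 1
        controls = None
        if d.get("n_controls"):
            nc = int(d["n_controls"])
            controls = np.full(m, nc // m)
            controls[: nc % m] += 1
        return CohortDesign(per, controls, omega)

    def build_panel(self, m: int) -> PanelSpec:
        p = self.panel
        if "composition" in p:
            return PanelSpec(np.asarray(p["composition"], dtype=int))
        size = int(p.get("panel_size", 1000))
        comp = np.full(m, size // m)
        comp[: size % m] += 1
        return PanelSpec(comp)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


# ----------------------------------------------------------------------- VCF


def export_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write simulated genotypes as an uncompressed biallelic VCF.

    One record per SNP on contig ``1``; unphased GT with REF counted by the
    dosage (G reference alleles -> ``2-G`` ALT alleles); INFO ``PA`` carries
    the ancestral frequency and ``PSUB`` the per-subpopulation frequencies
    for auditability.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=sbcc-simulator")
    header.contigs.add("1", length=2**29)
    header.add_meta(
        "INFO",
        items=[("ID", "PA"), ("Number", "1"), ("Type", "Float"),
               ("Description", "Simulated ancestral reference-allele frequency")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "PSUB"), ("Number", "."), ("Type", "Float"),
               ("Description", "Simulated per-subpopulation reference-allele frequencies")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    samples = [f"s{idx:05d}" for idx in range(gm.n_subjects)]
    for s in samples:
        header.add_sample(s)
    gt_for_dosage = {0: (1, 1), 1: (0, 1), 2: (0, 0)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, snp in enumerate(gm.snp_ids):
            rec = vf.new_record(
                contig="1", start=j, stop=j + 1, id=str(snp), alleles=("A", "C")
            )
            if gm.ancestral_freqs is not None:
                rec.info["PA"] = float(gm.ancestral_freqs[j])
            if gm.subpop_freqs is not None:
                rec.info["PSUB"] = tuple(float(v) for v in gm.subpop_freqs[:, j])
            for sidx, sample in enumerate(samples):
                rec.samples[sample]["GT"] = gt_for_dosage[int(gm.dosages[sidx, j])]
                rec.samples[sample].phased = False
            vf.write(rec)


def import_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF written by :func:`export_vcf` back into a dosage matrix.

    Subpopulation labels and case status are not carried by VCF; subjects
    come back unlabeled (subpop 0, control status).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        snp_ids, cols, pa, psub = [], [], [], []
        for rec in vf:
            snp_ids.append(rec.id)
            pa.append(rec.info.get("PA", np.nan))
            if "PSUB" in rec.info:
                psub.append([float(v) for v in rec.info["PSUB"]])
            dos = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    raise ValueError(f"{path}: missing genotype for {s} at {rec.id}")
                dos.append(sum(1 for a in gt if a == 0))
            cols.append(dos)
    if not snp_ids:
        raise ValueError(f"{path}: no records")
    dosages = np.asarray(cols).T.astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        subpop=np.zeros(len(samples), dtype=int),
        is_case=np.zeros(len(samples), dtype=bool),
        snp_ids=np.asarray(snp_ids),
        ancestral_freqs=np.asarray(pa, dtype=float) if pa else None,
        subpop_freqs=np.asarray(psub, dtype=float).T if psub else None,
    )
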