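"""Genotype and phenotype containers plus the standard-format readers.

Dosages are always stored as counts of the *panel risk allele* (0, 1, 2 or
missing), whatever the orientation of the source file: the gene score is
defined on risk-allele counts, so orientation is resolved once, at load.
Missing genotypes are kept missing — downstream analyses are complete-case,
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import RSID_ALIASES, SnpPanel

__all__ = [
    "GenotypeMatrix",
    "GenotypeError",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "PHENOTYPE_COLUMNS",
    "read_phenotypes",
    "write_phenotypes",
    "validate_cohort",
]

#: Strand-ambiguous allele pairs: orientation cannot be resolved against
#: REF/ALT for these, so such sites are rejected rather than guessed at.
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

#: Deterministic partner allele used when *writing* VCF for simulated
#: genotypes (transitions only, never a strand-ambiguous pair).
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class GenotypeError(ValueError):
    """Raised for malformed genotype input."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs risk-allele dosages.

    ``dosage`` is a float DataFrame indexed by individual id with rsid
    columns; values are 0, 1, 2 or NaN (missing).
    """

    dosage: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise GenotypeError(
                f"dosage for individual {self.dosage.index[i]!r} at "
                f"{self.dosage.columns[j]!r} is {values[i, j]!r}; "
                "expected 0, 1, 2 or missing"
            )
        if self.dosage.index.has_duplicates or self.dosage.columns.has_duplicates:
            raise GenotypeError("duplicate individual ids or rsids")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.dosage.columns)

    def restrict(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        """Columns for ``rsids`` in that order; absent sites become missing."""
        out = self.dosage.reindex(columns=list(rsids))
        return GenotypeMatrix(out)


def _canonical_columns(columns: Sequence[str]) -> list[str]:
    return [RSID_ALIASES.get(c, c) for c in columns]


def read_genotypes_tsv(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read a dosage table (rows = individuals, columns = rsids, cells
    0/1/2/NA) and restrict it to the panel's rsids."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "individual_id":
        raise GenotypeError(f"{path}: first column must be 'individual_id'")
    df = df.set_index("individual_id")
    df.columns = _canonical_columns(df.columns)
    raw = df.to_numpy(dtype=object)
    text = np.char.strip(raw.astype(str))
    values = np.full(text.shape, np.nan)
    for tok, val in (("0", 0.0), ("1", 1.0), ("2", 2.0)):
        values[text == tok] = val
    bad = ~(np.isin(text, ("0", "1", "2", "", "NA", "nan", "None", ".")))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeError(
            f"{path}: invalid dosage {text[i, j]!r} for individual "
            f"{df.index[i]!r} at {df.columns[j]!r}"
        )
    parsed = pd.DataFrame(values, index=df.index, columns=df.columns)
    return GenotypeMatrix(parsed).restrict(panel.rsids)


def write_genotypes_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    out = matrix.dosage.copy()
    out.index.name = "individual_id"
    with Path(path).open("w") as fh:
        fh.write("individual_id\t" + "\t".join(out.columns) + "\n")
        for ind, row in out.iterrows():
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(ind) + "\t" + "\t".join(cells) + "\n")


def read_genotypes_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Extract risk-allele dosages from a VCF (GT field, biallelic sites).

    Sites are matched to the panel by the ID column (aliases resolved).
    The risk allele may be either REF or ALT; dosage is flipped accordingly.
    A matched site whose alleles do not include the risk allele, a
    multi-allelic site, or a strand-ambiguous (A/T, C/G) site is an error.
    Panel sites absent from the file yield missing dosages.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        data: dict[str, np.ndarray] = {}
        for rec in vcf:
            rsid = RSID_ALIASES.get(rec.id or "", rec.id or "")
            if rsid not in panel:
                continue
            entry = panel[rsid]
            alts = rec.alts or ()
            if len(alts) != 1:
                raise GenotypeError(
                    f"{rsid}: multi-allelic site not supported "
                    f"(ALT = {','.join(alts) or '.'})"
                )
            ref, alt = rec.ref.upper(), alts[0].upper()
            if {ref, alt} in _AMBIGUOUS_PAIRS:
                raise GenotypeError(
                    f"{rsid}: strand-ambiguous alleles {ref}/{alt}; "
                    "orientation cannot be resolved"
                )
            if entry.risk_allele == alt:
                risk_is_alt = True
            elif entry.risk_allele == ref:
                risk_is_alt = False
            else:
                raise GenotypeError(
                    f"{rsid}: risk allele {entry.risk_allele} matches neither "
                    f"REF ({ref}) nor ALT ({alt})"
                )
            col = np.full(len(samples), np.nan)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                alt_count = sum(1 for a in gt if a == 1)
                col[i] = alt_count if risk_is_alt else len(gt) - alt_count
            data[rsid] = col
    dosage = pd.DataFrame(data, index=pd.Index(samples, name="individual_id"))
    return GenotypeMatrix(dosage).restrict(panel.rsids)


def write_genotypes_vcf(matrix: GenotypeMatrix, panel: SnpPanel,
                        path: str | Path) -> None:
    """Write dosages as a minimal VCF 4.2 with GT only.

    The risk allele is written as ALT with a deterministic transition
    partner as REF, so heterozygous dosages round-trip unambiguously.
    Missing dosages become ``./.``.  Positions are synthetic (panel order on
    a single placeholder contig); only the ID column carries identity.
    """
    ids = matrix.individual_ids
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=panel,length=1000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in ids) + "\n")
        for pos, rsid in enumerate(matrix.rsids, start=1):
            risk = panel[rsid].risk_allele
            ref = _TRANSITION[risk]
            calls = []
            for v in matrix.dosage[rsid].to_numpy():
                if np.isnan(v):
                    calls.append("./.")
                else:
                    n = int(v)
                    calls.append(("0/0", "0/1", "1/1")[n])
            fh.write(f"panel\t{pos}\t{rsid}\t{ref}\t{risk}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# Phenotype / covariate table

PHENOTYPE_COLUMNS = [
    "individual_id",
    "outcome",
    "age",
    "sex",
    "total_cholesterol",
    "hdl_cholesterol",
    "systolic_bp",
    "diastolic_bp",
    "smoker",
    "diabetic",
]


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort/phenotype table and return it indexed by individual.

    Units are fixed: age in years, cholesterol in mmol/l, blood pressure in
    mmHg; ``outcome``, ``smoker`` and ``diabetic`` are 0/1; ``sex`` is
    ``male``/``female``.  Optional derived columns (``gene_score``,
    ``framingham_risk``) are passed through, with probabilities checked.
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    out = df.copy()
    if out["individual_id"].duplicated().any():
        raise ValueError("duplicate individual_id in phenotype table")
    out = out.set_index("individual_id")
    for col in ("outcome", "smoker", "diabetic"):
        if not out[col].dropna().isin([0, 1]).all():
            raise ValueError(f"{col} must be 0/1")
    if not out["sex"].isin(["male", "female"]).all():
        raise ValueError("sex must be 'male' or 'female'")
    if (out["age"].dropna() <= 0).any():
        raise ValueError("ages must be positive")
    if "framingham_risk" in out.columns:
        risk = out["framingham_risk"].dropna()
        if ((risk < 0) | (risk > 1)).any():
            raise ValueError("framingham_risk must lie in [0, 1]")
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep="\t", comment="#"))


def write_phenotypes(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.reset_index().to_csv(path, sep="\t", index=False)
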