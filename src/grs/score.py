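"""Weighted gene score: per-individual sum of risk-allele dosage x ln(OR).

Additive variants contribute ``dosage * weight``; the single recessive
variant (NOS3 rs1799983) contributes its weight only when both risk alleles
are carried.  A protective variant (APOE rs7412, OR 0.80) enters with a
negative weight.  No rescaling by SNP count is applied — the score is the
raw weighted sum.

Individuals missing any panel genotype still receive a score over their
available SNPs but are flagged ``complete = False``; cohort-level statistics
downstream use complete individuals only.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .panel import SnpPanel, SnpPanelEntry

__all__ = ["snp_contribution", "compute_scores", "score_bounds"]


class MissingDosageError(ValueError):
    """Signalled when a single-SNP contribution is requested for a missing
    genotype; the caller decides whether to exclude the individual."""


def snp_contribution(dosage: float, entry: SnpPanelEntry) -> float:
    """Contribution of one variant to the score.

    Additive model: ``dosage * ln(OR)``.  Recessive model: ``ln(OR)`` for
    dosage 2, otherwise 0.
    """
    if dosage is None or (isinstance(dosage, float) and math.isnan(dosage)):
        raise MissingDosageError(f"{entry.rsid}: missing dosage")
    if dosage not in (0, 1, 2):
        raise ValueError(f"{entry.rsid}: dosage must be 0, 1 or 2, got {dosage}")
    if entry.genetic_model == "recessive":
        return entry.weight if dosage == 2 else 0.0
    return dosage * entry.weight


def _coding_matrix(dosage: pd.DataFrame, panel: SnpPanel) -> pd.DataFrame:
    """Per-SNP model coding: dosage for additive, 1{dosage == 2} recessive."""
    coded = dosage.copy()
    for entry in panel:
        if entry.genetic_model == "recessive":
            col = coded[entry.rsid]
            coded[entry.rsid] = np.where(np.isnan(col), np.nan,
                                         (col == 2).astype(float))
    return coded


def compute_scores(genotypes: GenotypeMatrix, panel: SnpPanel,
                   subset: int = 19) -> pd.DataFrame:
    """Score every individual on the 19- or 13-SNP panel.

    Returns a DataFrame indexed by individual id with columns ``score``,
    ``n_missing`` and ``complete``.  Missing SNP contributions are treated
    as 0 in the partial score; ``complete`` is True only when every panel
    SNP was genotyped.
    """
    sub = panel.subset(subset)
    if len(sub) == 0:
        raise ValueError("empty panel subset")
    dosage = genotypes.restrict(sub.rsids).dosage
    coded = _coding_matrix(dosage, sub)
    weights = np.array([e.weight for e in sub])
    values = coded.to_numpy(dtype=float)
    n_missing = np.isnan(values).sum(axis=1)
    score = np.nansum(values * weights, axis=1)
    return pd.DataFrame(
        {
            "score": score,
            "n_missing": n_missing.astype(int),
            "complete": n_missing == 0,
        },
        index=pd.Index(dosage.index, name="individual_id"),
    )


def score_bounds(panel: SnpPanel, subset: int = 19) -> tuple[float, float]:
    """Attainable [min, max] score over all complete genotype vectors.

    Per SNP the extreme contributions are 0 and ``2 * weight`` (additive) or
    0 and ``weight`` (recessive); a negative weight flips which end is the
    minimum.
    """
    sub = panel.subset(subset)
    lo = hi = 0.0
    for entry in sub:
        top = entry.weight if entry.genetic_model == "recessive" else 2 * entry.weight
        lo += min(0.0, top)
        hi += max(0.0, top)
    return lo, hi
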