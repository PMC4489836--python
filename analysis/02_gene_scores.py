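#!/usr/bin/env python
"""Gene-score distributions by cohort and outcome group.

Computes the 19- and 13-SNP weighted scores for each simulated cohort
(complete-genotype individuals only), compares cases with controls by
Welch's t-test, and contrasts the UK-profile control scores with the
Pakistani-profile controls — the analysis behind the published group-mean
score comparisons.

Reads the cohorts written by 01_simulate_cohorts.py; writes
results/gene_scores.tsv.
"""

from pathlib import Path

import pandas as pd

import grs
from grs.genotypes import read_genotypes_tsv, read_phenotypes

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    panel = grs.default_panel()
    rows = []
    control_scores: dict[tuple[str, int], pd.Series] = {}
    for name in ("nphsii", "islamabad", "lahore"):
        geno = read_genotypes_tsv(SCRATCH / f"{name}.dosage.tsv", panel)
        cohort = read_phenotypes(SCRATCH / f"{name}.pheno.tsv")
        for subset in (19, 13):
            scores = grs.compute_scores(geno, panel, subset)
            ok = scores["complete"]
            cases = scores.loc[ok & (cohort["outcome"] == 1), "score"]
            ctrls = scores.loc[ok & (cohort["outcome"] == 0), "score"]
            t, df, p = grs.welch_t_test(cases, ctrls)
            control_scores[(name, subset)] = ctrls
            rows.append({
                "scenario": name, "panel": subset,
                "n_complete": int(ok.sum()),
                "mean_cases": round(cases.mean(), 2),
                "sd_cases": round(cases.std(ddof=1), 2),
                "mean_controls": round(ctrls.mean(), 2),
                "sd_controls": round(ctrls.std(ddof=1), 2),
                "welch_p": f"{p:.3g}",
            })
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "gene_scores.tsv", sep="\t", index=False)
    print("Gene scores by cohort and outcome (complete genotypes):")
    print(out.to_string(index=False))
    for subset in (19, 13):
        uk = control_scores[("nphsii", subset)]
        pk = pd.concat([control_scores[("islamabad", subset)],
                        control_scores[("lahore", subset)]])
        _, _, p = grs.welch_t_test(uk, pk)
        print(f"{subset}-SNP score, UK vs pooled Pakistani controls: "
              f"{uk.mean():.2f} vs {pk.mean():.2f} (Welch p = {p:.3g})")


if __name__ == "__main__":
    main()
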