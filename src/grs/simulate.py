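"""Synthetic genotype/phenotype cohorts for exercising the pipeline.

No individual-level data are distributed with the study this package
analyses, so every pipeline stage is validated on simulated cohorts that
reproduce the assumed statistical structure:

* independent loci with dosages drawn Binomial(2, RAF) — Hardy-Weinberg
  equilibrium by construction, at the published risk-allele frequencies;
* a logistic disease model whose per-SNP log-odds effects are the panel
  weights (the recessive variant coded as an indicator of two risk
  alleles), scaled by an ``effect_multiplier`` (0 = null, 1 = published);
* conventional risk factors drawn independently with normal or Bernoulli
  marginals at the published group moments;
* an intercept calibrated by root finding so the expected event fraction
  equals the target prevalence;
* either a prospective design (one cohort, outcomes as they fall) or a
  case-control design (cases and controls sampled post hoc to requested
  counts).

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .genotypes import GenotypeMatrix, validate_cohort
from .panel import SnpPanel, default_panel
from .score import _coding_matrix

__all__ = [
    "SimulationSpec",
    "simulate_genotypes",
    "simulate_outcomes",
    "simulate_cohort",
    "nphsii_scenario",
    "islamabad_scenario",
    "lahore_scenario",
    "NPHSII_RAF",
    "ISLAMABAD_CONTROL_RAF",
    "LAHORE_CONTROL_RAF",
]

# Published risk-allele frequencies (panel rsids).  The two Pakistani
# profiles are the control-group frequencies.
NPHSII_RAF: dict[str, float] = {
    "rs17465637": 0.71, "rs10757274": 0.48, "rs7025486": 0.26,
    "rs1746048": 0.86, "rs17228212": 0.31, "rs9818870": 0.16,
    "rs599839": 0.78, "rs4341": 0.52, "rs1799983": 0.33,
    "rs662799": 0.06, "rs1042031": 0.18, "rs708272": 0.56,
    "rs3798220": 0.02, "rs10455872": 0.07, "rs11591147": 0.99,
    "rs429358": 0.17, "rs7412": 0.91, "rs328": 0.90, "rs1801177": 0.01,
}

ISLAMABAD_CONTROL_RAF: dict[str, float] = {
    "rs17465637": 0.64, "rs10757274": 0.44, "rs7025486": 0.31,
    "rs1746048": 0.65, "rs17228212": 0.19, "rs9818870": 0.10,
    "rs599839": 0.72, "rs4341": 0.41, "rs1799983": 0.16,
    "rs662799": 0.15, "rs1042031": 0.15, "rs708272": 0.55,
    "rs3798220": 0.01, "rs10455872": 0.01, "rs11591147": 1.00,
    "rs429358": 0.09, "rs7412": 0.96, "rs328": 0.92, "rs1801177": 0.01,
}

LAHORE_CONTROL_RAF: dict[str, float] = {
    "rs17465637": 0.63, "rs10757274": 0.46, "rs7025486": 0.32,
    "rs1746048": 0.64, "rs17228212": 0.18, "rs9818870": 0.09,
    "rs599839": 0.74, "rs4341": 0.47, "rs1799983": 0.18,
    "rs662799": 0.17, "rs1042031": 0.13, "rs708272": 0.56,
    "rs3798220": 0.003, "rs10455872": 0.01, "rs11591147": 0.995,
    "rs429358": 0.11, "rs7412": 0.96, "rs328": 0.91, "rs1801177": 0.0,
}

#: Default log-odds coefficients for the conventional risk factors, per
#: natural unit (years, mmHg, mmol/l, indicator).  Chosen once to give
#: case/control covariate contrasts of the size seen in middle-aged CHD
#: cohorts; see the methods note.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age": 0.07,
    "systolic_bp": 0.015,
    "diastolic_bp": 0.0,
    "total_cholesterol": 0.30,
    "hdl_cholesterol": -0.50,
    "smoker": 0.55,
    "diabetic": 0.60,
}

#: Marginal covariate model: ("normal", mean, sd) or ("bernoulli", p).
#: ``female`` controls the sex split.
CovariateModel = Mapping[str, tuple]

_PHYSIOLOGIC_FLOORS = {
    "age": 18.0,
    "total_cholesterol": 1.0,
    "hdl_cholesterol": 0.3,
    "systolic_bp": 80.0,
    "diastolic_bp": 45.0,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters governing one synthetic cohort."""

    panel: SnpPanel
    raf: Mapping[str, float]
    covariate_model: CovariateModel
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    effect_multiplier: float = 1.0
    design: str = "prospective"
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    baseline_prevalence: float = 0.10
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rsid, f in self.raf.items():
            if rsid not in self.panel:
                raise ValueError(f"raf profile rsid {rsid} absent from panel")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{rsid}: frequency {f} outside [0, 1]")
        if self.design not in ("prospective", "case_control"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "prospective":
            if not self.n or self.n <= 0:
                raise ValueError("prospective design needs n > 0")
        else:
            if not self.n_cases or not self.n_controls:
                raise ValueError("case_control design needs n_cases and "
                                 "n_controls")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _pool_size(spec: SimulationSpec) -> int:
    if spec.design == "prospective":
        return spec.n
    prev = spec.baseline_prevalence
    need = max(spec.n_cases / prev, spec.n_controls / (1.0 - prev))
    return int(need * 1.4) + 500


def _draw_genotypes(spec: SimulationSpec, n: int,
                    rng: np.random.Generator) -> GenotypeMatrix:
    rsids = spec.panel.rsids
    cols = {}
    for rsid in rsids:
        f = spec.raf[rsid]
        cols[rsid] = rng.binomial(2, f, size=n).astype(float)
    ids = pd.Index([f"ind{i:06d}" for i in range(n)], name="individual_id")
    return GenotypeMatrix(pd.DataFrame(cols, index=ids))


def apply_missingness(genotypes: GenotypeMatrix, rate: float,
                      rng: np.random.Generator) -> GenotypeMatrix:
    """Mask each dosage to missing independently with probability ``rate``."""
    if rate == 0.0:
        return genotypes
    values = genotypes.dosage.to_numpy(dtype=float).copy()
    mask = rng.random(values.shape) < rate
    values[mask] = np.nan
    return GenotypeMatrix(pd.DataFrame(values, index=genotypes.dosage.index,
                                       columns=genotypes.dosage.columns))


def simulate_genotypes(spec: SimulationSpec,
                       rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Independent HWE genotypes at the spec's frequencies, with
    missingness applied at ``missing_rate``."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n if spec.design == "prospective" else _pool_size(spec)
    geno = _draw_genotypes(spec, n, rng)
    return apply_missingness(geno, spec.missing_rate, rng)


def _draw_covariates(spec: SimulationSpec, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, model in spec.covariate_model.items():
        kind = model[0]
        if kind == "normal":
            _, mean, sd = model
            vals = rng.normal(mean, sd, size=n)
            floor = _PHYSIOLOGIC_FLOORS.get(name)
            if floor is not None:
                vals = np.maximum(vals, floor)
            cols[name] = vals
        elif kind == "bernoulli":
            cols[name] = rng.binomial(1, model[1], size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate model {model!r} for {name}")
    df = pd.DataFrame(cols)
    female = df.pop("female") if "female" in df else np.zeros(n)
    df["sex"] = np.where(np.asarray(female) == 1, "female", "male")
    return df


def _genetic_lp(genotypes: GenotypeMatrix, spec: SimulationSpec) -> np.ndarray:
    coded = _coding_matrix(genotypes.dosage, spec.panel)
    weights = np.array([spec.panel[r].weight for r in genotypes.rsids])
    values = coded.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("outcome simulation requires complete genotypes")
    return spec.effect_multiplier * values @ weights


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + lp)) = target, |error| < 1e-6."""

    def excess(b0: float) -> float:
        return float(np.mean(expit(b0 + lp)) - target)

    lo, hi = -40.0, 40.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise ValueError(f"prevalence {target} unattainable given effects")
    return float(optimize.brentq(excess, lo, hi, xtol=1e-10))


def simulate_outcomes(genotypes: GenotypeMatrix, spec: SimulationSpec,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw covariates and outcomes for complete genotypes.

    Returns a validated cohort table (indexed by individual id) whose
    expected event fraction equals ``baseline_prevalence`` before any
    case-control sampling.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    n = len(genotypes.individual_ids)
    cov = _draw_covariates(spec, n, rng)
    cov.index = genotypes.dosage.index
    lp = _genetic_lp(genotypes, spec)
    for name, beta in spec.covariate_effects.items():
        if beta and name in cov.columns:
            lp = lp + beta * cov[name].to_numpy(float)
    b0 = _calibrate_intercept(lp, spec.baseline_prevalence)
    prob = expit(b0 + lp)
    cov.insert(0, "outcome", rng.binomial(1, prob))
    for required, default in (("diabetic", 0.0), ("smoker", 0.0)):
        if required not in cov.columns:
            cov[required] = default
    return validate_cohort(cov.reset_index())


def simulate_cohort(spec: SimulationSpec
                    ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """End-to-end cohort: genotypes plus phenotype table.

    Outcomes are generated on complete genotypes; missingness is applied to
    the released genotype matrix afterwards.  Under the case-control design
    the requested numbers of cases and controls are sampled from a larger
    simulated population.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n if spec.design == "prospective" else _pool_size(spec)
    geno = _draw_genotypes(spec, n, rng)
    cohort = simulate_outcomes(geno, spec, rng)
    if spec.design == "case_control":
        cases = cohort.index[cohort["outcome"] == 1]
        controls = cohort.index[cohort["outcome"] == 0]
        if len(cases) < spec.n_cases or len(controls) < spec.n_controls:
            raise RuntimeError(
                "simulated pool too small for requested case/control counts; "
                "increase the pool safety factor")
        keep = list(cases[: spec.n_cases]) + list(controls[: spec.n_controls])
        cohort = cohort.loc[keep]
        geno = GenotypeMatrix(geno.dosage.loc[keep])
    geno = apply_missingness(geno, spec.missing_rate, rng)
    return geno, cohort


# ---------------------------------------------------------------------------
# Ready-made study scenarios


def nphsii_scenario(seed: int = 0, **overrides) -> SimulationSpec:
    """Prospective UK middle-aged male cohort: 2775 men, 284 events over
    follow-up, published risk-allele frequencies and baseline covariate
    moments.  HDL cholesterol moments are not published for this cohort and
    use a typical UK male distribution; diabetics were excluded at
    recruitment."""
    base = dict(
        panel=default_panel(),
        raf=dict(NPHSII_RAF),
        covariate_model={
            "age": ("normal", 56.0, 3.4),
            "total_cholesterol": ("normal", 5.70, 1.01),
            "hdl_cholesterol": ("normal", 1.30, 0.35),
            "systolic_bp": ("normal", 137.9, 19.1),
            "diastolic_bp": ("normal", 84.3, 11.2),
            "smoker": ("bernoulli", 0.27),
            "diabetic": ("bernoulli", 0.0),
            "female": ("bernoulli", 0.0),
        },
        design="prospective",
        n=2775,
        baseline_prevalence=284 / 2775,
        missing_rate=0.04,
        seed=seed,
    )
    base.update(overrides)
    return SimulationSpec(**base)


def islamabad_scenario(seed: int = 0, **overrides) -> SimulationSpec:
    """Pakistani MI case-control sample (321 cases / 228 controls) at the
    published control risk-allele frequencies.  Covariate moments follow the
    published control group; blood pressure moments are unpublished and use
    typical South Asian adult values."""
    base = dict(
        panel=default_panel(),
        raf=dict(ISLAMABAD_CONTROL_RAF),
        covariate_model={
            "age": ("normal", 38.0, 11.83),
            "total_cholesterol": ("normal", 4.52, 1.38),
            "hdl_cholesterol": ("normal", 1.35, 0.60),
            "systolic_bp": ("normal", 125.0, 18.0),
            "diastolic_bp": ("normal", 80.0, 11.0),
            "smoker": ("bernoulli", 0.25),
            "diabetic": ("bernoulli", 0.05),
            "female": ("bernoulli", 0.34),
        },
        design="case_control",
        n_cases=321,
        n_controls=228,
        baseline_prevalence=0.10,
        seed=seed,
    )
    base.update(overrides)
    return SimulationSpec(**base)


def lahore_scenario(seed: int = 0, **overrides) -> SimulationSpec:
    """Pakistani CHD case-control sample at the published Lahore control
    frequencies.  The source reports the case count as 414 in one place and
    404 in another; this scenario uses 414 cases / 219 controls.  Lipid and
    blood-pressure moments beyond LDL are unpublished and use typical
    values."""
    base = dict(
        panel=default_panel(),
        raf=dict(LAHORE_CONTROL_RAF),
        covariate_model={
            "age": ("normal", 56.0, 10.5),
            "total_cholesterol": ("normal", 4.80, 1.10),
            "hdl_cholesterol": ("normal", 1.10, 0.30),
            "systolic_bp": ("normal", 130.0, 18.0),
            "diastolic_bp": ("normal", 82.0, 11.0),
            "smoker": ("bernoulli", 0.11),
            "diabetic": ("bernoulli", 0.14),
            "female": ("bernoulli", 0.46),
        },
        design="case_control",
        n_cases=414,
        n_controls=219,
        baseline_prevalence=0.10,
        seed=seed,
    )
    base.update(overrides)
    return SimulationSpec(**base)


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    return replace(spec, seed=seed)
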