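"""Framingham-form 10-year CHD risk.

The risk engine evaluates the parametric survival form

    risk10 = 1 - S0 ** exp(LP - LP_mean)

where ``LP`` is a linear predictor over conventional risk factors.  The
numeric coefficients are data, not code: they live in a YAML equation file
(one is shipped, see ``grs/data/framingham_chd_1998.yaml``), which keeps
coefficient transcription separate from the engine and lets tests exercise
the machinery with synthetic coefficient sets.

Covariate transforms: ``identity``, ``natural_log``, ``squared`` (used by
the published female age term), and ``category_table`` (right-open bins
with one coefficient per bin).  Blood pressure is a joint category term
over systolic and diastolic pressure: the higher of the two stages wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RiskEquationSpec",
    "SexEquation",
    "RiskEquationError",
    "load_risk_equation",
    "save_risk_equation",
    "default_risk_equation",
    "framingham_risk10",
]

_TRANSFORMS = ("identity", "natural_log", "squared", "category_table")


class RiskEquationError(ValueError):
    """Raised for schema-invalid risk equation files."""


@dataclass(frozen=True)
class Term:
    covariate: str
    transform: str
    coefficient: float | None = None
    bins: tuple[float, ...] | None = None
    bins_systolic: tuple[float, ...] | None = None
    bins_diastolic: tuple[float, ...] | None = None
    coefficients: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise RiskEquationError(
                f"term {self.covariate!r}: unknown transform {self.transform!r}"
            )
        if self.transform == "category_table":
            if self.coefficients is None:
                raise RiskEquationError(
                    f"term {self.covariate!r}: category table needs coefficients"
                )
            for bins in filter(None, (self.bins, self.bins_systolic,
                                      self.bins_diastolic)):
                if list(bins) != sorted(set(bins)):
                    raise RiskEquationError(
                        f"term {self.covariate!r}: bin edges must be strictly "
                        "increasing (bins are contiguous and non-overlapping)"
                    )
                if not math.isinf(bins[-1]):
                    raise RiskEquationError(
                        f"term {self.covariate!r}: last bin edge must be .inf "
                        "so the table covers the covariate's full range"
                    )
                if len(bins) != len(self.coefficients):
                    raise RiskEquationError(
                        f"term {self.covariate!r}: {len(bins)} bins but "
                        f"{len(self.coefficients)} coefficients"
                    )
        elif self.coefficient is None:
            raise RiskEquationError(
                f"term {self.covariate!r}: missing coefficient"
            )


@dataclass(frozen=True)
class SexEquation:
    baseline_survival: float
    mean_linear_predictor: float
    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_survival < 1.0:
            raise RiskEquationError(
                f"baseline_survival must lie in (0, 1), "
                f"got {self.baseline_survival}"
            )


@dataclass(frozen=True)
class RiskEquationSpec:
    name: str
    sex_specific: bool
    equations: Mapping[str, SexEquation]
    unit_conversions: Mapping[str, float] = field(default_factory=dict)
    guard_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def equation_for(self, sex: str) -> SexEquation:
        if self.sex_specific:
            try:
                return self.equations[sex]
            except KeyError:
                raise RiskEquationError(f"no equation for sex {sex!r}") from None
        return next(iter(self.equations.values()))


def _term_from_dict(d: Mapping) -> Term:
    def tup(key):
        v = d.get(key)
        return tuple(float(x) for x in v) if v is not None else None

    return Term(
        covariate=d["covariate"],
        transform=d["transform"],
        coefficient=float(d["coefficient"]) if "coefficient" in d else None,
        bins=tup("bins"),
        bins_systolic=tup("bins_systolic"),
        bins_diastolic=tup("bins_diastolic"),
        coefficients=tup("coefficients"),
    )


def spec_from_dict(data: Mapping) -> RiskEquationSpec:
    try:
        equations = {
            sex: SexEquation(
                baseline_survival=float(eq["baseline_survival"]),
                mean_linear_predictor=float(eq["mean_linear_predictor"]),
                terms=tuple(_term_from_dict(t) for t in eq["terms"]),
            )
            for sex, eq in data["equations"].items()
        }
        return RiskEquationSpec(
            name=data["name"],
            sex_specific=bool(data["sex_specific"]),
            equations=equations,
            unit_conversions={k: float(v) for k, v in
                              (data.get("unit_conversions") or {}).items()},
            guard_ranges={k: (float(v[0]), float(v[1])) for k, v in
                          (data.get("guard_ranges") or {}).items()},
        )
    except (KeyError, TypeError) as err:
        raise RiskEquationError(f"malformed risk equation file: {err}") from None


def spec_to_dict(spec: RiskEquationSpec) -> dict:
    def term_dict(t: Term) -> dict:
        d: dict = {"covariate": t.covariate, "transform": t.transform}
        if t.coefficient is not None:
            d["coefficient"] = t.coefficient
        for key in ("bins", "bins_systolic", "bins_diastolic", "coefficients"):
            v = getattr(t, key)
            if v is not None:
                d[key] = list(v)
        return d

    return {
        "name": spec.name,
        "sex_specific": spec.sex_specific,
        "unit_conversions": dict(spec.unit_conversions),
        "guard_ranges": {k: list(v) for k, v in spec.guard_ranges.items()},
        "equations": {
            sex: {
                "baseline_survival": eq.baseline_survival,
                "mean_linear_predictor": eq.mean_linear_predictor,
                "terms": [term_dict(t) for t in eq.terms],
            }
            for sex, eq in spec.equations.items()
        },
    }


def load_risk_equation(path: str | Path) -> RiskEquationSpec:
    """Parse and validate a YAML risk equation file."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    return spec_from_dict(data)


def save_risk_equation(spec: RiskEquationSpec, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def default_risk_equation() -> RiskEquationSpec:
    """The shipped sex-specific categorical 10-year CHD equations."""
    ref = resources.files("grs.data").joinpath("framingham_chd_1998.yaml")
    with resources.as_file(ref) as path:
        return load_risk_equation(path)


def _bin_index(values: np.ndarray, bins: tuple[float, ...]) -> np.ndarray:
    # right-open bins: value < bins[i] -> bin i; NaN parked in bin 0 and
    # masked out later by the completeness check
    safe = np.nan_to_num(values, nan=-np.inf)
    return np.searchsorted(np.asarray(bins), safe, side="right")


def _term_value(term: Term, row: pd.DataFrame, spec: RiskEquationSpec
                ) -> np.ndarray:
    if term.transform == "category_table":
        coeffs = np.asarray(term.coefficients)
        if term.covariate == "blood_pressure":
            i_sys = _bin_index(row["systolic_bp"].to_numpy(float),
                               term.bins_systolic)
            i_dia = _bin_index(row["diastolic_bp"].to_numpy(float),
                               term.bins_diastolic)
            return coeffs[np.maximum(i_sys, i_dia)]
        scale = spec.unit_conversions.get(term.covariate, 1.0)
        vals = row[term.covariate].to_numpy(float) * scale
        return coeffs[_bin_index(vals, term.bins)]
    scale = spec.unit_conversions.get(term.covariate, 1.0)
    vals = row[term.covariate].to_numpy(float) * scale
    if term.transform == "natural_log":
        vals = np.log(vals)
    elif term.transform == "squared":
        vals = vals ** 2
    return term.coefficient * vals


def _check_guards(cohort: pd.DataFrame, spec: RiskEquationSpec) -> None:
    for cov, (lo, hi) in spec.guard_ranges.items():
        if cov not in cohort.columns:
            continue
        vals = cohort[cov].dropna()
        n_out = int(((vals < lo) | (vals > hi)).sum())
        if n_out:
            warnings.warn(
                f"{n_out} value(s) of {cov} outside physiologic guard range "
                f"[{lo}, {hi}]", stacklevel=3)


def framingham_risk10(cohort: pd.DataFrame | pd.Series,
                      spec: RiskEquationSpec | None = None) -> pd.Series:
    """10-year CHD risk for each cohort row.

    ``cohort`` carries the conventional risk factors in the package's
    declared units (cholesterol mmol/l, pressure mmHg); any unit conversion
    the equation needs is declared in the spec and applied here.  Rows with
    a missing required covariate get NaN risk and are excluded downstream.
    """
    if spec is None:
        spec = default_risk_equation()
    if isinstance(cohort, pd.Series):
        return framingham_risk10(cohort.to_frame().T, spec)
    _check_guards(cohort, spec)
    risk = pd.Series(np.nan, index=cohort.index, name="framingham_risk")
    for sex, group in cohort.groupby("sex", observed=True):
        eq = spec.equation_for(str(sex))
        lp = np.zeros(len(group))
        required: set[str] = set()
        for term in eq.terms:
            if term.covariate == "blood_pressure":
                required |= {"systolic_bp", "diastolic_bp"}
            else:
                required.add(term.covariate)
            lp = lp + _term_value(term, group, spec)
        complete = ~group[sorted(required)].isna().any(axis=1).to_numpy()
        value = 1.0 - eq.baseline_survival ** np.exp(
            lp - eq.mean_linear_predictor)
        value = np.clip(value, 0.0, 1.0)
        value[~complete] = np.nan
        risk.loc[group.index] = value
    return risk
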