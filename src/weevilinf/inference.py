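"""Derived analyses: standardized impacts, insecticide efficacy, harvest timing.

Standardized impacts project the averaged model onto interpretable changes in
infestation.  The model is anchored at a baseline field — sample means for
continuous variables, sample modes for binary/ordinal ones, and *zero*
monthly insecticide treatments (the no-pesticide baseline overrides the mean
rule for treatment counts).  Each variable is then perturbed (+1 SD for
continuous, +1 unit for counts and ordinals — except the number of hillings,
perturbed downward to stay within observed bounds; binaries flip away from
the mode) and the impact is the difference of *squared* sqrt-scale
predictions, in percentage points.  Predictions use the shrinkage
(weight-multiplied) estimates, so variables with parameter weight below 1 are
attenuated; no retransformation bias correction is applied (simple squaring).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io import build_design, encode_term
from .multimodel import AveragedParameter
from .regression import fit_ols
from .registry import (
    OBSERVER_LEVELS,
    OBSERVER_TERMS,
    CovariateSpec,
    default_registry,
    registry_map,
)

#: monthly treatment-count columns for the efficacy regression, in season order
INSECTICIDE_MONTHS = ("insecticide_dec", "insecticide_jan",
                      "insecticide_feb", "insecticide_mar")

#: ordinal perturbed downward (only a decrease keeps predictions in bounds)
DOWNWARD_ORDINALS = ("n_hillings",)


@dataclass
class BaselineProfile:
    """Raw-scale baseline value per variable plus the rule that produced it."""

    values: dict[str, object]
    notes: dict[str, str]        # mean | mode | zero


@dataclass
class ImpactEstimate:
    name: str
    perturbation: str            # "+1 SD" | "+1 unit" | "-1 unit" | "flip"
    delta_infestation: float     # percentage points on the proportion scale


def _mode(series: pd.Series):
    """Most common value; ties broken toward the lower level."""
    counts = series.value_counts()
    top = counts.max()
    return sorted(counts[counts == top].index)[0]


def baseline_profile(table: pd.DataFrame,
                     registry: list[CovariateSpec] | None = None) -> BaselineProfile:
    """Baseline field: covariate means/modes with zero pesticide treatments."""
    if len(table) == 0:
        raise ValidationError("empty table")
    registry = default_registry() if registry is None else registry
    values: dict[str, object] = {}
    notes: dict[str, str] = {}
    for spec in registry:
        col = table[spec.name]
        if spec.kind == "count" and spec.category == "chemical":
            values[spec.name], notes[spec.name] = 0, "zero"
        elif spec.kind == "continuous":
            values[spec.name], notes[spec.name] = float(col.mean()), "mean"
        else:
            values[spec.name], notes[spec.name] = _mode(col), "mode"
    values["observer"], notes["observer"] = _mode(table["observer"]), "mode"
    return BaselineProfile(values=values, notes=notes)


def _predict_sqrt(avg: list[AveragedParameter], profile_values: dict[str, object],
                  specs: dict[str, CovariateSpec]) -> float:
    """Sqrt-scale prediction at a raw-value profile using shrinkage estimates."""
    pred = 0.0
    observer = str(profile_values.get("observer", OBSERVER_LEVELS[0]))
    frame = pd.DataFrame({"observer": [observer], "field_id": ["baseline"]})
    for name, value in profile_values.items():
        if name != "observer":
            frame[name] = [value]
    for par in avg:
        if par.name == "intercept":
            pred += par.shrinkage_avg
            continue
        if math.isnan(par.shrinkage_avg):
            continue
        x = float(encode_term(frame, par.name, specs)[0])
        pred += par.shrinkage_avg * x
    return pred


def standardized_impacts(avg: list[AveragedParameter],
                         profile: BaselineProfile,
                         table: pd.DataFrame,
                         registry: list[CovariateSpec] | None = None,
                         ) -> list[ImpactEstimate]:
    """Predicted infestation change (percentage points) per perturbed variable."""
    registry = default_registry() if registry is None else registry
    specs = registry_map(registry)
    base_sqrt = _predict_sqrt(avg, profile.values, specs)

    def clamp(s: float) -> float:
        if s < 0.0:
            warnings.warn("sqrt-scale prediction below 0; clamped")
            return 0.0
        return s

    base_p = clamp(base_sqrt) ** 2
    out = []
    for par in avg:
        if par.name == "intercept" or par.name in OBSERVER_TERMS:
            continue
        spec = specs[par.name]
        values = dict(profile.values)
        if spec.kind == "continuous":
            sd = float(table[par.name].std(ddof=1))
            values[par.name] = float(values[par.name]) + sd
            label = "+1 SD"
        elif spec.kind == "count":
            values[par.name] = int(values[par.name]) + 1
            label = "+1 unit"
        elif spec.kind == "ordinal":
            step = -1 if par.name in DOWNWARD_ORDINALS else 1
            values[par.name] = int(values[par.name]) + step
            label = f"{step:+d} unit"
        else:  # binary: flip away from the baseline mode
            current = str(values[par.name])
            values[par.name] = spec.labels[1] if current == spec.labels[0] \
                else spec.labels[0]
            label = "flip"
        pert_p = clamp(_predict_sqrt(avg, values, specs)) ** 2
        out.append(ImpactEstimate(name=par.name, perturbation=label,
                                  delta_infestation=100.0 * (pert_p - base_p)))
    return out


def impacts_to_frame(impacts: list[ImpactEstimate]) -> pd.DataFrame:
    return pd.DataFrame({
        "variable": [i.name for i in impacts],
        "perturbation": [i.perturbation for i in impacts],
        "delta_infestation_pp": [i.delta_infestation for i in impacts],
    })


def insecticide_model(table: pd.DataFrame,
                      registry: list[CovariateSpec] | None = None
                      ) -> pd.DataFrame:
    """Per-month insecticide effect on sqrt-scale infestation (one joint OLS).

    Months with zero variance across fields are dropped (rank protection) and
    reported with NaN estimates.
    """
    registry = default_registry() if registry is None else registry
    missing = [m for m in INSECTICIDE_MONTHS if m not in table.columns]
    if missing:
        raise ValidationError(f"missing treatment columns: {missing}")
    kept = []
    for month in INSECTICIDE_MONTHS:
        if table[month].nunique() <= 1:
            warnings.warn(f"{month} is constant across fields; dropped")
        else:
            kept.append(month)
    design = build_design(table, kept, registry)
    rows = []
    if kept:
        fit = fit_ols(design)
        for month in INSECTICIDE_MONTHS:
            if month in kept:
                j = kept.index(month) + 1
                rows.append((month, float(fit.coefficients[j]),
                             float(fit.coef_se[j])))
            else:
                rows.append((month, math.nan, math.nan))
    else:
        fit_ols(build_design(table, [], registry))  # intercept-only sanity fit
        rows = [(m, math.nan, math.nan) for m in INSECTICIDE_MONTHS]
    return pd.DataFrame(rows, columns=["month", "estimate", "se"])


@dataclass
class HarvestAdaptation:
    """Simple regression of harvest day on model-expected infestation."""

    slope: float
    intercept: float
    df: int
    p_value: float


def expected_infestation(table: pd.DataFrame, avg: list[AveragedParameter],
                         registry: list[CovariateSpec] | None = None
                         ) -> np.ndarray:
    """Back-transformed (squared) shrinkage-model prediction per field."""
    registry = default_registry() if registry is None else registry
    terms = [a.name for a in avg
             if a.name != "intercept" and not math.isnan(a.shrinkage_avg)]
    design = build_design(table, terms, registry, response=False)
    coefs = {a.name: a.shrinkage_avg for a in avg}
    beta = np.array([coefs.get(c, 0.0) for c in design.columns])
    s = design.X @ beta
    return np.clip(s, 0.0, None) ** 2


def harvest_adaptation(table: pd.DataFrame,
                       expected: np.ndarray) -> HarvestAdaptation:
    """Do farmers expecting higher infestation harvest earlier?"""
    if "harvest_day" not in table.columns:
        raise ValidationError("harvest_day column required")
    expected = np.asarray(expected, float)
    if len(expected) != len(table):
        raise ValidationError("expected vector length mismatch")
    if len(table) < 3:
        raise InsufficientDataError("need at least 3 fields")
    if np.ptp(expected) == 0.0:
        raise ValidationError("expected infestations have zero variance")
    res = stats.linregress(expected, table["harvest_day"].to_numpy(float))
    return HarvestAdaptation(slope=float(res.slope),
                             intercept=float(res.intercept),
                             df=len(table) - 2,
                             p_value=float(res.pvalue))
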