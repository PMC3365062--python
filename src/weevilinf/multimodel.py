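"""All-subsets evaluation, Akaike weights, and multi-model averaging.

Every non-empty additive combination of the global-model variables is fitted
(2^k - 1 models for k variables; 17 variables give the 131,071 models of the
source analysis).  Models within ``delta_max`` (default 2.0, inclusive) of
the minimum AIC form the confidence set.  Within a set,

    w_i  = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)         (Akaike weight)
    w_p  = sum of w_i over models containing parameter p       (parameter weight)

The "natural" average of a parameter conditions on the models containing it,
natural = sum_{i in p} w_i beta_i / w_p; the shrinkage average multiplies the
natural average by w_p and is the estimate used for prediction.  The
unconditional standard error pools within-model variance and between-model
spread: se = sqrt( sum (w_i/w_p) [var(beta_i) + (beta_i - natural)^2] ).

``parameter_weight`` divides exact float sums (math.fsum) of the unnormalized
exp(-delta/2) masses, so a parameter occurring in every model has weight
exactly 1.0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import build_design, expand_terms
from .regression import FittedModel, GramSystem, aic_array, fit_ols
from .registry import CovariateSpec, default_registry
from .stepwise import build_global_model

#: refuse plain enumeration beyond this many variables (2^20 ~ 1e6 models)
MAX_ENUM_VARS = 20

#: chunk size for batched subset solves (bounds peak memory)
_CHUNK = 40000


@dataclass
class ModelSet:
    """A collection of fitted subsets over a fixed term list.

    Each model is a bitmask over ``term_names`` (bit j set = term j included;
    the intercept is always included).  Weights are present only after
    ``akaike_weights``/``confidence_set``.
    """

    term_names: list[str]
    masks: np.ndarray            # uint32
    rss: np.ndarray
    aic: np.ndarray
    n: int                       # number of observations
    corrected: bool = False
    weights: np.ndarray | None = None
    gram: GramSystem | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def best_aic(self) -> float:
        return float(np.min(self.aic))

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.aic))

    @property
    def delta(self) -> np.ndarray:
        return self.aic - self.best_aic

    def member_terms(self, i: int) -> list[str]:
        mask = int(self.masks[i])
        return [t for j, t in enumerate(self.term_names) if mask >> j & 1]

    def contains(self, name: str) -> np.ndarray:
        if name == "intercept":
            return np.ones(len(self.masks), dtype=bool)
        if name not in self.term_names:
            raise ValidationError(f"unknown parameter {name!r}")
        bit = np.uint32(1 << self.term_names.index(name))
        return (self.masks & bit) != 0

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "variables": ["+".join(self.member_terms(i)) for i in range(len(self))],
            "k_terms": [bin(int(m)).count("1") for m in self.masks],
            "rss": self.rss, "aic": self.aic, "delta": self.delta,
        })
        if self.weights is not None:
            out["weight"] = self.weights
        return out


def _masks_for_size(k: int, s: int) -> np.ndarray:
    """All (C(k,s), s) index arrays of s-of-k terms, in lexicographic order."""
    combos = np.array(list(combinations(range(k), s)), dtype=np.int64)
    return combos.reshape(-1, s)


def enumerate_and_fit(table: pd.DataFrame, variables: list[str],
                      registry: list[CovariateSpec] | None = None,
                      corrected: bool = False,
                      allow_large: bool = False) -> ModelSet:
    """Fit every non-empty subset of ``variables`` (each with an intercept).

    Enumeration is deterministic given the table: subsets are generated by
    size then lexicographic order.  Refuses more than 20 variables unless
    ``allow_large`` is set.
    """
    registry = default_registry() if registry is None else registry
    terms = expand_terms(list(variables))
    k = len(terms)
    if k == 0:
        raise ValidationError("no variables to enumerate")
    if k > 32:
        raise ValidationError("bitmask enumeration supports at most 32 variables")
    if k > MAX_ENUM_VARS and not allow_large:
        raise ValidationError(
            f"{k} variables give {2 ** k - 1:,} models; pass allow_large=True "
            f"to enumerate beyond {MAX_ENUM_VARS}")
    design = build_design(table, terms, registry)
    # fail fast on rank problems of the full design
    fit_ols(design, corrected=corrected)
    gram = GramSystem.from_design(design)

    total = 2 ** k - 1
    masks = np.empty(total, dtype=np.uint32)
    rss = np.empty(total)
    pos = 0
    bits = np.uint32(1) << np.arange(k, dtype=np.uint32)
    for s in range(1, k + 1):
        combos = _masks_for_size(k, s)
        for lo in range(0, len(combos), _CHUNK):
            block = combos[lo:lo + _CHUNK]
            m = len(block)
            rss[pos:pos + m] = gram.rss_batch(block)
            masks[pos:pos + m] = bits[block].sum(axis=1, dtype=np.uint32)
            pos += m
    sizes = np.concatenate([np.full(math.comb(k, s), s, dtype=np.int64)
                            for s in range(1, k + 1)])
    aics = aic_array(gram.n, rss, sizes + 1, corrected)
    if np.any(np.isnan(aics)):
        raise ValidationError("rank-deficient or perfectly-fitting subsets "
                              "encountered during enumeration")
    return ModelSet(term_names=terms, masks=masks, rss=rss, aic=aics,
                    n=gram.n, corrected=corrected, gram=gram)


def akaike_weights(mset: ModelSet) -> ModelSet:
    """Model set with normalized Akaike weights attached."""
    if len(mset) == 0:
        raise ValidationError("empty model set")
    e = np.exp(-0.5 * mset.delta)
    return replace(mset, weights=e / math.fsum(e))


def confidence_set(mset: ModelSet, delta_max: float = 2.0) -> ModelSet:
    """Models within ``delta_max`` of the best AIC (inclusive), re-weighted."""
    if len(mset) == 0:
        raise ValidationError("empty model set")
    keep = mset.delta <= delta_max
    sub = replace(mset, masks=mset.masks[keep], rss=mset.rss[keep],
                  aic=mset.aic[keep], weights=None)
    return akaike_weights(sub)


def parameter_weight(name: str, mset: ModelSet) -> float:
    """Sum of Akaike weights over the models containing ``name``.

    Computed as an exact-sum ratio of unnormalized exp(-delta/2) masses, so a
    parameter present in every model gets weight exactly 1.0.
    """
    has = mset.contains(name)
    e = np.exp(-0.5 * mset.delta)
    return math.fsum(e[has]) / math.fsum(e)


@dataclass
class AveragedParameter:
    """Model-averaged estimate of one parameter across a confidence set."""

    name: str
    weight: float              # w_p
    natural_avg: float
    shrinkage_avg: float       # natural_avg * weight, exactly
    se: float                  # unconditional SE (conditional on containing models)
    ci_low: float
    ci_high: float


def refit_members(mset: ModelSet, table: pd.DataFrame,
                  registry: list[CovariateSpec] | None = None) -> list[FittedModel]:
    """Full OLS refits (coefficients + SEs) of every model in a small set."""
    registry = default_registry() if registry is None else registry
    design = build_design(table, mset.term_names, registry)
    fits = []
    for i in range(len(mset)):
        terms = mset.member_terms(i)
        fit = fit_ols(design.subset(terms), corrected=mset.corrected)
        fit.delta = float(mset.delta[i])
        if mset.weights is not None:
            fit.weight = float(mset.weights[i])
        fits.append(fit)
    return fits


def average_parameters(cset: ModelSet, table: pd.DataFrame,
                       registry: list[CovariateSpec] | None = None,
                       z: float = 1.96) -> list[AveragedParameter]:
    """Natural and shrinkage averages with unconditional SEs and normal CIs.

    Parameters absent from every model are reported with weight 0 and NaN
    averages.  The intercept (present everywhere) is averaged too.
    """
    if cset.weights is None:
        cset = akaike_weights(cset)
    fits = refit_members(cset, table, registry)
    out = []
    for name in ["intercept"] + list(cset.term_names):
        w_p = parameter_weight(name, cset)
        has = cset.contains(name)
        if not np.any(has):
            out.append(AveragedParameter(name, 0.0, math.nan, math.nan,
                                         math.nan, math.nan, math.nan))
            continue
        betas, variances, ws = [], [], []
        for i in np.where(has)[0]:
            fit = fits[i]
            j = 0 if name == "intercept" else fit.variable_names.index(name) + 1
            betas.append(fit.coefficients[j])
            variances.append(fit.coef_se[j] ** 2)
            ws.append(cset.weights[i])
        betas, variances = np.asarray(betas), np.asarray(variances)
        ws = np.asarray(ws) / math.fsum(ws)
        natural = float(ws @ betas)
        var_u = float(ws @ (variances + (betas - natural) ** 2))
        se = math.sqrt(var_u)
        out.append(AveragedParameter(
            name=name, weight=w_p, natural_avg=natural,
            shrinkage_avg=natural * w_p, se=se,
            ci_low=natural - z * se, ci_high=natural + z * se))
    return out


def averages_to_frame(avg: list[AveragedParameter]) -> pd.DataFrame:
    return pd.DataFrame({
        "parameter": [a.name for a in avg],
        "estimate": [a.natural_avg for a in avg],
        "sem": [a.se for a in avg],
        "ci_low": [a.ci_low for a in avg],
        "ci_high": [a.ci_high for a in avg],
        "parameter_weight": [a.weight for a in avg],
        "shrinkage_estimate": [a.shrinkage_avg for a in avg],
    })


# ---------------------------------------------------------------------------
# local vs landscape vs combined model classes

@dataclass
class ClassResult:
    label: str
    pool: list[str]
    selected: list[str]
    best_model: FittedModel
    delta_aic: float = math.nan     # relative to the best combined model
    weight: float = math.nan        # three-way Akaike weight


@dataclass
class ClassComparison:
    combined: ClassResult
    local: ClassResult
    landscape: ClassResult

    def to_frame(self) -> pd.DataFrame:
        rows = [self.combined, self.local, self.landscape]
        return pd.DataFrame({
            "class": [r.label for r in rows],
            "delta_aic": [r.delta_aic for r in rows],
            "weight": [r.weight for r in rows],
            "best_model": ["+".join(r.best_model.variable_names) for r in rows],
        })


def _best_subset_model(table, pool, registry, tolerance, corrected,
                       label) -> ClassResult:
    """Global-build then all-subsets best model within one candidate pool."""
    traj = build_global_model(table, pool, tolerance=tolerance,
                              registry=registry, corrected=corrected)
    selected = list(traj.selected)
    if not selected:
        raise ValidationError(f"{label}: forward selection admitted no variables")
    if len(selected) > MAX_ENUM_VARS:
        warnings.warn(
            f"{label}: {len(selected)} variables selected; enumerating the "
            f"first {MAX_ENUM_VARS} in entry order")
        selected = selected[:MAX_ENUM_VARS]
    mset = enumerate_and_fit(table, selected, registry, corrected=corrected)
    i = mset.best_index
    best = refit_subset(mset, i, table, registry)
    return ClassResult(label=label, pool=list(pool), selected=selected,
                       best_model=best)


def class_result(label: str, selected: list[str], mset: ModelSet, table,
                 registry=None, pool: list[str] | None = None) -> ClassResult:
    """Wrap an existing enumeration as a class-comparison entry."""
    best = refit_subset(mset, mset.best_index, table, registry)
    return ClassResult(label=label, pool=list(pool or selected),
                       selected=list(selected), best_model=best)


def refit_subset(mset: ModelSet, i: int, table, registry=None) -> FittedModel:
    registry = default_registry() if registry is None else registry
    design = build_design(table, mset.term_names, registry)
    fit = fit_ols(design.subset(mset.member_terms(i)), corrected=mset.corrected)
    return fit


def compare_classes(table: pd.DataFrame,
                    local_vars: list[str],
                    landscape_vars: list[str],
                    controls: list[str] = ("observer",),
                    registry: list[CovariateSpec] | None = None,
                    tolerance: float = 2.0,
                    corrected: bool = False,
                    combined: ClassResult | None = None) -> ClassComparison:
    """Best local-only, landscape-only and combined models with Akaike weights.

    Control variables join every candidate pool.  Weights are the three-way
    Akaike weights of the class-best models; deltas are AIC differences from
    the best combined model.  A precomputed combined-class result (e.g. from
    the main enumeration) can be passed to avoid refitting it.
    """
    if not local_vars or not landscape_vars:
        raise ValidationError("local and landscape classes must be non-empty")
    registry = default_registry() if registry is None else registry
    controls = list(controls)
    combined_pool = list(dict.fromkeys(
        list(local_vars) + list(landscape_vars) + controls))
    results = {
        "combined": combined if combined is not None else _best_subset_model(
            table, combined_pool, registry, tolerance, corrected, "combined"),
        "local": _best_subset_model(table, list(local_vars) + controls,
                                    registry, tolerance, corrected, "local"),
        "landscape": _best_subset_model(table, list(landscape_vars) + controls,
                                        registry, tolerance, corrected,
                                        "landscape"),
    }
    ref = results["combined"].best_model.aic
    aics = np.array([results[k].best_model.aic for k in results])
    e = np.exp(-0.5 * (aics - aics.min()))
    w = e / math.fsum(e)
    for j, key in enumerate(results):
        results[key].delta_aic = float(aics[j] - ref)
        results[key].weight = float(w[j])
    return ClassComparison(combined=results["combined"], local=results["local"],
                           landscape=results["landscape"])
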