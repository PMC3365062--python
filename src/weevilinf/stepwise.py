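"""Forward AIC-guided construction of the global (least parsimonious) model.

Starting from the intercept-only model, the candidate whose addition lowers
AIC the most enters at each step.  The walk deliberately continues past the
AIC minimum: additions are admitted as long as the resulting model's AIC is no
more than ``tolerance`` (default 2.0) above the lowest AIC reached so far —
models within 2 AIC units are considered similarly supported.  With tolerance
zero the procedure reduces to classical forward selection stopping at the
first AIC increase.  Ties between candidates are broken by pool order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoCandidateError
from .io import build_design, expand_terms
from .regression import GramSystem, aic_array
from .registry import CovariateSpec, default_registry, registry_names

#: relative tolerance below which a subset Gram pivot is treated as singular
_SINGULAR_RSS = 1e-10


@dataclass
class Step:
    variable: str
    aic: float
    cum_delta: float    # AIC change from the intercept-only model (negative = better)
    r2: float


@dataclass
class StepTrajectory:
    """Full record of one forward walk."""

    steps: list[Step] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    aic_intercept_only: float = np.nan
    aic_min_reached: float = np.nan
    best_step: int = -1          # index into steps of the minimum-AIC model (-1: intercept only)

    @property
    def best_r2(self) -> float:
        """R^2 of the minimum-AIC model along the walk."""
        return 0.0 if self.best_step < 0 else self.steps[self.best_step].r2

    @property
    def best_variables(self) -> list[str]:
        return self.selected[: self.best_step + 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(1, len(self.steps) + 1),
            "variable": [s.variable for s in self.steps],
            "aic": [s.aic for s in self.steps],
            "cum_delta_aic": [s.cum_delta for s in self.steps],
            "r2": [s.r2 for s in self.steps],
        })


def default_pool(registry: list[CovariateSpec] | None = None) -> list[str]:
    """All covariates plus the observer-control indicators, in registry order.

    Controls compete on equal terms: in the source analysis they entered the
    global model through the same forward procedure.
    """
    registry = default_registry() if registry is None else registry
    return registry_names(registry) + ["observer"]


class _ForwardState:
    """Shared Gram system over the full candidate pool for cheap re-fits."""

    def __init__(self, table: pd.DataFrame, pool: list[str],
                 registry: list[CovariateSpec] | None, corrected: bool):
        self.terms = expand_terms(list(pool))
        design = build_design(table, self.terms, registry)
        self.gram = GramSystem.from_design(design)
        self.n = self.gram.n
        self.corrected = corrected
        # zero-variance terms (e.g. a month with no treatments anywhere) can
        # never enter: flag them once up front
        g = self.gram.G
        col_var = np.diag(g)[1:] / self.n - (g[0, 1:] / self.n) ** 2
        self.degenerate = [t for t, v in zip(self.terms, col_var)
                           if v <= 1e-12]
        if self.degenerate:
            warnings.warn("dropping zero-variance candidates: "
                          f"{self.degenerate}")

    def intercept_aic(self) -> float:
        rss = self.gram.rss_single(())
        return float(aic_array(self.n, np.array([rss]), np.array([1]),
                               self.corrected)[0])

    def candidate_aics(self, current_idx: list[int],
                       candidates: list[int]) -> np.ndarray:
        """AIC of current-model-plus-one-candidate, NaN where rank deficient."""
        m = len(candidates)
        s = len(current_idx)
        subsets = np.empty((m, s + 1), dtype=np.int64)
        subsets[:, :s] = np.asarray(current_idx, dtype=np.int64)
        subsets[:, s] = np.asarray(candidates, dtype=np.int64)
        rss = self.gram.rss_batch(subsets)
        rss = np.where(rss <= _SINGULAR_RSS * self.gram.tss, np.nan, rss)
        return aic_array(self.n, rss, np.full(m, s + 2), self.corrected)

    def r2(self, idx: list[int]) -> float:
        rss = self.gram.rss_single(tuple(idx))
        return 1.0 - rss / self.gram.tss if self.gram.tss > 0 else 0.0


def next_best_variable(table: pd.DataFrame, current: list[str],
                       pool: list[str],
                       registry: list[CovariateSpec] | None = None,
                       corrected: bool = False) -> tuple[str, float]:
    """The pool variable whose addition to ``current`` gives the lowest AIC.

    Rank-deficient candidates are skipped with a warning; ties go to the
    earlier pool entry.
    """
    if not pool:
        raise NoCandidateError("candidate pool is empty")
    state = _ForwardState(table, list(dict.fromkeys(list(current) + list(pool))),
                          registry, corrected)
    current_terms = expand_terms(list(current))
    pool_terms = [t for t in expand_terms(list(pool)) if t not in current_terms]
    cur_idx = [state.terms.index(t) for t in current_terms]
    cand_idx = [state.terms.index(t) for t in pool_terms]
    aics = state.candidate_aics(cur_idx, cand_idx)
    if np.all(np.isnan(aics)):
        raise NoCandidateError("all candidate variables are rank deficient")
    if np.any(np.isnan(aics)):
        skipped = [pool_terms[i] for i in np.where(np.isnan(aics))[0]]
        warnings.warn(f"skipping rank-deficient candidates: {skipped}")
    j = int(np.nanargmin(aics))
    return pool_terms[j], float(aics[j])


def build_global_model(table: pd.DataFrame,
                       pool: list[str] | None = None,
                       tolerance: float = 2.0,
                       registry: list[CovariateSpec] | None = None,
                       corrected: bool = False) -> StepTrajectory:
    """Forward walk over the pool under the running-minimum tolerance rule.

    Stops before an addition whose AIC would exceed (lowest AIC reached so
    far) + tolerance, or when the pool is exhausted.  The returned trajectory
    records every admitted step; the "global model" is ``trajectory.selected``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    registry = default_registry() if registry is None else registry
    pool = default_pool(registry) if pool is None else list(pool)
    traj = StepTrajectory()
    if not pool:
        design = build_design(table, [], registry)
        gram = GramSystem.from_design(design)
        traj.aic_intercept_only = float(
            aic_array(gram.n, np.array([gram.rss_single(())]), np.array([1]),
                      corrected)[0])
        traj.aic_min_reached = traj.aic_intercept_only
        return traj

    state = _ForwardState(table, pool, registry, corrected)
    aic0 = state.intercept_aic()
    traj.aic_intercept_only = aic0
    run_min = aic0
    best_step = -1
    cur_idx: list[int] = []
    remaining = [i for i in range(len(state.terms))
                 if state.terms[i] not in state.degenerate]
    dropped: set[int] = set()

    while remaining:
        aics = state.candidate_aics(cur_idx, remaining)
        if np.all(np.isnan(aics)):
            warnings.warn("all remaining candidates rank deficient; stopping")
            break
        if np.any(np.isnan(aics)):
            newly = [i for i, a in zip(remaining, aics)
                     if np.isnan(a) and i not in dropped]
            if newly:
                warnings.warn("skipping rank-deficient candidates: "
                              f"{[state.terms[i] for i in newly]}")
                dropped.update(newly)
        j = int(np.nanargmin(aics))
        best_aic = float(aics[j])
        if best_aic > run_min + tolerance:
            break
        cand = remaining.pop(j)
        cur_idx.append(cand)
        traj.selected.append(state.terms[cand])
        traj.steps.append(Step(variable=state.terms[cand], aic=best_aic,
                               cum_delta=best_aic - aic0,
                               r2=state.r2(cur_idx)))
        if best_aic < run_min:
            run_min = best_aic
            best_step = len(traj.steps) - 1
    traj.aic_min_reached = run_min
    traj.best_step = best_step
    return traj
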