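"""Synthetic field-record generator emulating the study's 138-field dataset.

The generator reproduces the *statistical* structure the downstream analysis
assumes — not any individual field.  Covariates are drawn independently with
the printed marginal moments (moment-matched truncated normals; gammas for
the right-skewed non-negative ones; Poisson counts; Bernoulli/categorical for
yes-no and ordinal practices).  The sqrt-scale response is

    s = intercept + sum_j beta_j * x_j(encoded) + observer offset + N(0, sigma)

clipped to [0, 1] and squared into a field-level infested proportion, which is
split into edge and center strata (edges run hotter by the observed 25.1/18.3
factor) such that the area-weighted average recovers the field proportion.
Observers are assigned in near-equal blocks and fields sit in four
village-like Gaussian clusters (SD 300 m, centers within 3 km), matching the
250 m / 3 km correlogram design.

An optional covariate correlation hook (Gaussian copula over the continuous
variables) is provided; the default is independence, since only marginal
moments were reported.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CalibrationError, ValidationError
from .registry import (
    CENTER_INFESTATION,
    EDGE_INFESTATION,
    FIELD_AREA_MEAN,
    FIELD_AREA_SD,
    MEAN_INFESTATION,
    OBSERVER_LEVELS,
    CovariateSpec,
    TruthRecord,
    default_registry,
    default_truth,
    registry_map,
)

#: village cluster centers (m); pairwise distances stay below 3 km
CLUSTER_CENTERS = ((0.0, 0.0), (1400.0, 400.0), (500.0, 1600.0), (1900.0, 1300.0))
CLUSTER_SD = 300.0

#: edge/center stratum inflation factors (Results means 25.1 / 18.3 / 16.1)
EDGE_FACTOR = EDGE_INFESTATION / MEAN_INFESTATION
CENTER_FACTOR = CENTER_INFESTATION / MEAN_INFESTATION

#: upper resampling bound for Poisson counts ("truncated Poisson")
COUNT_CAP = 6

#: edge-area share: Beta with mean ~0.244 (implied by the stratum means)
EDGE_SHARE_A, EDGE_SHARE_B = 4.4, 13.6

_MIN_AREA = 30.0


@lru_cache(maxsize=None)
def _truncnorm_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose lower-truncated normal has the target moments."""
    if sd == 0.0:
        return mean, 0.0
    if mean - lower > 6.0 * sd:   # truncation never binds in practice
        return mean, sd

    def gap(params):
        mu, log_s = params
        s = np.exp(log_s)
        a = (lower - mu) / s
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=s, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ok, msg = optimize.fsolve(gap, [mean, np.log(sd)],
                                         full_output=True)
    if ok != 1:
        raise CalibrationError(
            f"cannot moment-match truncated normal (mean={mean}, sd={sd}): {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def _draw_covariate(spec: CovariateSpec, n: int, rng: np.random.Generator):
    if spec.kind == "continuous":
        if spec.family == "gamma":
            if spec.mean <= 0:
                raise ValidationError(f"{spec.name}: gamma needs positive mean")
            shape = (spec.mean / spec.sd) ** 2
            return rng.gamma(shape, spec.sd**2 / spec.mean, size=n)
        if spec.lower is None:
            return rng.normal(spec.mean, spec.sd, size=n)
        mu, s = _truncnorm_params(spec.mean, spec.sd, spec.lower)
        x = rng.normal(mu, s, size=n)
        for _ in range(100):
            bad = x < spec.lower
            if not bad.any():
                break
            x[bad] = rng.normal(mu, s, size=int(bad.sum()))
        return np.maximum(x, spec.lower)
    if spec.kind == "count":
        x = rng.poisson(spec.rate, size=n)
        while (x > COUNT_CAP).any():
            bad = x > COUNT_CAP
            x[bad] = rng.poisson(spec.rate, size=int(bad.sum()))
        return x.astype("int64")
    if spec.kind == "binary":
        ones = rng.random(n) < spec.p_one
        return np.where(ones, spec.labels[1], spec.labels[0])
    # ordinal
    return rng.choice(np.asarray(spec.levels), size=n,
                      p=np.asarray(spec.level_probs)).astype("int64")


def _encode(spec: CovariateSpec, values: np.ndarray) -> np.ndarray:
    if spec.kind == "binary":
        out = (values == spec.labels[1]).astype(float)
    else:
        out = np.asarray(values, float)
    if spec.transform == "sqrt":
        out = np.sqrt(out)
    return out


def observer_blocks(n_fields: int, n_observers: int) -> np.ndarray:
    """Near-equal observer block sizes, e.g. 138 over 4 gives 35/35/34/34."""
    base, extra = divmod(n_fields, n_observers)
    sizes = [base + (1 if i < extra else 0) for i in range(n_observers)]
    return np.repeat(np.arange(n_observers), sizes)


def generate_dataset(registry: list[CovariateSpec] | None = None,
                     n_fields: int = 138,
                     n_observers: int = 4,
                     truth: TruthRecord | None = None,
                     seed: int | None = None,
                     correlation: np.ndarray | None = None,
                     ) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one field table plus the truth record that produced it.

    Identical seeds give byte-identical tables.  ``correlation``, if given,
    imposes a Gaussian-copula correlation across the continuous covariates
    (default: identity = independence).
    """
    registry = default_registry() if registry is None else registry
    if not registry:
        raise ValidationError("registry must be non-empty")
    if not 1 <= n_observers <= n_fields:
        raise ValidationError("need n_fields >= n_observers >= 1")
    if n_observers > len(OBSERVER_LEVELS):
        raise ValidationError(f"at most {len(OBSERVER_LEVELS)} observers supported")
    if truth is None:
        truth = default_truth(registry, seed=seed)
    elif seed is not None:
        truth = truth.with_(seed=seed)
    truth.validate(registry)
    rng = np.random.default_rng(truth.seed)

    specs = registry_map(registry)
    columns: dict[str, np.ndarray] = {}
    if correlation is not None:
        cont = [s for s in registry if s.kind == "continuous"]
        if correlation.shape != (len(cont), len(cont)):
            raise ValidationError("correlation must be square over the "
                                  f"{len(cont)} continuous covariates")
        z = rng.multivariate_normal(np.zeros(len(cont)), correlation,
                                    size=n_fields)
        u = stats.norm.cdf(z)
        for j, spec in enumerate(cont):
            if spec.family == "gamma":
                shape = (spec.mean / spec.sd) ** 2
                columns[spec.name] = stats.gamma.ppf(
                    u[:, j], shape, scale=spec.sd**2 / spec.mean)
            elif spec.lower is None:
                columns[spec.name] = stats.norm.ppf(u[:, j], spec.mean, spec.sd)
            else:
                mu, s = _truncnorm_params(spec.mean, spec.sd, spec.lower)
                a = (spec.lower - mu) / s
                columns[spec.name] = stats.truncnorm.ppf(u[:, j], a, np.inf,
                                                         loc=mu, scale=s)
    for spec in registry:
        if spec.name not in columns:
            columns[spec.name] = _draw_covariate(spec, n_fields, rng)

    obs_idx = observer_blocks(n_fields, n_observers)
    observers = np.array(OBSERVER_LEVELS)[obs_idx]
    centers = np.asarray(CLUSTER_CENTERS)[:n_observers]
    xy = centers[obs_idx] + rng.normal(0.0, CLUSTER_SD, size=(n_fields, 2))

    # sqrt-scale linear predictor
    s = np.full(n_fields, truth.intercept)
    for name, beta in truth.betas.items():
        s += beta * _encode(specs[name], columns[name])
    s += np.asarray(truth.observer_effects)[obs_idx]
    s += rng.normal(0.0, truth.sigma, size=n_fields)
    s = np.clip(s, 0.0, 1.0)
    proportion = s**2

    total_area = np.maximum(
        rng.gamma((FIELD_AREA_MEAN / FIELD_AREA_SD) ** 2,
                  FIELD_AREA_SD**2 / FIELD_AREA_MEAN, size=n_fields),
        _MIN_AREA)
    edge_share = rng.beta(EDGE_SHARE_A, EDGE_SHARE_B, size=n_fields)
    edge_area = edge_share * total_area
    center_area = (1.0 - edge_share) * total_area
    # stratum proportions; renormalized so the area-weighted mean is exact
    denom = EDGE_FACTOR * edge_share + CENTER_FACTOR * (1.0 - edge_share)
    edge_inf = np.clip(proportion * EDGE_FACTOR / denom, 0.0, 1.0)
    center_inf = np.clip(proportion * CENTER_FACTOR / denom, 0.0, 1.0)

    table = pd.DataFrame({
        "field_id": [f"F{i + 1:03d}" for i in range(n_fields)],
        "observer": observers,
        "x": xy[:, 0], "y": xy[:, 1],
        "edge_area": edge_area, "center_area": center_area,
        "edge_infested": edge_inf, "center_infested": center_inf,
        **columns,
    })
    return table, truth


def best_model_r2(table: pd.DataFrame,
                  registry: list[CovariateSpec] | None = None,
                  tolerance: float = 2.0) -> float:
    """R^2 of the minimum-AIC model along the forward selection walk."""
    from .stepwise import build_global_model

    traj = build_global_model(table, tolerance=tolerance, registry=registry)
    return traj.best_r2


def calibrate_sigma(registry: list[CovariateSpec] | None = None,
                    truth: TruthRecord | None = None,
                    target_r2_band: tuple[float, float] = (0.402, 0.464),
                    n_reps: int = 20,
                    seed: int = 0,
                    n_fields: int = 138,
                    sigma_bracket: tuple[float, float] = (0.02, 1.5),
                    max_iter: int = 40) -> float:
    """Residual SD whose median best-model R^2 lands in the target band.

    Bisects on sigma (median best-model R^2 is monotone decreasing in sigma);
    raises CalibrationError with the achievable range when the band cannot be
    reached (e.g. all-zero effects).
    """
    lo, hi = target_r2_band
    if not (0.0 < lo < hi < 1.0):
        raise ValidationError("target band must satisfy 0 < lo < hi < 1")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    registry = default_registry() if registry is None else registry
    if truth is None:
        truth = default_truth(registry)

    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)

    def median_r2(sigma: float) -> float:
        vals = []
        for s in seeds:
            table, _ = generate_dataset(registry, n_fields=n_fields,
                                        truth=truth.with_(sigma=sigma, seed=int(s)))
            vals.append(best_model_r2(table, registry))
        return float(np.median(vals))

    s_lo, s_hi = sigma_bracket          # note: r2 decreasing in sigma
    r_hi, r_lo = median_r2(s_lo), median_r2(s_hi)
    target = 0.5 * (lo + hi)
    if r_hi < lo or r_lo > hi:
        raise CalibrationError(
            f"band ({lo}, {hi}) unreachable: achievable median best-model R^2 "
            f"range is about ({r_lo:.3f}, {r_hi:.3f}) for sigma in "
            f"{sigma_bracket}", achievable=(r_lo, r_hi))
    a, b = s_lo, s_hi
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        r = median_r2(mid)
        if lo < r < hi and abs(r - target) < 0.1 * (hi - lo):
            return mid
        if r > target:
            a = mid
        else:
            b = mid
    r = median_r2(0.5 * (a + b))
    if lo < r < hi:
        return 0.5 * (a + b)
    raise CalibrationError(
        f"bisection failed to land in ({lo}, {hi}); last median R^2 {r:.3f}",
        achievable=None)
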