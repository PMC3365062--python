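"""Field-record tables: validation, response construction, design matrices.

A field record holds the two-stratum infestation measurements (edge vs center
proportions and areas), planar coordinates in meters, the observer, and one
column per registry covariate.  The modelled response is

    y = sqrt( (p_edge * A_edge + p_center * A_center) / (A_edge + A_center) )

i.e. the area-weighted proportion of infested tubers, square-root transformed
*after* weighting (the reverse order differs numerically).  Proportions are
stored in [0, 1]; printed percentages are divided by 100 at ingest.  Missing
values are rejected, not imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import (
    OBSERVER_LEVELS,
    OBSERVER_TERMS,
    CovariateSpec,
    TruthRecord,
    default_registry,
    registry_map,
)

#: fixed leading columns of every field table
BASE_COLUMNS = ("field_id", "observer", "x", "y",
                "edge_area", "center_area", "edge_infested", "center_infested")

RESPONSE_COLUMN = "response_sqrt"


def compute_response(edge_infested, center_infested, edge_area, center_area):
    """Sqrt of the area-weighted infested proportion.  Accepts scalars or arrays."""
    e, c = np.asarray(edge_infested, float), np.asarray(center_infested, float)
    ae, ac = np.asarray(edge_area, float), np.asarray(center_area, float)
    if np.any(ae < 0) or np.any(ac < 0):
        raise ValidationError("areas must be non-negative")
    total = ae + ac
    if np.any(total <= 0):
        raise ValidationError("edge_area + center_area must be positive")
    for name, p in (("edge_infested", e), ("center_infested", c)):
        if np.any((p < 0) | (p > 1)):
            raise ValidationError(f"{name} must lie in [0, 1]")
    out = np.sqrt((e * ae + c * ac) / total)
    return float(out) if out.ndim == 0 else out


def attach_response(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the table with the sqrt-scale response column added."""
    out = table.copy()
    out[RESPONSE_COLUMN] = compute_response(
        table["edge_infested"].to_numpy(), table["center_infested"].to_numpy(),
        table["edge_area"].to_numpy(), table["center_area"].to_numpy())
    return out


def validate_table(table: pd.DataFrame,
                   registry: list[CovariateSpec] | None = None) -> None:
    """Check the field-table schema and invariants; raise ValidationError."""
    registry = default_registry() if registry is None else registry
    specs = registry_map(registry)
    missing_cols = [c for c in BASE_COLUMNS if c not in table.columns]
    missing_cols += [n for n in specs if n not in table.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")
    if len(table) == 0:
        raise ValidationError("table has no records")

    null_mask = table[list(BASE_COLUMNS) + list(specs)].isna()
    if null_mask.to_numpy().any():
        row = int(np.where(null_mask.any(axis=1))[0][0])
        col = null_mask.columns[int(np.where(null_mask.iloc[row])[0][0])]
        fid = table["field_id"].iloc[row]
        raise ValidationError(f"missing value for variable {col!r} in field {fid!r}")

    bad_obs = set(table["observer"].unique()) - set(OBSERVER_LEVELS)
    if bad_obs:
        raise ValidationError(f"unknown observer levels: {sorted(bad_obs)}")
    # row-level invariants; report the first offending field
    try:
        compute_response(table["edge_infested"], table["center_infested"],
                         table["edge_area"], table["center_area"])
    except ValidationError as err:
        raise ValidationError(f"invalid response components: {err}") from err
    for name, spec in specs.items():
        col = table[name]
        if spec.kind == "binary":
            bad = set(col.astype(str).unique()) - set(spec.labels)
            if bad:
                raise ValidationError(
                    f"variable {name!r}: unexpected levels {sorted(bad)}")
        elif spec.kind == "ordinal":
            bad = set(np.unique(col.to_numpy())) - set(spec.levels)
            if bad:
                raise ValidationError(
                    f"variable {name!r}: unexpected levels {sorted(bad)}")


@dataclass
class DesignMatrix:
    """Design for one regression: ordered columns, values, sqrt-scale response."""

    columns: list[str]      # includes leading "intercept"
    X: np.ndarray           # n x p
    y: np.ndarray | None    # length n, sqrt scale

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, names: list[str]) -> "DesignMatrix":
        idx = [self.columns.index(n) for n in ["intercept"] + list(names)]
        return DesignMatrix([self.columns[i] for i in idx], self.X[:, idx], self.y)


def encode_term(table: pd.DataFrame, name: str,
                specs: dict[str, CovariateSpec],
                transforms: dict[str, str] | None = None) -> np.ndarray:
    """Numeric design column for one term (covariate or observer indicator)."""
    if name in OBSERVER_TERMS:
        level = OBSERVER_LEVELS[OBSERVER_TERMS.index(name) + 1]
        return (table["observer"].astype(str) == level).to_numpy(float)
    if name not in specs:
        raise ValidationError(f"unknown variable {name!r}")
    spec = specs[name]
    col = table[name]
    if col.isna().any():
        fid = table.loc[col.isna(), "field_id"].iloc[0]
        raise ValidationError(f"missing value for variable {name!r} in field {fid!r}")
    if spec.kind == "binary":
        values = (col.astype(str) == spec.labels[1]).to_numpy(float)
    else:
        values = col.to_numpy(float)
    transform = (transforms or {}).get(name, spec.transform)
    if transform == "sqrt":
        if np.any(values < 0):
            raise ValidationError(f"variable {name!r}: sqrt transform of negative value")
        values = np.sqrt(values)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r} for {name!r}")
    return values


def expand_terms(variable_names: list[str]) -> list[str]:
    """Expand the 4-level 'observer' factor into its three indicator terms."""
    out: list[str] = []
    for name in variable_names:
        if name == "observer":
            out.extend(OBSERVER_TERMS)
        else:
            out.append(name)
    return out


def build_design(table: pd.DataFrame, variable_names: list[str],
                 registry: list[CovariateSpec] | None = None,
                 transforms: dict[str, str] | None = None,
                 response: bool = True) -> DesignMatrix:
    """Design matrix with an intercept column prepended.

    Binary variables are coded 0/1 with the first label (reference, e.g. "no"
    or "potato") as 0; 'observer' expands to three indicators against the
    first observer; elevation is sqrt-transformed by registry default.  Column
    order follows the requested order and is deterministic.
    """
    registry = default_registry() if registry is None else registry
    specs = registry_map(registry)
    terms = expand_terms(list(variable_names))
    if len(set(terms)) != len(terms):
        raise ValidationError(f"duplicate variables requested: {terms}")
    n = len(table)
    X = np.empty((n, 1 + len(terms)))
    X[:, 0] = 1.0
    for j, name in enumerate(terms, start=1):
        X[:, j] = encode_term(table, name, specs, transforms)
    y = None
    if response:
        if RESPONSE_COLUMN in table.columns:
            y = table[RESPONSE_COLUMN].to_numpy(float)
        else:
            y = compute_response(
                table["edge_infested"].to_numpy(), table["center_infested"].to_numpy(),
                table["edge_area"].to_numpy(), table["center_area"].to_numpy())
    return DesignMatrix(["intercept"] + terms, X, y)


# ---------------------------------------------------------------------------
# delimited-text persistence

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path,
               registry: list[CovariateSpec] | None = None,
               validate: bool = True) -> pd.DataFrame:
    """Read a comma-separated field table, coercing registry dtypes."""
    registry = default_registry() if registry is None else registry
    table = pd.read_csv(path)
    for spec in registry:
        if spec.name not in table.columns:
            continue
        if spec.kind in ("count", "ordinal"):
            table[spec.name] = table[spec.name].astype("int64")
        elif spec.kind == "continuous":
            table[spec.name] = table[spec.name].astype(float)
        else:
            table[spec.name] = table[spec.name].astype(str)
    if validate:
        validate_table(table, registry)
    return table


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    payload = {
        "betas": truth.betas,
        "intercept": truth.intercept,
        "sigma": truth.sigma,
        "observer_effects": list(truth.observer_effects),
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> TruthRecord:
    payload = json.loads(Path(path).read_text())
    return TruthRecord(
        betas={str(k): float(v) for k, v in payload["betas"].items()},
        intercept=float(payload["intercept"]),
        sigma=float(payload["sigma"]),
        observer_effects=tuple(payload["observer_effects"]),
        seed=payload.get("seed"),
    )
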