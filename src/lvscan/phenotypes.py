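"""Fixed-effect pre-correction of observed traits.

Each trait is regressed on its specified covariates by ordinary least
squares and replaced by the residual.  Growth traits are adjusted for year
of birth only; all other traits for year of birth and slaughter age.  Year
of birth enters as a categorical factor, slaughter age as a continuous
covariate.  Missing trait values are handled complete-case per trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AdjustmentSpec", "adjust_phenotypes", "default_specs"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdjustmentSpec:
    trait_name: str
    covariates: tuple[str, ...] = ("year_of_birth", "slaughter_age")
    categorical_flags: tuple[bool, ...] = (True, False)

    def __post_init__(self) -> None:
        if len(self.covariates) != len(self.categorical_flags):
            raise ValueError("one categorical flag per covariate required")


def default_specs(
    traits, growth_traits: tuple[str, ...] = ()
) -> list[AdjustmentSpec]:
    """Year-of-birth-only specs for growth traits, full spec otherwise."""
    out = []
    for t in traits:
        if t in growth_traits:
            out.append(AdjustmentSpec(t, ("year_of_birth",), (True,)))
        else:
            out.append(AdjustmentSpec(t))
    return out


def _design(df: pd.DataFrame, spec: AdjustmentSpec) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for cov, cat in zip(spec.covariates, spec.categorical_flags):
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in phenotype table")
        if cat:
            levels = sorted(df[cov].unique())
            for lev in levels[1:]:  # first level absorbed by intercept
                cols.append((df[cov] == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            x = df[cov].to_numpy(float)
            cols.append(x - x.mean())
            names.append(cov)
    return np.column_stack(cols), names


def _ols_residuals(y: np.ndarray, X: np.ndarray, names: list[str]) -> np.ndarray:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # drop trailing columns until full rank (confounded levels)
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                log.warning("dropping rank-deficient design column %s", names[j])
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def adjust_phenotypes(
    phenotypes: pd.DataFrame, specs: list[AdjustmentSpec]
) -> pd.DataFrame:
    """Return per-trait OLS residuals, aligned to the input rows.

    Rows with a missing trait value are dropped for that trait (NaN in the
    output); rows with missing covariates raise.
    """
    out = pd.DataFrame(index=phenotypes.index)
    if "animal" in phenotypes.columns:
        out["animal"] = phenotypes["animal"]
    for spec in specs:
        t = spec.trait_name
        if t not in phenotypes.columns:
            raise ValueError(f"trait {t!r} not in phenotype table")
        y_all = phenotypes[t].to_numpy(float)
        mask = ~np.isnan(y_all)
        if not mask.any():
            raise ValueError(f"trait {t!r} has no observed values")
        sub = phenotypes.loc[mask]
        for cov in spec.covariates:
            if sub[cov].isna().any():
                raise ValueError(f"missing covariate {cov!r} for trait {t!r}")
        X, names = _design(sub, spec)
        resid = _ols_residuals(y_all[mask], X, names)
        col = np.full(len(phenotypes), np.nan)
        col[mask] = resid
        out[t] = col
    return out
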