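"""Classify genomic windows by comparing three variance scans.

A window's variance share in the scan for latent trait A (upstream), latent
trait B (downstream) and B-conditioned-on-A determines its effect class:

* ``direct_A_only``  — signal in A only.
* ``direct_B_only``  — signal in B only.
* ``direct_both``    — signal in both; survives conditioning on A
  (pleiotropy).
* ``indirect_via_A`` — signal in both; vanishes when A is a covariate, so
  the effect on B flows through the causal path.
* ``not_associated`` — below threshold everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ClassifierConfig", "RegionCall", "classify_window", "classify_genome"]

CLASSES = (
    "direct_A_only",
    "direct_B_only",
    "direct_both",
    "indirect_via_A",
    "not_associated",
)


@dataclass(frozen=True)
class ClassifierConfig:
    assoc_threshold: float = 0.05  # % additive variance
    strong_threshold: float = 0.15
    indirect_band: tuple[float, float] = (0.1, 0.15)

    def __post_init__(self) -> None:
        if not (0.0 < self.assoc_threshold <= self.strong_threshold):
            raise ValueError("need 0 < assoc_threshold <= strong_threshold")


@dataclass(frozen=True)
class RegionCall:
    window_id: str
    pct_A: float
    pct_B: float
    pct_B_given_A: float
    effect_class: str
    strong: bool  # exceeds strong_threshold in some scan


def classify_window(
    pct_A: float,
    pct_B: float,
    pct_B_given_A: float,
    cfg: ClassifierConfig = ClassifierConfig(),
    window_id: str = "",
) -> RegionCall:
    if min(pct_A, pct_B, pct_B_given_A) < 0:
        raise ValueError("variance percentages must be non-negative")
    t = cfg.assoc_threshold
    a, b, bga = pct_A >= t, pct_B >= t, pct_B_given_A >= t
    if a and not b:
        cls = "direct_A_only"
    elif b and not a:
        cls = "direct_B_only"
    elif a and b and bga:
        cls = "direct_both"
    elif a and b and not bga:
        cls = "indirect_via_A"
    else:
        cls = "not_associated"
    strong = max(pct_A, pct_B) >= cfg.strong_threshold
    return RegionCall(window_id, pct_A, pct_B, pct_B_given_A, cls, strong)


def classify_genome(
    table_A: pd.DataFrame,
    table_B: pd.DataFrame,
    table_B_given_A: pd.DataFrame,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-window calls plus class counts for three aligned scan tables."""
    ids = list(table_A["window_id"])
    for t in (table_B, table_B_given_A):
        if list(t["window_id"]) != ids:
            raise ValueError("the three scans have different window sets")

    def pct_col(df: pd.DataFrame) -> pd.Series:
        cols = [c for c in df.columns if c.startswith("pct_")]
        if len(cols) != 1:
            raise ValueError(f"expected one pct_ column, found {cols}")
        return df[cols[0]]

    pa = pct_col(table_A).to_numpy()
    pb = pct_col(table_B).to_numpy()
    pba = pct_col(table_B_given_A).to_numpy()
    calls = [
        classify_window(a, b, c, cfg, window_id=w)
        for w, a, b, c in zip(ids, pa, pb, pba)
    ]
    out = table_A[["window_id", "chrom", "start_bp", "end_bp"]].copy()
    out["pct_A"] = pa
    out["pct_B"] = pb
    out["pct_B_given_A"] = pba
    out["effect_class"] = [c.effect_class for c in calls]
    out["strong"] = [c.strong for c in calls]
    counts = {cls: int((out["effect_class"] == cls).sum()) for cls in CLASSES}
    counts["total_associated"] = len(out) - counts["not_associated"]
    return out, counts
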