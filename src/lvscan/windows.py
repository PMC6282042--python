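"""Partition additive genetic variance into consecutive SNP windows.

Windows are non-overlapping blocks of ``size`` map-adjacent SNPs that never
span chromosomes; the trailing window on a chromosome may hold fewer SNPs
and is flagged.  A sliding mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Window", "make_windows", "window_variance"]


@dataclass(frozen=True)
class Window:
    window_id: str  # e.g. "19w9"
    chrom: object
    ordinal: int  # 1-based within chromosome
    start_bp: int
    end_bp: int
    snp_indices: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.snp_indices)


def make_windows(
    marker_map: pd.DataFrame, size: int = 20, sliding: bool = False
) -> list[Window]:
    """Block (or sliding) windows of ``size`` SNPs per chromosome."""
    if size < 1:
        raise ValueError("window size must be >= 1")
    chrom = marker_map["chrom"].to_numpy()
    pos = marker_map["pos"].to_numpy()
    # map must be sorted by chromosome then position
    order_key = pd.DataFrame({"chrom": chrom, "pos": pos})
    if not order_key.equals(
        order_key.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    ):
        raise ValueError("marker map not sorted by chromosome then position")
    windows: list[Window] = []
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        starts = (
            range(0, len(idx)) if sliding else range(0, len(idx), size)
        )
        ordinal = 0
        for s in starts:
            member = idx[s : s + size]
            if sliding and len(member) < size:
                break
            ordinal += 1
            windows.append(
                Window(
                    window_id=f"{c}w{ordinal}",
                    chrom=c,
                    ordinal=ordinal,
                    start_bp=int(pos[member].min()),
                    end_bp=int(pos[member].max()),
                    snp_indices=tuple(int(j) for j in member),
                )
            )
    return windows


def window_variance(
    snp_effects: np.ndarray,
    Zc: np.ndarray,
    windows: list[Window],
    sigma2_a_total: float,
    model_tag: str = "trait",
) -> pd.DataFrame:
    """Percent of total additive variance per window for one scan.

    For window w: g_w = Zc[:, w] @ u[w]; pct = 100 * Var(g_w) / sigma2_a_total.
    """
    if sigma2_a_total <= 0:
        raise ValueError("total additive variance must be positive")
    u = np.asarray(snp_effects, dtype=float)
    rows = []
    for w in windows:
        cols = list(w.snp_indices)
        g = Zc[:, cols] @ u[cols]
        pct = 100.0 * g.var() / sigma2_a_total
        rows.append(
            {
                "window_id": w.window_id,
                "chrom": w.chrom,
                "ordinal": w.ordinal,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "n_snps": w.size,
                "truncated": w.size < max(x.size for x in windows),
                f"pct_{model_tag}": pct,
            }
        )
    return pd.DataFrame(rows)
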