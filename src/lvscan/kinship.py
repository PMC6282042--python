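"""Relationship matrices and SNP quality control.

* ``pedigree_A`` — numerator relationship matrix by the tabular (recursive)
  method with inbreeding.
* ``genomic_G`` — VanRaden method 1: G = Zc Zc' / (2 sum p(1-p)).
* ``blend_G`` — alpha*G + (1-alpha)*A22 to guarantee invertibility.
* ``build_H_inverse`` — single-step H inverse, H^-1 = A^-1 plus the
  (G^-1 - A22^-1) correction on the genotyped block (tau = omega = 1).
* ``snp_qc`` — monomorphic / MAF / call-rate filters applied in that order,
  with missing dosages imputed to twice the allele frequency afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PedigreeTable

__all__ = [
    "RelationshipMatrix",
    "QcReport",
    "snp_qc",
    "pedigree_A",
    "genomic_G",
    "blend_G",
    "build_H_inverse",
]


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    ids: np.ndarray
    kind: str  # A, A22, G, G_blended, Hinv, ...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix not square over its ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix not symmetric")

    def submatrix(self, ids) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        rows = np.asarray([pos[a] for a in ids])
        return RelationshipMatrix(
            self.values[np.ix_(rows, rows)], np.asarray(list(ids)), self.kind
        )

    def inverse(self) -> "RelationshipMatrix":
        return RelationshipMatrix(
            np.linalg.inv(self.values), self.ids.copy(), self.kind + "_inv"
        )

    def write(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep=sep
        )


@dataclass(frozen=True)
class QcReport:
    n_input_snps: int
    n_retained: int
    removed_monomorphic: int
    removed_maf: int
    removed_callrate: int

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.removed_monomorphic
            + self.removed_maf
            + self.removed_callrate
        )
        if total != self.n_input_snps:
            raise ValueError("QC counts do not partition the input SNPs")


def snp_qc(
    geno: GenotypeMatrix, maf_min: float = 0.05, callrate_min: float = 0.9
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs (monomorphic -> MAF -> call rate, first failing rule
    assigns the removal category) and impute missing dosages to 2p."""
    freqs = geno.allele_frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    callrate = geno.call_rates()
    mono = (maf <= 0.0) | np.isnan(freqs)
    low_maf = ~mono & (maf < maf_min)
    low_call = ~mono & ~low_maf & (callrate < callrate_min)
    keep = ~(mono | low_maf | low_call)
    report = QcReport(
        n_input_snps=geno.n_snps,
        n_retained=int(keep.sum()),
        removed_monomorphic=int(mono.sum()),
        removed_maf=int(low_maf.sum()),
        removed_callrate=int(low_call.sum()),
    )
    if report.n_retained == 0:
        raise ValueError("QC removed every SNP")
    out = geno.subset_snps(np.where(keep)[0])
    missing = np.isnan(out.dosages)
    if missing.any():
        fill = 2.0 * out.allele_frequencies()
        idx = np.where(missing)
        out.dosages[idx] = fill[idx[1]]
    return out, report


def pedigree_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix via the tabular method.

    a_ii = 1 + 0.5 * a_{sire,dam};  a_ij = 0.5 * (a_{j,sire(i)} + a_{j,dam(i)})
    processed in parent-before-offspring order.
    """
    order = ped.topological_order()
    idx = {a: i for i, a in enumerate(order)}
    tab = ped.table.set_index("animal")
    n = len(order)
    A = np.zeros((n, n))
    for a in order:
        i = idx[a]
        s, d = int(tab.at[a, "sire"]), int(tab.at[a, "dam"])
        si = idx.get(s, -1)
        di = idx.get(d, -1)
        for j in range(i):
            val = 0.0
            if si >= 0:
                val += 0.5 * A[j, si]
            if di >= 0:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(A, order, "A")


def genomic_G(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden method 1 genomic relationship matrix."""
    if np.isnan(geno.dosages).any():
        raise ValueError("genotypes contain missing calls; run snp_qc first")
    if freqs is None:
        freqs = geno.allele_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        bad = np.where((freqs <= 0.0) | (freqs >= 1.0))[0]
        raise ValueError(
            f"{len(bad)} SNPs with allele frequency 0 or 1 "
            "(should have been filtered)"
        )
    Zc = geno.dosages - 2.0 * freqs
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    G = Zc @ Zc.T / denom
    return RelationshipMatrix(G, geno.ids.copy(), "G")


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, alpha: float = 0.95
) -> RelationshipMatrix:
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"blending alpha={alpha} outside [0, 1]")
    if G.values.shape != A22.values.shape:
        raise ValueError("G and A22 not conformable")
    vals = alpha * G.values + (1.0 - alpha) * A22.values
    return RelationshipMatrix(vals, G.ids.copy(), "G_blended")


def build_H_inverse(
    Ainv: RelationshipMatrix,
    A22inv: RelationshipMatrix,
    Ginv: RelationshipMatrix,
    genotyped_ids,
) -> RelationshipMatrix:
    """H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1] over the genotyped animals."""
    genotyped_ids = np.asarray(list(genotyped_ids))
    pos = {a: i for i, a in enumerate(Ainv.ids)}
    missing = [a for a in genotyped_ids if a not in pos]
    if missing:
        raise ValueError(
            f"genotyped animals not in pedigree: {missing[:5]}"
        )
    H = Ainv.values.copy()
    if len(genotyped_ids):
        rows = np.asarray([pos[a] for a in genotyped_ids])
        # align the genotyped-block inverses to genotyped_ids order
        g = _aligned(Ginv, genotyped_ids)
        a22 = _aligned(A22inv, genotyped_ids)
        H[np.ix_(rows, rows)] += g - a22
    return RelationshipMatrix(H, Ainv.ids.copy(), "Hinv")


def _aligned(mat: RelationshipMatrix, ids: np.ndarray) -> np.ndarray:
    pos = {a: i for i, a in enumerate(mat.ids)}
    rows = np.asarray([pos[a] for a in ids])
    return mat.values[np.ix_(rows, rows)]
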