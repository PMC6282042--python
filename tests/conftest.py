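"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use different algorithms from the package
(enumeration, augmented least squares, direct V-matrix algebra) so that
agreement is informative.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from lvscan.datatypes import GenotypeMatrix, PedigreeTable

MODEL_TEXT = """\
carcass =~ QG + FOR + MARB
meat =~ JC + TD + CT
meat ~ carcass
"""


@pytest.fixture(scope="session")
def model_text() -> str:
    return MODEL_TEXT


def make_pedigree(rows) -> PedigreeTable:
    """rows: (animal, sire, dam) or (animal, sire, dam, generation)."""
    rows = [r if len(r) == 4 else (*r, 0) for r in rows]
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation"])
    df["sex"] = "M"
    return PedigreeTable(df)


def random_genotypes(
    n: int, m: int, seed: int = 0, maf=(0.1, 0.5)
) -> GenotypeMatrix:
    """Unrelated animals, Hardy-Weinberg, linkage equilibrium.

    Columns that come out monomorphic by chance are nudged (one het call)
    so the matrix is QC-clean; the generating frequencies are attached as
    ``founder_freqs``.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    fixed = np.where((dos.min(axis=0) == dos.max(axis=0)))[0]
    for j in fixed:
        dos[rng.integers(0, n), j] = 1.0
    mp = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(m)], "chrom": 1,
         "pos": (np.arange(m) + 1) * 1000}
    )
    return GenotypeMatrix(dos, np.arange(1, n + 1), mp, founder_freqs=p)


# --------------------------------------------------------------------------
# oracle: expected relationship by exhaustive gamete-transmission enumeration
# --------------------------------------------------------------------------
def enumeration_A(ped: PedigreeTable) -> np.ndarray:
    """Numerator relationships via brute-force enumeration of every
    possible founder-allele transmission pattern (equally likely)."""
    order = list(ped.topological_order())
    tab = ped.table.set_index("animal")
    founders = [a for a in order
                if int(tab.at[a, "sire"]) == 0 and int(tab.at[a, "dam"]) == 0]
    nonf = [a for a in order if a not in founders]
    if len(nonf) > 8:
        raise ValueError("enumeration oracle limited to 8 non-founders")
    allele = {}
    label = 0
    for f in founders:
        allele[f] = (label, label + 1)
        label += 2
    n = len(order)
    idx = {a: i for i, a in enumerate(order)}
    acc = np.zeros((n, n))
    patterns = list(itertools.product((0, 1), repeat=2 * len(nonf)))
    for pat in patterns:
        al = dict(allele)
        for k, a in enumerate(nonf):
            s, d = int(tab.at[a, "sire"]), int(tab.at[a, "dam"])
            al[a] = (al[s][pat[2 * k]], al[d][pat[2 * k + 1]])
        for i, ai in enumerate(order):
            for j, aj in enumerate(order):
                if j < i:
                    continue
                share = sum(
                    al[ai][x] == al[aj][y] for x in (0, 1) for y in (0, 1)
                ) / 4.0
                acc[i, j] += share
                acc[j, i] = acc[i, j] if i != j else acc[i, j]
    acc /= len(patterns)
    A = 2.0 * acc
    for i in range(n):
        for j in range(n):
            if i != j:
                A[j, i] = A[i, j]
    return A


def random_small_pedigree(seed: int, n_founders: int = 3, n_nonf: int = 4):
    """A random small pedigree with n_nonf non-founders."""
    rng = np.random.default_rng(seed)
    rows = [(i + 1, 0, 0) for i in range(n_founders)]
    next_id = n_founders + 1
    for _ in range(n_nonf):
        pool = [r[0] for r in rows]
        s, d = rng.choice(pool, size=2, replace=False)
        rows.append((next_id, int(s), int(d)))
        next_id += 1
    return make_pedigree(rows)


# --------------------------------------------------------------------------
# oracle: ridge / GLS solutions without Henderson's equations
# --------------------------------------------------------------------------
def ridge_oracle(y, X, lam):
    """argmin ||y - Xb - a||^2 + lam ||a||^2 via augmented least squares."""
    n = len(y)
    k = X.shape[1]
    top = np.hstack([X, np.eye(n)])
    bot = np.hstack([np.zeros((n, k)), np.sqrt(lam) * np.eye(n)])
    aug = np.vstack([top, bot])
    rhs = np.concatenate([y, np.zeros(n)])
    sol, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    return sol[:k], sol[k:]


def gls_blup_oracle(y, X, H, W, sigma2_a, sigma2_e):
    """Direct V-matrix BLUE/BLUP: b=(X'V^-1X)^-1 X'V^-1 y,
    a = sigma2_a H W' V^-1 (y - Xb)."""
    V = sigma2_a * W @ H @ W.T + sigma2_e * np.eye(len(y))
    Vinv = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    a = sigma2_a * H @ W.T @ Vinv @ (y - X @ b)
    return b, a


def direct_H_oracle(A: np.ndarray, G: np.ndarray, gen_idx: np.ndarray) -> np.ndarray:
    """Single-step H built directly from its definition (genotyped block
    replaced by G, ungenotyped block regressed through the pedigree)."""
    n = A.shape[0]
    non = np.setdiff1d(np.arange(n), gen_idx)
    A11 = A[np.ix_(non, non)]
    A12 = A[np.ix_(non, gen_idx)]
    A22 = A[np.ix_(gen_idx, gen_idx)]
    A22i = np.linalg.inv(A22)
    H = np.zeros_like(A)
    H11 = A11 + A12 @ A22i @ (G - A22) @ A22i @ A12.T
    H12 = A12 @ A22i @ G
    H[np.ix_(non, non)] = H11
    H[np.ix_(non, gen_idx)] = H12
    H[np.ix_(gen_idx, non)] = H12.T
    H[np.ix_(gen_idx, gen_idx)] = G
    return H
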