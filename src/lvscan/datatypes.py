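"""Shared data containers: pedigree, marker map, genotype matrix.

Conventions
-----------
* Animal identifiers are positive integers; ``0`` denotes an unknown parent.
* Genotypes are allele dosages in ``{0, 1, 2}`` stored as ``float64`` so that
  missing calls can be carried as ``NaN`` until QC imputes them.
* The marker map is sorted by chromosome then position and is row-aligned
  with the columns of the dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PedigreeTable", "GenotypeMatrix"]


@dataclass
class PedigreeTable:
    """Animal/sire/dam records defining the numerator relationship structure."""

    table: pd.DataFrame  # columns: animal, sire, dam, generation, sex

    REQUIRED = ("animal", "sire", "dam")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns {missing}")
        if self.table["animal"].duplicated().any():
            dup = self.table.loc[self.table["animal"].duplicated(), "animal"]
            raise ValueError(f"duplicate animal ids: {sorted(set(dup))[:5]}")

    @property
    def animals(self) -> np.ndarray:
        return self.table["animal"].to_numpy()

    @property
    def n_animals(self) -> int:
        return len(self.table)

    def parents_of(self, animal: int) -> tuple[int, int]:
        row = self.table.loc[self.table["animal"] == animal].iloc[0]
        return int(row["sire"]), int(row["dam"])

    def topological_order(self) -> np.ndarray:
        """Return animal ids sorted so every parent precedes its offspring.

        Raises ``ValueError`` on a pedigree cycle (an animal that is its own
        ancestor).
        """
        ids = list(self.table["animal"])
        sire = dict(zip(self.table["animal"], self.table["sire"]))
        dam = dict(zip(self.table["animal"], self.table["dam"]))
        known = set(ids)
        state: dict[int, int] = {}  # 0 = visiting, 1 = done
        order: list[int] = []

        def visit(a: int) -> None:
            stack = [(a, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise ValueError(f"pedigree cycle involving animal {node}")
                state[node] = 0
                stack.append((node, True))
                for p in (sire[node], dam[node]):
                    if p != 0 and p in known and state.get(p) != 1:
                        if state.get(p) == 0:
                            raise ValueError(
                                f"pedigree cycle involving animal {p}"
                            )
                        stack.append((p, False))

        for a in ids:
            if state.get(a) != 1:
                visit(a)
        return np.asarray(order)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "PedigreeTable":
        return cls(pd.read_csv(path, sep=sep))


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele-dosage matrix with its marker map."""

    dosages: np.ndarray  # (n_animals, n_snps) float, NaN = missing call
    ids: np.ndarray  # animal ids, row-aligned
    marker_map: pd.DataFrame  # columns: snp, chrom, pos (bp)
    founder_freqs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.dosages.shape != (len(self.ids), len(self.marker_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.ids)} animals x {len(self.marker_map)} markers"
            )

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of the counted allele, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        ff = None if self.founder_freqs is None else self.founder_freqs[keep]
        return GenotypeMatrix(
            self.dosages[:, keep],
            self.ids.copy(),
            self.marker_map.iloc[keep].reset_index(drop=True),
            founder_freqs=ff,
        )

    def subset_animals(self, keep_ids) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        rows = np.asarray([pos[a] for a in keep_ids])
        return GenotypeMatrix(
            self.dosages[rows],
            np.asarray(list(keep_ids)),
            self.marker_map.copy(),
            founder_freqs=self.founder_freqs,
        )

    # ------------------------------------------------------------------ I/O
    def write_plink_text(self, path: str | Path, sep: str = "\t") -> None:
        """Transposed PLINK-style text: one animal row, one dosage column."""
        df = pd.DataFrame(
            self.dosages, columns=self.marker_map["snp"].tolist()
        )
        df.insert(0, "animal", self.ids)
        df.to_csv(path, sep=sep, index=False, na_rep="NA")

    def write_map(self, path: str | Path, sep: str = "\t") -> None:
        self.marker_map.to_csv(path, sep=sep, index=False)

    @classmethod
    def read_plink_text(
        cls, geno_path: str | Path, map_path: str | Path, sep: str = "\t"
    ) -> "GenotypeMatrix":
        df = pd.read_csv(geno_path, sep=sep)
        mp = pd.read_csv(map_path, sep=sep)
        ids = df["animal"].to_numpy()
        dos = df.drop(columns=["animal"]).to_numpy(dtype=float)
        return cls(dos, ids, mp)

    def write_vcf(self, path: str | Path) -> None:
        """Minimal uncompressed VCF (GT only), dosage counted for ALT."""
        gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            cols = "\t".join(str(a) for a in self.ids)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
            for j, row in enumerate(self.marker_map.itertuples(index=False)):
                calls = "\t".join(
                    gt.get(d, "./.") for d in self.dosages[:, j]
                )
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.snp}\tA\tB\t.\tPASS\t.\tGT\t{calls}\n"
                )
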