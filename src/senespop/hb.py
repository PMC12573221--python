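"""Phased haploblock matrix container.

A haploblock (HB) is a short run of tightly linked array SNPs summarised as a
single multi-allelic phased marker.  Calls hold two allele codes per
individual per block; slot 0 is the maternal homolog and slot 1 the paternal
homolog for pedigreed material (arbitrary but consistent phase otherwise).
Missing calls are coded -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class HaploblockMatrix:
    individuals: list
    blocks: pd.DataFrame       # columns: chrom, index, cm, bp_start, bp_end
    calls: np.ndarray          # (n_individuals, n_blocks, 2) integer allele codes

    def __post_init__(self):
        self.individuals = [str(i) for i in self.individuals]
        self.calls = np.asarray(self.calls, dtype=int)
        if self.calls.shape != (len(self.individuals), len(self.blocks), 2):
            raise ValueError("calls shape does not match individuals x blocks x 2")
        for chrom, g in self.blocks.groupby("chrom", sort=False):
            if np.any(np.diff(g["cm"].to_numpy()) <= 0):
                raise ValueError(f"cM positions not strictly increasing on {chrom}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def index_of(self, individual) -> int:
        return self.individuals.index(str(individual))

    def chrom_block_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.blocks["chrom"].astype(str).to_numpy() == str(chrom))

    def subset_individuals(self, ids) -> "HaploblockMatrix":
        idx = [self.index_of(i) for i in ids]
        return HaploblockMatrix([self.individuals[i] for i in idx],
                                self.blocks.reset_index(drop=True),
                                self.calls[idx])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: indiv, chrom, hb_index, allele_1, allele_2."""
        rows = []
        chroms = self.blocks["chrom"].astype(str).to_numpy()
        hb_idx = self.blocks["index"].to_numpy()
        for i, ind in enumerate(self.individuals):
            for j in range(self.n_blocks):
                rows.append((ind, chroms[j], int(hb_idx[j]),
                             int(self.calls[i, j, 0]), int(self.calls[i, j, 1])))
        return pd.DataFrame(rows, columns=["indiv", "chrom", "hb_index",
                                           "allele_1", "allele_2"])

    def write(self, calls_path, map_path) -> None:
        self.to_frame().to_csv(calls_path, sep="\t", index=False)
        self.blocks.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def read(cls, calls_path, map_path) -> "HaploblockMatrix":
        blocks = pd.read_csv(map_path, sep="\t")
        long = pd.read_csv(calls_path, sep="\t", dtype={"indiv": str, "chrom": str})
        individuals = list(dict.fromkeys(long["indiv"]))
        key = list(zip(blocks["chrom"].astype(str), blocks["index"].astype(int)))
        pos = {k: j for j, k in enumerate(key)}
        calls = np.full((len(individuals), len(blocks), 2), MISSING, dtype=int)
        ind_pos = {ind: i for i, ind in enumerate(individuals)}
        for ind, chrom, hb, a1, a2 in long[["indiv", "chrom", "hb_index",
                                            "allele_1", "allele_2"]].itertuples(index=False):
            j = pos[(str(chrom), int(hb))]
            calls[ind_pos[ind], j] = (a1, a2)
        return cls(individuals, blocks, calls)
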