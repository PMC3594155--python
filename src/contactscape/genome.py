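"""Genome coordinate bookkeeping: chromosome tables and fixed-width bin grids.

All genomic positions in this package are 1-based base-pair coordinates, as
reported by read aligners.  Bin indices are 0-based and bins are half-open
intervals ``[k*resolution, (k+1)*resolution)`` in 0-based coordinates, so the
1-based position ``p`` falls into bin ``(p - 1) // resolution``.  The last bin
of a chromosome may be shorter than the resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd


class Genome:
    """Ordered chromosome -> length (bp) table.

    The input order of chromosomes defines the canonical chromosome order used
    to orient contacts and to enumerate chromosome pairs.
    """

    def __init__(self, lengths: Mapping[str, int]):
        self._lengths: dict[str, int] = {}
        for name, length in lengths.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._lengths[str(name)] = length
        if not self._lengths:
            raise ValueError("genome has no chromosomes")
        self._order = {name: i for i, name in enumerate(self._lengths)}

    @classmethod
    def from_tsv(cls, path) -> "Genome":
        """Read a two-column (name, length-bp) tab-separated table."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(dict(zip(df["chrom"], df["length"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._lengths.items():
                fh.write(f"{name}\t{length}\n")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._lengths == other._lengths

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise ValueError(f"unknown chromosome {chrom!r}") from None

    def index(self, chrom: str) -> int:
        """Rank of ``chrom`` in the canonical chromosome order."""
        try:
            return self._order[chrom]
        except KeyError:
            raise ValueError(f"unknown chromosome {chrom!r}") from None

    def grid(self, chrom: str, resolution: int) -> "BinGrid":
        return BinGrid(chrom, self.length(chrom), int(resolution))

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered chromosome pairs (i < j) in canonical order."""
        chroms = self.chromosomes
        return [(chroms[i], chroms[j])
                for i in range(len(chroms)) for j in range(i + 1, len(chroms))]


@dataclass(frozen=True)
class BinGrid:
    """Fixed-resolution binning of one chromosome."""

    chromosome: str
    length: int
    resolution: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.length / self.resolution)

    def bin_of(self, pos):
        """Bin index of a 1-based position (scalar or array)."""
        pos = np.asarray(pos, dtype=np.int64)
        if np.any(pos < 1) or np.any(pos > self.length):
            bad = pos[(pos < 1) | (pos > self.length)]
            raise ValueError(
                f"position {int(bad.flat[0])} outside chromosome "
                f"{self.chromosome} [1, {self.length}]")
        idx = (pos - 1) // self.resolution
        return idx if idx.ndim else int(idx)

    def bin_start(self, idx: int) -> int:
        return idx * self.resolution

    def bin_end(self, idx: int) -> int:
        return min((idx + 1) * self.resolution, self.length)

    def label(self, idx: int) -> str:
        return f"{self.chromosome}:{self.bin_start(idx)}-{self.bin_end(idx)}"

    def labels(self) -> list[str]:
        return [self.label(i) for i in range(self.n_bins)]


def grid_from_labels(labels: list[str]) -> BinGrid:
    """Reconstruct a :class:`BinGrid` from ``chrom:start-end`` bin labels."""
    if not labels:
        raise ValueError("no bin labels")
    chrom, span = labels[0].rsplit(":", 1)
    start0, end0 = (int(x) for x in span.split("-"))
    resolution = end0 - start0
    last_end = int(labels[-1].rsplit(":", 1)[1].split("-")[1])
    if len(labels) > 1:
        # resolution is the width of a full (non-terminal) bin
        first_full = labels[0].rsplit(":", 1)[1].split("-")
        resolution = int(first_full[1]) - int(first_full[0])
    return BinGrid(chrom, last_end, resolution)
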