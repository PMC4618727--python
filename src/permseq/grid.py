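"""Genome coordinate grid.

Positions across all chromosomes are indexed by a single flat index
``j = 0 .. M-1`` so that densities, covariate tracks and prior pseudo-counts
can be held in flat arrays.  Chromosomes occupy contiguous index ranges in
the order they were declared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeGrid"]


@dataclass(frozen=True)
class GenomeGrid:
    """Ordered chromosomes binned at a fixed width.

    Parameters
    ----------
    chrom_names : tuple of str
        Chromosome names in genome order.
    chrom_lengths : tuple of int
        Length of each chromosome in bp.
    bin_width : int, default 1
        Bin size in bp; position ``p`` maps to bin ``p // bin_width``.
    """

    chrom_names: tuple
    chrom_lengths: tuple
    bin_width: int = 1
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(self.chrom_names) == 0:
            raise ValueError("grid needs at least one chromosome")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        nbins = np.array(
            [-(-l // self.bin_width) for l in self.chrom_lengths], dtype=np.int64
        )
        offsets = np.concatenate([[0], np.cumsum(nbins)])
        object.__setattr__(self, "_offsets", offsets)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_dict(cls, lengths: dict, bin_width: int = 1) -> "GenomeGrid":
        return cls(tuple(lengths.keys()), tuple(int(v) for v in lengths.values()), bin_width)

    @classmethod
    def from_table(cls, path, bin_width: int = 1) -> "GenomeGrid":
        """Read a two-column (name, length) TSV chromosome table."""
        tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                          names=["chrom", "length"], dtype={"chrom": str})
        return cls(tuple(tab["chrom"]), tuple(int(v) for v in tab["length"]), bin_width)

    # -- properties -----------------------------------------------------
    @property
    def M(self) -> int:
        """Total number of grid positions."""
        return int(self._offsets[-1])

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def chrom_length(self, name: str) -> int:
        return self.chrom_lengths[self.chrom_index(name)]

    def n_bins(self, name: str) -> int:
        c = self.chrom_index(name)
        return int(self._offsets[c + 1] - self._offsets[c])

    def chrom_range(self, name: str) -> tuple:
        """Half-open flat-index range [start, stop) of a chromosome."""
        c = self.chrom_index(name)
        return int(self._offsets[c]), int(self._offsets[c + 1])

    @property
    def offsets(self) -> np.ndarray:
        """Cumulative bin offsets, length n_chroms + 1."""
        return self._offsets

    # -- coordinate conversion ------------------------------------------
    def to_global(self, chrom_idx, pos):
        """Vectorized (chromosome index, bp position) -> flat index."""
        chrom_idx = np.asarray(chrom_idx, dtype=np.int64)
        pos = np.asarray(pos, dtype=np.int64)
        return self._offsets[chrom_idx] + pos // self.bin_width

    def to_local(self, j):
        """Flat index -> (chromosome index, bin offset within chromosome)."""
        j = np.asarray(j, dtype=np.int64)
        c = np.searchsorted(self._offsets, j, side="right") - 1
        return c, j - self._offsets[c]
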