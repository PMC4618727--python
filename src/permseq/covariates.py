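"""Per-position covariate tracks and the aggregated prior-fitting table.

The prior regresses ChIP-seq uni-read counts on chromatin accessibility, so
this module builds the two inputs of that regression:

* a DNase fragment-coverage track ``x_j`` (reads pre-allocated at probability
  >= 0.9, extended to the average library size from their 5' ends), plus
  optional trinary histone enrichment codes ``h_j`` in {0, 1, 2};
* the aggregated table obtained by grouping all genome positions that share
  the same (pooled) DNase count and histone pattern and averaging the ChIP
  uni-read count within each group.

Pooling follows the estimation recipe: DNase counts 0, 1 and 2 form a single
low-count group, and counts above the 99.95th percentile of the positive
count distribution form a single high-count group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GenomeGrid

__all__ = [
    "CovariateTrack",
    "AggregatedPriorTable",
    "filter_prealloc_reads",
    "build_coverage_track",
    "start_count_track",
    "trinarize_histone",
    "aggregate_by_covariate",
    "write_bedgraph",
    "read_bedgraph",
]

log = logging.getLogger(__name__)

POOL_LOW = "pooled_low"    # DNase counts {0, 1, 2}
POOL_HIGH = "pooled_high"  # DNase counts above the 99.95th percentile


@dataclass
class CovariateTrack:
    """Covariate values on every position of a :class:`GenomeGrid`.

    ``x`` holds the DNase count per grid position; ``histone_codes`` holds
    zero or more trinary (0/1/2) enrichment tracks of the same length.
    """

    grid: GenomeGrid
    x: np.ndarray
    histone_codes: list = field(default_factory=list)
    fragment_length: int = 200

    def __post_init__(self):
        self.x = np.asarray(self.x)
        if self.x.shape != (self.grid.M,):
            raise ValueError("x track length does not match grid size")
        if len(self.x) and self.x.min() < 0:
            raise ValueError("DNase counts must be non-negative")
        for h in self.histone_codes:
            if h.shape != (self.grid.M,):
                raise ValueError("histone track length does not match grid size")
            if len(h) and (h.min() < 0 or h.max() > 2):
                raise ValueError("histone codes must be trinary (0/1/2)")

    @property
    def n_histones(self) -> int:
        return len(self.histone_codes)


def filter_prealloc_reads(records: pd.DataFrame, cutoff: float = 0.9) -> pd.DataFrame:
    """Keep pre-allocated reads whose allocation probability is >= ``cutoff``.

    ``records`` needs columns chrom, start, strand and (optionally)
    probability; rows without a probability column are treated as uni-reads
    (probability 1).  The inclusive cut keeps a read at exactly the cutoff,
    and uni-reads always pass.
    """
    if "probability" not in records.columns:
        return records.copy()
    p = records["probability"].to_numpy(dtype=float)
    if len(p) and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("allocation probabilities must lie in [0, 1]")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    return records.loc[p >= cutoff].copy()


def _positions_as_arrays(positions, grid: GenomeGrid):
    if isinstance(positions, pd.DataFrame):
        chrom = positions["chrom"].to_numpy()
        start = positions["start"].to_numpy(dtype=np.int64)
        strand = positions["strand"].to_numpy()
    else:
        chrom, start, strand = map(np.asarray, zip(*positions)) if len(positions) else (
            np.array([]), np.array([], dtype=np.int64), np.array([]))
        start = start.astype(np.int64)
    cidx = np.empty(len(chrom), dtype=np.int64)
    for name in np.unique(chrom):
        cidx[chrom == name] = grid.chrom_index(str(name))
    fwd = np.asarray(strand) == "+" if strand.dtype.kind in "UOS" else np.asarray(strand) == 0
    lengths = np.array(grid.chrom_lengths, dtype=np.int64)[cidx] if len(cidx) else np.array([], dtype=np.int64)
    bad = (start < 0) | (start >= lengths)
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"position off chromosome: {chrom[k]}:{start[k]} "
            f"(length {lengths[k]})"
        )
    return cidx, start, fwd


def _per_bin(bp_values: np.ndarray, grid: GenomeGrid, chrom_i: int) -> np.ndarray:
    if grid.bin_width == 1:
        return bp_values
    edges = np.arange(0, len(bp_values), grid.bin_width)
    return np.add.reduceat(bp_values, edges)


def build_coverage_track(positions, grid: GenomeGrid,
                         fragment_length: int = 200) -> np.ndarray:
    """Fragment-coverage counts per grid position.

    Every read is extended ``fragment_length`` bp from its 5' end in the
    direction of its strand (minus-strand reads extend leftward), truncated
    at chromosome boundaries; the returned array counts covering fragments
    at each position (summed within bins for bin widths > 1).
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    cidx, start, fwd = _positions_as_arrays(positions, grid)
    left = np.where(fwd, start, start - fragment_length + 1)
    right = np.where(fwd, start + fragment_length, start + 1)
    out = np.zeros(grid.M, dtype=np.int64)
    for c, name in enumerate(grid.chrom_names):
        mask = cidx == c
        if not mask.any():
            continue
        L = grid.chrom_lengths[c]
        diff = np.zeros(L + 1, dtype=np.int64)
        lo = np.clip(left[mask], 0, L)
        hi = np.clip(right[mask], 0, L)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        g0, g1 = grid.chrom_range(name)
        out[g0:g1] = _per_bin(np.cumsum(diff[:-1]), grid, c)
    return out


def start_count_track(positions, grid: GenomeGrid) -> np.ndarray:
    """Number of read 5' starts at each grid position (no extension)."""
    cidx, start, _ = _positions_as_arrays(positions, grid)
    j = grid.to_global(cidx, start)
    return np.bincount(j, minlength=grid.M).astype(np.int64)


def trinarize_histone(counts: np.ndarray) -> np.ndarray:
    """Trinary enrichment codes from a histone count track.

    Cut points are the 90th and 99th nearest-rank percentiles of the track's
    own empirical distribution (zeros included): counts <= p90 code 0
    (non-enriched), counts <= p99 code 1 (moderately enriched), larger
    counts code 2 (enriched).
    """
    counts = np.asarray(counts)
    if len(counts) and counts.min() < 0:
        raise ValueError("histone counts must be non-negative")
    if len(counts) == 0:
        return np.zeros(0, dtype=np.uint8)
    p90, p99 = np.quantile(counts, [0.90, 0.99], method="inverted_cdf")
    if p90 == counts.max():
        log.warning("histone track is (near-)constant; all positions coded 0")
    codes = np.zeros(len(counts), dtype=np.uint8)
    codes[counts > p90] = 1
    codes[counts > p99] = 2
    return codes


@dataclass
class AggregatedPriorTable:
    """Genome positions grouped by (pooled DNase count, histone pattern).

    ``table`` has one row per group with columns

    x_key
        the DNase count, or the labels ``pooled_low`` / ``pooled_high``;
    histone_pattern
        '|'-joined trinary codes (empty string without histones);
    S_bar
        mean ChIP uni-read count over the member positions;
    size
        number of member positions (sums to M over all rows);
    x_rep
        representative DNase value for the spline (the group mean of x).
    """

    table: pd.DataFrame
    M: int
    n_histones: int = 0
    high_pool_threshold: float = np.inf

    def __post_init__(self):
        if int(self.table["size"].sum()) != self.M:
            raise ValueError("group sizes do not partition the grid")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, M=None, n_histones=None, high_pool_threshold=np.inf):
        tab = pd.read_csv(path, sep="\t", dtype={"x_key": str, "histone_pattern": str})
        tab["histone_pattern"] = tab["histone_pattern"].fillna("")
        if M is None:
            M = int(tab["size"].sum())
        if n_histones is None:
            pat = tab["histone_pattern"].iloc[0]
            n_histones = 0 if pat == "" else len(pat.split("|"))
        return cls(tab, M=M, n_histones=n_histones,
                   high_pool_threshold=high_pool_threshold)


def _high_pool_threshold(x: np.ndarray) -> float:
    """99.95th nearest-rank percentile of the positive DNase counts."""
    pos = x[x > 0]
    if len(pos) == 0:
        return np.inf
    return float(np.quantile(pos, 0.9995, method="inverted_cdf"))


def pool_keys(x: np.ndarray, high_threshold: float) -> np.ndarray:
    """Map raw DNase counts to string group keys with low/high pooling."""
    keys = x.astype(str).astype(object)
    keys[x <= 2] = POOL_LOW
    keys[x > high_threshold] = POOL_HIGH
    return keys


def aggregate_by_covariate(chip_uni_counts: np.ndarray,
                           cov: CovariateTrack) -> AggregatedPriorTable:
    """Group positions by (pooled DNase count, histone pattern) and average
    the ChIP uni-read count within each group."""
    chip = np.asarray(chip_uni_counts)
    if chip.shape != (cov.grid.M,):
        raise ValueError("ChIP count track length does not match the grid")
    x = np.asarray(cov.x)
    thr = _high_pool_threshold(x)
    keys = pool_keys(x, thr)
    frame = {"x_key": keys, "x": x.astype(float), "chip": chip.astype(float)}
    if cov.n_histones:
        pat = np.char.add(cov.histone_codes[0].astype(str), "")
        for h in cov.histone_codes[1:]:
            pat = np.char.add(np.char.add(pat, "|"), h.astype(str))
        frame["histone_pattern"] = pat
    else:
        frame["histone_pattern"] = ""
    df = pd.DataFrame(frame)
    agg = (
        df.groupby(["x_key", "histone_pattern"], sort=False)
        .agg(S_bar=("chip", "mean"), size=("chip", "size"), x_rep=("x", "mean"))
        .reset_index()
    )
    agg = agg.sort_values(["x_rep", "histone_pattern"], kind="stable").reset_index(drop=True)
    return AggregatedPriorTable(agg, M=cov.grid.M, n_histones=cov.n_histones,
                                high_pool_threshold=thr)


def write_bedgraph(values: np.ndarray, grid: GenomeGrid, path) -> None:
    """Write a per-position track as bedGraph (run-length collapsed)."""
    values = np.asarray(values)
    with open(path, "w") as out:
        for c, name in enumerate(grid.chrom_names):
            g0, g1 = grid.chrom_range(name)
            v = values[g0:g1]
            breaks = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(v)]])
            w = grid.bin_width
            for s, e in zip(starts, ends):
                out.write(f"{name}\t{s * w}\t{min(e * w, grid.chrom_lengths[c])}"
                          f"\t{v[s]:.10g}\n")


def read_bedgraph(path, grid: GenomeGrid, dtype=float) -> np.ndarray:
    """Read a bedGraph file onto a grid (positions absent from the file
    are zero)."""
    out = np.zeros(grid.M, dtype=dtype)
    tab = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "value"],
                      dtype={"chrom": str})
    for name, sub in tab.groupby("chrom", sort=False):
        g0, _ = grid.chrom_range(str(name))
        w = grid.bin_width
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            out[g0 + s // w: g0 + -(-e // w)] = v
    return out
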