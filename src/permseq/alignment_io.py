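"""Alignment input/output.

Reads "all alignments" files (SAM/BAM or Bowtie legacy text, i.e. aligner runs
that report every mapping position of every read) into a compact columnar
:class:`MultiAlignmentSet`, and writes the allocator's results back out as a
per-alignment probability table (TSV) and as BED6.

Coordinates are 0-based half-open throughout; SAM's 1-based starts are
converted on ingest.  Each alignment is stored by the 5' coordinate of the
read (for minus-strand alignments this is the *rightmost* aligned base), so
that a read's coordinate is the point its fragment extends from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "MultiAlignmentSet",
    "parse_alignments",
    "write_allocation_table",
    "read_allocation_table",
    "export_bed",
]

log = logging.getLogger(__name__)

STRAND_CHARS = np.array(["+", "-"])


@dataclass
class MultiAlignmentSet:
    """All candidate alignments for a set of reads, CSR-style.

    ``indptr`` delimits each read's alignments in the flat ``chrom_idx`` /
    ``start`` / ``strand`` arrays: read ``i`` owns slots
    ``indptr[i]:indptr[i+1]``.  ``chrom_idx`` indexes into ``chrom_names``;
    ``start`` is the 0-based 5' coordinate; ``strand`` is 0 for ``+`` and
    1 for ``-``.
    """

    read_ids: list
    read_lengths: np.ndarray
    indptr: np.ndarray
    chrom_names: list
    chrom_idx: np.ndarray
    start: np.ndarray
    strand: np.ndarray
    n_dropped_max_hits: int = 0

    def __post_init__(self):
        counts = np.diff(self.indptr)
        if len(counts) and counts.min() < 1:
            raise ValueError("every retained read needs at least one alignment")

    @property
    def N(self) -> int:
        """Number of retained reads."""
        return len(self.read_ids)

    @property
    def n_alignments(self) -> int:
        return int(self.indptr[-1]) if len(self.indptr) else 0

    @property
    def alignments_per_read(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def is_multi(self) -> np.ndarray:
        return self.alignments_per_read > 1

    @property
    def multi_fraction(self) -> float:
        return float(self.is_multi.mean()) if self.N else 0.0

    def read_of_alignment(self) -> np.ndarray:
        """Flat array mapping each alignment slot to its read index."""
        return np.repeat(np.arange(self.N), self.alignments_per_read)

    def candidate_indices(self, grid) -> np.ndarray:
        """Flat genome-grid index for every alignment slot (same CSR layout).

        The grid must contain every chromosome named in this set.
        """
        remap = np.array([grid.chrom_index(c) for c in self.chrom_names],
                         dtype=np.int64)
        return grid.to_global(remap[self.chrom_idx], self.start)

    @classmethod
    def from_records(cls, records, max_hits: int = 99):
        """Build from an iterable of (read_id, read_length, chrom, start, strand).

        Records of one read need not be adjacent; duplicates of the same
        (chrom, start, strand) within a read are collapsed.  Reads with more
        than ``max_hits`` distinct alignments are dropped and counted.
        """
        by_read: dict = {}
        lengths: dict = {}
        order: list = []
        for rid, rlen, chrom, start, strand in records:
            if rid not in by_read:
                by_read[rid] = set()
                lengths[rid] = int(rlen)
                order.append(rid)
            by_read[rid].add((chrom, int(start), strand))

        chrom_names: list = []
        chrom_lookup: dict = {}
        read_ids, read_lengths = [], []
        indptr = [0]
        cidx, starts, strands = [], [], []
        n_dropped = 0
        for rid in order:
            alns = sorted(by_read[rid])
            if not alns:
                log.warning("read %s has zero parsed alignments; skipped", rid)
                continue
            if len(alns) > max_hits:
                n_dropped += 1
                continue
            read_ids.append(rid)
            read_lengths.append(lengths[rid])
            for chrom, start, strand in alns:
                if chrom not in chrom_lookup:
                    chrom_lookup[chrom] = len(chrom_names)
                    chrom_names.append(chrom)
                cidx.append(chrom_lookup[chrom])
                starts.append(start)
                strands.append(0 if strand == "+" else 1)
            indptr.append(len(starts))
        if n_dropped:
            log.info("dropped %d reads exceeding max_hits=%d", n_dropped, max_hits)
        return cls(
            read_ids=read_ids,
            read_lengths=np.asarray(read_lengths, dtype=np.int64),
            indptr=np.asarray(indptr, dtype=np.int64),
            chrom_names=chrom_names,
            chrom_idx=np.asarray(cidx, dtype=np.int64),
            start=np.asarray(starts, dtype=np.int64),
            strand=np.asarray(strands, dtype=np.int8),
            n_dropped_max_hits=n_dropped,
        )


def _iter_sam(path):
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            rlen = rec.query_length or rec.infer_read_length() or 0
            if rec.is_reverse:
                coord = rec.reference_end - 1  # 5' end of a minus-strand read
                strand = "-"
            else:
                coord = rec.reference_start
                strand = "+"
            yield rec.query_name, rlen, rec.reference_name, coord, strand


def _iter_bowtie(path):
    # Legacy Bowtie text: name, strand, chrom, 0-based leftmost start, seq,
    # quals, #other-hits, mismatch descriptors (last two optional).
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{line_no}: expected >= 5 tab-separated Bowtie fields"
                )
            rid, strand, chrom, start, seq = fields[:5]
            if strand not in "+-":
                raise ValueError(f"{path}:{line_no}: bad strand {strand!r}")
            rlen = len(seq)
            left = int(start)
            coord = left + rlen - 1 if strand == "-" else left
            yield rid, rlen, chrom, coord, strand


def parse_alignments(path, max_hits: int = 99, fmt: str | None = None) -> MultiAlignmentSet:
    """Parse an all-alignments file into a :class:`MultiAlignmentSet`.

    Parameters
    ----------
    path : path-like
        SAM/BAM or Bowtie legacy text file.
    max_hits : int
        Reads with more than this many distinct alignments are dropped
        (mirrors aligning with ``-m 99``); the drop count is recorded on the
        returned object.
    fmt : {"sam", "bowtie", None}
        Force the input format; by default inferred from the extension
        (``.sam``/``.bam`` -> SAM, anything else -> Bowtie text).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    if fmt is None:
        fmt = "sam" if path.suffix.lower() in {".sam", ".bam"} else "bowtie"
    if fmt == "sam":
        records = _iter_sam(path)
    elif fmt == "bowtie":
        records = _iter_bowtie(path)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    aln = MultiAlignmentSet.from_records(records, max_hits=max_hits)
    log.info(
        "parsed %s: %d reads retained (%.1f%% multi), %d dropped at max_hits=%d",
        path, aln.N, 100 * aln.multi_fraction, aln.n_dropped_max_hits, max_hits,
    )
    return aln


def write_bowtie(aln: MultiAlignmentSet, path) -> None:
    """Write a set back out as Bowtie legacy text (placeholder sequence).

    Intended for synthetic instances: the sequence column carries ``N``s of
    the read length so the file round-trips through
    :func:`parse_alignments`.
    """
    read_idx = aln.read_of_alignment()
    with open(path, "w") as out:
        for k in range(aln.n_alignments):
            i = read_idx[k]
            rlen = int(aln.read_lengths[i])
            c5 = int(aln.start[k])
            left = c5 if aln.strand[k] == 0 else c5 - rlen + 1
            out.write(
                f"{aln.read_ids[i]}\t{STRAND_CHARS[aln.strand[k]]}\t"
                f"{aln.chrom_names[aln.chrom_idx[k]]}\t{left}\t"
                f"{'N' * rlen}\t{'I' * rlen}\t0\t\n"
            )


def _flat_probs(aln: MultiAlignmentSet, state) -> np.ndarray:
    z = state.z if hasattr(state, "z") else np.asarray(state, dtype=float)
    if z.shape != (aln.n_alignments,):
        raise ValueError(
            f"allocation state covers {z.shape} probabilities but the alignment "
            f"set has {aln.n_alignments} candidate alignments"
        )
    if aln.N:
        sums = np.add.reduceat(z, aln.indptr[:-1])
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("per-read allocation probabilities do not sum to 1")
    return z


def write_allocation_table(aln: MultiAlignmentSet, state, path) -> None:
    """Write one TSV row per (read, candidate alignment) with its probability.

    Columns: read_id, chrom, start, strand, probability.  Probabilities are
    printed with 10 significant digits; per-read rows sum to 1.
    """
    z = _flat_probs(aln, state)
    read_idx = aln.read_of_alignment()
    with open(path, "w") as out:
        out.write("read_id\tchrom\tstart\tstrand\tprobability\n")
        for k in range(aln.n_alignments):
            out.write(
                f"{aln.read_ids[read_idx[k]]}\t{aln.chrom_names[aln.chrom_idx[k]]}\t"
                f"{aln.start[k]}\t{STRAND_CHARS[aln.strand[k]]}\t{z[k]:.10g}\n"
            )


def read_allocation_table(path) -> pd.DataFrame:
    """Read a probability table written by :func:`write_allocation_table`."""
    return pd.read_csv(
        path, sep="\t",
        dtype={"read_id": str, "chrom": str, "start": np.int64,
               "strand": str, "probability": float},
    )


def export_bed(aln: MultiAlignmentSet, state, path,
               threshold: float = 0.5, mode: str = "strict",
               seed: int = 0, inclusive: bool = False) -> int:
    """Export allocated reads as BED6; returns the number of lines written.

    mode "strict"
        A multi-read is written at its best position only if that position's
        probability strictly exceeds ``threshold`` (or ``>=`` with
        ``inclusive=True``); otherwise the read is discarded.  Uni-reads are
        always written.
    mode "argmax"
        Every read is written at its highest-probability position; exact ties
        are broken by a random choice seeded with ``seed``.

    The BED interval spans the read's aligned bases (0-based half-open);
    column 5 holds ``round(1000 * probability)``.
    """
    if mode not in {"strict", "argmax"}:
        raise ValueError(f"invalid export mode {mode!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    z = _flat_probs(aln, state)
    rng = np.random.default_rng(seed)
    n_out = 0
    with open(path, "w") as out:
        for i in range(aln.N):
            lo, hi = aln.indptr[i], aln.indptr[i + 1]
            zi = z[lo:hi]
            best = zi.max()
            if mode == "strict" and hi - lo > 1:
                keep = best >= threshold if inclusive else best > threshold
                if not keep:
                    continue
                k = lo + int(np.argmax(zi))
            else:  # argmax (and uni-reads in either mode)
                ties = np.flatnonzero(zi >= best - 1e-12)
                k = lo + int(ties[0] if len(ties) == 1 else rng.choice(ties))
            rlen = int(aln.read_lengths[i])
            c5 = int(aln.start[k])
            if aln.strand[k] == 0:
                b_start, b_end = c5, c5 + rlen
            else:
                b_start, b_end = max(0, c5 - rlen + 1), c5 + 1
            out.write(
                f"{aln.chrom_names[aln.chrom_idx[k]]}\t{b_start}\t{b_end}\t"
                f"{aln.read_ids[i]}\t{int(round(1000 * z[k]))}\t"
                f"{STRAND_CHARS[aln.strand[k]]}\n"
            )
            n_out += 1
    return n_out
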