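"""Expectation-Maximization-Smoothing (EMS) multi-read allocation.

Reads are modelled as draws from a multinomial density ``pi`` over genome
positions, with a Dirichlet prior whose pseudo-counts ``S_j`` come from the
covariate model (:mod:`permseq.prior`).  Iterating

* E-step:  ``z_ij = pi_j / sum_{j' in R_i} pi_j'`` for each read's candidate
  set ``R_i``;
* M-step:  ``mu_j = (sum_i z_ij + S_j) / (N + sum_j S_j)``;
* S-step:  ``pi`` = per-chromosome moving average of ``mu`` with half-window
  ``w`` (windows truncated at chromosome ends), renormalized to the simplex,

yields maximum-a-posteriori responsibilities ``z`` for every candidate
alignment.  With ``S_j == 0`` the algorithm reduces to the uniform-prior
baseline (CSEM); see :func:`csem_allocate`.

The density is genome-sized but reads are few, so ``pi`` is materialized
only on a buffer of merged intervals spanning every candidate position
+/- 2w; positions outside carry their prior-only mass ``S_j / (N + S_total)``,
accounted for analytically through the prior's exact total mass.  Smoothed
values are computed where they can differ from that baseline (candidates
+/- w); elsewhere the unsmoothed baseline stands in, which is exact at
``w = 0`` and never affects ``z`` (within-read ratios cancel the global
normalizer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import MultiAlignmentSet
from .grid import GenomeGrid
from .prior import UniformPriors

__all__ = ["AllocationState", "ems_allocate", "csem_allocate", "smooth_density"]

log = logging.getLogger(__name__)

DEFAULT_LIBRARY_SIZE = 200  # bp; 2w + 1 is set to this at 1-bp bins


def default_half_window(grid: GenomeGrid,
                        library_size: int = DEFAULT_LIBRARY_SIZE) -> int:
    """Half smoothing window so that 2w+1 spans the average library size."""
    return max(0, library_size // (2 * grid.bin_width))


@dataclass
class AllocationState:
    """Converged (or iteration-capped) allocator state.

    ``z`` is flat in the CSR layout of the originating
    :class:`~permseq.alignment_io.MultiAlignmentSet`; ``pi_active`` holds the
    density on ``active_idx`` (sorted flat grid indices) with
    ``remainder_mass`` spread over the rest of the genome as prior-only
    mass.
    """

    z: np.ndarray
    pi_active: np.ndarray
    active_idx: np.ndarray
    remainder_mass: float
    w: int
    n_iter: int
    converged: bool
    max_dz_history: list = field(default_factory=list)
    posterior_history: list = field(default_factory=list)
    max_simplex_error: float = 0.0  # worst |sum(pi) - 1| over all S-steps

    @property
    def pi_total(self) -> float:
        return float(self.pi_active.sum() + self.remainder_mass)

    def pi_at(self, idx) -> np.ndarray:
        """Density at given flat indices (0 off the active set)."""
        idx = np.asarray(idx, dtype=np.int64)
        pos = np.searchsorted(self.active_idx, idx)
        pos = np.clip(pos, 0, len(self.active_idx) - 1)
        hit = self.active_idx[pos] == idx
        out = np.zeros(len(idx))
        out[hit] = self.pi_active[pos[hit]]
        return out


def smooth_density(mu: np.ndarray, w: int, grid: GenomeGrid) -> np.ndarray:
    """Moving-average smooth of a dense per-position track.

    Each position is replaced by the mean of the surrounding ``2w+1``
    positions of its own chromosome, with windows truncated (and the divisor
    shrunk accordingly) at chromosome ends; the result is renormalized to
    sum to one.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (grid.M,):
        raise ValueError("density length does not match the grid")
    if w < 0:
        raise ValueError("half-window must be >= 0")
    if mu.min() < 0:
        raise ValueError("density values must be non-negative")
    out = np.empty_like(mu)
    for name in grid.chrom_names:
        g0, g1 = grid.chrom_range(name)
        seg = mu[g0:g1]
        n = len(seg)
        if w == 0 or n == 1:
            out[g0:g1] = seg
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        j = np.arange(n)
        lo = np.maximum(j - w, 0)
        hi = np.minimum(j + w, n - 1)
        out[g0:g1] = (cum[hi + 1] - cum[lo]) / (hi - lo + 1)
    total = out.sum()
    if total <= 0:
        raise ValueError("cannot smooth an all-zero density")
    return out / total


class _ActiveBuffer:
    """Merged per-chromosome intervals spanning candidates +/- 2w."""

    def __init__(self, cand: np.ndarray, grid: GenomeGrid, w: int):
        uniq = np.unique(cand)
        segs = []  # (start, stop) flat half-open, per chromosome
        for name in grid.chrom_names:
            g0, g1 = grid.chrom_range(name)
            cj = uniq[(uniq >= g0) & (uniq < g1)]
            if len(cj) == 0:
                continue
            lo = np.maximum(cj - 2 * w, g0)
            hi = np.minimum(cj + 2 * w + 1, g1)
            s, e = lo[0], hi[0]
            for a, b in zip(lo[1:], hi[1:]):
                if a <= e:
                    e = max(e, b)
                else:
                    segs.append((s, e))
                    s, e = a, b
            segs.append((s, e))
        self.seg_start = np.array([s for s, _ in segs], dtype=np.int64)
        self.seg_stop = np.array([e for _, e in segs], dtype=np.int64)
        lens = self.seg_stop - self.seg_start
        self.seg_off = np.concatenate([[0], np.cumsum(lens)])
        self.size = int(self.seg_off[-1])
        self.global_idx = np.concatenate(
            [np.arange(s, e) for s, e in segs]) if segs else np.zeros(0, np.int64)
        # chromosome bounds of each segment (for window truncation)
        cidx, _ = grid.to_local(self.seg_start) if len(segs) else (np.zeros(0, np.int64),) * 2
        self.seg_chrom_lo = grid.offsets[cidx]
        self.seg_chrom_hi = grid.offsets[cidx + 1] if len(segs) else np.zeros(0, np.int64)
        # smoothing targets: candidates +/- w (values can differ from baseline)
        mark = np.zeros(self.size + 1, dtype=np.int8)
        cb = self.to_buffer(uniq)
        lo = np.maximum(cb - w, self._seg_lo_of(cb))
        hi = np.minimum(cb + w + 1, self._seg_hi_of(cb))
        np.add.at(mark, lo, 1)
        np.add.at(mark, hi, -1)
        self.smooth_mask = np.cumsum(mark[:-1]) > 0
        # precompute window bounds for the targets; they never change
        # across iterations
        self._tgt = np.flatnonzero(self.smooth_mask)
        if w > 0 and len(self._tgt):
            seg = self._seg_of(self._tgt)
            g = self.global_idx[self._tgt]
            lo_g = np.maximum(g - w, self.seg_chrom_lo[seg])
            hi_g = np.minimum(g + w, self.seg_chrom_hi[seg] - 1)
            base = self.seg_off[seg] - self.seg_start[seg]
            self._win_lo = lo_g + base
            self._win_hi = hi_g + base
            self._win_len = (hi_g - lo_g + 1).astype(float)

    def _seg_of(self, buf_pos):
        return np.searchsorted(self.seg_off, buf_pos, side="right") - 1

    def _seg_lo_of(self, buf_pos):
        return self.seg_off[self._seg_of(buf_pos)]

    def _seg_hi_of(self, buf_pos):
        return self.seg_off[self._seg_of(buf_pos) + 1]

    def to_buffer(self, j: np.ndarray) -> np.ndarray:
        """Flat grid indices -> buffer offsets (must lie in the buffer)."""
        k = np.searchsorted(self.seg_start, j, side="right") - 1
        return self.seg_off[k] + (j - self.seg_start[k])

    def smooth(self, mu_buf: np.ndarray, w: int) -> np.ndarray:
        """Truncated-mean smoothing at the marked target positions; other
        buffer positions keep their (prior-only) value."""
        if w == 0 or len(self._tgt) == 0:
            return mu_buf.copy()
        out = mu_buf.copy()
        cum = np.concatenate([[0.0], np.cumsum(mu_buf)])
        # windows [lo, hi] lie inside the owning segment by construction
        out[self._tgt] = (cum[self._win_hi + 1] - cum[self._win_lo]) / self._win_len
        return out


def _active_posterior(pi_cand_per_read_sum, S_buf, pi_buf):
    """Variable part of the Dirichlet-multinomial log posterior
    (position terms restricted to the buffer)."""
    read_term = float(np.sum(np.log(np.maximum(pi_cand_per_read_sum, 1e-300))))
    mask = S_buf > 0
    prior_term = float(np.sum(S_buf[mask] * np.log(np.maximum(pi_buf[mask], 1e-300))))
    return read_term + prior_term


def ems_allocate(aln: MultiAlignmentSet, priors, grid: GenomeGrid,
                 w: int | None = None, tol: float = 1e-6,
                 max_iter: int = 500,
                 track_posterior: bool = False) -> AllocationState:
    """Run the EMS iteration to convergence of the responsibilities.

    Parameters
    ----------
    aln : MultiAlignmentSet
        All candidate alignments; uni-reads contribute fixed counts.
    priors : object with ``values(idx)`` and ``total_mass``
        Per-position pseudo-counts S_j (e.g.
        :class:`~permseq.prior.PositionPriors`,
        :class:`~permseq.prior.ArrayPriors` or
        :class:`~permseq.prior.UniformPriors`).
    w : int, optional
        Half smoothing window in grid positions; defaults to half the
        average library size (2w+1 = 200 bp at 1-bp bins).
    tol : float
        Convergence threshold on the largest change of any responsibility
        between successive E-steps.
    max_iter : int
        Iteration cap.
    track_posterior : bool
        Record the variable part of the Dirichlet-multinomial log posterior
        after every S-step (at w = 0 the omitted off-buffer terms are
        constant, so recorded differences equal full-posterior differences).

    Returns
    -------
    AllocationState
        Final responsibilities, sparse density and iteration diagnostics.
    """
    if w is None:
        w = default_half_window(grid)
    if w < 0:
        raise ValueError("half-window must be >= 0")
    N = aln.N
    if N == 0:
        return AllocationState(z=np.zeros(0), pi_active=np.zeros(0),
                               active_idx=np.zeros(0, np.int64),
                               remainder_mass=1.0, w=w, n_iter=0, converged=True)

    cand = aln.candidate_indices(grid)
    buf = _ActiveBuffer(cand, grid, w)
    cand_buf = buf.to_buffer(cand)
    S_buf = np.asarray(priors.values(buf.global_idx), dtype=float)
    S_total = float(priors.total_mass)
    S_outside = max(S_total - float(S_buf.sum()), 0.0)
    denom = N + S_total

    counts_per_read = aln.alignments_per_read
    read_of = aln.read_of_alignment()
    multi_mask = np.repeat(counts_per_read > 1, counts_per_read)
    uni_buf_counts = np.bincount(cand_buf[~multi_mask], minlength=buf.size).astype(float)
    m_cand = cand_buf[multi_mask]
    m_read = read_of[multi_mask]
    # compact multi-read ids for per-read reductions
    m_read_c = np.searchsorted(np.unique(m_read), m_read)
    n_multi = m_read_c.max() + 1 if len(m_read_c) else 0

    z = np.ones(aln.n_alignments)

    def e_step(pi_buf):
        """Responsibilities from the current density; returns (z_multi, per-read
        candidate-density sums for every read)."""
        pz = pi_buf[m_cand]
        sums = np.bincount(m_read_c, weights=pz, minlength=n_multi)
        bad = sums <= 0
        if bad.any():
            log.warning("%d multi-reads have zero density at every candidate; "
                        "uniform responsibilities assigned", int(bad.sum()))
            bad_rows = bad[m_read_c]
            pz = pz.copy()
            pz[bad_rows] = 1.0
            sums = np.bincount(m_read_c, weights=pz, minlength=n_multi)
        return pz / sums[m_read_c]

    def all_read_pi_sums(pi_buf):
        return np.bincount(read_of, weights=pi_buf[cand_buf], minlength=N)

    def density_from_counts(mult_counts):
        """(mu, pi, remainder) from buffer-scattered read mass."""
        mu_buf = (uni_buf_counts + mult_counts + S_buf) / denom
        sm = buf.smooth(mu_buf, w)
        outside = S_outside / denom
        total = float(sm.sum()) + outside
        return mu_buf, sm / total, outside / total

    # initialization: proportional to uni-read counts + prior mass + 1/M
    c0 = 1.0 / grid.M
    init = uni_buf_counts + S_buf + c0
    init_total = float(init.sum()) + S_outside + (grid.M - buf.size) * c0
    pi_buf = init / init_total
    remainder = (S_outside + (grid.M - buf.size) * c0) / init_total

    z_multi = e_step(pi_buf) if len(m_cand) else np.zeros(0)
    max_dz_history: list = []
    posterior_history: list = []
    converged = False
    max_simplex_error = 0.0
    t = 0
    for t in range(1, max_iter + 1):
        mult_counts = np.bincount(m_cand, weights=z_multi, minlength=buf.size) \
            if len(m_cand) else np.zeros(buf.size)
        _, pi_buf, remainder = density_from_counts(mult_counts)
        max_simplex_error = max(max_simplex_error,
                                abs(float(pi_buf.sum()) + remainder - 1.0))
        if track_posterior:
            posterior_history.append(_active_posterior(
                all_read_pi_sums(pi_buf), S_buf, pi_buf))
        if len(m_cand):
            z_new = e_step(pi_buf)
            dz = float(np.max(np.abs(z_new - z_multi))) if len(z_new) else 0.0
            z_multi = z_new
        else:
            dz = 0.0
        max_dz_history.append(dz)
        if dz < tol:
            converged = True
            break
    if not converged:
        log.warning("EMS reached max_iter=%d (last max|dz|=%.3g)", max_iter,
                    max_dz_history[-1] if max_dz_history else float("nan"))

    z[multi_mask] = z_multi
    return AllocationState(
        z=z, pi_active=pi_buf, active_idx=buf.global_idx,
        remainder_mass=remainder, w=w, n_iter=t, converged=converged,
        max_dz_history=max_dz_history, posterior_history=posterior_history,
        max_simplex_error=max_simplex_error,
    )


def csem_allocate(aln: MultiAlignmentSet, grid: GenomeGrid,
                  w: int | None = None, tol: float = 1e-6,
                  max_iter: int = 500) -> AllocationState:
    """Uniform-prior baseline: EMS with S_j = 0 everywhere (gamma_j = 1).

    This is the no-prior special case of :func:`ems_allocate`, allocating
    multi-reads purely from local uni-read evidence, and serves as the
    comparison baseline for the informative prior.
    """
    return ems_allocate(aln, UniformPriors(), grid, w=w, tol=tol,
                        max_iter=max_iter)
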