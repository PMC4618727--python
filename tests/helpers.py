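"""Shared test utilities: instance builders and an independent dense
reference implementation of the EMS iteration (plain loops over the full
position grid, no sparsity), used as the oracle for the production engine."""

from __future__ import annotations

import numpy as np

from permseq import GenomeGrid, MultiAlignmentSet


def build_aln(cands_per_read, chrom="chr1", read_len=36, strand="+"):
    """MultiAlignmentSet from a list of per-read candidate position lists."""
    recs = []
    for i, cl in enumerate(cands_per_read):
        for p in cl:
            recs.append((f"r{i}", read_len, chrom, int(p), strand))
    return MultiAlignmentSet.from_records(recs)


def dense_log_posterior(cands_per_read, S, pi):
    """Dirichlet-multinomial log posterior (up to an additive constant):
    sum_i log sum_{j in R_i} pi_j  +  sum_j S_j log pi_j."""
    val = 0.0
    for cl in cands_per_read:
        val += np.log(sum(pi[p] for p in cl))
    for j in range(len(pi)):
        if S[j] > 0:
            val += S[j] * np.log(max(pi[j], 1e-300))
    return val


def dense_ems_fixed_point(cands_per_read, S, M, w=0, tol=1e-13,
                          max_iter=100_000):
    """Brute-force EMS fixed point on a dense length-M density.

    Implements the E/M/S updates with explicit loops and a full dense
    density over one chromosome; initialization matches the production
    engine's documented rule (uni-read counts + S + 1/M, normalized).

    Returns (z, pi, posterior_history) where z is a list of per-read
    responsibility arrays and the history records the dense log posterior
    after every S-step.
    """
    N = len(cands_per_read)
    S = np.asarray(S, dtype=float)
    uni = np.zeros(M)
    for cl in cands_per_read:
        if len(cl) == 1:
            uni[cl[0]] += 1.0
    denom = N + S.sum()
    pi = uni + S + 1.0 / M
    pi = pi / pi.sum()

    def e_step(pi):
        out = []
        for cl in cands_per_read:
            vals = np.array([pi[p] for p in cl])
            out.append(vals / vals.sum())
        return out

    z = e_step(pi)
    history = []
    for _ in range(max_iter):
        mu = S.copy()
        for cl, zi in zip(cands_per_read, z):
            for p, v in zip(cl, zi):
                mu[p] += v
        mu = mu / denom
        if w > 0:
            sm = np.empty(M)
            for j in range(M):
                lo, hi = max(0, j - w), min(M - 1, j + w)
                sm[j] = mu[lo:hi + 1].mean()
        else:
            sm = mu
        pi = sm / sm.sum()
        history.append(dense_log_posterior(cands_per_read, S, pi))
        z_new = e_step(pi)
        dz = max((np.abs(a - b).max() for a, b in zip(z_new, z)), default=0.0)
        z = z_new
        if dz < tol:
            break
    return z, pi, history


def random_small_instance(rng, max_reads=10, max_pos=8):
    """Random instance for oracle comparisons: a handful of reads with 1-3
    candidates each on a tiny genome, and random prior pseudo-counts."""
    M = int(rng.integers(2, max_pos + 1))
    N = int(rng.integers(2, max_reads + 1))
    cands = []
    for _ in range(N):
        k = int(rng.integers(1, min(3, M) + 1))
        cands.append(sorted(rng.choice(M, size=k, replace=False).tolist()))
    S = rng.uniform(0.0, 3.0, M)
    return M, cands, S


def run_engine(cands_per_read, S, M, w=0, tol=1e-12, max_iter=100_000,
               track_posterior=False):
    """Run the production engine on a helper-style instance; returns
    (state, aln, grid) with z in the same per-read order as the input."""
    from permseq import ems_allocate
    from permseq.prior import ArrayPriors

    aln = build_aln(cands_per_read)
    grid = GenomeGrid(("chr1",), (M,))
    state = ems_allocate(aln, ArrayPriors(S), grid, w=w, tol=tol,
                         max_iter=max_iter, track_posterior=track_posterior)
    return state, aln, grid
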