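"""Synthetic repeat-genome benchmark for multi-read allocation.

The generator builds a toy genome containing pairs of duplicated segments
(the stand-in for segmental duplications), a latent read-generating density
``pi*``, and a DNase accessibility track linked to the density through the
same log-linear model the prior assumes:

1. a DNase rate track is laid down (background rate everywhere, an elevated
   rate inside binding-event windows, some of which sit inside *source*
   duplication copies while the homologous copy stays at background);
2. per-position DNase counts are Poisson draws around that rate;
3. the read density is ``pi*_j ~ exp(beta0 + beta1 * x_j)`` so the assumed
   mean ChIP-versus-DNase structure holds by construction;
4. reads are drawn i.i.d. from ``pi*``; any read whose 5' start falls in a
   duplicated interval deterministically acquires the homologous coordinate
   as a second candidate alignment (the confusion rule), while its true
   origin is recorded.

Scoring compares an allocator's responsibilities with the recorded truth:
proportion of multi-reads assigned to their true origin (argmax with seeded
random tie-breaking), stratified by whether the top allocation probability
reaches 0.5, plus the per-read log loss.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .alignment_io import MultiAlignmentSet
from .allocator import AllocationState, csem_allocate, ems_allocate
from .covariates import CovariateTrack, aggregate_by_covariate, start_count_track
from .grid import GenomeGrid
from .prior import compute_position_priors, fit_log_linear_prior

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_instance",
    "score_allocation",
    "compare_methods",
    "allocate_with_fitted_prior",
    "random_allocation",
]

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic instance.

    Defaults describe a 1-Mb single-chromosome genome at medium sequencing
    depth (1e5 reads), four 5-kb duplication pairs, and 200-bp binding
    events whose accessibility (Poisson mean ``dnase_event``) stands out
    against a sparse background (``dnase_background``).  ``beta0``/``beta1``
    are the log-linear link between DNase counts and the read density.
    """

    chrom_name: str = "chr1"
    chrom_length: int = 1_000_000
    n_duplication_pairs: int = 10
    duplication_length: int = 1_000
    n_events: int = 25
    event_width: int = 200
    n_reads: int = 100_000
    read_length: int = 36
    fragment_length: int = 200
    beta0: float = 0.0
    beta1: float = 0.2
    dnase_background: float = 0.2
    dnase_event: float = 20.0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Ground truth of one generated instance."""

    pi_star: np.ndarray
    true_idx: np.ndarray            # flat grid index of each read's origin
    duplication_pairs: list         # (source_start, copy_start, length)
    seed: int
    config: SimulationConfig
    event_starts: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))


def _place_duplications(cfg: SimulationConfig):
    """Source/copy intervals in disjoint equal-width blocks (no overlap)."""
    n_iv = 2 * cfg.n_duplication_pairs
    if n_iv == 0:
        return []
    block = cfg.chrom_length // n_iv
    if cfg.duplication_length >= block:
        raise ValueError("duplication intervals would overlap: "
                         "duplication_length too large for the genome")
    pairs = []
    for k in range(cfg.n_duplication_pairs):
        margin = (block - cfg.duplication_length) // 2
        src = 2 * k * block + margin
        cpy = (2 * k + 1) * block + margin
        pairs.append((src, cpy, cfg.duplication_length))
    return pairs


def generate_instance(cfg: SimulationConfig, seed: int):
    """Generate one seeded instance.

    Returns ``(grid, aln, cov, truth)``: the genome grid, the candidate
    alignments (with duplication-induced multi-reads), the DNase covariate
    track, and the recorded truth.
    """
    if cfg.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    grid = GenomeGrid((cfg.chrom_name,), (cfg.chrom_length,))
    L = cfg.chrom_length
    pairs = _place_duplications(cfg)

    # DNase rate: background everywhere, elevated in event windows; one
    # event centered in every *source* duplication copy, the rest spread
    # over non-duplicated ground.
    lam = np.full(L, cfg.dnase_background)
    event_starts = []
    for src, _, dlen in pairs[: cfg.n_events]:
        event_starts.append(src + (dlen - cfg.event_width) // 2)
    n_rest = max(0, cfg.n_events - len(event_starts))
    if n_rest:
        in_dup = np.zeros(L, dtype=bool)
        for src, cpy, dlen in pairs:
            in_dup[src:src + dlen] = True
            in_dup[cpy:cpy + dlen] = True
        free = np.flatnonzero(~in_dup[: L - cfg.event_width])
        # keep events clear of duplications and of each other
        chosen = rng.choice(free[:: cfg.event_width * 2], size=n_rest, replace=False)
        event_starts.extend(int(s) for s in chosen)
    # accessibility peaks are triangular (summit at the event centre) with
    # log-uniform summit heights, so DNase rates sweep the whole range
    # between background and summit as real hypersensitive sites do
    summits = cfg.dnase_event * np.exp(
        rng.uniform(np.log(1 / 2), np.log(3 / 2), size=len(event_starts)))
    half = cfg.event_width / 2
    shape = 1.0 - np.abs(np.arange(cfg.event_width) - half) / half
    for s, lam_e in zip(event_starts, summits):
        lam[s:s + cfg.event_width] = cfg.dnase_background + \
            (lam_e - cfg.dnase_background) * shape

    x = rng.poisson(lam).astype(np.int64)

    # density linked to accessibility through the assumed log-linear model
    weights = np.exp(cfg.beta0 + cfg.beta1 * x)
    pi_star = weights / weights.sum()

    # read origins and strands
    cum = np.cumsum(pi_star)
    origins = np.searchsorted(cum, rng.random(cfg.n_reads), side="right")
    origins = np.minimum(origins, L - 1)
    strands = rng.integers(0, 2, size=cfg.n_reads).astype(np.int8)

    # confusion rule: origins inside a duplicated interval gain the
    # homologous coordinate as a second candidate
    homolog = np.full(L, -1, dtype=np.int64)
    for src, cpy, dlen in pairs:
        off = np.arange(dlen)
        homolog[src + off] = cpy + off
        homolog[cpy + off] = src + off
    mates = homolog[origins]
    is_multi = mates >= 0

    n_cand = 1 + is_multi.astype(np.int64)
    indptr = np.concatenate([[0], np.cumsum(n_cand)])
    starts = np.empty(int(indptr[-1]), dtype=np.int64)
    strand_flat = np.empty(int(indptr[-1]), dtype=np.int8)
    first = indptr[:-1]
    # candidates listed in coordinate order
    lo = np.where(is_multi, np.minimum(origins, mates), origins)
    hi = np.where(is_multi, np.maximum(origins, mates), origins)
    starts[first] = lo
    strand_flat[first] = strands
    second = first[is_multi] + 1
    starts[second] = hi[is_multi]
    strand_flat[second] = strands[is_multi]

    aln = MultiAlignmentSet(
        read_ids=[f"read_{i:07d}" for i in range(cfg.n_reads)],
        read_lengths=np.full(cfg.n_reads, cfg.read_length, dtype=np.int64),
        indptr=indptr,
        chrom_names=[cfg.chrom_name],
        chrom_idx=np.zeros(int(indptr[-1]), dtype=np.int64),
        start=starts,
        strand=strand_flat,
    )
    cov = CovariateTrack(grid, x, fragment_length=cfg.fragment_length)
    truth = SimulationTruth(pi_star=pi_star, true_idx=origins.astype(np.int64),
                            duplication_pairs=pairs, seed=seed, config=cfg,
                            event_starts=np.asarray(sorted(event_starts), np.int64))
    return grid, aln, cov, truth


def write_truth_tsv(truth: SimulationTruth, aln: MultiAlignmentSet, path) -> None:
    pd.DataFrame({
        "read_id": aln.read_ids,
        "true_chrom": truth.config.chrom_name,
        "true_start": truth.true_idx,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_allocation(truth: SimulationTruth, state: AllocationState,
                     aln: MultiAlignmentSet, grid: GenomeGrid,
                     mode: str = "argmax+random-tie", seed: int = 0,
                     threshold: float = 0.5) -> dict:
    """Correct-allocation metrics of a state against recorded truth.

    Multi-reads are assigned to their top-probability candidate (mode
    ``argmax+random-tie``; exact ties broken by a seeded draw) or, in mode
    ``threshold``, only when the top probability strictly exceeds
    ``threshold``.  Returns overall and >=0.5-stratified accuracies over
    multi-reads, the all-read accuracy (uni-reads count as correct), and
    the mean log loss ``-log z_{i, L_i}``.
    """
    if mode not in {"argmax+random-tie", "threshold"}:
        raise ValueError(f"unknown scoring mode {mode!r}")
    if len(truth.true_idx) != aln.N:
        raise ValueError("truth and alignment set cover different reads")
    if state.z.shape != (aln.n_alignments,):
        raise ValueError("state does not match the alignment set")
    rng = np.random.default_rng(seed)
    cand = aln.candidate_indices(grid)
    counts = aln.alignments_per_read
    indptr = aln.indptr

    multi = np.flatnonzero(counts > 1)
    n_multi = len(multi)
    correct = np.zeros(n_multi, dtype=bool)
    assigned = np.ones(n_multi, dtype=bool)
    zmax = np.zeros(n_multi)
    ztrue = np.zeros(n_multi)
    for k, i in enumerate(multi):
        lo, hi = indptr[i], indptr[i + 1]
        zi = state.z[lo:hi]
        best = zi.max()
        zmax[k] = best
        truth_slots = np.flatnonzero(cand[lo:hi] == truth.true_idx[i])
        ztrue[k] = zi[truth_slots].sum() if len(truth_slots) else 0.0
        if mode == "threshold" and not best > threshold:
            assigned[k] = False
            continue
        ties = np.flatnonzero(zi >= best - 1e-12)
        pick = int(ties[0] if len(ties) == 1 else rng.choice(ties))
        correct[k] = cand[lo + pick] == truth.true_idx[i]

    def _prop(mask):
        return float(correct[mask].mean()) if mask.any() else float("nan")

    strat_hi = assigned & (zmax >= 0.5)
    strat_lo = assigned & (zmax < 0.5)
    n_assigned = int(assigned.sum())
    return {
        "n_reads": aln.N,
        "n_multi": n_multi,
        "n_assigned_multi": n_assigned,
        "accuracy_multi": _prop(assigned),
        "accuracy_multi_high_conf": _prop(strat_hi),
        "accuracy_multi_low_conf": _prop(strat_lo),
        "n_multi_high_conf": int(strat_hi.sum()),
        "accuracy_all": float((correct.sum() + (aln.N - n_multi)) / aln.N)
        if aln.N else float("nan"),
        "mean_log_loss": float(np.mean(-np.log(np.maximum(ztrue, 1e-300))))
        if n_multi else float("nan"),
    }


# ---------------------------------------------------------------------------
# allocation strategies for comparisons
# ---------------------------------------------------------------------------

def allocate_with_fitted_prior(aln: MultiAlignmentSet, cov: CovariateTrack,
                               grid: GenomeGrid, w: int | None = None,
                               tol: float = 1e-6, max_iter: int = 500):
    """Full informative-prior chain on one instance: aggregate the uni-read
    counts by DNase value, fit the spline prior, and run EMS with it."""
    uni = ~np.repeat(aln.is_multi, aln.alignments_per_read)
    uni_positions = pd.DataFrame({
        "chrom": np.array(aln.chrom_names, dtype=object)[aln.chrom_idx[uni]],
        "start": aln.start[uni],
        "strand": np.where(aln.strand[uni] == 0, "+", "-"),
    })
    chip_counts = start_count_track(uni_positions, grid)
    table = aggregate_by_covariate(chip_counts, cov)
    model = fit_log_linear_prior(table)
    priors = compute_position_priors(model, cov, grid)
    state = ems_allocate(aln, priors, grid, w=w, tol=tol, max_iter=max_iter)
    return state, model, priors


def random_allocation(aln: MultiAlignmentSet, seed: int = 0) -> AllocationState:
    """Assign each multi-read uniformly at random to one candidate."""
    rng = np.random.default_rng(seed)
    z = np.zeros(aln.n_alignments)
    for i in range(aln.N):
        lo, hi = aln.indptr[i], aln.indptr[i + 1]
        z[lo + rng.integers(hi - lo)] = 1.0
    return AllocationState(z=z, pi_active=np.zeros(0),
                           active_idx=np.zeros(0, np.int64), remainder_mass=1.0,
                           w=0, n_iter=0, converged=True)


def score_allocation_table(table: pd.DataFrame, truth: pd.DataFrame,
                           seed: int = 0) -> dict:
    """Score a written allocation table against a truth table.

    ``table`` has columns read_id/chrom/start/probability (one row per
    candidate), ``truth`` has read_id/true_chrom/true_start.  Multi-reads
    are assigned by argmax with seeded random tie-breaking.
    """
    rng = np.random.default_rng(seed)
    tru = truth.set_index("read_id")
    missing = ~table["read_id"].isin(tru.index)
    if missing.any():
        raise ValueError("allocation table contains reads absent from truth")
    n_multi = 0
    n_correct = 0
    for rid, sub in table.groupby("read_id", sort=False):
        if len(sub) < 2:
            continue
        n_multi += 1
        p = sub["probability"].to_numpy()
        ties = np.flatnonzero(p >= p.max() - 1e-12)
        k = int(ties[0] if len(ties) == 1 else rng.choice(ties))
        row = sub.iloc[k]
        t = tru.loc[rid]
        if row["chrom"] == t["true_chrom"] and int(row["start"]) == int(t["true_start"]):
            n_correct += 1
    return {"n_multi": n_multi,
            "accuracy_multi": n_correct / n_multi if n_multi else float("nan")}


_METHODS = {"informative", "uniform", "random"}


def _run_method(name, aln, cov, grid, seed, w=None):
    if name == "informative":
        state, *_ = allocate_with_fitted_prior(aln, cov, grid, w=w)
    elif name == "uniform":
        state = csem_allocate(aln, grid, w=w)
    elif name == "random":
        state = random_allocation(aln, seed=seed)
    else:
        raise ValueError(f"unknown method {name!r}; choose from {_METHODS}")
    return state


def compare_methods(cfg: SimulationConfig, methods, replicates: int,
                    seed: int, w: int | None = None) -> pd.DataFrame:
    """Paired comparison of allocation strategies over seeded replicates.

    Every replicate generates a fresh instance and scores each method on
    it (multi-read argmax accuracy, random tie-breaks seeded per
    replicate).  Returns a per-method summary with mean accuracy, its
    standard error over replicates, wins against the first listed method,
    and the mean paired difference.
    """
    methods = list(methods)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    if replicates < 2:
        raise ValueError("need >= 2 replicates for a standard error")
    acc = np.zeros((len(methods), replicates))
    for r in range(replicates):
        inst_seed = seed + 1000 * r
        grid, aln, cov, truth = generate_instance(cfg, inst_seed)
        for m, name in enumerate(methods):
            state = _run_method(name, aln, cov, grid, seed=inst_seed + m, w=w)
            metrics = score_allocation(truth, state, aln, grid,
                                       seed=inst_seed + 7 * m)
            acc[m, r] = metrics["accuracy_multi"]
    base = acc[0]
    rows = []
    for m, name in enumerate(methods):
        diff = acc[m] - base
        rows.append({
            "method": name,
            "mean_accuracy": acc[m].mean(),
            "se_accuracy": acc[m].std(ddof=1) / np.sqrt(replicates),
            "mean_paired_diff": diff.mean(),
            "se_paired_diff": diff.std(ddof=1) / np.sqrt(replicates),
            "wins_vs_first": int((diff > 0).sum()),
        })
    out = pd.DataFrame(rows)
    out.attrs["accuracies"] = acc
    return out
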