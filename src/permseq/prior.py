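"""The DNase-informed Dirichlet prior.

The prior pseudo-count at genome position ``j`` is modelled as

    S_j = exp[ beta0 + beta1 . SP(x_j) + beta2 . h_j ]

where ``SP`` is a piecewise-linear (degree-1) B-spline basis in the DNase
count ``x_j`` with interior knots at the 90/99/99.9th size-weighted
percentiles of the aggregated counts, and ``h_j`` are dummy-coded trinary
histone indicators (codes 1 and 2 against baseline 0, two columns per
histone dataset).  The Dirichlet parameter is ``gamma_j = S_j + 1``, so the
prior never places mass below the uniform baseline.

Fitting is group-size-weighted least squares of ``log(S_bar + eps)`` on the
aggregated table: the response is a group mean rather than a raw count, so a
Gaussian fit on the log scale with the group size as weight is the natural
estimator, and ``eps`` (default 0.1) guards the all-zero low-count group.
Histone relevance is decided by a group lasso whose groups are the dummy
columns of each histone dataset (spline columns unpenalized), with the
penalty weight chosen by BIC and an unpenalized refit on the winners.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .covariates import (POOL_HIGH, POOL_LOW, AggregatedPriorTable,
                         CovariateTrack, pool_keys)
from .grid import GenomeGrid

__all__ = [
    "PriorModel",
    "fit_log_linear_prior",
    "select_histone_covariates",
    "group_lasso_path",
    "compute_position_priors",
    "PositionPriors",
    "ArrayPriors",
    "UniformPriors",
]

log = logging.getLogger(__name__)

KNOT_PERCENTILES = (0.90, 0.99, 0.999)


def _weighted_quantile(values, weights, qs):
    """Nearest-rank quantiles of a weighted sample."""
    order = np.argsort(values, kind="stable")
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cum = np.cumsum(w)
    total = cum[-1]
    return [float(v[np.searchsorted(cum, q * total, side="left")]) for q in qs]


@dataclass
class PriorModel:
    """Fitted log-linear spline prior with optional histone terms."""

    beta0: float
    spline_coefs: np.ndarray          # empty => intercept-only
    knots: np.ndarray | None          # full degree-1 knot vector, or None
    x_range: tuple
    epsilon: float = 0.1
    n_histones: int = 0
    selected_histones: list = field(default_factory=list)
    histone_coefs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    # pooled-class bookkeeping: positions in a pooled DNase class are
    # predicted at the class representative, not at their raw count
    high_threshold: float = np.inf
    low_rep: float = 1.0
    high_rep: float = np.nan

    # -- spline machinery ----------------------------------------------
    def _basis(self, x: np.ndarray) -> np.ndarray:
        """Degree-1 B-spline design (first column dropped against the
        intercept), with flat extrapolation outside the trained range."""
        xc = np.clip(np.asarray(x, dtype=float), *self.x_range)
        B = BSpline.design_matrix(xc, self.knots, 1).toarray()
        return B[:, 1:]

    def linear_predictor(self, x, histone_codes=None) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        eta = np.full(len(x), self.beta0)
        if len(self.spline_coefs):
            eta = eta + self._basis(x) @ self.spline_coefs
        for k, h_idx in enumerate(self.selected_histones):
            codes = np.atleast_1d(histone_codes[h_idx])
            eta = eta + self.histone_coefs[k, 0] * (codes == 1)
            eta = eta + self.histone_coefs[k, 1] * (codes == 2)
        return eta

    def predict(self, x, histone_codes=None) -> np.ndarray:
        """S-hat(x, h) = exp(linear predictor); always positive."""
        return np.exp(self.linear_predictor(x, histone_codes))

    def predict_position(self, x, histone_codes=None) -> np.ndarray:
        """Per-position prediction with pooled-class substitution."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        x_eff = x.copy()
        x_eff[x <= 2] = self.low_rep
        if np.isfinite(self.high_threshold) and not np.isnan(self.high_rep):
            x_eff[x > self.high_threshold] = self.high_rep
        return self.predict(x_eff, histone_codes)

    # -- (de)serialization ---------------------------------------------
    def to_json(self, path=None):
        payload = {
            "beta0": self.beta0,
            "spline_coefs": list(map(float, self.spline_coefs)),
            "knots": None if self.knots is None else list(map(float, self.knots)),
            "x_range": list(self.x_range),
            "epsilon": self.epsilon,
            "n_histones": self.n_histones,
            "selected_histones": list(self.selected_histones),
            "histone_coefs": [list(map(float, r)) for r in self.histone_coefs],
            "high_threshold": None if np.isinf(self.high_threshold) else self.high_threshold,
            "low_rep": self.low_rep,
            "high_rep": None if np.isnan(self.high_rep) else self.high_rep,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PriorModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            beta0=payload["beta0"],
            spline_coefs=np.asarray(payload["spline_coefs"], dtype=float),
            knots=None if payload["knots"] is None else np.asarray(payload["knots"]),
            x_range=tuple(payload["x_range"]),
            epsilon=payload["epsilon"],
            n_histones=payload["n_histones"],
            selected_histones=list(payload["selected_histones"]),
            histone_coefs=np.asarray(payload["histone_coefs"], dtype=float).reshape(-1, 2),
            high_threshold=np.inf if payload["high_threshold"] is None else payload["high_threshold"],
            low_rep=payload["low_rep"],
            high_rep=np.nan if payload["high_rep"] is None else payload["high_rep"],
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _knot_vector(x_rep, sizes=None):
    """Degree-1 knot vector with interior knots at the 90/99/99.9th
    nearest-rank percentiles of the aggregated (group-averaged) counts,
    deduplicated and kept strictly interior.

    Percentiles are taken over the table's representative values, one per
    group: with zero-inflated accessibility the genome-weighted distribution
    is all low-count mass and would collapse every knot onto the pooled
    class, leaving the upper tail unmodelled.
    """
    x_rep = np.asarray(x_rep, dtype=float)
    lo, hi = float(np.min(x_rep)), float(np.max(x_rep))
    interior = np.quantile(np.unique(x_rep), KNOT_PERCENTILES,
                           method="inverted_cdf")
    interior = sorted({float(k) for k in interior if lo < k < hi})
    return np.array([lo, lo, *interior, hi, hi], dtype=float), (lo, hi)


def _histone_dummies(patterns: pd.Series, n_histones: int) -> np.ndarray:
    """(n rows) x (2 * n_histones) dummy matrix from '|'-joined patterns."""
    if n_histones == 0:
        return np.zeros((len(patterns), 0))
    codes = np.array([[int(c) for c in p.split("|")] for p in patterns])
    cols = []
    for h in range(n_histones):
        cols.append((codes[:, h] == 1).astype(float))
        cols.append((codes[:, h] == 2).astype(float))
    return np.column_stack(cols)


def _design(table: AggregatedPriorTable, knots, x_range, with_histones):
    tab = table.table
    x = tab["x_rep"].to_numpy(dtype=float)
    cols = [np.ones(len(tab))]
    n_spline = 0
    if knots is not None:
        xc = np.clip(x, *x_range)
        B = BSpline.design_matrix(xc, knots, 1).toarray()[:, 1:]
        n_spline = B.shape[1]
        cols.append(B)
    H = _histone_dummies(tab["histone_pattern"].astype(str), table.n_histones) \
        if with_histones else np.zeros((len(tab), 0))
    cols.append(H)
    return np.column_stack(cols), n_spline


def _wls(X, y, w):
    sw = np.sqrt(w / w.sum())
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta, rank


def _pool_reps(table: AggregatedPriorTable):
    tab = table.table
    low = tab[tab["x_key"] == POOL_LOW]
    high = tab[tab["x_key"] == POOL_HIGH]
    low_rep = float(np.average(low["x_rep"], weights=low["size"])) if len(low) else 1.0
    high_rep = float(np.average(high["x_rep"], weights=high["size"])) if len(high) else np.nan
    return low_rep, high_rep


def resolve_epsilon(table: AggregatedPriorTable, epsilon) -> float:
    """The log-guard offset: a fixed float, or "auto".

    "auto" scales the guard to the response: one tenth of the size-weighted
    mean count, capped at 0.1 (so deep data keep the conventional 0.1) and
    floored at 1e-4.  A guard much larger than the typical count would
    dominate the low-coverage end of the regression.
    """
    if epsilon != "auto":
        return float(epsilon)
    tab = table.table
    mean_s = float(np.average(tab["S_bar"], weights=tab["size"]))
    return float(np.clip(0.1 * mean_s, 1e-4, 0.1))


def fit_log_linear_prior(table: AggregatedPriorTable, epsilon="auto",
                         include_histones: bool = True,
                         histone_subset=None) -> PriorModel:
    """Weighted least-squares fit of the log-linear spline prior.

    ``log(S_bar + epsilon)`` is regressed on the intercept, the degree-1
    spline basis of the representative DNase count, and (optionally) histone
    dummies; rows are weighted by group size.  A rank-deficient design is
    retried with fewer interior knots.
    """
    tab = table.table
    if len(tab) == 0:
        raise ValueError("empty aggregated table")
    epsilon = resolve_epsilon(table, epsilon)
    y = np.log(tab["S_bar"].to_numpy(dtype=float) + epsilon)
    w = tab["size"].to_numpy(dtype=float)
    x = tab["x_rep"].to_numpy(dtype=float)

    n_h = table.n_histones if include_histones else 0
    if histone_subset is None:
        histone_subset = list(range(n_h))

    if len(np.unique(x)) < 2:
        # intercept-only fallback
        beta0 = float(np.average(y, weights=w))
        low_rep, high_rep = _pool_reps(table)
        return PriorModel(beta0=beta0, spline_coefs=np.zeros(0), knots=None,
                          x_range=(float(x.min()), float(x.max())),
                          epsilon=epsilon, n_histones=table.n_histones,
                          high_threshold=table.high_pool_threshold,
                          low_rep=low_rep, high_rep=high_rep)

    knots, x_range = _knot_vector(x, w)
    while True:
        X, n_spline = _design(table, knots, x_range, with_histones=n_h > 0)
        beta, rank = _wls(X, y, w)
        if rank == X.shape[1] or len(knots) <= 4:
            if rank < X.shape[1]:
                log.warning("design still rank-deficient at minimal knots; "
                            "using least-norm solution")
            break
        log.warning("singular spline design; dropping one interior knot")
        knots = np.delete(knots, len(knots) // 2)

    beta0 = float(beta[0])
    spline_coefs = beta[1:1 + n_spline]
    hist_block = beta[1 + n_spline:].reshape(-1, 2)
    low_rep, high_rep = _pool_reps(table)
    if n_h:
        selected = list(histone_subset)
        coefs = hist_block
    else:
        selected, coefs = [], np.zeros((0, 2))
    return PriorModel(beta0=beta0, spline_coefs=spline_coefs, knots=knots,
                      x_range=x_range, epsilon=epsilon,
                      n_histones=table.n_histones,
                      selected_histones=selected, histone_coefs=coefs,
                      high_threshold=table.high_pool_threshold,
                      low_rep=low_rep, high_rep=high_rep)


# ---------------------------------------------------------------------------
# group lasso for histone selection
# ---------------------------------------------------------------------------

def _restrict_table(table: AggregatedPriorTable, subset) -> AggregatedPriorTable:
    """Re-key the table to a subset of histones (patterns re-aggregated)."""
    tab = table.table.copy()
    if table.n_histones == 0 or len(subset) == table.n_histones:
        return table
    if len(subset) == 0:
        tab["histone_pattern"] = ""
    else:
        tab["histone_pattern"] = tab["histone_pattern"].map(
            lambda p: "|".join(p.split("|")[i] for i in subset))
    tot = tab["S_bar"] * tab["size"]
    tab["_sx"] = tab["x_rep"] * tab["size"]
    tab["_st"] = tot
    agg = (tab.groupby(["x_key", "histone_pattern"], sort=False)
              .agg(size=("size", "sum"), _st=("_st", "sum"), _sx=("_sx", "sum"))
              .reset_index())
    agg["S_bar"] = agg["_st"] / agg["size"]
    agg["x_rep"] = agg["_sx"] / agg["size"]
    agg = agg[["x_key", "histone_pattern", "S_bar", "size", "x_rep"]]
    agg = agg.sort_values(["x_rep", "histone_pattern"], kind="stable").reset_index(drop=True)
    return AggregatedPriorTable(agg, M=table.M, n_histones=len(subset),
                                high_pool_threshold=table.high_pool_threshold)


def _fista_group_lasso(A, y, groups, lam, b0=None, max_iter=2000, tol=1e-9):
    """Minimise 0.5*||A b - y||^2 + lam * sum_g sqrt(p_g) ||b_g|| by FISTA.

    ``groups`` lists the column-index arrays of the *penalized* groups;
    remaining columns are unpenalized.
    """
    n, p = A.shape
    L = np.linalg.norm(A, 2) ** 2
    step = 1.0 / L
    b = np.zeros(p) if b0 is None else b0.copy()
    v, t_mom = b.copy(), 1.0
    AtA, Aty = A.T @ A, A.T @ y
    for _ in range(max_iter):
        grad = AtA @ v - Aty
        b_new = v - step * grad
        for g in groups:
            norm = np.linalg.norm(b_new[g])
            thr = step * lam * np.sqrt(len(g))
            b_new[g] = 0.0 if norm <= thr else b_new[g] * (1 - thr / norm)
        t_new = (1 + np.sqrt(1 + 4 * t_mom ** 2)) / 2
        v = b_new + (t_mom - 1) / t_new * (b_new - b)
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b, t_mom = b_new, t_new
    return b


def group_lasso_path(table: AggregatedPriorTable, lambda_grid=None,
                     epsilon="auto", n_lambda: int = 30):
    """Group-lasso selection path over a lambda grid.

    Returns (lambdas, selected_sets, bics) with one entry per lambda; each
    selected set lists the histone indices with a nonzero coefficient group.
    BIC is computed from an unpenalized refit on the selected set.
    """
    if table.n_histones < 1:
        raise ValueError("histone selection needs at least one histone track")
    tab = table.table
    epsilon = resolve_epsilon(table, epsilon)
    y = np.log(tab["S_bar"].to_numpy(dtype=float) + epsilon)
    w = tab["size"].to_numpy(dtype=float)
    x = tab["x_rep"].to_numpy(dtype=float)
    knots, x_range = _knot_vector(x, w)
    X, n_spline = _design(table, knots, x_range, with_histones=True)
    sw = np.sqrt(w / w.sum())
    A, ystar = X * sw[:, None], y * sw

    n_unpen = 1 + n_spline
    groups = [np.arange(n_unpen + 2 * h, n_unpen + 2 * h + 2)
              for h in range(table.n_histones)]

    if lambda_grid is None:
        # lambda_max: smallest lambda zeroing every group at the
        # unpenalized-baseline residual
        Xu = A[:, :n_unpen]
        bu, *_ = np.linalg.lstsq(Xu, ystar, rcond=None)
        resid = ystar - Xu @ bu
        lam_max = max(np.linalg.norm(A[:, g].T @ resid) / np.sqrt(len(g))
                      for g in groups)
        lam_max = max(lam_max, 1e-12)
        lambda_grid = np.geomspace(lam_max * 1.001, lam_max * 1e-4, n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    n = len(tab)
    sets, bics = [], []
    b_warm = None
    for lam in lambda_grid:
        b = _fista_group_lasso(A, ystar, groups, lam, b0=b_warm)
        b_warm = b
        sel = [h for h, g in enumerate(groups)
               if np.linalg.norm(b[g]) > 1e-8]
        # unpenalized refit on selected columns for the BIC
        cols = np.concatenate([np.arange(n_unpen)] + [groups[h] for h in sel]) \
            if sel else np.arange(n_unpen)
        br, *_ = np.linalg.lstsq(A[:, cols], ystar, rcond=None)
        resid = ystar - A[:, cols] @ br
        wrss = float(resid @ resid) * n  # weights normalized to mean 1
        df = len(cols)
        bic = n * np.log(max(wrss / n, 1e-300)) + df * np.log(n)
        sets.append(sel)
        bics.append(bic)
    return np.asarray(lambda_grid), sets, np.asarray(bics)


def select_histone_covariates(table: AggregatedPriorTable, lambda_grid=None,
                              epsilon="auto",
                              n_lambda: int = 30) -> PriorModel:
    """Group-lasso histone selection with BIC, then an unpenalized refit.

    One penalty group per histone dataset (its two dummy columns); the
    intercept and spline columns are never penalized.  The lambda minimising
    the BIC of the refit wins; the returned model is refit by weighted least
    squares on the selected histones only.
    """
    if lambda_grid is not None and len(lambda_grid) == 0:
        raise ValueError("empty lambda grid")
    lambdas, sets, bics = group_lasso_path(table, lambda_grid, epsilon, n_lambda)
    best = int(np.argmin(bics))
    subset = sets[best]
    log.info("group lasso: selected histones %s at lambda=%.4g", subset, lambdas[best])
    sub_table = _restrict_table(table, subset)
    model = fit_log_linear_prior(sub_table, epsilon=epsilon)
    model.n_histones = table.n_histones
    model.selected_histones = list(subset)
    return model


# ---------------------------------------------------------------------------
# per-position priors
# ---------------------------------------------------------------------------

class PositionPriors:
    """Lazy per-position pseudo-counts S_j with an exact total mass.

    ``values(idx)`` evaluates S at arbitrary flat grid indices from the
    covariate track; ``total_mass`` is computed once by summing
    (class size x class prediction) over the distinct covariate classes,
    never by a dense length-M accumulation.
    """

    def __init__(self, model: PriorModel, cov: CovariateTrack, grid: GenomeGrid):
        if cov.grid.M != grid.M:
            raise ValueError("covariate track does not match the grid")
        self.model = model
        self.cov = cov
        self.grid = grid
        self.n_clamped = int(np.count_nonzero(
            (cov.x > model.x_range[1]) & ~(cov.x > model.high_threshold)))
        self.total_mass = self._total_by_class()

    def _total_by_class(self) -> float:
        x = self.cov.x
        frame = {"x": x.astype(float),
                 "key": pool_keys(x, self.model.high_threshold)}
        for h, codes in enumerate(self.cov.histone_codes):
            frame[f"h{h}"] = codes
        df = pd.DataFrame(frame)
        gb_cols = ["key", "x"] + [f"h{h}" for h in range(self.cov.n_histones)]
        classes = df.groupby(gb_cols, sort=False).size().reset_index(name="size")
        codes = [classes[f"h{h}"].to_numpy() for h in range(self.cov.n_histones)]
        pred = self.model.predict_position(classes["x"].to_numpy(), codes)
        return float(np.dot(classes["size"].to_numpy(), pred))

    def values(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.int64)
        codes = [h[idx] for h in self.cov.histone_codes]
        return self.model.predict_position(self.cov.x[idx], codes)

    def gamma(self, idx) -> np.ndarray:
        return self.values(idx) + 1.0

    def dense(self) -> np.ndarray:
        """Full-length S track (small grids / export only)."""
        return self.values(np.arange(self.grid.M))


class ArrayPriors:
    """Pseudo-counts held in an explicit array (tests, small problems)."""

    def __init__(self, S: np.ndarray):
        self.S = np.asarray(S, dtype=float)
        if len(self.S) and self.S.min() < 0:
            raise ValueError("pseudo-counts must be non-negative")
        self.total_mass = float(self.S.sum())

    def values(self, idx) -> np.ndarray:
        return self.S[np.asarray(idx, dtype=np.int64)]


class UniformPriors:
    """The no-information prior: S_j = 0 everywhere (gamma_j = 1)."""

    total_mass = 0.0

    def values(self, idx) -> np.ndarray:
        return np.zeros(len(np.atleast_1d(idx)))


def compute_position_priors(model: PriorModel, cov: CovariateTrack,
                            grid: GenomeGrid) -> PositionPriors:
    """Materialize per-position pseudo-counts for a fitted prior model."""
    return PositionPriors(model, cov, grid)
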