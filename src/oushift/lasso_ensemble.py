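"""Ensemble LASSO ranking of candidate shift branches.

The ranking engine: on each random taxa subsample, whiten the data with the
subsampled OU covariance, run the LASSO solution path over the candidate
branch effects, and rank branches by the largest penalty at which they are
ever selected.  Per-subsample rankings are aggregated (first quartile by
default, which is robust to the occasional subsample in which the taxa that
identify a shift are missing) into one overall branch ranking that stepwise
model selection then consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lars_path

from . import ou_model
from .tree_core import PhyloTree

__all__ = [
    "SolutionPath",
    "RankingTable",
    "lasso_path",
    "rank_from_path",
    "subsample_taxa",
    "aggregate_ranks",
    "ensemble_rank",
    "AGGREGATION_METHODS",
]

AGGREGATION_METHODS = ("first_quartile", "median", "arith_mean", "geo_mean")


@dataclass(frozen=True)
class SolutionPath:
    """LASSO solution path summary.

    ``entry_lambda[b]`` is the largest penalty (on the
    ``1/2 ||r||^2 + lambda ||beta||_1`` scale) at which variable ``b`` has a
    nonzero coefficient anywhere on the path; 0 for never-selected
    variables.  ``knot_lambdas`` and ``knot_coefs`` record the full path.
    """

    entry_lambda: np.ndarray
    knot_lambdas: np.ndarray = field(repr=False)
    knot_coefs: np.ndarray = field(repr=False)  # (p, n_knots)

    @property
    def n_variables(self) -> int:
        return self.entry_lambda.size

    def active_sets(self) -> list[tuple[int, ...]]:
        """Active variable set at each knot, in decreasing-penalty order."""
        return [tuple(np.flatnonzero(self.knot_coefs[:, j]))
                for j in range(self.knot_lambdas.size)]


def _project_out_intercept(w1: np.ndarray, *arrays):
    """Residualize against the (whitened, unpenalized) intercept column."""
    u = w1 / np.linalg.norm(w1)
    return tuple(a - np.outer(u, u @ a) if a.ndim == 2 else a - u * (u @ a)
                 for a in arrays)


def lasso_path(Xw: np.ndarray, yw: np.ndarray) -> SolutionPath:
    """LASSO/LARS solution path on whitened data.

    ``Xw`` and ``yw`` must already have the whitened intercept projected
    out (see :func:`ensemble_rank`).  Columns are used as-is — no
    standardization, matching the binary clade design whose scale is
    meaningful.
    """
    Xw = np.asarray(Xw, float)
    yw = np.asarray(yw, float)
    n, p = Xw.shape
    if not np.any(yw):
        return SolutionPath(np.zeros(p), np.zeros(1), np.zeros((p, 1)))
    with warnings.catch_warnings():
        # clade designs contain near-collinear column groups by construction;
        # LARS drops such regressors and warns, which is the desired outcome
        warnings.simplefilter("ignore", ConvergenceWarning)
        alphas, _, coefs = lars_path(Xw, yw, method="lasso", Xy=Xw.T @ yw,
                                     Gram=Xw.T @ Xw)
    lambdas = alphas * n  # sklearn normalizes the squared loss by n
    entry = np.zeros(p)
    for j in range(1, lambdas.size):
        entering = (coefs[:, j] != 0) & (coefs[:, j - 1] == 0)
        # sup of penalties with nonzero coefficient = knot where it enters
        entry[entering] = np.maximum(entry[entering], lambdas[j - 1])
    return SolutionPath(entry, lambdas, coefs)


def rank_from_path(path: SolutionPath) -> np.ndarray:
    """Ranks (1 = best) in decreasing order of entry penalty; ties — in
    particular all never-entered variables — share their average rank."""
    return rankdata(-path.entry_lambda, method="average")


def subsample_taxa(n: int, fraction: float, rng) -> np.ndarray:
    """Sorted without-replacement sample of ``ceil(fraction * n)`` taxa."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    size = int(np.ceil(fraction * n))
    if size < 3:
        raise ValueError(f"subsample of {size} taxa is too small (need >= 3)")
    rng = np.random.default_rng(rng)
    return np.sort(rng.choice(n, size=size, replace=False))


@dataclass(frozen=True)
class RankingTable:
    """Per-subsample ranks (rows) for every candidate branch (columns),
    their aggregate statistic and the induced overall ranking."""

    ranks: np.ndarray  # (n_subsamples, p)
    method: str
    aggregate: np.ndarray          # per-branch aggregate statistic
    order: np.ndarray              # branch ids, best first

    @property
    def overall_rank(self) -> np.ndarray:
        """Position (1 = best) of each branch in the aggregated order."""
        r = np.empty(self.order.size, int)
        r[self.order] = np.arange(1, self.order.size + 1)
        return r


def aggregate_ranks(ranks: np.ndarray, method: str = "first_quartile") -> RankingTable:
    """Aggregate per-subsample rank rows into one overall branch ordering.

    Branches are ordered by ascending aggregate statistic; ties broken by
    branch id (stable).  ``first_quartile`` uses linear interpolation
    between order statistics.
    """
    ranks = np.atleast_2d(np.asarray(ranks, float))
    if method == "first_quartile":
        agg = np.quantile(ranks, 0.25, axis=0)
    elif method == "median":
        agg = np.median(ranks, axis=0)
    elif method == "arith_mean":
        agg = ranks.mean(axis=0)
    elif method == "geo_mean":
        agg = np.exp(np.log(ranks).mean(axis=0))
    else:
        raise ValueError(f"unknown aggregation method {method!r}; "
                         f"choose from {AGGREGATION_METHODS}")
    order = np.lexsort((np.arange(agg.size), agg))
    return RankingTable(ranks, method, agg, order)


def _path_ranks_for_subset(tree: PhyloTree, Y: np.ndarray, alpha: float,
                           idx: np.ndarray) -> np.ndarray:
    """Whiten the subsampled data, run the LASSO path over usable branch
    columns and return a full-length rank row.

    Branch columns that are constant within the subsample (the taxa that
    distinguish the branch are all excluded, or all included taxa lie under
    it) carry no information there and are treated as never-entered.
    """
    C = ou_model._structure_matrix(tree, alpha)[np.ix_(idx, idx)]
    L = ou_model._chol_with_ridge(C)
    eye = np.eye(idx.size)
    W = linalg.solve_triangular(L, eye, lower=True)
    X = tree.incidence_matrix()[idx, :]
    p = X.shape[1]
    usable = np.flatnonzero(X.var(axis=0) > 0)
    yw = W @ Y[idx]
    Xw = W @ X[:, usable]
    w1 = W @ np.ones(idx.size)
    Xw, yw = _project_out_intercept(w1, Xw, yw)
    sub_path = lasso_path(Xw, yw)
    entry = np.zeros(p)
    entry[usable] = sub_path.entry_lambda
    return rank_from_path(SolutionPath(entry, sub_path.knot_lambdas,
                                       np.zeros((p, 1))))


def ensemble_rank(
    tree: PhyloTree,
    Y: np.ndarray,
    alpha: float,
    *,
    n_subsamples: int = 100,
    fraction: float = 0.5,
    method: str = "first_quartile",
    seed=None,
) -> RankingTable:
    """Overall branch ranking from LASSO paths on random taxa subsamples.

    For each subsample the OU covariance at ``alpha`` is subset to the
    sampled taxa and re-whitened (whitened rows of the full data are not
    exchangeable, so subsampling must happen on the original taxa).  Fully
    deterministic given ``seed``.
    """
    Y = np.asarray(Y, float)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_subsamples):
        idx = subsample_taxa(tree.n_tips, fraction, rng)
        rows.append(_path_ranks_for_subset(tree, Y, alpha, idx))
    return aggregate_ranks(np.array(rows), method)
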