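"""Information criteria and stepwise search producing the detected shift set.

Two detection modes share the same outer loop over the selection strength
``alpha`` (start from the Brownian limit ``alpha = 0``, select branches,
re-estimate ``alpha`` on the selection, repeat, keep the criterion-best
iterate):

* :func:`ensemble_detect` — ensemble-LASSO ranking of branches followed by
  stepwise (forward-backward by default) selection along that ranking;
* :func:`path_detect` — a single whole-data LASSO path whose per-knot
  active sets each seed a backward pass, keeping the criterion-best model
  (the strategy of the l1ou method).

Criteria: classical BIC with ``2k + 3`` parameters, and the phylogenetic
BIC (pBIC) which replaces the per-shift ``log n`` with the position penalty
``2 log(2n - 3)`` plus a log-determinant term for the shift magnitudes and
intercept — a more conservative choice, by design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from . import lasso_ensemble, ou_model
from .ou_model import GLSFit
from .tree_core import PhyloTree

__all__ = [
    "ModelFit",
    "bic",
    "pbic",
    "Evaluator",
    "forward_select",
    "backward_select",
    "forward_backward_select",
    "ensemble_detect",
    "path_detect",
    "DetectionResult",
]

logger = logging.getLogger(__name__)

CRITERIA = ("bic", "pbic")
STEPWISE = ("forward", "backward", "forward_backward")


@dataclass(frozen=True)
class ModelFit:
    """A selected branch set with its refit parameters and scores."""

    fit: GLSFit
    score: float
    criterion: str

    @property
    def branch_ids(self) -> tuple[int, ...]:
        return self.fit.branch_ids

    @property
    def k(self) -> int:
        return self.fit.k


def bic(fit: GLSFit, n: int) -> float:
    """Classical BIC: ``-2 loglik + (2k + 3) log n`` — each shift counts
    its position and magnitude, plus beta0, alpha and sigma."""
    return -2.0 * fit.loglik + (2 * fit.k + 3) * np.log(n)


def _magnitude_design(tree: PhyloTree, branch_ids, alpha: float,
                      scaled: bool = False) -> np.ndarray:
    """Intercept plus the selected shift columns.

    ``scaled=False`` (default) uses the binary incidence columns: the
    determinant then measures the Fisher information of the tip-level
    effects ``beta_b``, which stay on the trait scale for every branch.
    ``scaled=True`` rescales column ``b`` by ``1 - exp(-alpha t_start(b))``
    — the information of the optimum shifts ``dtheta_b`` instead.  The
    scaled form collapses for short external branches (``t_start -> 0``
    sends the column, hence the determinant, to zero, turning the penalty
    into an unbounded reward for near-tip shifts), so it is kept only as a
    diagnostic.
    """
    n = tree.n_tips
    X = tree.incidence_matrix()
    cols = [np.ones(n)]
    for b in branch_ids:
        scale = (1.0 - np.exp(-alpha * tree.branches[b].t_start)
                 if scaled and alpha > 0 else 1.0)
        cols.append(scale * X[:, b])
    return np.column_stack(cols)


def pbic(fit: GLSFit, tree: PhyloTree, trait_variance: float = 1.0,
         scaled_design: bool = False) -> float:
    """Phylogenetic BIC:
    ``-2 loglik + 2k log(2n-3) + 2 log n + log det(X_M' v Sigma^-1 X_M)``
    with ``X_M`` the intercept-plus-selected-shifts design (see
    :func:`_magnitude_design` for the two readings of its columns) and
    ``v`` the scalar sample variance of the observed traits, acting as the
    prior scale of the shift magnitudes.  A singular determinant argument
    (exactly collinear surrogate shifts) scores +inf so such models are
    never selected.
    """
    n = tree.n_tips
    A = _magnitude_design(tree, fit.branch_ids, fit.alpha, scaled_design)
    L = ou_model._structure_cholesky(tree, fit.alpha)
    Aw = linalg.solve_triangular(L, A, lower=True)
    sigma2 = max(fit.sigma2, 1e-300)
    M = (Aw.T @ Aw) * (trait_variance / sigma2)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular pBIC determinant (unidentifiable shift set)")
        return np.inf
    return (-2.0 * fit.loglik + 2 * fit.k * np.log(2 * n - 3)
            + 2 * np.log(n) + logdet)


class Evaluator:
    """Fits candidate branch sets at a fixed ``alpha`` and scores them.

    sigma2 is profiled per candidate from the whitened residuals; the
    whitening at ``alpha`` is factorized once and reused, so each candidate
    costs one least-squares solve.  Fits are cached by branch set.
    """

    def __init__(self, tree: PhyloTree, Y: np.ndarray, alpha: float,
                 criterion: str = "pbic"):
        if criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {criterion!r}")
        self.tree = tree
        self.Y = np.asarray(Y, float)
        self.alpha = float(alpha)
        self.criterion = criterion
        self.trait_variance = float(np.var(self.Y, ddof=1))
        n = tree.n_tips
        self._L = ou_model._structure_cholesky(tree, self.alpha)
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._L))))
        self._Yw = linalg.solve_triangular(self._L, self.Y, lower=True)
        self._Xw = linalg.solve_triangular(
            self._L, np.column_stack([np.ones(n), tree.incidence_matrix()]),
            lower=True)
        self.n_fits = 0
        self._cache: dict[tuple[int, ...], GLSFit] = {}

    def fit(self, branch_ids) -> GLSFit:
        branch_ids = tuple(sorted(int(b) for b in branch_ids))
        cached = self._cache
        if branch_ids in cached:
            return cached[branch_ids]
        n = self.tree.n_tips
        A = self._Xw[:, [0] + [b + 1 for b in branch_ids]]
        coef, _, rank, _ = np.linalg.lstsq(A, self._Yw, rcond=None)
        if rank < A.shape[1]:
            # collinear surrogate branches: flag with an unusable fit
            fit = GLSFit(branch_ids, float("nan"), coef[1:].copy(), np.inf,
                         self.alpha, -np.inf, np.inf, self._logdet)
        else:
            resid = self._Yw - A @ coef
            rss = float(resid @ resid)
            sigma2 = rss / n
            ll = (np.inf if sigma2 == 0 else
                  -0.5 * (n * np.log(2 * np.pi * sigma2) + self._logdet + n))
            fit = GLSFit(branch_ids, float(coef[0]), coef[1:].copy(), sigma2,
                         self.alpha, float(ll), rss, self._logdet)
        cached[branch_ids] = fit
        self.n_fits += 1
        return fit

    def score(self, branch_ids) -> ModelFit:
        fit = self.fit(branch_ids)
        if fit.loglik == -np.inf:  # rank-deficient (surrogate clash)
            return ModelFit(fit, np.inf, self.criterion)
        if self.criterion == "bic":
            s = bic(fit, self.tree.n_tips)
        else:
            s = pbic(fit, self.tree, self.trait_variance)
        return ModelFit(fit, float(s), self.criterion)


def forward_select(ranking, evaluator: Evaluator) -> ModelFit:
    """One greedy forward pass along the ranking: consider branches
    best-ranked first, adding each whose addition strictly improves the
    criterion.

    Non-improving candidates are skipped rather than terminating the pass:
    a shift's *surrogate* (a branch inducing the same tip contrast, e.g.
    the root's other child) can never improve once the shift is in, and
    halting there would discard every lower-ranked true shift.
    """
    current = evaluator.score(())
    selected: list[int] = []
    for b in ranking:
        cand = evaluator.score(selected + [int(b)])
        if cand.score < current.score:
            selected.append(int(b))
            current = cand
    return current


def backward_select(start: ModelFit, ranking, evaluator: Evaluator) -> ModelFit:
    """One greedy backward pass: consider the selected branches
    worst-ranked first, removing each whose removal strictly improves the
    criterion (non-improving removals are skipped, mirroring
    :func:`forward_select`)."""
    current = start
    selected = list(start.branch_ids)
    rank_pos = {int(b): i for i, b in enumerate(ranking)}
    for b in sorted(selected, key=lambda b: rank_pos.get(b, -1), reverse=True):
        cand = evaluator.score([x for x in selected if x != b])
        if cand.score < current.score:
            selected.remove(b)
            current = cand
    return current


def forward_backward_select(ranking, evaluator: Evaluator) -> ModelFit:
    """One forward pass, then one backward pass starting from its result."""
    fwd = forward_select(ranking, evaluator)
    return backward_select(fwd, ranking, evaluator)


@dataclass(frozen=True)
class DetectionResult:
    """Final detected model plus the outer-loop trajectory."""

    model: ModelFit
    alpha_trajectory: tuple[float, ...]
    converged: bool
    iterates: tuple[ModelFit, ...] = field(repr=False)

    @property
    def branch_ids(self) -> tuple[int, ...]:
        return self.model.branch_ids


def _stepwise(ranking, evaluator, stepwise: str) -> ModelFit:
    if stepwise == "forward":
        return forward_select(ranking, evaluator)
    if stepwise == "backward":
        start = evaluator.score(tuple(int(b) for b in ranking))
        return backward_select(start, ranking, evaluator)
    if stepwise == "forward_backward":
        return forward_backward_select(ranking, evaluator)
    raise ValueError(f"unknown stepwise mode {stepwise!r}")


def _outer_loop(tree, Y, select_at_alpha, *, criterion, fixed_alpha,
                max_iter) -> DetectionResult:
    """The shared alpha loop: select at alpha = 0 (or a supplied fixed
    alpha, in which case no re-estimation happens), refit alpha on the
    selection, repeat until the branch set stabilizes or ``max_iter``, and
    return the criterion-best iterate overall."""
    alpha = 0.0 if fixed_alpha is None else float(fixed_alpha)
    trajectory = [alpha]
    iterates: list[ModelFit] = []
    prev_set = None
    converged = False
    for it in range(max_iter):
        model = select_at_alpha(alpha)
        iterates.append(model)
        logger.info("iteration %d: alpha=%.4g -> %d branch(es), %s=%.4f",
                    it, alpha, model.k, criterion, model.score)
        if fixed_alpha is not None:
            converged = True
            break
        if prev_set == set(model.branch_ids):
            converged = True
            break
        prev_set = set(model.branch_ids)
        refit = ou_model.estimate_alpha_sigma(tree, Y, model.branch_ids)
        alpha = refit.alpha
        trajectory.append(alpha)
    if not converged:
        logger.warning("alpha did not converge in %d iterations; "
                       "returning the best-scoring iterate", max_iter)
    best = min(iterates, key=lambda m: m.score)
    return DetectionResult(best, tuple(trajectory), converged, tuple(iterates))


def ensemble_detect(
    tree: PhyloTree,
    Y: np.ndarray,
    *,
    criterion: str = "pbic",
    stepwise: str = "forward_backward",
    n_subsamples: int = 100,
    fraction: float = 0.5,
    aggregation: str = "first_quartile",
    seed=None,
    fixed_alpha: float | None = None,
    max_iter: int = 10,
) -> DetectionResult:
    """Detect optimum shifts by ensemble-LASSO ranking + stepwise selection.

    The five-step procedure: (1) a null Brownian fit initializes sigma2
    (implicit — sigma2 is profiled throughout, so only ``alpha = 0``
    matters); (2) ensemble ranking and stepwise selection at the current
    alpha; (3) (alpha, sigma2) refit on the selected branches; (4) repeat
    selection/refit until the branch set stabilizes, up to ``max_iter``
    rounds; (5) return the iterate with the best criterion score.

    Deterministic given ``seed``; ``fixed_alpha`` disables the outer loop
    (used when studying deliberate mis-estimation of alpha).
    """
    Y = np.asarray(Y, float)
    seed_seq = np.random.SeedSequence(seed)

    def select(alpha: float) -> ModelFit:
        # successive spawns are deterministic given the parent seed
        child = seed_seq.spawn(1)[0]
        table = lasso_ensemble.ensemble_rank(
            tree, Y, alpha, n_subsamples=n_subsamples, fraction=fraction,
            method=aggregation, seed=np.random.default_rng(child))
        ev = Evaluator(tree, Y, alpha, criterion)
        return _stepwise(table.order, ev, stepwise)

    return _outer_loop(tree, Y, select, criterion=criterion,
                       fixed_alpha=fixed_alpha, max_iter=max_iter)


def path_detect(
    tree: PhyloTree,
    Y: np.ndarray,
    *,
    criterion: str = "pbic",
    fixed_alpha: float | None = None,
    max_iter: int = 10,
) -> DetectionResult:
    """Detect shifts from a single whole-data LASSO path (l1ou strategy).

    At each alpha, the whitened LASSO path is computed once; every knot's
    active set seeds a backward pass (removal order: smallest entry penalty
    first) and the criterion-best model over all knots is kept.  Outer
    alpha loop as in :func:`ensemble_detect`.
    """
    Y = np.asarray(Y, float)

    def select(alpha: float) -> ModelFit:
        L = ou_model._structure_cholesky(tree, alpha)
        X = tree.incidence_matrix()
        yw = linalg.solve_triangular(L, Y, lower=True)
        Xw = linalg.solve_triangular(L, X, lower=True)
        w1 = linalg.solve_triangular(L, np.ones(tree.n_tips), lower=True)
        Xw, yw = lasso_ensemble._project_out_intercept(w1, Xw, yw)
        path = lasso_ensemble.lasso_path(Xw, yw)
        entry_order = np.argsort(-path.entry_lambda, kind="stable")
        ev = Evaluator(tree, Y, alpha, criterion)
        best = ev.score(())
        seen = set()
        for active in path.active_sets():
            if active in seen or len(active) >= tree.n_tips - 1:
                continue
            seen.add(active)
            start = ev.score(active)
            cand = backward_select(start, entry_order, ev)
            if cand.score < best.score:
                best = cand
        return best

    return _outer_loop(tree, Y, select, criterion=criterion,
                       fixed_alpha=fixed_alpha, max_iter=max_iter)
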