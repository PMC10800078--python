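"""Ornstein-Uhlenbeck trait model on a tree: covariance, mean, GLS,
likelihood, parameter estimation and trait simulation.

The model
---------
A continuous trait evolves along each branch as an OU process
``dY = alpha (theta - Y) dt + sigma dB`` with selection strength ``alpha``,
diffusion intensity ``sigma2 = sigma**2`` and a piecewise-constant optimum
``theta`` that may shift at the start of a branch.  With the root drawn from
the stationary distribution, the tip values are multivariate normal with

* covariance ``Sigma_ij = sigma2 * exp(-alpha * d_ij) / (2 alpha)`` for
  ``alpha > 0`` (``d_ij`` the patristic distance), and
* mean ``E(Y_i) = beta0 + sum_{b in path(root, i)} beta_b`` where
  ``beta_b = (1 - exp(-alpha * t_start(b))) * dtheta_b`` absorbs the shift
  ``dtheta_b`` in the optimum on branch ``b``.

This turns shift detection into selection of nonzero ``beta_b`` in a linear
model with the binary clade-incidence design.  ``alpha = 0`` is the
Brownian-motion limit with covariance ``sigma2 * t_ij`` (shared times).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .tree_core import PhyloTree

__all__ = [
    "OUParams",
    "ShiftConfiguration",
    "ou_covariance",
    "mean_vector",
    "whiten",
    "apply_whitening",
    "gls_fit",
    "GLSFit",
    "log_likelihood",
    "estimate_alpha_sigma",
    "simulate_traits",
    "ALPHA_SEARCH_BOUNDS",
]

#: bounds of the bounded search for alpha (1/time, tree depth 1)
ALPHA_SEARCH_BOUNDS = (1e-4, 1e2)

#: relative ridge added to the BM covariance diagonal
_BM_RIDGE = 1e-8


@dataclass(frozen=True)
class OUParams:
    """Global OU parameters.

    alpha : selection strength (1/time), >= 0; 0 selects the BM limit.
    sigma2 : diffusion variance intensity (trait^2/time), > 0.
    beta0 : baseline mean at the tips (trait units); under a stationary
        root this is the ancestral optimum theta0.
    """

    alpha: float
    sigma2: float
    beta0: float = 0.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def stationary_variance(self) -> float:
        if self.alpha == 0:
            raise ValueError("BM (alpha = 0) has no stationary variance")
        return self.sigma2 / (2.0 * self.alpha)


@dataclass(frozen=True)
class ShiftConfiguration:
    """A set of ``(branch id, effect)`` pairs defining the optimum shifts.

    ``as_optimum_change`` says whether effects are optimum shifts
    ``dtheta_b`` (True) or regression effects ``beta_b`` (False); the two
    are related by ``beta_b = (1 - exp(-alpha t_start(b))) dtheta_b``.
    """

    entries: tuple[tuple[int, float], ...] = ()
    as_optimum_change: bool = False

    def __post_init__(self):
        ids = [b for b, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate branch ids in shift configuration")

    @property
    def branch_ids(self) -> tuple[int, ...]:
        return tuple(b for b, _ in self.entries)

    def beta(self, tree: PhyloTree, alpha: float) -> np.ndarray:
        """Per-branch regression effects, dense over all branches."""
        beta = np.zeros(tree.n_branches)
        for b, eff in self.entries:
            if not 0 <= b < tree.n_branches:
                raise ValueError(f"branch id {b} not in tree")
            if self.as_optimum_change:
                scale = 1.0 - np.exp(-alpha * tree.branches[b].t_start)
                beta[b] = scale * eff
            else:
                beta[b] = eff
        return beta

    def dtheta(self, tree: PhyloTree, alpha: float) -> np.ndarray:
        """Per-branch optimum shifts, dense over all branches."""
        dtheta = np.zeros(tree.n_branches)
        for b, eff in self.entries:
            if self.as_optimum_change:
                dtheta[b] = eff
            else:
                if alpha == 0:
                    raise ValueError("beta-form shifts have no dtheta at alpha = 0")
                scale = 1.0 - np.exp(-alpha * tree.branches[b].t_start)
                dtheta[b] = eff / scale
        return dtheta

    @staticmethod
    def uniform(branch_ids, beta: float) -> "ShiftConfiguration":
        """All listed branches share the same effect size ``beta``."""
        return ShiftConfiguration(tuple((int(b), float(beta)) for b in branch_ids))


def ou_covariance(tree: PhyloTree, params: OUParams) -> np.ndarray:
    """Tip covariance of the stationary-root OU model.

    For ``alpha > 0``: ``sigma2 * exp(-alpha d_ij) / (2 alpha)``; for
    ``alpha = 0`` the BM covariance ``sigma2 * t_ij`` with a small relative
    ridge on the diagonal to keep the matrix safely positive definite.
    """
    if params.alpha > 0:
        Sigma = params.stationary_variance * np.exp(-params.alpha * tree.distance_matrix())
    else:
        Sigma = params.sigma2 * tree.shared_time_matrix()
        Sigma = Sigma + np.eye(tree.n_tips) * (_BM_RIDGE * np.trace(Sigma) / tree.n_tips)
    if not np.all(np.isfinite(Sigma)):
        raise ValueError("non-finite entries in OU covariance")
    return Sigma


def mean_vector(tree: PhyloTree, params: OUParams,
                shifts: ShiftConfiguration = ShiftConfiguration()) -> np.ndarray:
    """``E(Y) = beta0 * 1 + X @ beta`` with the clade-incidence design."""
    beta = shifts.beta(tree, params.alpha)
    return params.beta0 + tree.incidence_matrix() @ beta


def whiten(Sigma: np.ndarray) -> np.ndarray:
    """Inverse lower-Cholesky whitening transform ``W`` with
    ``W @ Sigma @ W.T = I``.

    Any valid inverse square root yields the same GLS and LASSO results;
    the Cholesky choice is deterministic and cheap.
    """
    Sigma = np.asarray(Sigma, float)
    try:
        L = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        smallest = float(np.min(linalg.eigvalsh(Sigma)))
        raise ValueError(
            f"covariance is not positive definite (smallest eigenvalue {smallest:.3g})"
        ) from exc
    return linalg.solve_triangular(L, np.eye(Sigma.shape[0]), lower=True)


def apply_whitening(W: np.ndarray, *arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    """Apply the whitening transform consistently to vectors/matrices."""
    return tuple(W @ a for a in arrays)


@dataclass(frozen=True)
class GLSFit:
    """Result of a generalized-least-squares fit on a fixed branch set."""

    branch_ids: tuple[int, ...]
    beta0: float
    beta: np.ndarray            # effects aligned with branch_ids
    sigma2: float               # ML (profile) estimate
    alpha: float
    loglik: float               # at (alpha, profiled sigma2, GLS betas)
    rss_whitened: float = field(repr=False)
    logdet_corr: float = field(repr=False)  # log det of the sigma2-free correlation

    @property
    def k(self) -> int:
        return len(self.branch_ids)

    def fitted_mean(self, tree: PhyloTree) -> np.ndarray:
        shifts = ShiftConfiguration(tuple(zip(self.branch_ids, self.beta)))
        return mean_vector(tree, OUParams(self.alpha, max(self.sigma2, 1e-300),
                                          self.beta0), shifts)


def _structure_matrix(tree: PhyloTree, alpha: float) -> np.ndarray:
    """The sigma2-free covariance structure C with Sigma = sigma2 * C."""
    if alpha > 0:
        return np.exp(-alpha * tree.distance_matrix()) / (2.0 * alpha)
    C = tree.shared_time_matrix()
    return C + np.eye(tree.n_tips) * (_BM_RIDGE * np.trace(C) / tree.n_tips)


def _chol_with_ridge(M: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, escalating a tiny relative diagonal ridge if
    the matrix is numerically semidefinite (tiny alpha or zero-length
    cherries push it to the PD boundary)."""
    mean_diag = float(np.mean(np.diag(M)))
    for ridge in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return linalg.cholesky(M + ridge * mean_diag * np.eye(M.shape[0]),
                                   lower=True)
        except linalg.LinAlgError:
            continue
    raise ValueError("covariance structure is not positive definite")


def _structure_cholesky(tree: PhyloTree, alpha: float) -> np.ndarray:
    """Lower Cholesky factor of :func:`_structure_matrix`, computed on the
    unit-diagonal correlation ``exp(-alpha d)`` for numerical stability at
    small alpha (where ``1/(2 alpha)`` dwarfs the entry differences)."""
    if alpha > 0:
        R = np.exp(-alpha * tree.distance_matrix())
        return _chol_with_ridge(R) / np.sqrt(2.0 * alpha)
    return _chol_with_ridge(_structure_matrix(tree, 0.0))


def gls_fit(tree: PhyloTree, Y: np.ndarray, branch_ids, alpha: float) -> GLSFit:
    """GLS estimates of (beta0, beta_b for b in ``branch_ids``) with the
    OU error structure at ``alpha``; sigma2 is profiled from the whitened
    residual sum of squares (ML: RSS/n).

    Raises on a rank-deficient design, naming the collinear branch pairs
    (surrogate shifts with identical tip partitions).
    """
    branch_ids = tuple(int(b) for b in branch_ids)
    Y = np.asarray(Y, float)
    n = tree.n_tips
    L = _structure_cholesky(tree, alpha)
    X = tree.incidence_matrix()
    A = np.column_stack([np.ones(n)] + [X[:, b] for b in branch_ids])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        cols = {}
        clash = []
        for j, b in enumerate(("intercept",) + branch_ids):
            key = A[:, j].tobytes()
            if key in cols:
                clash.append((cols[key], b))
            cols[key] = b
        raise ValueError(f"rank-deficient design; collinear branch pairs: {clash}")
    Aw = linalg.solve_triangular(L, A, lower=True)
    Yw = linalg.solve_triangular(L, Y, lower=True)
    coef, _, _, _ = np.linalg.lstsq(Aw, Yw, rcond=None)
    resid = Yw - Aw @ coef
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 > 0:
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    else:  # exact interpolation (noiseless data): density degenerates
        ll = np.inf
    return GLSFit(branch_ids, float(coef[0]), coef[1:].copy(), sigma2,
                  float(alpha), float(ll), rss, logdet)


def log_likelihood(tree: PhyloTree, Y: np.ndarray, params: OUParams,
                   shifts: ShiftConfiguration = ShiftConfiguration()) -> float:
    """Multivariate-normal log density of ``Y`` under the OU model with the
    given (fully specified) parameters and shifts."""
    mu = mean_vector(tree, params, shifts)
    L = np.sqrt(params.sigma2) * _structure_cholesky(tree, params.alpha)
    z = linalg.solve_triangular(L, Y - mu, lower=True)
    n = tree.n_tips
    return float(-0.5 * (n * np.log(2 * np.pi)
                         + 2.0 * np.sum(np.log(np.diag(L))) + z @ z))


def estimate_alpha_sigma(tree: PhyloTree, Y: np.ndarray, branch_ids=(),
                         bounds: tuple[float, float] = ALPHA_SEARCH_BOUNDS) -> GLSFit:
    """Maximize the likelihood over ``alpha`` for a fixed branch set.

    One-dimensional bounded search on ``log alpha`` with ``sigma2`` (and the
    regression effects) profiled out in closed form.  On optimizer failure
    the better boundary value is returned with a warning — mirroring the
    non-convergence this crude profile search is known to exhibit.
    """
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def neg_profile(log_alpha: float) -> float:
        fit = gls_fit(tree, Y, branch_ids, float(np.exp(log_alpha)))
        return -fit.loglik if np.isfinite(fit.loglik) else -1e300

    res = optimize.minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-4 * (hi - lo)})
    candidates = [lo, hi]
    if res.success:
        candidates.append(float(res.x))
    else:
        warnings.warn("alpha search did not converge; using best boundary value")
    best = min(candidates, key=neg_profile)
    return gls_fit(tree, Y, branch_ids, float(np.exp(best)))


def simulate_traits(
    tree: PhyloTree,
    params: OUParams,
    shifts: ShiftConfiguration = ShiftConfiguration(),
    *,
    rng=None,
    measurement_sd: float = 0.0,
    variance_shift: tuple[int, float] | None = None,
) -> np.ndarray:
    """Draw one tip-trait vector from the OU model.

    With constant ``sigma2`` the draw is from the closed-form multivariate
    normal.  ``variance_shift = (branch_id, sigma2_local)`` switches to a
    recursive branch-by-branch simulation with exact OU transition moments,
    where every branch at or below ``branch_id`` uses ``sigma2_local``
    instead of ``params.sigma2`` (requires ``alpha > 0``).  Additive
    Gaussian measurement error of standard deviation ``measurement_sd`` is
    applied per tip in either case.
    """
    rng = np.random.default_rng(rng)
    if variance_shift is None:
        mu = mean_vector(tree, params, shifts)
        L = np.sqrt(params.sigma2) * _structure_cholesky(tree, params.alpha)
        Y = mu + L @ rng.standard_normal(tree.n_tips)
    else:
        Y = _simulate_recursive(tree, params, shifts, rng, variance_shift)
    if measurement_sd > 0:
        Y = Y + rng.normal(0.0, measurement_sd, size=tree.n_tips)
    return Y


def _simulate_recursive(tree, params, shifts, rng, variance_shift):
    """Branch-by-branch OU simulation with a branch-local diffusion
    variance; root drawn from the stationary distribution of its regime."""
    alpha = params.alpha
    if alpha <= 0:
        raise ValueError("recursive variance-shift simulation requires alpha > 0")
    shift_branch, sigma2_local = (None, None) if variance_shift is None else variance_shift
    dtheta = shifts.dtheta(tree, alpha)

    theta0 = params.beta0  # stationary root: baseline mean is theta0
    root_val = rng.normal(theta0, np.sqrt(params.sigma2 / (2 * alpha)))
    values = np.empty(tree.n_tips)

    # preorder over branches: parents before children
    order = sorted(range(tree.n_branches), key=lambda b: -tree.branches[b].t_start)
    node_val = {}
    node_theta = {}
    shifted_var = np.zeros(tree.n_branches, bool)
    for b in order:
        br = tree.branches[b]
        p = br.parent_branch
        parent_val = root_val if p is None else node_val[p]
        theta = theta0 if p is None else node_theta[p]
        theta = theta + dtheta[b]
        s2 = params.sigma2
        if shift_branch is not None and (b == shift_branch
                                         or (p is not None and shifted_var[p])):
            shifted_var[b] = True
            s2 = sigma2_local
        ell = br.length
        mean = theta + (parent_val - theta) * np.exp(-alpha * ell)
        var = s2 * (1.0 - np.exp(-2 * alpha * ell)) / (2 * alpha)
        val = rng.normal(mean, np.sqrt(var))
        node_val[b] = val
        node_theta[b] = theta
        if br.is_terminal:
            (i,) = br.descendant_tips
            values[i] = val
    return values
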