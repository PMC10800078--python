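"""Simulation scenarios: tree shapes, shift grids and the
mis-specification mechanisms used to stress the detectors.

Four ultrametric tree shapes (all rescaled to depth 1): complete balanced,
caterpillar (pectinate), pure-birth (Yule) and Kingman coalescent.  The
scenario grids — signal sizes, shift counts, variance-shift levels and
branch-length perturbation scales — are module constants so every study
uses the same conditions.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import dendropy
import msprime
import numpy as np
from scipy import stats

from . import ou_model
from .ou_model import OUParams, ShiftConfiguration
from .tree_core import PhyloTree, read_newick

__all__ = [
    "gen_tree",
    "TREE_TYPES",
    "BETA_GRID",
    "SHIFT_COUNTS",
    "VARIANCE_SHIFT_SIGMA2",
    "PERTURBATION_SCALES",
    "alpha_misestimation_grid",
    "perturb_branch_lengths",
    "shift_preset",
    "Scenario",
    "simulate_replicates",
]

TREE_TYPES = ("balanced", "caterpillar", "pure_birth", "coalescent")

#: common shift magnitudes applied to every shift in a scenario
BETA_GRID = (0.2, 1.0, 1.5, 2.0, 2.5, 3.0, 5.0, 7.0, 10.0)
#: numbers of simultaneous optimum shifts studied
SHIFT_COUNTS = (3, 7, 12)
#: local diffusion variances for the variance-shift mechanism (baseline 1)
VARIANCE_SHIFT_SIGMA2 = (2.0, 4.0, 6.0, 8.0, 11.0)
#: gamma scales for branch-length mis-specification
PERTURBATION_SCALES = (1 / 30, 1 / 10, 1 / 5)


def alpha_misestimation_grid() -> tuple[float, ...]:
    """Fixed selection strengths used to probe deliberate mis-estimation:
    powers of ten from 1e-4 to 1e2 (the generating value 1 included)."""
    return tuple(10.0 ** e for e in range(-4, 3))


# --------------------------------------------------------------------- #
# tree generators

def _tree_from_merges(n: int, merge_times: np.ndarray, pairs) -> PhyloTree:
    """Build a tree from a sequence of (time, pair-of-lineages) merges."""
    parent = np.full(2 * n - 1, -1, dtype=int)
    lengths = np.zeros(2 * n - 1)
    age = np.zeros(2 * n - 1)
    labels = {i: f"t{i + 1}" for i in range(n)}
    nxt = n
    for t, (a, b) in zip(merge_times, pairs):
        for c in (a, b):
            parent[c] = nxt
            lengths[c] = t - age[c]
        age[nxt] = t
        nxt += 1
    tree = PhyloTree(parent, lengths, labels)
    return _rescaled(tree)


def _rescaled(tree: PhyloTree, depth: float = 1.0) -> PhyloTree:
    if abs(tree.total_depth - depth) < 1e-12:
        return tree
    return tree.with_branch_lengths(tree.branch_lengths * depth / tree.total_depth)


def _balanced_tree(n: int) -> PhyloTree:
    levels = int(np.log2(n))
    if 2 ** levels != n:
        raise ValueError(f"balanced tree requires n a power of 2, got {n}")
    # nodes: tips 0..n-1, then internals level by level
    parent = np.full(2 * n - 1, -1, dtype=int)
    lengths = np.zeros(2 * n - 1)
    current = list(range(n))
    nxt = n
    ell = 1.0 / levels
    while len(current) > 1:
        merged = []
        for i in range(0, len(current), 2):
            a, b = current[i], current[i + 1]
            parent[a] = parent[b] = nxt
            lengths[a] = lengths[b] = ell
            merged.append(nxt)
            nxt += 1
        current = merged
    labels = {i: f"t{i + 1}" for i in range(n)}
    return PhyloTree(parent, lengths, labels)


def _caterpillar_tree(n: int) -> PhyloTree:
    """Pectinate tree; internal nodes evenly spaced in age."""
    ages = np.linspace(1.0 / (n - 1), 1.0, n - 1)  # shallowest join first
    pairs = [(0, 1)]
    for i in range(1, n - 1):
        pairs.append((i + 1, n + i - 1))  # next tip joins the growing spine
    return _tree_from_merges(n, ages, pairs)


def _pure_birth_tree(n: int, seed: int) -> PhyloTree:
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=_pyrandom.Random(int(seed)))
    t.seed_node.edge.length = None
    for i, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    newick = t.as_string(schema="newick", suppress_rooting=True)
    # birth-death leaves near-contemporaneous tips up to float noise
    tree = read_newick(newick, ultrametric_tol=1e-6)
    return _rescaled(tree)


def _coalescent_tree(n: int, seed: int, rescale: bool = True) -> PhyloTree:
    ts = msprime.sim_ancestry(samples=n, ploidy=1, random_seed=int(seed) % (2**31) or 1)
    newick = ts.first().as_newick(include_branch_lengths=True)
    tree = read_newick(newick)
    return _rescaled(tree) if rescale else tree


def gen_tree(tree_type: str, n: int, seed: int = 0) -> PhyloTree:
    """Generate an ultrametric tree of the requested shape, rescaled to
    depth 1, with tips labeled ``t1..tn`` (or ``n1..`` for coalescent)."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    if tree_type == "balanced":
        return _balanced_tree(n)
    if tree_type == "caterpillar":
        return _caterpillar_tree(n)
    if tree_type == "pure_birth":
        return _pure_birth_tree(n, seed)
    if tree_type == "coalescent":
        return _coalescent_tree(n, seed)
    raise ValueError(f"unknown tree type {tree_type!r}; choose from {TREE_TYPES}")


# --------------------------------------------------------------------- #
# branch-length mis-specification

def perturb_branch_lengths(tree: PhyloTree, scale: float, seed=None) -> PhyloTree:
    """Gamma-perturb internal branch lengths, preserving ultrametricity.

    Each internal branch length is redrawn from a gamma distribution with
    mean equal to the original length (shape = length/scale, scale =
    scale), processed in depth-first (preorder) order; a draw that would
    push the branch's bottom node to or beyond the total tree depth is
    rejected and redrawn, which is realized exactly (and without a failure
    mode when the admissible interval is tiny) by inverse-CDF sampling of
    the gamma truncated to ``(0, depth - top)``.  External branches are
    then set to ``depth - age of their top node``, restoring the exact
    original depth at every tip.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    T = tree.total_depth
    new_len = tree.branch_lengths.copy()
    # depth of the bottom node of each branch, updated as we go
    bottom_depth = np.empty(tree.n_branches)
    order = sorted(range(tree.n_branches),
                   key=lambda b: -tree.branches[b].t_start)  # preorder
    for b in order:
        br = tree.branches[b]
        p = br.parent_branch
        top = 0.0 if p is None else bottom_depth[p]
        if br.is_terminal:
            new_len[b] = T - top
            bottom_depth[b] = T
            continue
        shape = br.length / scale
        cap = stats.gamma.cdf(T - top, shape, scale=scale)
        if cap <= 0:  # admissible mass numerically zero: take a midpoint
            draw = 0.5 * (T - top)
        else:
            draw = float(stats.gamma.ppf(rng.uniform(0.0, cap), shape,
                                         scale=scale))
            draw = min(max(draw, 0.0), T - top)
        new_len[b] = draw
        bottom_depth[b] = top + draw
    return tree.with_branch_lengths(new_len)


# --------------------------------------------------------------------- #
# shift placement and scenarios

def shift_preset(tree: PhyloTree, position: str, count: int = 1,
                 seed=None) -> tuple[int, ...]:
    """Pick ``count`` internal branches by depth tercile: ``near_root``,
    ``middle`` or ``near_tip`` (by ``t_start``), disjoint in tip sets when
    possible so the shifts are separately identifiable."""
    internal = [b for b in range(tree.n_branches)
                if not tree.branches[b].is_terminal]
    starts = np.array([tree.branches[b].t_start for b in internal])
    lo, hi = np.quantile(starts, [1 / 3, 2 / 3])
    if position == "near_root":
        pool = [b for b, s in zip(internal, starts) if s >= hi]
    elif position == "middle":
        pool = [b for b, s in zip(internal, starts) if lo <= s < hi]
    elif position == "near_tip":
        pool = [b for b, s in zip(internal, starts) if s < lo]
    else:
        raise ValueError(f"unknown position preset {position!r}")
    rng = np.random.default_rng(seed)
    rng.shuffle(pool)
    chosen: list[int] = []
    covered: set[int] = set()
    for b in pool:
        tips = tree.branches[b].descendant_tips
        # disjoint, and never covering *all* tips: equal shifts on clades
        # that tile the whole tree collapse into an intercept change
        if covered.isdisjoint(tips) and len(covered | tips) < tree.n_tips:
            chosen.append(b)
            covered |= tips
        if len(chosen) == count:
            return tuple(chosen)
    raise ValueError(f"could not place {count} disjoint shifts {position!r}")


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: a tree, a shift configuration and the
    noise mechanisms, plus replicate counts and the master seed.

    ``beta`` is the common magnitude applied to every shift branch (all
    shifts in a scenario share one effect size).  Defaults follow the
    study conditions: ``alpha = 1``, ``sigma2 = 2`` so the stationary
    variance is 1, 200 training and 1000 test replicates.
    """

    tree: PhyloTree
    shift_branches: tuple[int, ...] = ()
    beta: float = 1.0
    alpha: float = 1.0
    sigma2: float = 2.0
    measurement_sd: float = 0.0
    variance_shift: tuple[int, float] | None = None
    n_train: int = 200
    n_test: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("replicate counts must be >= 1 train, >= 0 test")
        for b in self.shift_branches:
            if not 0 <= b < self.tree.n_branches:
                raise ValueError(f"shift branch {b} not in tree")
        if self.variance_shift is not None:
            b, _ = self.variance_shift
            if not 0 <= b < self.tree.n_branches:
                raise ValueError(f"variance-shift branch {b} not in tree")

    @property
    def params(self) -> OUParams:
        return OUParams(self.alpha, self.sigma2, 0.0)

    @property
    def shifts(self) -> ShiftConfiguration:
        return ShiftConfiguration.uniform(self.shift_branches, self.beta)

    def replicate_seed(self, kind: str, index: int) -> np.random.SeedSequence:
        """Deterministic per-replicate seed; regenerating replicate ``i``
        from scratch is bitwise reproducible."""
        stream = {"train": 0, "test": 1}[kind]
        return np.random.SeedSequence(self.seed, spawn_key=(stream, index))

    def draw(self, kind: str, index: int) -> np.ndarray:
        rng = np.random.default_rng(self.replicate_seed(kind, index))
        return ou_model.simulate_traits(
            self.tree, self.params, self.shifts, rng=rng,
            measurement_sd=self.measurement_sd,
            variance_shift=self.variance_shift)


def simulate_replicates(scenario: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """All training and test trait matrices for a scenario, shaped
    ``(n_train, n_tips)`` and ``(n_test, n_tips)``."""
    train = np.array([scenario.draw("train", i) for i in range(scenario.n_train)])
    test = np.array([scenario.draw("test", i) for i in range(scenario.n_test)])
    return train, test
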