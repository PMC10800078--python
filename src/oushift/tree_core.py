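"""Rooted ultrametric phylogenetic trees and the matrices built from them.

A :class:`PhyloTree` is the coordinate system for everything else in this
package: branches carry stable integer ids (deterministic postorder of the
child-sorted tree), and the shared-time, distance and incidence matrices are
all expressed in the resulting tip/branch orders.

Conventions
-----------
* Node *ages* are measured backwards in time: tips have age 0 and the root
  has age ``T`` (the tree depth).
* A *branch* is identified with the node below it; the root has no branch,
  so a binary tree with ``n`` tips has ``2n - 2`` branches.
* Branch ``b`` runs from age ``t_start(b)`` (its top, the parent node's age)
  down to ``t_end(b)`` (its bottom).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "Branch",
    "read_newick",
    "read_trait_table",
    "TraitTableError",
    "NewickError",
    "UltrametricityError",
]

#: default relative tolerance for ultrametricity checks
DEFAULT_ULTRAMETRIC_TOL = 1e-6


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed into a usable tree."""


class UltrametricityError(ValueError):
    """Raised when a tree fails the ultrametricity requirement."""


class TraitTableError(ValueError):
    """Raised when a trait table does not match the tree's tips."""


@dataclass(frozen=True)
class Branch:
    """One branch (edge) of the tree, identified with the node below it."""

    id: int
    parent_branch: int | None  # None when the parent node is the root
    length: float
    t_start: float  # age of the top of the branch
    t_end: float    # age of the bottom of the branch
    descendant_tips: frozenset[int] = field(repr=False)

    @property
    def is_terminal(self) -> bool:
        return len(self.descendant_tips) == 1


class PhyloTree:
    """A rooted tree with branch lengths, indexed for shift detection.

    Parameters are low-level; build instances with :func:`read_newick` or
    the generators in :mod:`oushift.simulation`.

    Parameters
    ----------
    parent : sequence of int
        ``parent[v]`` is the parent node id of node ``v``; the root has
        ``parent[root] == -1``.  Node ids are arbitrary but dense (0..m-1).
    lengths : sequence of float
        ``lengths[v]`` is the length of the branch above node ``v``
        (ignored for the root).
    labels : dict[int, str]
        Mapping from leaf node id to tip label.
    ultrametric_tol : float
        Relative tolerance for the ultrametricity check (fraction of the
        tree depth ``T``).
    require_ultrametric : bool
        If true (default), reject trees whose tips are not contemporaneous
        within ``ultrametric_tol``; tip ages are then snapped to exactly 0.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        labels: dict[int, str],
        *,
        ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
        require_ultrametric: bool = True,
    ):
        parent = np.asarray(parent, dtype=int)
        lengths = np.asarray(lengths, dtype=float)
        m = parent.size
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        root = int(roots[0])
        if np.any(lengths[np.arange(m) != root] < 0):
            raise ValueError("negative branch length")

        children: list[list[int]] = [[] for _ in range(m)]
        for v in range(m):
            if v != root:
                children[parent[v]].append(v)
        n_tips = sum(1 for v in range(m) if not children[v])
        if set(labels) != {v for v in range(m) if not children[v]}:
            raise ValueError("labels must cover exactly the leaf nodes")
        if len(set(labels.values())) != n_tips:
            raise ValueError("tip labels must be unique")
        if any(len(c) > 2 for c in children):
            warnings.warn("tree contains polytomies; branch indexing still applies")

        # depth of every node from the root
        depth = np.zeros(m)
        order = [root]
        for v in order:  # BFS; children appended as discovered
            for c in children[v]:
                depth[c] = depth[v] + lengths[c]
                order.append(c)
        tip_nodes = [v for v in range(m) if not children[v]]
        T = float(max(depth[v] for v in tip_nodes))
        if T <= 0:
            raise ValueError("tree depth must be positive")

        dev = {labels[v]: T - depth[v] for v in tip_nodes}
        if require_ultrametric:
            bad = {k: d for k, d in dev.items() if abs(d) > ultrametric_tol * T}
            if bad:
                worst = max(bad, key=lambda k: abs(bad[k]))
                raise UltrametricityError(
                    f"tree is not ultrametric within tol={ultrametric_tol:g}: "
                    f"{len(bad)} tip(s) deviate, worst {worst!r} by {bad[worst]:.6g}"
                )
            # snap tip ages to exactly 0 so d_ij = 2(T - t_ij) holds exactly
            lengths = lengths.copy()
            for v in tip_nodes:
                lengths[v] += T - depth[v]
                depth[v] = T

        # deterministic branch order: postorder of the child-sorted tree.
        # Children are sorted by the smallest tip label in their clade.
        min_label: dict[int, str] = {}

        def _minlab(v: int) -> str:
            if v not in min_label:
                min_label[v] = (
                    labels[v] if not children[v]
                    else min(_minlab(c) for c in children[v])
                )
            return min_label[v]

        post: list[int] = []
        stack: list[tuple[int, bool]] = [(root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                if v != root:
                    post.append(v)
                continue
            stack.append((v, True))
            for c in sorted(children[v], key=_minlab, reverse=True):
                stack.append((c, False))

        self.ultrametric_tol = ultrametric_tol
        self._root_node = root
        self._node_parent = parent
        self._node_children = children
        self._node_depth = depth
        self.total_depth = T
        self.n_branches = len(post)

        # tips in order of first appearance in the postorder
        tip_order = [v for v in post if not children[v]]
        self._tip_nodes = tip_order
        self.n_tips = len(tip_order)
        self.tip_labels: list[str] = [labels[v] for v in tip_order]
        tip_index = {v: i for i, v in enumerate(tip_order)}
        node_of_branch = np.array(post, dtype=int)
        branch_of_node = {v: b for b, v in enumerate(post)}

        X = np.zeros((self.n_tips, self.n_branches), dtype=float)
        desc: dict[int, set[int]] = {v: set() for v in range(m)}
        for v in post:  # postorder: children resolved before parents
            if not children[v]:
                desc[v] = {tip_index[v]}
            else:
                desc[v] = set().union(*(desc[c] for c in children[v]))
            X[sorted(desc[v]), branch_of_node[v]] = 1.0
        desc[root] = set(range(self.n_tips))

        self.branches: list[Branch] = []
        for b, v in enumerate(node_of_branch):
            p = int(parent[v])
            self.branches.append(Branch(
                id=b,
                parent_branch=None if p == root else branch_of_node[p],
                length=float(lengths[v]),
                t_start=float(T - depth[p]),
                t_end=float(T - depth[v]),
                descendant_tips=frozenset(desc[v]),
            ))
        self.branch_lengths = np.array([br.length for br in self.branches])
        self.t_start = np.array([br.t_start for br in self.branches])
        self.t_end = np.array([br.t_end for br in self.branches])
        self._incidence = X
        self._node_of_branch = node_of_branch
        self._branch_of_node = branch_of_node
        self._tip_deviations = dev

    # ------------------------------------------------------------------ #

    def validate_ultrametric(self, tol: float | None = None) -> tuple[bool, dict[str, float]]:
        """Check that every tip's age is within ``tol * T`` of zero.

        Returns ``(ok, deviations)`` where ``deviations`` maps each tip
        label to ``T - depth(tip)`` as measured at construction time
        (before any snapping).
        """
        tol = self.ultrametric_tol if tol is None else tol
        dev = self._tip_deviations
        ok = all(abs(d) <= tol * self.total_depth for d in dev.values())
        return ok, dict(dev)

    def shared_time_matrix(self) -> np.ndarray:
        """Pairwise shared evolution time ``t_ij`` (age of MRCA measured
        from the root); ``t_ii = T``."""
        Xw = self._incidence * self.branch_lengths
        return Xw @ self._incidence.T

    def distance_matrix(self) -> np.ndarray:
        """Pairwise patristic distance ``d_ij``; equals ``2(T - t_ij)`` on
        an ultrametric tree."""
        t = self.shared_time_matrix()
        depths = np.diag(t)
        return depths[:, None] + depths[None, :] - 2.0 * t

    def incidence_matrix(self) -> np.ndarray:
        """Binary ``n_tips x n_branches`` matrix; ``X[i, b] = 1`` iff tip
        ``i`` descends from branch ``b``.  Returns a copy."""
        return self._incidence.copy()

    def tip_path(self, tip: int) -> list[int]:
        """Branch ids on the root-to-tip path, root-most first."""
        v = self._tip_nodes[tip]
        path = []
        while v != self._root_node:
            path.append(self._branch_of_node[v])
            v = self._node_parent[v]
        return path[::-1]

    def with_branch_lengths(self, new_lengths: np.ndarray) -> "PhyloTree":
        """A new tree with the same topology and the given per-branch
        lengths (indexed by branch id)."""
        m = self._node_parent.size
        lengths = np.zeros(m)
        for b, v in enumerate(self._node_of_branch):
            lengths[v] = new_lengths[b]
        labels = {v: self.tip_labels[i] for i, v in enumerate(self._tip_nodes)}
        return PhyloTree(self._node_parent, lengths, labels,
                         ultrametric_tol=self.ultrametric_tol)

    def to_newick(self) -> str:
        """Serialize to a Newick string with branch lengths on all edges."""

        def quote(lab: str) -> str:
            if any(c in lab for c in "(),:;[] \t'"):
                return "'" + lab.replace("'", "''") + "'"
            return lab

        node_label = {v: quote(self.tip_labels[i])
                      for i, v in enumerate(self._tip_nodes)}

        def rec(v: int) -> str:
            kids = self._node_children[v]
            if not kids:
                body = node_label[v]
            else:
                body = "(" + ",".join(rec(c) for c in kids) + ")"
            if v == self._root_node:
                return body + ";"
            b = self._branch_of_node[v]
            return f"{body}:{self.branches[b].length:.12g}"

        return rec(self._root_node)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PhyloTree(n_tips={self.n_tips}, n_branches={self.n_branches}, "
                f"depth={self.total_depth:.4g})")


def read_newick(
    text: str,
    *,
    ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
    require_ultrametric: bool = True,
) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are mandatory on all non-root edges; tip ages are
    validated against ultrametricity and snapped to exactly 0.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick string: {exc}") from exc

    nodes = list(dtree.preorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    labels: dict[int, str] = {}
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
            if nd.edge.length is None:
                where = nd.taxon.label if nd.taxon else "an internal node"
                raise NewickError(f"missing branch length on the edge above {where!r}")
            lengths[i] = nd.edge.length
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickError("unlabeled tip in Newick string")
            labels[i] = nd.taxon.label
    return PhyloTree(parent, lengths, labels,
                     ultrametric_tol=ultrametric_tol,
                     require_ultrametric=require_ultrametric)


def read_trait_table(source, tree: PhyloTree) -> np.ndarray:
    """Read a 2-column (taxon, value) delimited table and align it to
    ``tree.tip_labels``.

    The delimiter is sniffed (comma, tab or whitespace) and a single header
    line is tolerated.  Taxa are matched by exact label; any mismatch in
    either direction raises :class:`TraitTableError` listing the offenders.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python", header=None,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise TraitTableError("trait table must have two columns: taxon, value")
    df = df.iloc[:, :2]
    # drop a header line if the value column is not numeric there
    first_val = pd.to_numeric(df.iloc[0, 1], errors="coerce")
    if df.shape[0] and pd.isna(first_val):
        df = df.iloc[1:]
    taxa = df.iloc[:, 0].astype(str).str.strip()
    values = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise TraitTableError("trait values must be finite")
    mapping = dict(zip(taxa, values))
    if len(mapping) != len(taxa):
        dup = taxa[taxa.duplicated()].tolist()
        raise TraitTableError(f"duplicated taxa in trait table: {dup}")
    missing = [t for t in tree.tip_labels if t not in mapping]
    extra = [t for t in mapping if t not in set(tree.tip_labels)]
    if missing or extra:
        raise TraitTableError(
            "trait table does not match tree tips"
            + (f"; missing from table: {missing}" if missing else "")
            + (f"; not in tree: {extra}" if extra else "")
        )
    return np.array([mapping[t] for t in tree.tip_labels])
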