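"""Rooted time-calibrated trees, phylogenetic covariance algebra, and regime paintings.

Trees here are generally *non-ultrametric*: fossil tips terminate at different
heights, so root-to-tip path lengths differ between taxa.  Branch lengths are
interpreted as durations (Myr in the intended use).  Node indices are assigned
in preorder at construction time and are stable for the lifetime of a
:class:`PhyloTree`; :class:`RegimePainting` objects are keyed on them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "PhyloTree",
    "PhyloCov",
    "RegimePainting",
    "vcv_matrix",
    "lambda_transform",
    "prune",
    "fix_zero_branches",
]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class _Node:
    __slots__ = ("children", "parent", "length", "label", "index")

    def __init__(self, length: float = 0.0, label: str | None = None):
        self.children: list[_Node] = []
        self.parent: _Node | None = None
        self.length = float(length)
        self.label = label
        self.index = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def deep_copy(self) -> "_Node":
        new = _Node(self.length, self.label)
        new.children = [c.deep_copy() for c in self.children]
        for c in new.children:
            c.parent = new
        return new


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths.

    Parameters
    ----------
    root : _Node
        Root of an already-linked node structure.  The root's own ``length``
        is ignored (set to 0).

    Attributes
    ----------
    nodes : list
        All nodes in preorder; ``nodes[i].index == i``.
    tip_labels : list of str
        Tip labels in preorder (left-to-right) order; this is the canonical
        taxon order of every matrix the tree produces.
    """

    def __init__(self, root: _Node):
        root.length = 0.0
        root.parent = None
        self.root = root
        self.nodes: list[_Node] = []
        stack = [root]
        while stack:
            node = stack.pop()
            node.index = len(self.nodes)
            self.nodes.append(node)
            stack.extend(reversed(node.children))
        self.tips = [n for n in self.nodes if n.is_leaf]
        self.tip_labels = [t.label for t in self.tips]
        if any(lab is None or lab == "" for lab in self.tip_labels):
            raise TreeError("every tip must carry a label")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted({x for x in self.tip_labels if self.tip_labels.count(x) > 1})
            raise TreeError(f"duplicated tip labels: {dupes}")
        # node heights measured from the root (root = 0)
        self._heights = np.zeros(len(self.nodes))
        for node in self.nodes:
            if node.parent is not None:
                self._heights[node.index] = self._heights[node.parent.index] + node.length

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise TreeError(f"malformed Newick: {exc}") from exc
        missing: list[str] = []

        def convert(dnode, at_root: bool) -> _Node:
            if dnode.taxon is not None:
                label = dnode.taxon.label
            else:
                label = dnode.label
            length = dnode.edge.length
            if length is None:
                if not at_root:
                    missing.append(label or "<internal>")
                length = 0.0
            node = _Node(length, label)
            node.children = [convert(c, False) for c in dnode.child_nodes()]
            for c in node.children:
                c.parent = node
            return node

        root = convert(dtree.seed_node, True)
        if missing:
            raise TreeError(f"branch lengths missing for: {missing}")
        if root.is_leaf:
            raise TreeError("tree has a single node")
        return cls(root)

    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: _Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.{precision}g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node.parent is None:
                return f"({inner})"
            return f"({inner}):{node.length:.{precision}g}"

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.deep_copy())

    # ---------------------------------------------------------- basic props
    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def postorder(self) -> list[_Node]:
        out: list[_Node] = []

        def rec(node: _Node):
            for c in node.children:
                rec(c)
            out.append(node)

        rec(self.root)
        return out

    def node_heights(self) -> np.ndarray:
        """Height (time from the root) of every node, indexed by node index."""
        return self._heights.copy()

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path length per tip, in ``tip_labels`` order."""
        return np.array([self._heights[t.index] for t in self.tips])

    @property
    def height(self) -> float:
        return float(self.tip_depths().max())

    def total_length(self) -> float:
        return float(sum(n.length for n in self.nodes if n.parent is not None))

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise TreeError(f"unknown tip: {label!r}") from None

    def clade_tips(self, node: _Node) -> list[str]:
        if node.is_leaf:
            return [node.label]
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return out

    def mrca(self, labels) -> _Node:
        """Most recent common ancestor of a set of tip labels."""
        want = set(labels)
        unknown = want - set(self.tip_labels)
        if unknown:
            raise TreeError(f"unknown tips: {sorted(unknown)}")
        counts: dict[int, int] = {}
        best = self.root
        for node in self.postorder():
            if node.is_leaf:
                counts[node.index] = 1 if node.label in want else 0
            else:
                counts[node.index] = sum(counts[c.index] for c in node.children)
        # deepest node containing all wanted tips
        target = len(want)
        best = self.root
        for node in self.nodes:  # preorder: later hits are deeper only if on path
            if counts.get(node.index, 0) == target and self._heights[node.index] >= self._heights[best.index]:
                best = node
        return best

    # -------------------------------------------------------- covariances
    def mrca_index_matrix(self) -> np.ndarray:
        """n×n matrix of MRCA node indices over tip pairs (diagonal = tip index)."""
        n = self.n_tips
        pos = {t.index: i for i, t in enumerate(self.tips)}
        M = np.zeros((n, n), dtype=int)
        tipsets: dict[int, list[int]] = {}
        for node in self.postorder():
            if node.is_leaf:
                tipsets[node.index] = [pos[node.index]]
                M[pos[node.index], pos[node.index]] = node.index
            else:
                kids = [tipsets[c.index] for c in node.children]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                M[i, j] = M[j, i] = node.index
                tipsets[node.index] = [i for k in kids for i in k]
        return M

    def vcv(self) -> "PhyloCov":
        """Brownian-motion phylogenetic covariance: shared path length from the root."""
        M = self.mrca_index_matrix()
        C = self._heights[M]
        return PhyloCov(np.asarray(C, dtype=float), list(self.tip_labels))

    # ------------------------------------------------------------ transforms
    def prune(self, keep_taxa) -> "PhyloTree":
        keep = [str(t) for t in keep_taxa]
        keepset = set(keep)
        unknown = keepset - set(self.tip_labels)
        if unknown:
            raise TreeError(f"cannot prune: unknown taxa {sorted(unknown)}")
        if len(keepset) < 3:
            raise TreeError("pruning must keep at least 3 taxa")

        def rec(node: _Node) -> _Node | None:
            if node.is_leaf:
                if node.label in keepset:
                    return _Node(node.length, node.label)
                return None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            new = _Node(node.length, node.label)
            new.children = kids
            for k in kids:
                k.parent = new
            return new

        newroot = rec(self.root)
        assert newroot is not None
        # collapse a unary chain at the root; the stem edge is discarded
        while len(newroot.children) == 1:
            newroot = newroot.children[0]
        newroot.parent = None
        return PhyloTree(newroot)

    def fix_zero_branches(self, epsilon: float = 0.1, floor: float = 1e-12) -> "PhyloTree":
        """Replace non-positive / numerically-zero branch lengths with ``epsilon``."""
        new = self.copy()
        for node in new.nodes:
            if node.parent is not None and node.length < floor:
                node.length = epsilon
        return PhyloTree(new.root)

    # ------------------------------------------------------------ paintings
    def path_segments(self, painting: "RegimePainting") -> list[list[tuple[float, float, str]]]:
        """Per tip: ordered (t_start, t_end, regime) segments from the root to the tip."""
        segs_by_node: dict[int, list[tuple[float, float, str]]] = {self.root.index: []}
        for node in self.nodes:
            if node.parent is None:
                continue
            upstream = segs_by_node[node.parent.index]
            t0 = self._heights[node.parent.index]
            own: list[tuple[float, float, str]] = []
            for dur, reg in painting.segments[node.index]:
                own.append((t0, t0 + dur, reg))
                t0 += dur
            segs_by_node[node.index] = upstream + own
        return [segs_by_node[t.index] for t in self.tips]

    def regime_root_times(self, painting: "RegimePainting") -> dict[str, np.ndarray]:
        """Per regime: node-indexed vector of time spent in that regime on the root→node path."""
        regs = painting.regime_levels
        acc = {r: np.zeros(len(self.nodes)) for r in regs}
        for node in self.nodes:
            if node.parent is None:
                continue
            for r in regs:
                acc[r][node.index] = acc[r][node.parent.index]
            for dur, reg in painting.segments[node.index]:
                acc[reg][node.index] += dur
        return acc

    def regime_shared_times(self, painting: "RegimePainting") -> dict[str, np.ndarray]:
        """Per regime: n×n matrix of regime-specific shared path time (root→MRCA)."""
        acc = self.regime_root_times(painting)
        M = self.mrca_index_matrix()
        return {r: v[M] for r, v in acc.items()}


@dataclass
class PhyloCov:
    """Phylogenetic covariance matrix with its taxon order."""

    matrix: np.ndarray
    taxa: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.taxa), len(self.taxa)):
            raise TreeError("covariance shape does not match taxon list")

    def reorder(self, taxa) -> "PhyloCov":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCov(self.matrix[np.ix_(idx, idx)], list(taxa))


@dataclass
class RegimePainting:
    """Assignment of regime labels to branch segments of a specific tree.

    ``segments[i]`` holds the ordered (duration, regime) pieces of the edge
    *above* node ``i`` (rootward first).  Durations on each edge must sum to
    the edge length.
    """

    tree: PhyloTree
    segments: dict[int, tuple[tuple[float, str], ...]]
    root_regime: str
    regime_levels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.regime_levels:
            seen = {self.root_regime}
            for segs in self.segments.values():
                seen.update(r for _, r in segs)
            self.regime_levels = tuple(sorted(seen))
        self.validate()

    def validate(self, tol: float = 1e-8):
        for node in self.tree.nodes:
            if node.parent is None:
                continue
            segs = self.segments.get(node.index)
            if segs is None:
                raise TreeError(f"painting misses edge above node {node.index}")
            total = sum(d for d, _ in segs)
            if abs(total - node.length) > tol * max(1.0, node.length):
                raise TreeError(
                    f"segment durations on edge above node {node.index} sum to "
                    f"{total}, edge length is {node.length}"
                )
            for _, r in segs:
                if r not in self.regime_levels:
                    raise TreeError(f"unknown regime {r!r}")

    @classmethod
    def uniform(cls, tree: PhyloTree, regime: str = "0") -> "RegimePainting":
        segs = {
            n.index: ((n.length, regime),)
            for n in tree.nodes
            if n.parent is not None
        }
        return cls(tree, segs, regime, (regime,))

    def tip_states(self) -> dict[str, str]:
        """Regime at each tip (tipmost segment of the terminal edge)."""
        return {t.label: self.segments[t.index][-1][1] for t in self.tree.tips}

    def n_transitions(self) -> int:
        count = 0
        state_at: dict[int, str] = {self.tree.root.index: self.root_regime}
        for node in self.tree.nodes:
            if node.parent is None:
                continue
            cur = state_at[node.parent.index]
            for _, reg in self.segments[node.index]:
                if reg != cur:
                    count += 1
                    cur = reg
            state_at[node.index] = cur
        return count

    def regime_time(self) -> dict[str, float]:
        out = {r: 0.0 for r in self.regime_levels}
        for segs in self.segments.values():
            for d, r in segs:
                out[r] += d
        return out

    def to_table(self) -> pd.DataFrame:
        rows = []
        for node in self.tree.nodes:
            if node.parent is None:
                continue
            tips = ";".join(sorted(self.tree.clade_tips(node)))
            for k, (dur, reg) in enumerate(self.segments[node.index]):
                rows.append(
                    {
                        "node": node.index,
                        "clade_tips": tips,
                        "segment": k,
                        "duration": dur,
                        "regime": reg,
                    }
                )
        return pd.DataFrame(rows)

    def to_simmap_newick(self, precision: int = 6) -> str:
        """SIMMAP-annotated Newick (`{regime,duration:...}` branch annotations)."""

        def fmt(node: _Node) -> str:
            if node.parent is None:
                inner = ",".join(fmt(c) for c in node.children)
                return f"({inner})"
            segs = self.segments[node.index]
            ann = ":".join(f"{r},{d:.{precision}g}" for d, r in segs)
            core = (
                node.label
                if node.is_leaf
                else "(" + ",".join(fmt(c) for c in node.children) + ")"
            )
            return f"{core}:{{{ann}}}"

        return fmt(self.tree.root) + ";"


# ----------------------------------------------------------------- functions

def vcv_matrix(tree: PhyloTree) -> PhyloCov:
    """Shared-path-length (Brownian motion) covariance of a tree's tips."""
    return tree.vcv()


def lambda_transform(C: PhyloCov | np.ndarray, lam: float, upper: float = 1.0):
    """Pagel's λ rescaling: off-diagonal entries multiplied by ``lam``.

    λ=1 leaves the matrix unchanged; λ=0 yields a star phylogeny (no
    phylogenetic signal).
    """
    if not (0.0 <= lam <= upper):
        raise ValueError(f"lambda must lie in [0, {upper}], got {lam}")
    if isinstance(C, PhyloCov):
        M = C.matrix
    else:
        M = np.asarray(C, dtype=float)
    out = M * lam
    np.fill_diagonal(out, np.diag(M))
    if isinstance(C, PhyloCov):
        return PhyloCov(out, list(C.taxa))
    return out


def prune(tree: PhyloTree, keep_taxa) -> PhyloTree:
    return tree.prune(keep_taxa)


def fix_zero_branches(tree: PhyloTree, epsilon: float = 0.1) -> PhyloTree:
    return tree.fix_zero_branches(epsilon)
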