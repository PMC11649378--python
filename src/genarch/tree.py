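"""Rooted dated phylogenies and the conditioning operations applied to them.

Trees are stored as a lightweight parent/child node structure with branch
lengths in millions of years (Myr); Newick reading and writing is delegated
to :mod:`dendropy`.  Node *ages* are measured in Myr before present, so the
root carries the largest age and (on an ultrametric tree) every tip sits at
age 0.  The conditioning operations mirror common pre-processing of dated
species trees: collapsing species pairs that diverged too recently to be
informative, collapsing very short internal branches into polytomies, and
mapping branches onto named clades (phyla, kingdoms) via their MRCAs.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "DatedTree",
    "read_newick",
    "write_newick",
    "collapse_recent_tips",
    "collapse_short_internal",
    "mrca",
    "assign_branches",
]


class TreeNode:
    """A node in a rooted tree; ``length`` is the subtending branch length."""

    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.parent: "TreeNode | None" = None
        self.children: list["TreeNode"] = []

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf() else f"{len(self.children)}-furcation"
        return f"<TreeNode {self.name or '?'} ({kind}, l={self.length})>"


class DatedTree:
    """A rooted tree with branch lengths; ages derived from the tip plane.

    Branch lengths are the primary data.  Ages are computed on demand as
    ``max tip depth − depth(node)``; for ultrametric trees this places all
    tips at age 0.
    """

    def __init__(self, root: TreeNode):
        self.root = root

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="default-rooted"
        )
        if dtree.is_rooted is False:
            raise ValueError("tree is explicitly unrooted; a rooted tree is required")

        def convert(dnode: dendropy.Node) -> TreeNode:
            name = None
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            node = TreeNode(name=name, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        root = convert(dtree.seed_node)
        root.length = None
        tree = cls(root)
        missing = [n for n in tree.branches() if n.length is None]
        if missing:
            raise ValueError("tree has branches without lengths")
        names = tree.tip_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate tip labels")
        return tree

    def to_newick(self) -> str:
        tns = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)

        def convert(node: TreeNode, dnode: dendropy.Node) -> None:
            dnode.edge.length = node.length
            if node.is_leaf():
                dnode.taxon = tns.new_taxon(node.name)
            else:
                dnode.label = node.name
                for child in node.children:
                    convert(child, dnode.new_child())

        convert(self.root, dtree.seed_node)
        dtree.is_rooted = True
        return dtree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".17g"
        )

    def copy(self) -> "DatedTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(name=node.name, length=node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return DatedTree(clone(self.root))

    # ----------------------------------------------------------- traversal
    def nodes(self) -> list[TreeNode]:
        """All nodes in preorder (root first)."""
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def tips(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf()]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes() if not n.is_leaf()]

    def branches(self) -> list[TreeNode]:
        """Non-root nodes in preorder; each node identifies its parent branch."""
        return [n for n in self.nodes() if n.parent is not None]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    # ------------------------------------------------------------ geometry
    def depths(self) -> dict[TreeNode, float]:
        depth: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.nodes():
            if node.parent is not None:
                depth[node] = depth[node.parent] + node.length
        return depth

    def ages(self) -> dict[TreeNode, float]:
        """Node ages in Myr before present (root age = max tip depth)."""
        depth = self.depths()
        total = max(depth[t] for t in self.tips())
        return {n: total - d for n, d in depth.items()}

    def root_age(self) -> float:
        return max(self.depths()[t] for t in self.tips())

    def total_length(self) -> float:
        return float(sum(n.length for n in self.branches()))

    def set_ages(self, ages: Mapping[TreeNode, float]) -> None:
        """Recompute branch lengths from a full node→age assignment."""
        for node in self.branches():
            node.length = ages[node.parent] - ages[node]
            if node.length < 0:
                raise ValueError("age assignment creates a negative branch length")

    def clade_key(self, node: TreeNode) -> str:
        """Stable node identifier: sorted descendant tip names joined by '|'."""
        return "|".join(sorted(self._tipset(node)))

    def _tipset(self, node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        out: set[str] = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf():
                out.add(cur.name)
            else:
                stack.extend(cur.children)
        return frozenset(out)

    def find_tip(self, name: str) -> TreeNode:
        for tip in self.tips():
            if tip.name == name:
                return tip
        raise KeyError(f"tip {name!r} not in tree")

    # ---------------------------------------------------------- operations
    def drop_tips(self, names: Iterable[str]) -> None:
        """Remove tips in place; unifurcations are suppressed, lengths merged."""
        doomed = set(names)
        unknown = doomed - set(self.tip_names())
        if unknown:
            raise KeyError(f"tips not in tree: {sorted(unknown)}")
        if len(doomed) >= self.n_tips:
            raise ValueError("cannot drop all tips")
        for tip in [t for t in self.tips() if t.name in doomed]:
            parent = tip.parent
            parent.children.remove(tip)
            # walk upward removing now-childless internals
            while parent is not None and not parent.children and parent.parent:
                grand = parent.parent
                grand.children.remove(parent)
                parent = grand
        self._suppress_unifurcations()

    def _suppress_unifurcations(self) -> None:
        while len(self.root.children) == 1:
            self.root = self.root.children[0]
            self.root.parent = None
            self.root.length = None
        for node in self.nodes():
            if node.parent is not None and len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent


# -------------------------------------------------------------------- I/O


def read_newick(source) -> DatedTree:
    """Read a rooted, branch-length-bearing Newick tree.

    ``source`` may be a Newick string, a path, or an open text stream.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        data = str(source)
        if "(" not in data:  # treat as a path
            with open(data) as handle:
                data = handle.read()
    return DatedTree.from_newick(data)


def write_newick(tree: DatedTree, dest=None) -> str:
    """Serialize to Newick; write to ``dest`` (path or stream) if given."""
    text = tree.to_newick()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as handle:
                handle.write(text)
    return text


# ---------------------------------------------------------- conditioning


def collapse_recent_tips(
    tree: DatedTree,
    threshold: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[DatedTree, list[str]]:
    """Collapse species pairs that diverged more recently than ``threshold`` Myr.

    Every cherry (node whose children include ≥2 tips) younger than the
    threshold is reduced to a single randomly retained tip; the rule is
    re-applied until no such cherry remains, so clusters of more than two
    recent tips also collapse to one representative.  Returns the new tree
    and the list of dropped tip names.  Strict inequality: a divergence at
    exactly ``threshold`` is kept.
    """
    rng = np.random.default_rng() if rng is None else rng
    tree = tree.copy()
    dropped: list[str] = []
    while True:
        ages = tree.ages()
        candidate = None
        for node in tree.internal_nodes():
            leaf_children = [c for c in node.children if c.is_leaf()]
            if len(leaf_children) >= 2 and ages[node] < threshold:
                candidate = (node, leaf_children)
                break
        if candidate is None:
            break
        node, leaves = candidate
        keep = leaves[int(rng.integers(len(leaves)))]
        losers = [leaf.name for leaf in leaves if leaf is not keep]
        tree.drop_tips(losers)
        dropped.extend(losers)
    return tree, dropped


def collapse_short_internal(tree: DatedTree, threshold: float = 1.0) -> DatedTree:
    """Collapse internal branches shorter than ``threshold`` Myr into polytomies.

    Branches are marked by their *original* lengths, then all marked nodes
    are spliced out (children re-attach to the nearest surviving ancestor,
    preserving node ages), so the result is order-independent.  Tip branches
    are never collapsed.
    """
    tree = tree.copy()
    marked = [
        n
        for n in tree.branches()
        if not n.is_leaf() and n.length < threshold
    ]
    for node in marked:
        parent = node.parent
        idx = parent.children.index(node)
        parent.children.pop(idx)
        for child in node.children:
            child.length += node.length
            child.parent = parent
            parent.children.append(child)
    return tree


def mrca(tree: DatedTree, tip_names: Iterable[str]) -> TreeNode:
    """Most recent common ancestor of a non-empty set of tips."""
    names = list(tip_names)
    if not names:
        raise ValueError("empty tip set has no MRCA")
    tips = {t.name: t for t in tree.tips()}
    missing = [n for n in names if n not in tips]
    if missing:
        raise KeyError(f"tips not in tree: {missing}")

    def root_path(node: TreeNode) -> list[TreeNode]:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    paths = [root_path(tips[n]) for n in names]
    anc = None
    for level in zip(*paths):
        if all(nd is level[0] for nd in level):
            anc = level[0]
        else:
            break
    return anc


def assign_branches(
    tree: DatedTree, clade_map: Mapping[str, str]
) -> dict[TreeNode, str]:
    """Assign each branch to a named clade, or ``"stem"`` if none applies.

    A branch (identified by its child node) belongs to clade *C* when its
    parent node is the MRCA of *C*'s mapped tips or a descendant of it.
    When clades are nested or their MRCAs overlap, the deepest (most recent)
    matching anchor wins.  Tips absent from ``clade_map`` simply never
    anchor a clade; their branches may still fall inside another clade's
    MRCA subtree.
    """
    present = set(tree.tip_names())
    groups: dict[str, list[str]] = {}
    for tip, label in clade_map.items():
        if tip in present:
            groups.setdefault(label, []).append(tip)
    depth = tree.depths()
    anchors = {label: mrca(tree, tips) for label, tips in groups.items()}

    def is_desc_or_equal(node: TreeNode, anc: TreeNode) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    out: dict[TreeNode, str] = {}
    for branch in tree.branches():
        best = None
        for label, anchor in anchors.items():
            if is_desc_or_equal(branch.parent, anchor):
                if best is None or depth[anchor] > depth[anchors[best]]:
                    best = label
        out[branch] = best if best is not None else "stem"
    return out


def clade_outliers(tree: DatedTree, clade_map: Mapping[str, str]) -> dict[str, list[str]]:
    """Tips inside a clade's MRCA subtree that are mapped to another clade."""
    present = set(tree.tip_names())
    groups: dict[str, set[str]] = {}
    for tip, label in clade_map.items():
        if tip in present:
            groups.setdefault(label, set()).add(tip)
    out: dict[str, list[str]] = {}
    for label, tips in groups.items():
        anchor = mrca(tree, tips)
        subtree = tree._tipset(anchor)
        stray = sorted(t for t in subtree if clade_map.get(t) not in (None, label))
        if stray:
            out[label] = stray
    return out
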