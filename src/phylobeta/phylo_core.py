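"""Rooted phylogenies and the branch-length primitives of phylogenetic beta diversity.

The quantities every index in this package is built from are Faith's
phylogenetic diversity (PD) — the total branch length of the rooted subtree
spanning a community's species — and the shared/unique branch-length
partition ``(a, b, c)`` for a pair of communities:

* ``a``: branch length lying on root-to-tip paths of *both* communities,
* ``b``: branch length on paths of the first community only,
* ``c``: branch length on paths of the second community only.

The PD convention here is root-inclusive: a community's branch set contains
every edge on a path from the root to one of its tips, including basal/stem
edges.  Two communities occupying the two basal clades of a tree therefore
share no branch length (``a = 0``) even though their paths meet at the root
node.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np

logger = logging.getLogger("phylobeta")

__all__ = [
    "RootedPhylogeny",
    "BranchPartition",
    "NewickError",
    "parse_newick",
    "write_newick",
    "faith_pd",
    "branch_partition",
]


class NewickError(ValueError):
    """Malformed or invalid newick input."""


@dataclass(frozen=True)
class BranchPartition:
    """Shared/unique branch lengths for a community pair.

    Satisfies ``a + b = PD(first)``, ``a + c = PD(second)`` and
    ``a + b + c = PD(union)``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"branch partition component {name} must be finite and >= 0, got {v}")

    def swapped(self) -> "BranchPartition":
        return BranchPartition(self.a, self.c, self.b)


class RootedPhylogeny:
    """A validated rooted tree with branch lengths and uniquely labelled tips.

    Wraps a :class:`dendropy.Tree` and pre-indexes, for every tip, the set of
    edges on its root-to-tip path, so that PD and branch-partition queries
    reduce to boolean operations on an edge x tip incidence matrix.
    """

    def __init__(self, tree: dendropy.Tree, *, missing_length_as_zero: bool = False):
        self._tree = tree
        self._validate_and_index(missing_length_as_zero)

    # ------------------------------------------------------------------ setup

    def _validate_and_index(self, missing_length_as_zero: bool) -> None:
        tree = self._tree
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            logger.warning(
                "tree root has %d children (basal multifurcation); treating it as rooted as written",
                len(root.child_nodes()),
            )

        edges = []  # one entry per non-root node: its subtending branch
        nodes = [n for n in tree.preorder_node_iter() if n is not root]
        for node in nodes:
            length = node.edge.length
            if length is None:
                if missing_length_as_zero:
                    length = 0.0
                else:
                    raise NewickError("branch length missing on an edge (strict mode)")
            length = float(length)
            if not math.isfinite(length) or length < 0:
                raise NewickError(f"branch length must be finite and >= 0, got {length}")
            edges.append(length)

        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf is root:
                # single-node tree: a bare root that is also the only tip
                label = leaf.taxon.label if leaf.taxon is not None else None
                if not label:
                    raise NewickError("tip with empty label")
                labels.append(label)
                continue
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise NewickError("tip with empty label")
            labels.append(label)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")

        node_index = {id(n): i for i, n in enumerate(nodes)}
        tip_labels = []
        tip_nodes = []
        for leaf in tree.leaf_node_iter():
            if leaf is root:
                continue
            tip_labels.append(leaf.taxon.label)
            tip_nodes.append(leaf)
        if not tip_labels and root.taxon is not None:
            tip_labels = [root.taxon.label]
            tip_nodes = [root]

        n_edges, n_tips = len(edges), len(tip_labels)
        incidence = np.zeros((max(n_edges, 1), max(n_tips, 1)), dtype=bool)
        for j, leaf in enumerate(tip_nodes):
            node = leaf
            while node is not root:
                incidence[node_index[id(node)], j] = True
                node = node.parent_node

        self._edge_lengths = np.asarray(edges, dtype=float)
        self._incidence = incidence[: max(n_edges, 1), :]
        self._tip_index: dict[str, int] = {lab: j for j, lab in enumerate(tip_labels)}
        self._tip_labels = tuple(tip_labels)

    # ------------------------------------------------------------- properties

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def total_length(self) -> float:
        return float(self._edge_lengths.sum())

    @property
    def branch_lengths(self) -> np.ndarray:
        """Lengths of all non-root edges (copy)."""
        return self._edge_lengths.copy()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    # -------------------------------------------------------------- internals

    def _tip_columns(self, tips: Iterable[str]) -> list[int]:
        cols = []
        missing = []
        for t in set(tips):
            j = self._tip_index.get(t)
            if j is None:
                missing.append(t)
            else:
                cols.append(j)
        if missing:
            raise KeyError(f"tips not on the tree: {sorted(missing)}")
        return cols

    def edge_mask(self, tips: Iterable[str]) -> np.ndarray:
        """Boolean mask over edges: which edges lie on a root-to-tip path of ``tips``."""
        cols = self._tip_columns(tips)
        if not cols:
            raise ValueError("tip set is empty")
        return self._incidence[:, cols].any(axis=1)

    # ------------------------------------------------------------- operations

    def pd(self, tips: Iterable[str]) -> float:
        """Faith's phylogenetic diversity of ``tips`` (root-inclusive)."""
        mask = self.edge_mask(tips)
        return float(self._edge_lengths[mask].sum())

    def relabelled(self, mapping: Mapping[str, str]) -> "RootedPhylogeny":
        """Return a copy of the tree with tip labels replaced via ``mapping``.

        Every tip label must appear in ``mapping`` and the new labels must be
        unique; topology and branch lengths are untouched.
        """
        new_labels = [mapping[lab] for lab in self._tip_labels]
        if len(set(new_labels)) != len(new_labels):
            raise ValueError("relabelling would create duplicate tip labels")
        clone = self._tree.clone(depth=1)
        taxa = dendropy.TaxonNamespace()
        clone.taxon_namespace = taxa
        for leaf in clone.leaf_node_iter():
            leaf.taxon = taxa.new_taxon(mapping[leaf.taxon.label])
        return RootedPhylogeny(clone)

    # ---------------------------------------------------------------- dunders

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<RootedPhylogeny: {self.n_tips} tips, total length {self.total_length:g}>"


# ---------------------------------------------------------------------- I/O


def parse_newick(text: str, *, missing_length_as_zero: bool = False) -> RootedPhylogeny:
    """Parse a single rooted newick tree with branch lengths.

    By default every edge must carry an explicit branch length; pass
    ``missing_length_as_zero=True`` to substitute 0 instead (logged).
    The root's own (absent) subtending branch is exempt.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickError("empty newick input")
    if not text.strip().endswith(";"):
        raise NewickError("newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickError(f"could not parse newick: {exc}") from exc
    if missing_length_as_zero:
        logger.info("missing branch lengths will be read as 0")
    return RootedPhylogeny(tree, missing_length_as_zero=missing_length_as_zero)


def write_newick(tree: RootedPhylogeny) -> str:
    """Serialise to newick; the output reparses to an isomorphic tree."""
    out = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,
        unquoted_underscores=True,
    )
    return out.strip() + "\n"


# ----------------------------------------------------------------- PD kernel


def faith_pd(tree: RootedPhylogeny, tips: Iterable[str]) -> float:
    """Faith's PD: total branch length on root-to-tip paths of ``tips``.

    Raises ``ValueError`` for an empty tip set and ``KeyError`` for tips not
    on the tree.  Equals ``tree.total_length`` when ``tips`` covers all tips.
    """
    return tree.pd(tips)


def branch_partition(
    tree: RootedPhylogeny,
    tips_j: Iterable[str],
    tips_k: Iterable[str],
) -> BranchPartition:
    """Shared/unique branch lengths ``(a, b, c)`` for two communities.

    Computed through the PD identities
    ``a = PD(j) + PD(k) - PD(j U k)``, ``b = PD(j U k) - PD(k)``,
    ``c = PD(j U k) - PD(j)``, which coincide with classifying each edge by
    whether it lies on a root-to-tip path of either community.
    """
    tips_j = set(tips_j)
    tips_k = set(tips_k)
    pd_j = tree.pd(tips_j)
    pd_k = tree.pd(tips_k)
    pd_union = tree.pd(tips_j | tips_k)
    # exact-arithmetic identities; clamp float dust at 0
    a = max(pd_j + pd_k - pd_union, 0.0)
    b = max(pd_union - pd_k, 0.0)
    c = max(pd_union - pd_j, 0.0)
    return BranchPartition(a, b, c)
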