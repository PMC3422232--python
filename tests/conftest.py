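"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from phylobeta import RootedPhylogeny, build_fixture, parse_newick

# Reference table for the six-community example: branch-length partition
# (a, b, c) and the six printed index values per pair, at 3 decimals.
TABLE1 = [
    # pair,      a, b, c, phylosor, ps_turn, ps_pd, unifrac, uf_turn, uf_pd
    (("A", "B"), 5, 1, 1, 0.166, 0.166, 0.000, 0.286, 0.286, 0.000),
    (("A", "C"), 5, 1, 4, 0.333, 0.166, 0.167, 0.500, 0.286, 0.214),
    (("A", "D"), 5, 1, 5, 0.375, 0.166, 0.209, 0.545, 0.286, 0.259),
    (("A", "E"), 5, 1, 7, 0.444, 0.166, 0.278, 0.615, 0.286, 0.329),
    (("A", "F"), 5, 1, 8, 0.474, 0.166, 0.308, 0.643, 0.286, 0.357),
    (("B", "C"), 6, 0, 3, 0.200, 0.000, 0.200, 0.333, 0.000, 0.333),
    (("B", "D"), 6, 0, 4, 0.250, 0.000, 0.250, 0.400, 0.000, 0.400),
    (("B", "E"), 6, 0, 6, 0.333, 0.000, 0.333, 0.500, 0.000, 0.500),
    (("B", "F"), 6, 0, 7, 0.368, 0.000, 0.368, 0.538, 0.000, 0.538),
]

# Printed values are 3-decimal truncations/roundings (e.g. 0.166 for 1/6),
# so full-precision results agree with them to within one unit in the third
# decimal place.
PRINTED_TOL = 1e-3


@pytest.fixture(scope="session")
def fig1a():
    return build_fixture("fig1a")


@pytest.fixture(scope="session")
def fig1b():
    return build_fixture("fig1b")


@pytest.fixture(scope="session")
def fig2_toy():
    return build_fixture("fig2_toy")


def site_tips(table: pd.DataFrame) -> dict[str, set[str]]:
    return {s: set(table.columns[table.loc[s].to_numpy() > 0]) for s in table.index}


# --------------------------------------------------------------- oracles


def per_edge_partition(tree: RootedPhylogeny, tips_j, tips_k):
    """Brute-force (a, b, c): classify every edge by walking tip-to-root paths.

    Independent of the incidence-matrix/PD-identity implementation: uses
    direct dendropy parent-pointer traversal and fsum.
    """
    dt = tree.dendropy_tree
    root = dt.seed_node

    def edge_ids(tips):
        tips = set(tips)
        edges = set()
        for leaf in dt.leaf_node_iter():
            if leaf.taxon is not None and leaf.taxon.label in tips:
                node = leaf
                while node is not root:
                    edges.add(id(node))
                    node = node.parent_node
        return edges

    lengths = {id(n): float(n.edge.length) for n in dt.preorder_node_iter() if n is not root}
    ej, ek = edge_ids(tips_j), edge_ids(tips_k)
    a = math.fsum(lengths[e] for e in ej & ek)
    b = math.fsum(lengths[e] for e in ej - ek)
    c = math.fsum(lengths[e] for e in ek - ej)
    return a, b, c


def closed_form_nestedness(a: float, b: float, c: float, family: str) -> float:
    """Closed-form nestedness/PD components, used as oracles for subtraction."""
    lo, hi = min(b, c), max(b, c)
    if a == 0:
        # disjoint communities are pure turnover unless one is empty,
        # in which case the pair is maximally nested
        return 1.0 if lo == 0 and hi > 0 else 0.0
    if family == "sorensen":
        return (hi - lo) / (2 * a + lo + hi) * (a / (a + lo))
    if family == "jaccard":
        return (hi - lo) / (a + lo + hi) * (a / (a + 2 * lo))
    raise ValueError(family)


def random_tree(rng: np.random.Generator, n_tips: int, *, integer_lengths: bool = False) -> RootedPhylogeny:
    """Random rooted binary topology with random branch lengths, via newick."""

    def grow(labels: list[str]) -> str:
        if len(labels) == 1:
            return labels[0]
        k = int(rng.integers(1, len(labels)))
        idx = rng.permutation(len(labels))
        left = [labels[i] for i in idx[:k]]
        right = [labels[i] for i in idx[k:]]
        return f"({grow(left)}:{length()},{grow(right)}:{length()})"

    def length() -> str:
        if integer_lengths:
            return str(int(rng.integers(0, 5)))
        return repr(float(rng.uniform(0.0, 2.0)))

    labels = [f"x{i}" for i in range(n_tips)]
    return parse_newick(grow(labels) + ";")


def random_tip_set(rng: np.random.Generator, tree: RootedPhylogeny, min_size: int = 1) -> set[str]:
    labels = list(tree.tip_labels)
    size = int(rng.integers(min_size, len(labels) + 1))
    return set(rng.choice(labels, size=size, replace=False))
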