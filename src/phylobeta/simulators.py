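"""Random trees, simulated community pairs, and archetypal fixtures.

Two classical random-topology models are provided:

* **Yule** (pure birth): starting from two lineages, a uniformly chosen
  extant lineage splits at each event; with exponential waiting times
  (total rate proportional to the number of lineages) the result is an
  ultrametric tree.  Yule trees tend to be relatively balanced.
* **PDA** (proportional to distinguishable arrangements): the uniform
  distribution over labelled rooted binary topologies, built by attaching
  each new tip to a uniformly chosen insertion point (any existing branch
  or a new root) of the growing tree.  PDA trees tend to be imbalanced.

The community-pair simulator draws species counts ``a`` (shared), ``b`` and
``c`` (unique) independently and uniformly from ``[abc_min, abc_max]``
(defaults 1..100), rejecting triples with ``a + b + c`` above the pool size
(default 100 species) so the pair can be realised by sampling distinct
species without replacement.  The study driver evaluates all six
compositional and six phylogenetic indices for every pair on one regional
Yule tree and one regional PDA tree, and summarises the Pearson
correlations between matched compositional/phylogenetic indices and
between tree models.

``build_fixture`` reconstructs the archetypal examples used throughout the
documentation and tests: a balanced eight-tip unit-branch-length tree with
a clustered and an interleaved community pair, and a ten-species
unit-branch-length tree with six communities whose pairwise branch
partitions realise a fixed reference table of (a, b, c) values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .beta_decomp import (
    CountPartition,
    jaccard_decomposition,
    phylosor_decomposition,
    sorensen_decomposition,
    unifrac_decomposition,
)
from .phylo_core import RootedPhylogeny, branch_partition, parse_newick

logger = logging.getLogger("phylobeta")

__all__ = [
    "SimulationConfig",
    "yule_tree",
    "pda_tree",
    "sample_community_pair",
    "run_simulation_study",
    "build_fixture",
    "colless_index",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the community-pair simulation study.

    ``branch_length_mode=None`` uses each tree model's natural default:
    exponential waiting times for Yule, unit lengths for PDA.
    """

    pool_size: int = 100
    n_pairs: int = 10_000
    abc_min: int = 1
    abc_max: int = 100
    tree_model: str = "pda"
    branch_length_mode: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 3:
            raise ValueError("pool_size must be >= 3")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.abc_min < 1 or self.abc_max < self.abc_min:
            raise ValueError("need 1 <= abc_min <= abc_max")
        if self.tree_model not in ("yule", "pda"):
            raise ValueError("tree_model must be 'yule' or 'pda'")
        if self.branch_length_mode not in (None, "unit", "exponential"):
            raise ValueError("branch_length_mode must be 'unit', 'exponential' or None")
        if 3 * self.abc_min > self.pool_size:
            raise ValueError("infeasible: 3 * abc_min exceeds the species pool")


# ------------------------------------------------------------ tree builders


class _SimNode:
    """Minimal mutable node used only while growing a random topology."""

    __slots__ = ("children", "label", "length")

    def __init__(self, label: str | None = None, length: float = 1.0):
        self.children: list["_SimNode"] = []
        self.label = label
        self.length = length


def _to_newick(node: _SimNode, is_root: bool = False) -> str:
    if node.children:
        inner = ",".join(_to_newick(ch) for ch in node.children)
        body = f"({inner})"
    else:
        body = node.label or ""
    return body + (";" if is_root else f":{node.length!r}")


def _finish(root: _SimNode, tips: Sequence[_SimNode], n_tips: int, rng: np.random.Generator) -> RootedPhylogeny:
    labels = [f"s{i + 1}" for i in range(n_tips)]
    for tip, idx in zip(tips, rng.permutation(n_tips)):
        tip.label = labels[idx]
    return parse_newick(_to_newick(root, is_root=True))


def _all_nodes(root: _SimNode) -> list[_SimNode]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return out


def yule_tree(
    n_tips: int,
    rng: np.random.Generator,
    branch_length_mode: str = "exponential",
) -> RootedPhylogeny:
    """Pure-birth (Yule) random tree on ``n_tips`` labelled tips.

    With ``branch_length_mode='exponential'`` the tree is ultrametric, built
    from exponential inter-speciation waiting times at total rate equal to
    the current lineage count; ``'unit'`` sets every branch length to 1.
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    root = _SimNode()
    active = []
    for _ in range(2):
        child = _SimNode(length=0.0)
        root.children.append(child)
        active.append(child)
    while len(active) < n_tips:
        k = len(active)
        wait = float(rng.exponential(1.0 / k))
        for node in active:
            node.length += wait
        parent = active.pop(int(rng.integers(k)))
        for _ in range(2):
            child = _SimNode(length=0.0)
            parent.children.append(child)
            active.append(child)
    final = float(rng.exponential(1.0 / n_tips))
    for node in active:
        node.length += final
    if branch_length_mode == "unit":
        for node in _all_nodes(root):
            node.length = 1.0
    elif branch_length_mode != "exponential":
        raise ValueError("branch_length_mode must be 'unit' or 'exponential'")
    return _finish(root, active, n_tips, rng)


def pda_tree(
    n_tips: int,
    rng: np.random.Generator,
    branch_length_mode: str = "unit",
) -> RootedPhylogeny:
    """Uniform (PDA) random labelled rooted binary topology on ``n_tips`` tips.

    Each new tip attaches to an insertion point chosen uniformly among the
    current branches plus the position above the root, which makes all
    (2n-3)!! labelled rooted topologies equally likely.  Branch lengths are
    all 1 (``'unit'``) or i.i.d. exponential(1) (``'exponential'``).
    """
    if n_tips < 2:
        raise ValueError("a PDA tree needs at least 2 tips")
    root = _SimNode()
    first, second = _SimNode(), _SimNode()
    root.children = [first, second]
    tips = [first, second]
    attachable = [first, second]  # non-root nodes, i.e. existing branches
    parent_of = {id(first): root, id(second): root}

    for _ in range(n_tips - 2):
        new_tip = _SimNode()
        pos = int(rng.integers(len(attachable) + 1))
        if pos == len(attachable):
            # new root above the old one
            new_root = _SimNode()
            new_root.children = [root, new_tip]
            parent_of[id(root)] = new_root
            parent_of[id(new_tip)] = new_root
            attachable.append(root)
            root = new_root
        else:
            target = attachable[pos]
            parent = parent_of[id(target)]
            mid = _SimNode()
            parent.children[parent.children.index(target)] = mid
            mid.children = [target, new_tip]
            parent_of[id(mid)] = parent
            parent_of[id(target)] = mid
            parent_of[id(new_tip)] = mid
            attachable.append(mid)
        attachable.append(new_tip)
        tips.append(new_tip)

    if branch_length_mode == "unit":
        pass  # _SimNode defaults to length 1
    elif branch_length_mode == "exponential":
        for node in _all_nodes(root):
            node.length = float(rng.exponential(1.0))
    else:
        raise ValueError("branch_length_mode must be 'unit' or 'exponential'")
    return _finish(root, tips, n_tips, rng)


def colless_index(tree: RootedPhylogeny) -> int:
    """Colless imbalance: sum over bifurcating nodes of |left - right| tip counts."""
    total = 0

    def count(node) -> int:
        nonlocal total
        children = node.child_nodes()
        if not children:
            return 1
        sizes = [count(ch) for ch in children]
        if len(sizes) == 2:
            total += abs(sizes[0] - sizes[1])
        return sum(sizes)

    count(tree.dendropy_tree.seed_node)
    return total


# ------------------------------------------------------- community sampling


def sample_community_pair(
    pool: Sequence[str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[set[str], set[str], CountPartition]:
    """Draw one community pair with uniform shared/unique species counts.

    ``a, b, c`` are drawn independently and uniformly on
    ``[abc_min, abc_max]``; the whole triple is redrawn until
    ``a + b + c <= |pool|`` so the communities can be filled with distinct
    species sampled without replacement.
    """
    pool = list(pool)
    if 3 * cfg.abc_min > len(pool):
        raise ValueError("infeasible: 3 * abc_min exceeds the species pool")
    while True:
        a, b, c = (int(x) for x in rng.integers(cfg.abc_min, cfg.abc_max + 1, size=3))
        if a + b + c <= len(pool):
            break
    chosen = rng.choice(len(pool), size=a + b + c, replace=False)
    shared = {pool[i] for i in chosen[:a]}
    unique_j = {pool[i] for i in chosen[a : a + b]}
    unique_k = {pool[i] for i in chosen[a + b :]}
    return shared | unique_j, shared | unique_k, CountPartition(a, b, c)


_PBD_COLUMNS = ("phylosor", "phylosor_turn", "phylosor_pd", "unifrac", "unifrac_turn", "unifrac_pd")
_CBD_COLUMNS = ("beta_sor", "beta_sim", "beta_sne", "beta_jac", "beta_jtu", "beta_jne")
_MATCHED = list(zip(_PBD_COLUMNS, _CBD_COLUMNS))


def run_simulation_study(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate community pairs and compare compositional vs phylogenetic indices.

    One regional Yule tree and one regional PDA tree are generated on the
    species pool; every simulated pair is scored with the six compositional
    indices and, per tree, the six phylogenetic ones.  Returns
    ``(records, summary)`` where ``summary`` holds Pearson correlations of
    matched index pairs per tree model plus Yule-vs-PDA correlations of
    each phylogenetic quantity.
    """
    rng = np.random.default_rng(cfg.seed)
    trees = {
        "yule": yule_tree(cfg.pool_size, rng, cfg.branch_length_mode or "exponential"),
        "pda": pda_tree(cfg.pool_size, rng, cfg.branch_length_mode or "unit"),
    }
    pool = [f"s{i + 1}" for i in range(cfg.pool_size)]

    rows = []
    for _ in range(cfg.n_pairs):
        comm_j, comm_k, counts = sample_community_pair(pool, cfg, rng)
        sor = sorensen_decomposition(counts)
        jac = jaccard_decomposition(counts)
        row = {
            "a": counts.a, "b": counts.b, "c": counts.c,
            "beta_sor": sor.total, "beta_sim": sor.turnover, "beta_sne": sor.pd_component,
            "beta_jac": jac.total, "beta_jtu": jac.turnover, "beta_jne": jac.pd_component,
        }
        for model, tree in trees.items():
            bp = branch_partition(tree, comm_j, comm_k)
            ps = phylosor_decomposition(bp)
            uf = unifrac_decomposition(bp)
            row.update({
                f"phylosor_{model}": ps.total,
                f"phylosor_turn_{model}": ps.turnover,
                f"phylosor_pd_{model}": ps.pd_component,
                f"unifrac_{model}": uf.total,
                f"unifrac_turn_{model}": uf.turnover,
                f"unifrac_pd_{model}": uf.pd_component,
            })
        rows.append(row)
    records = pd.DataFrame(rows)

    summary_rows = []
    for model in ("pda", "yule"):
        for pbd_col, cbd_col in _MATCHED:
            r = stats.pearsonr(records[f"{pbd_col}_{model}"], records[cbd_col]).statistic
            summary_rows.append(("pbd_vs_cbd", model, pbd_col, cbd_col, float(r)))
    for pbd_col in _PBD_COLUMNS:
        r = stats.pearsonr(records[f"{pbd_col}_yule"], records[f"{pbd_col}_pda"]).statistic
        summary_rows.append(("yule_vs_pda", "both", pbd_col, pbd_col, float(r)))
    summary = pd.DataFrame(
        summary_rows, columns=["comparison", "tree_model", "index_x", "index_y", "pearson_r"]
    )
    return records, summary


# ----------------------------------------------------------------- fixtures

# Fully balanced 8-tip tree, every branch length 1 (total length 14).
_FIG1_NEWICK = (
    "(((t1:1,t2:1):1,(t3:1,t4:1):1):1,"
    "((t5:1,t6:1):1,(t7:1,t8:1):1):1);"
)

# Ten-species tree, every branch length 1, hosting the six-community example.
_TOY_NEWICK = (
    "((s1:1,(s8:1,(s9:1,(s2:1,s3:1):1):1):1):1,"
    "((s4:1,s5:1):1,(s6:1,s7:1):1):1,s10:1);"
)

_TOY_COMMUNITIES = {
    "A": ["s1", "s2"],
    "B": ["s2", "s3"],
    "C": ["s2", "s3", "s4"],
    "D": ["s2", "s3", "s4", "s5"],
    "E": ["s2", "s3", "s4", "s5", "s6"],
    "F": ["s2", "s3", "s4", "s5", "s6", "s7"],
}


def _table(species: Sequence[str], communities: dict[str, Iterable[str]]) -> pd.DataFrame:
    table = pd.DataFrame(0, index=list(communities), columns=list(species), dtype=np.int8)
    for site, present in communities.items():
        table.loc[site, list(present)] = 1
    table.index.name = "site"
    return table


def build_fixture(name: str) -> tuple[RootedPhylogeny, pd.DataFrame]:
    """Archetypal tree + community-table fixtures.

    * ``fig1a``: balanced 8-tip unit tree; the two communities occupy the two
      basal clades (phylogenetically clustered pair; PD 7 each, PhyloSor 1).
    * ``fig1b``: same tree; each community takes one tip of every cherry
      (interleaved/overdispersed pair; PD 10 each, PhyloSor 0.4).
    * ``fig2_toy``: ten-species unit tree with six communities A-F whose
      pairwise branch partitions span a turnover-constant series (A-B..A-F)
      and a fully nested series (B-C..B-F).
    """
    if name == "fig1a":
        tree = parse_newick(_FIG1_NEWICK)
        table = _table(tree.tip_labels, {"A": ["t1", "t2", "t3", "t4"], "B": ["t5", "t6", "t7", "t8"]})
        return tree, table
    if name == "fig1b":
        tree = parse_newick(_FIG1_NEWICK)
        table = _table(tree.tip_labels, {"A": ["t1", "t3", "t5", "t7"], "B": ["t2", "t4", "t6", "t8"]})
        return tree, table
    if name == "fig2_toy":
        tree = parse_newick(_TOY_NEWICK)
        species = [f"s{i + 1}" for i in range(10)]
        return tree, _table(species, _TOY_COMMUNITIES)
    raise ValueError(f"unknown fixture {name!r}; expected fig1a, fig1b or fig2_toy")
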