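"""Additive decomposition of compositional and phylogenetic beta diversity.

Compositional beta diversity (CBD) between two sites is measured by the
Sorensen and Jaccard dissimilarity families, each split additively into a
*true turnover* component and a *nestedness* component (Baselga's
partition).  With species counts ``a`` (shared), ``b`` and ``c`` (unique to
each site), and ``m = min(b, c)``:

    Sorensen family:  beta_sor = (b + c) / (2a + b + c)
                      beta_sim = m / (a + m)            (turnover)
                      beta_sne = beta_sor - beta_sim     (nestedness)

    Jaccard family:   beta_jac = (b + c) / (a + b + c)
                      beta_jtu = 2m / (a + 2m)           (turnover)
                      beta_jne = beta_jac - beta_jtu     (nestedness)

Phylogenetic beta diversity (PBD) applies the same formulas to the
shared/unique *branch lengths* of a rooted regional tree: the Sorensen form
of the branch-length partition is the PhyloSor dissimilarity, the Jaccard
form is UniFrac.  The turnover component (PhyloSor_Turn, UniFrac_Turn)
measures replacement of lineages independent of phylogenetic-diversity
differences; the remainder (PhyloSor_PD, UniFrac_PD) is the dissimilarity
attributable to the PD gradient between the communities.

The second component is always computed by subtraction ``total - turnover``
so additivity holds exactly in floating point; the closed forms serve as
independent oracles in the test suite.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .phylo_core import BranchPartition, RootedPhylogeny, branch_partition

logger = logging.getLogger("phylobeta")

__all__ = [
    "CountPartition",
    "DecompositionResult",
    "UndefinedIndexError",
    "sorensen_decomposition",
    "jaccard_decomposition",
    "phylosor_decomposition",
    "unifrac_decomposition",
    "pairwise_pbd",
    "pairwise_cbd",
    "as_incidence",
]

FAMILIES = ("sorensen", "jaccard")


class UndefinedIndexError(ValueError):
    """The dissimilarity index is undefined (e.g. both communities empty)."""


@dataclass(frozen=True)
class CountPartition:
    """Species counts shared/unique to two sites."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a nonnegative integer, got {v}")


@dataclass(frozen=True)
class DecompositionResult:
    """One index family's (total, turnover, pd/nestedness) triple for a pair.

    ``total == turnover + pd_component`` holds exactly; for compositional
    input the third field is the nestedness-resultant component.
    """

    family: str
    total: float
    turnover: float
    pd_component: float


Partition = Union[BranchPartition, CountPartition, tuple]


def _abc(p: Partition) -> tuple[float, float, float]:
    if isinstance(p, (BranchPartition, CountPartition)):
        return float(p.a), float(p.b), float(p.c)
    a, b, c = p
    return float(a), float(b), float(c)


def _decompose(a: float, b: float, c: float, family: str) -> tuple[float, float, float]:
    if a + b + c <= 0:
        raise UndefinedIndexError("a + b + c must be positive for a defined index")
    # evaluate on (lo, hi) so the result is bitwise symmetric in (b, c)
    lo, hi = (b, c) if b <= c else (c, b)
    if family == "sorensen":
        total = (lo + hi) / (2 * a + lo + hi)
        turnover = lo / (a + lo) if lo > 0 else 0.0
    elif family == "jaccard":
        total = (lo + hi) / (a + lo + hi)
        turnover = 2 * lo / (a + 2 * lo) if lo > 0 else 0.0
    else:
        raise ValueError(f"unknown family {family!r}")
    # turnover is a function of (a, lo) only, and turnover <= total with
    # equality exactly at lo == hi; enforce both identities at the ulp level
    # on total, never on turnover, so turnover stays bitwise invariant to hi
    if lo == hi and lo > 0:
        total = turnover
    else:
        total = max(total, turnover)
    return total, turnover, total - turnover


def sorensen_decomposition(p: Partition) -> DecompositionResult:
    """Sorensen dissimilarity split into turnover (Simpson) and nestedness."""
    total, turn, nest = _decompose(*_abc(p), "sorensen")
    return DecompositionResult("sorensen", total, turn, nest)


def jaccard_decomposition(p: Partition) -> DecompositionResult:
    """Jaccard dissimilarity split into turnover and nestedness."""
    total, turn, nest = _decompose(*_abc(p), "jaccard")
    return DecompositionResult("jaccard", total, turn, nest)


def phylosor_decomposition(bp: Partition) -> DecompositionResult:
    """PhyloSor dissimilarity of a branch partition, split additively.

    PhyloSor double-weights the shared branch length (its denominator is the
    sum of the two communities' PD), so it is the Sorensen form on branch
    lengths; turnover is PhyloSor_Turn and the remainder PhyloSor_PD.
    """
    total, turn, pdc = _decompose(*_abc(bp), "sorensen")
    return DecompositionResult("sorensen", total, turn, pdc)


def unifrac_decomposition(bp: Partition) -> DecompositionResult:
    """UniFrac dissimilarity of a branch partition, split additively.

    UniFrac is the branch length unique to either community relative to the
    total branch length spanning both — the Jaccard form on branch lengths.
    """
    total, turn, pdc = _decompose(*_abc(bp), "jaccard")
    return DecompositionResult("jaccard", total, turn, pdc)


# ------------------------------------------------------------ table plumbing


def as_incidence(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a sites x species table to binary incidence (any value > 0)."""
    numeric = table.apply(pd.to_numeric, errors="raise")
    if ((numeric.to_numpy() != 0) & (numeric.to_numpy() != 1)).any():
        logger.info("non-binary abundances collapsed to presence/absence")
    return (numeric > 0).astype(np.int8)


def _site_tips(table: pd.DataFrame) -> dict[str, set[str]]:
    inc = as_incidence(table)
    return {site: set(inc.columns[inc.loc[site].to_numpy() > 0]) for site in inc.index}


def _prune_or_fail(species: set[str], tree: RootedPhylogeny, prune_missing: bool) -> set[str]:
    on_tree = set(tree.tip_labels)
    missing = species - on_tree
    if not missing:
        return species
    if prune_missing:
        logger.warning("pruning %d species absent from the tree", len(missing))
        return species & on_tree
    raise KeyError(f"species not on the tree: {sorted(missing)[:10]} (pass prune_missing=True to drop)")


def _families(family: str) -> tuple[str, ...]:
    if family == "both":
        return FAMILIES
    if family in FAMILIES:
        return (family,)
    raise ValueError(f"family must be one of {FAMILIES + ('both',)}, got {family!r}")


def pairwise_pbd(
    tree: RootedPhylogeny,
    table: pd.DataFrame,
    family: str = "both",
    *,
    prune_missing: bool = False,
) -> pd.DataFrame:
    """Phylogenetic beta-diversity decomposition for every unordered site pair.

    Returns a long-format frame with columns ``site_i, site_j, family,
    total, turnover, pd_component``.  An empty site yields NaN rows with a
    logged warning rather than failing the whole matrix.
    """
    fams = _families(family)
    tips_by_site = _site_tips(table)
    all_species = set().union(*tips_by_site.values()) if tips_by_site else set()
    kept = _prune_or_fail(all_species, tree, prune_missing)
    tips_by_site = {s: t & kept for s, t in tips_by_site.items()}

    rows = []
    for si, sj in itertools.combinations(table.index, 2):
        ti, tj = tips_by_site[si], tips_by_site[sj]
        if not ti or not tj:
            logger.warning("empty community in pair (%s, %s); emitting NaN", si, sj)
            for fam in fams:
                rows.append((si, sj, fam, math.nan, math.nan, math.nan))
            continue
        bp = branch_partition(tree, ti, tj)
        for fam in fams:
            dec = phylosor_decomposition(bp) if fam == "sorensen" else unifrac_decomposition(bp)
            rows.append((si, sj, fam, dec.total, dec.turnover, dec.pd_component))
    return pd.DataFrame(rows, columns=["site_i", "site_j", "family", "total", "turnover", "pd_component"])


def pairwise_cbd(table: pd.DataFrame, family: str = "both") -> pd.DataFrame:
    """Compositional beta-diversity decomposition for every unordered site pair.

    Same schema as :func:`pairwise_pbd`; ``pd_component`` holds the
    nestedness-resultant component.
    """
    fams = _families(family)
    tips_by_site = _site_tips(table)
    rows = []
    for si, sj in itertools.combinations(table.index, 2):
        ti, tj = tips_by_site[si], tips_by_site[sj]
        if not ti or not tj:
            logger.warning("empty community in pair (%s, %s); emitting NaN", si, sj)
            for fam in fams:
                rows.append((si, sj, fam, math.nan, math.nan, math.nan))
            continue
        p = CountPartition(len(ti & tj), len(ti - tj), len(tj - ti))
        for fam in fams:
            dec = sorensen_decomposition(p) if fam == "sorensen" else jaccard_decomposition(p)
            rows.append((si, sj, fam, dec.total, dec.turnover, dec.pd_component))
    return pd.DataFrame(rows, columns=["site_i", "site_j", "family", "total", "turnover", "pd_component"])


def square_matrices(long_table: pd.DataFrame, component: str = "total") -> dict[str, pd.DataFrame]:
    """Pivot a long pairwise table into symmetric square matrices per family."""
    out = {}
    for fam, sub in long_table.groupby("family"):
        sites = sorted(set(sub["site_i"]) | set(sub["site_j"]))
        mat = pd.DataFrame(0.0, index=sites, columns=sites)
        for _, r in sub.iterrows():
            mat.loc[r["site_i"], r["site_j"]] = r[component]
            mat.loc[r["site_j"], r["site_i"]] = r[component]
        out[str(fam)] = mat
    return out
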