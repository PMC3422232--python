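"""Richness- and CBD-preserving null model with standardized effect sizes.

The null hypothesis asked of a phylogenetic beta-diversity (PBD) value is:
is the observed phylogenetic dissimilarity larger or smaller than expected
*given the compositional dissimilarity* of the two communities?  The
randomization therefore shuffles species across the tips of the regional
phylogeny while leaving the community table untouched — per-site richness
and every compositional index are preserved exactly, and only the position
of each species on the tree varies.

For each pair and each index component, the standardized effect size is

    SES = (X_obs - mean(X_null)) / sd(X_null)

with the sample (n-1) standard deviation.  |SES| > 1.96 conventionally
flags PBD that is higher/lower than expected from composition alone.  The
observed value is not appended to the null vector (pure Monte-Carlo null);
when the null distribution is degenerate (sd = 0) the SES is reported as
NaN and both significance flags are False.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta_decomp import _families, pairwise_pbd
from .phylo_core import RootedPhylogeny

logger = logging.getLogger("phylobeta")

__all__ = [
    "NullDistribution",
    "SESResult",
    "shuffle_tip_labels",
    "null_pbd_distribution",
    "standardized_effect_size",
    "ses_table",
    "SES_CUTOFF",
    "DEFAULT_N_RAND",
]

SES_CUTOFF = 1.96
DEFAULT_N_RAND = 9999
COMPONENTS = ("total", "turnover", "pd_component")


@dataclass
class NullDistribution:
    """Null values of one index component for one site pair."""

    site_i: str
    site_j: str
    family: str
    component: str
    observed: float
    null_values: np.ndarray
    n_rand: int
    seed: int

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.null_values.shape != (self.n_rand,):
            raise ValueError("null vector length must equal the randomization count")


@dataclass(frozen=True)
class SESResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when the null distribution is degenerate
    significant_high: bool
    significant_low: bool
    sd_convention: str = "sample"  # n-1 denominator


def shuffle_tip_labels(tree: RootedPhylogeny, rng: np.random.Generator) -> RootedPhylogeny:
    """Return a tree with identical shape/lengths and permuted tip labels."""
    labels = list(tree.tip_labels)
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    return tree.relabelled(dict(zip(labels, permuted)))


def null_pbd_distribution(
    tree: RootedPhylogeny,
    table: pd.DataFrame,
    n_rand: int,
    seed: int,
    family: str = "both",
    *,
    prune_missing: bool = False,
) -> list[NullDistribution]:
    """Null distributions of every PBD component for every site pair.

    Runs ``n_rand`` independent tip shuffles; deterministic given
    ``(seed, n_rand)``.  Input validity is checked once (the observed
    computation) before the randomization loop.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    observed = pairwise_pbd(tree, table, family, prune_missing=prune_missing)
    rng = np.random.default_rng(seed)
    null = np.empty((len(observed), len(COMPONENTS), n_rand), dtype=float)
    for r in range(n_rand):
        shuffled = shuffle_tip_labels(tree, rng)
        perm = pairwise_pbd(shuffled, table, family, prune_missing=prune_missing)
        null[:, :, r] = perm[list(COMPONENTS)].to_numpy()

    out = []
    for row_idx, row in observed.iterrows():
        for comp_idx, comp in enumerate(COMPONENTS):
            out.append(
                NullDistribution(
                    site_i=row["site_i"],
                    site_j=row["site_j"],
                    family=row["family"],
                    component=comp,
                    observed=float(row[comp]),
                    null_values=null[row_idx, comp_idx],
                    n_rand=n_rand,
                    seed=seed,
                )
            )
    return out


def standardized_effect_size(dist: NullDistribution) -> SESResult:
    """SES of an observed value against its null distribution."""
    values = dist.null_values
    if values.size == 0:
        raise ValueError("null distribution is empty")
    mean = float(np.mean(values))
    degenerate = values.size < 2 or np.max(values) == np.min(values)
    sd = 0.0 if degenerate else float(np.std(values, ddof=1))
    if sd > 0:
        ses = (dist.observed - mean) / sd
        return SESResult(dist.observed, mean, sd, ses, ses > SES_CUTOFF, ses < -SES_CUTOFF)
    logger.info(
        "degenerate null (sd = 0) for pair (%s, %s) %s/%s; SES undefined",
        dist.site_i, dist.site_j, dist.family, dist.component,
    )
    return SESResult(dist.observed, mean, 0.0, math.nan, False, False)


def ses_table(
    tree: RootedPhylogeny,
    table: pd.DataFrame,
    n_rand: int = DEFAULT_N_RAND,
    seed: int = 0,
    family: str = "both",
    *,
    prune_missing: bool = False,
) -> pd.DataFrame:
    """Long-format SES table: one row per pair x family x component."""
    _families(family)  # validate early
    dists = null_pbd_distribution(tree, table, n_rand, seed, family, prune_missing=prune_missing)
    rows = []
    for d in dists:
        s = standardized_effect_size(d)
        rows.append(
            (
                d.site_i, d.site_j, d.family, d.component,
                s.observed, s.null_mean, s.null_sd, s.ses,
                s.significant_high, s.significant_low, d.n_rand, d.seed,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_i", "site_j", "family", "component",
            "observed", "null_mean", "null_sd", "ses",
            "significant_high", "significant_low", "n_rand", "seed",
        ],
    )
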