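"""The six index decompositions and the pairwise table drivers."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylobeta import (
    CountPartition,
    UndefinedIndexError,
    branch_partition,
    jaccard_decomposition,
    pairwise_cbd,
    pairwise_pbd,
    phylosor_decomposition,
    sorensen_decomposition,
    unifrac_decomposition,
)

from conftest import PRINTED_TOL, TABLE1, closed_form_nestedness, site_tips

counts = st.integers(min_value=0, max_value=200)
lengths = st.floats(min_value=0.0, max_value=1e6, allow_nan=False, allow_infinity=False)


@pytest.mark.parametrize("pair,a,b,c,ps,pst,psd,uf,uft,ufd", TABLE1)
def test_reference_rows_both_families(pair, a, b, c, ps, pst, psd, uf, uft, ufd):
    """Each printed (a, b, c) row reproduces all six index values at 3 decimals."""
    sor = phylosor_decomposition((a, b, c))
    jac = unifrac_decomposition((a, b, c))
    assert sor.total == pytest.approx(ps, abs=PRINTED_TOL)
    assert sor.turnover == pytest.approx(pst, abs=PRINTED_TOL)
    assert sor.pd_component == pytest.approx(psd, abs=PRINTED_TOL)
    assert jac.total == pytest.approx(uf, abs=PRINTED_TOL)
    assert jac.turnover == pytest.approx(uft, abs=PRINTED_TOL)
    assert jac.pd_component == pytest.approx(ufd, abs=PRINTED_TOL)


class TestSingleDecompositions:
    def test_sorensen_example(self):
        res = sorensen_decomposition(CountPartition(5, 1, 1))
        assert res.total == pytest.approx(1 / 6)
        assert res.turnover == pytest.approx(1 / 6)
        assert res.pd_component == 0.0

    def test_jaccard_examples(self):
        res = jaccard_decomposition(CountPartition(5, 1, 1))
        assert res.total == pytest.approx(2 / 7)
        assert res.turnover == pytest.approx(2 / 7)
        assert res.pd_component == 0.0
        res = jaccard_decomposition(CountPartition(5, 1, 4))
        assert res.total == pytest.approx(0.5)
        assert res.turnover == pytest.approx(2 / 7)
        assert res.pd_component == pytest.approx(0.5 - 2 / 7)

    def test_nested_pair_has_zero_turnover(self):
        for fam in (sorensen_decomposition, jaccard_decomposition):
            res = fam(CountPartition(4, 0, 9))
            assert res.turnover == 0.0
            assert res.pd_component == res.total

    def test_disjoint_communities_are_pure_turnover(self):
        res = sorensen_decomposition(CountPartition(0, 3, 5))
        assert res.total == 1.0 and res.turnover == 1.0 and res.pd_component == 0.0
        res = jaccard_decomposition(CountPartition(0, 3, 5))
        assert res.total == 1.0 and res.turnover == 1.0

    def test_identical_communities_are_all_zero(self):
        for fam in (sorensen_decomposition, jaccard_decomposition):
            res = fam(CountPartition(7, 0, 0))
            assert res.total == res.turnover == res.pd_component == 0.0

    def test_all_zero_partition_is_undefined(self):
        for fam in (sorensen_decomposition, jaccard_decomposition,
                    phylosor_decomposition, unifrac_decomposition):
            with pytest.raises(UndefinedIndexError):
                fam((0, 0, 0))

    def test_equal_unique_lengths_give_exact_zero_pd_component(self):
        for b in (0.1, 1 / 3, 2.7, 1e-9):
            assert phylosor_decomposition((1.3, b, b)).pd_component == 0.0
            assert unifrac_decomposition((1.3, b, b)).pd_component == 0.0


class TestDecompositionProperties:
    @given(a=lengths, b=lengths, c=lengths)
    @settings(max_examples=300, derandomize=True)
    def test_additivity_and_bounds(self, a, b, c):
        if a + b + c <= 0:
            return
        for fam in (phylosor_decomposition, unifrac_decomposition):
            res = fam((a, b, c))
            assert abs(res.total - (res.turnover + res.pd_component)) <= 1e-12
            assert 0.0 <= res.turnover <= res.total <= 1.0
            assert res.pd_component >= 0.0

    @given(a=lengths, b=lengths, c=lengths)
    @settings(max_examples=300, derandomize=True)
    def test_sorensen_family_never_exceeds_jaccard_family(self, a, b, c):
        if a + b + c <= 0:
            return
        ps = phylosor_decomposition((a, b, c))
        uf = unifrac_decomposition((a, b, c))
        assert ps.total <= uf.total + 1e-15

    @given(a=lengths, b=lengths, hi1=lengths, hi2=lengths)
    @settings(max_examples=300, derandomize=True)
    def test_turnover_ignores_larger_unique_component(self, a, b, hi1, hi2):
        """Turnover depends on (a, min(b, c)) only."""
        if a + b <= 0:
            return
        c1, c2 = b + hi1, b + hi2
        for fam in (phylosor_decomposition, unifrac_decomposition):
            assert fam((a, b, c1)).turnover == fam((a, b, c2)).turnover

    def test_pd_component_increases_with_larger_unique_component(self):
        grid = [4.0, 5.0, 7.0, 8.0, 20.0]
        for fam in (phylosor_decomposition, unifrac_decomposition):
            values = [fam((5.0, 1.0, c)).pd_component for c in grid]
            assert all(x < y for x, y in zip(values, values[1:]))

    @given(a=lengths, b=lengths, c=lengths)
    @settings(max_examples=300, derandomize=True)
    def test_symmetry(self, a, b, c):
        if a + b + c <= 0:
            return
        for fam in (phylosor_decomposition, unifrac_decomposition):
            fwd, rev = fam((a, b, c)), fam((a, c, b))
            assert fwd.total == rev.total
            assert fwd.turnover == rev.turnover

    @given(a=counts, b=counts, c=counts)
    @settings(max_examples=300, derandomize=True)
    def test_subtraction_matches_closed_form_nestedness(self, a, b, c):
        if a + b + c == 0:
            return
        sor = sorensen_decomposition(CountPartition(a, b, c))
        jac = jaccard_decomposition(CountPartition(a, b, c))
        assert sor.pd_component == pytest.approx(
            closed_form_nestedness(a, b, c, "sorensen"), abs=1e-12
        )
        assert jac.pd_component == pytest.approx(
            closed_form_nestedness(a, b, c, "jaccard"), abs=1e-12
        )


class TestPairwiseDrivers:
    def test_toy_fixture_reproduces_reference_table(self, fig2_toy):
        tree, table = fig2_toy
        out = pairwise_pbd(tree, table, "both").set_index(["site_i", "site_j", "family"])
        for (si, sj), a, b, c, ps, pst, psd, uf, uft, ufd in TABLE1:
            sor = out.loc[(si, sj, "sorensen")]
            jac = out.loc[(si, sj, "jaccard")]
            assert sor["total"] == pytest.approx(ps, abs=PRINTED_TOL)
            assert sor["turnover"] == pytest.approx(pst, abs=PRINTED_TOL)
            assert sor["pd_component"] == pytest.approx(psd, abs=PRINTED_TOL)
            assert jac["total"] == pytest.approx(uf, abs=PRINTED_TOL)
            assert jac["turnover"] == pytest.approx(uft, abs=PRINTED_TOL)
            assert jac["pd_component"] == pytest.approx(ufd, abs=PRINTED_TOL)

    def test_identical_sites_have_zero_dissimilarity(self, fig2_toy):
        tree, table = fig2_toy
        dup = table.loc[["A", "A"]].copy()
        dup.index = ["A1", "A2"]
        out = pairwise_pbd(tree, dup, "both")
        assert (out[["total", "turnover", "pd_component"]] == 0.0).all().all()

    def test_pbd_matches_single_pair_operations(self, fig2_toy):
        tree, table = fig2_toy
        tips = site_tips(table)
        out = pairwise_pbd(tree, table, "sorensen").set_index(["site_i", "site_j"])
        for (si, sj), row in out.iterrows():
            bp = branch_partition(tree, tips[si], tips[sj])
            ref = phylosor_decomposition(bp)
            assert row["total"] == ref.total
            assert row["turnover"] == ref.turnover

    def test_cbd_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(21)
        table = pd.DataFrame(
            rng.integers(0, 2, size=(5, 20)),
            index=[f"site{i}" for i in range(5)],
            columns=[f"sp{j}" for j in range(20)],
        )
        table.iloc[:, 0] = 1  # no empty site
        tips = site_tips(table)
        out = pairwise_cbd(table, "both").set_index(["site_i", "site_j", "family"])
        for si in table.index:
            for sj in table.index:
                if si >= sj:
                    continue
                a = len(tips[si] & tips[sj])
                b = len(tips[si] - tips[sj])
                c = len(tips[sj] - tips[si])
                ref = sorensen_decomposition(CountPartition(a, b, c))
                row = out.loc[(si, sj, "sorensen")]
                assert row["total"] == ref.total
                assert row["turnover"] == ref.turnover

    def test_disjoint_sites_cbd(self):
        table = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["u", "v"], columns=list("wxyz")
        )
        out = pairwise_cbd(table, "sorensen").iloc[0]
        assert out["total"] == 1.0 and out["turnover"] == 1.0 and out["pd_component"] == 0.0

    def test_empty_site_yields_nan_not_failure(self, fig2_toy, caplog):
        tree, table = fig2_toy
        table = table.copy()
        table.loc["empty"] = 0
        out = pairwise_pbd(tree, table, "sorensen")
        bad = out[(out.site_i == "empty") | (out.site_j == "empty")]
        good = out[(out.site_i != "empty") & (out.site_j != "empty")]
        assert bad["total"].isna().all()
        assert good["total"].notna().all()

    def test_species_missing_from_tree(self, fig2_toy):
        tree, table = fig2_toy
        table = table.copy()
        table["alien"] = 0
        table.loc["A", "alien"] = 1
        with pytest.raises(KeyError):
            pairwise_pbd(tree, table)
        out = pairwise_pbd(tree, table, prune_missing=True)
        ref = pairwise_pbd(tree, table.drop(columns="alien"))
        pd.testing.assert_frame_equal(out, ref)

    def test_abundances_collapse_to_incidence(self, fig2_toy):
        tree, table = fig2_toy
        scaled = table * 3
        pd.testing.assert_frame_equal(
            pairwise_pbd(tree, scaled), pairwise_pbd(tree, table)
        )


def test_unifrac_total_matches_scikit_bio_on_random_binary_trees():
    """Independent library cross-check of the UniFrac total (root-inclusive)."""
    skbio = pytest.importorskip("skbio")
    from skbio.diversity import beta_diversity

    from conftest import random_tree
    from phylobeta import write_newick

    rng = np.random.default_rng(17)
    for _ in range(10):
        tree = random_tree(rng, int(rng.integers(4, 10)))
        species = list(tree.tip_labels)
        data = rng.integers(0, 2, size=(3, len(species)))
        data[:, 0] = 1
        table = pd.DataFrame(data, index=["p", "q", "r"], columns=species)
        sk_tree = skbio.TreeNode.read(io.StringIO(write_newick(tree)))
        dm = beta_diversity(
            "unweighted_unifrac", table.to_numpy(), ids=list(table.index),
            taxa=species, tree=sk_tree,
        )
        out = pairwise_pbd(tree, table, "jaccard").set_index(["site_i", "site_j"])
        for (si, sj), row in out.iterrows():
            assert row["total"] == pytest.approx(dm[si, sj], abs=1e-10)
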