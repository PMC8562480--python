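"""Niche optima, phylogenetic signal, SES.MNTD and beta-NTI null models."""
import numpy as np
import pandas as pd
import pytest

from _oracles import brute_beta_mntd
from conftest import make_metadata, make_table
from gutassembly import assembly as asmb
from gutassembly.containers import DistanceMatrix, OtuTable
from gutassembly.synthetic import simulate_tree


class TestNicheOptima:
    def test_single_occurrence_takes_that_sample_value(self):
        table = make_table({"s1": [1, 0], "s2": [0, 2]}, ["o1", "o2"])
        meta = make_metadata([1, 2], ids=["s1", "s2"],
                             env={"glucose": [7.0, 3.0]})
        out = asmb.niche_optima(table, meta)
        assert out.optima.loc["o1", "glucose"] == pytest.approx(7.0)

    @pytest.mark.parametrize("weights,expected", [
        ((1, 1), 3.0),
        ((3, 1), 2.5),
    ])
    def test_abundance_weighted_mean(self, weights, expected):
        table = make_table({"s1": [weights[0]], "s2": [weights[1]]}, ["o1"])
        meta = make_metadata([1, 2], ids=["s1", "s2"],
                             env={"glucose": [2.0, 4.0]})
        out = asmb.niche_optima(table, meta)
        assert out.optima.loc["o1", "glucose"] == pytest.approx(expected)

    def test_optima_bounded_by_env_range(self, rng):
        counts = rng.integers(0, 20, size=(6, 10))
        counts[0] += 1
        table = OtuTable(pd.DataFrame(
            counts, index=[f"S{i + 1:03d}" for i in range(6)]))
        env = rng.normal(size=6)
        meta = make_metadata([1, 2, 3, 4, 5, 6], env={"glucose": env})
        out = asmb.niche_optima(table, meta)
        assert (out.optima["glucose"] >= env.min() - 1e-12).all()
        assert (out.optima["glucose"] <= env.max() + 1e-12).all()

    def test_no_shared_samples_rejected(self):
        table = make_table({"x1": [1]}, ["o1"])
        meta = make_metadata([1], ids=["y1"], env={"glucose": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            asmb.niche_optima(table, meta)

    def test_everywhere_absent_otus_dropped(self):
        table = make_table({"s1": [1, 0], "s2": [2, 0]}, ["o1", "o2"])
        meta = make_metadata([1, 2], ids=["s1", "s2"],
                             env={"glucose": [1.0, 2.0]})
        out = asmb.niche_optima(table, meta)
        assert list(out.optima.index) == ["o1"]


class TestNicheDistance:
    def _optima(self, values, cols):
        df = pd.DataFrame(values, columns=cols,
                          index=[f"o{i}" for i in range(len(values))])
        return asmb.NicheOptima(df, pd.Series(1.0, index=df.index))

    def test_identical_vectors_distance_zero(self):
        out = asmb.niche_distance(self._optima([[1.0, 2.0], [1.0, 2.0]],
                                               ["a", "b"]))
        assert out.values[0, 1] == 0

    def test_single_variable_absolute_difference(self):
        out = asmb.niche_distance(self._optima([[2.0], [5.0]], ["a"]),
                                  standardize=False)
        assert out.values[0, 1] == pytest.approx(3.0)

    def test_two_variables_pythagoras(self):
        out = asmb.niche_distance(
            self._optima([[0.0, 0.0], [3.0, 4.0]], ["a", "b"]),
            standardize=False)
        assert out.values[0, 1] == pytest.approx(5.0)

    def test_standardization_makes_units_irrelevant(self, rng):
        vals = rng.normal(size=(5, 2))
        a = asmb.niche_distance(self._optima(vals, ["a", "b"]))
        vals2 = vals.copy()
        vals2[:, 1] *= 1000.0
        b = asmb.niche_distance(self._optima(vals2, ["a", "b"]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_missing_optima_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            asmb.niche_distance(self._optima([[np.nan], [1.0]], ["a"]))


class TestMantelCorrelogram:
    def test_perfect_signal_significant_in_first_class(self):
        tree = simulate_tree(30, seed=1)
        phylo = tree.patristic()
        out = asmb.mantel_correlogram(phylo, phylo, permutations=999, seed=0)
        first = out.dropna(subset=["mantel_r"]).iloc[0]
        assert first["mantel_r"] > 0
        assert first["p_perm"] <= 0.05

    def test_minimum_p_is_one_over_permutations_plus_one(self):
        tree = simulate_tree(30, seed=1)
        phylo = tree.patristic()
        out = asmb.mantel_correlogram(phylo, phylo, permutations=999, seed=0)
        tested = out.dropna(subset=["p_perm"])
        assert (tested["p_perm"] >= 1 / 1000 - 1e-15).all()
        assert tested["p_perm"].min() == pytest.approx(1 / 1000)

    def test_null_niche_matrix_rejects_at_alpha_rate(self, rng):
        # niche distances unrelated to phylogeny: per-class rejection ~ alpha
        tree = simulate_tree(30, seed=2)
        phylo = tree.patristic()
        n = len(phylo.ids)
        total, hits = 0, 0
        for rep in range(100):
            vals = rng.normal(size=n)
            nd = DistanceMatrix(phylo.ids,
                                np.abs(vals[:, None] - vals[None, :]))
            out = asmb.mantel_correlogram(nd, phylo, permutations=99,
                                          seed=rep)
            tested = out.dropna(subset=["p_perm"])
            total += len(tested)
            hits += int((tested["p_perm"] <= 0.05).sum())
        assert 0.01 <= hits / total <= 0.12

    def test_zero_permutations_rejected(self):
        tree = simulate_tree(10, seed=0)
        phylo = tree.patristic()
        with pytest.raises(ValueError):
            asmb.mantel_correlogram(phylo, phylo, permutations=0, seed=0)


class TestSesMntd:
    def test_star_tree_null_degenerate(self, star_tree):
        # all pairwise distances equal: every shuffle gives the same MNTD
        table = make_table({"s1": [1, 1, 0, 0], "s2": [0, 0, 1, 1]},
                           ["A", "B", "C", "D"])
        out = asmb.ses_mntd(table, star_tree, n_null=99, seed=0)
        assert out.loc["s1", "null_sd"] == 0
        assert np.isnan(out.loc["s1", "ses"])

    def test_two_otu_sample_observed_distance(self, abc_tree):
        table = make_table({"s1": [1, 1, 0], "s2": [0, 1, 1]},
                           ["A", "B", "C"])
        out = asmb.ses_mntd(table, abc_tree, n_null=99, weighted=False,
                            seed=0)
        assert out.loc["s1", "mntd_obs"] == pytest.approx(2.0)
        assert out.loc["s2", "mntd_obs"] == pytest.approx(4.0)

    def test_full_pool_community_has_zero_ses(self):
        tree = simulate_tree(12, seed=4)
        table = OtuTable(pd.DataFrame(np.ones((2, 12)), index=["s1", "s2"],
                                      columns=list(tree.tip_labels)))
        out = asmb.ses_mntd(table, tree, n_null=99, seed=1)
        assert out.loc["s1", "ses"] == 0.0

    def test_small_samples_skipped(self, abc_tree):
        table = make_table({"tiny": [1, 0, 0], "ok": [1, 1, 0]},
                           ["A", "B", "C"])
        out = asmb.ses_mntd(table, abc_tree, n_null=99, seed=0)
        assert "tiny" not in out.index
        assert "ok" in out.index

    def test_invariant_to_otu_and_sample_order(self):
        tree = simulate_tree(15, seed=2)
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(4, 15))
        counts[:, 0] += 1
        ids = [f"s{i}" for i in range(4)]
        df = pd.DataFrame(counts, index=ids, columns=list(tree.tip_labels))
        base = asmb.ses_mntd(OtuTable(df), tree, n_null=99, seed=7)
        shuffled = df.iloc[::-1, ::-1]  # reverse sample and OTU order
        other = asmb.ses_mntd(OtuTable(shuffled), tree, n_null=99, seed=7)
        pd.testing.assert_frame_equal(base.sort_index(), other.sort_index())


class TestBetaMntd:
    def test_identical_taxon_sets_zero_even_with_different_abundances(
            self, abc_tree):
        table = make_table({"s1": [5, 1, 0], "s2": [1, 9, 0]},
                           ["A", "B", "C"])
        for weighted in (True, False):
            out = asmb.beta_mntd(table, abc_tree, weighted=weighted)
            assert out.values[0, 1] == 0.0

    def test_singleton_samples_hand_value(self, abc_tree):
        table = make_table({"s1": [1, 0, 0], "s2": [0, 1, 0]},
                           ["A", "B", "C"])
        out = asmb.beta_mntd(table, abc_tree, weighted=True)
        assert out.values[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_bruteforce_oracle(self, weighted, rng):
        for rep in range(5):
            tree = simulate_tree(10, seed=rep)
            counts = rng.integers(0, 6, size=(4, 10))
            counts[:, rep % 10] += 1  # no empty samples
            table = OtuTable(pd.DataFrame(
                counts, index=[f"s{i}" for i in range(4)],
                columns=list(tree.tip_labels)))
            ours = asmb.beta_mntd(table, tree, weighted=weighted)
            oracle = brute_beta_mntd(table, tree, weighted=weighted)
            np.testing.assert_allclose(ours.values, oracle, atol=1e-10)

    def test_empty_sample_rejected(self, abc_tree):
        table = make_table({"s1": [1, 1, 0], "s2": [0, 0, 0]},
                           ["A", "B", "C"])
        with pytest.raises(ValueError, match="s2"):
            asmb.beta_mntd(table, abc_tree)


class TestBetaNti:
    def test_threshold_is_strict(self):
        ids = ("s1", "s2")
        z = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = asmb.BetaNtiResult(ids, z * 0, z * 0, np.ones((2, 2)), z,
                                 threshold=2.0, n_null=999)
        assert res.classification()[0, 1] == "stochastic"
        res2 = asmb.BetaNtiResult(ids, z * 0, z * 0, np.ones((2, 2)),
                                  z + np.array([[0, 1e-9], [1e-9, 0]]),
                                  threshold=2.0, n_null=999)
        assert res2.classification()[0, 1] == "deterministic"

    def test_too_few_nulls_rejected(self, abc_tree):
        table = make_table({"s1": [1, 1, 0], "s2": [0, 1, 1]},
                           ["A", "B", "C"])
        with pytest.raises(ValueError):
            asmb.beta_nti(table, abc_tree, n_null=10)

    def test_null_generator_calibration(self):
        # communities drawn by the same mechanism as the null (random
        # subsets of the pool): ~5% of pairs beyond |2|
        tree = simulate_tree(40, seed=9)
        rng = np.random.default_rng(3)
        n_samples, richness = 11, 12  # 55 pairs
        counts = np.zeros((n_samples, 40), dtype=int)
        for k in range(n_samples):
            idx = rng.choice(40, size=richness, replace=False)
            counts[k, idx] = rng.integers(1, 50, size=richness)
        table = OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n_samples)],
            columns=list(tree.tip_labels)))
        res = asmb.beta_nti(table, tree, n_null=999, seed=5)
        vals = res.bnti[np.triu_indices(n_samples, k=1)]
        vals = vals[np.isfinite(vals)]
        frac = (np.abs(vals) > 2).mean()
        assert 0.0 <= frac <= 0.10

    def test_invariant_to_otu_and_sample_order(self):
        tree = simulate_tree(12, seed=6)
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 4, size=(4, 12))
        counts[:, 2] += 1
        ids = [f"s{i}" for i in range(4)]
        df = pd.DataFrame(counts, index=ids, columns=list(tree.tip_labels))
        a = asmb.beta_nti(OtuTable(df), tree, n_null=99, seed=3)
        b = asmb.beta_nti(OtuTable(df.iloc[::-1, ::-1]), tree, n_null=99,
                          seed=3)
        long_a = a.to_long().set_index(["sample_1", "sample_2"]).sort_index()
        long_b = b.to_long()
        # normalize pair orientation before comparing
        swap = long_b["sample_1"] > long_b["sample_2"]
        long_b.loc[swap, ["sample_1", "sample_2"]] = (
            long_b.loc[swap, ["sample_2", "sample_1"]].to_numpy())
        long_b = long_b.set_index(["sample_1", "sample_2"]).sort_index()
        pd.testing.assert_frame_equal(long_a, long_b)


class TestAssemblyFractions:
    def _result(self, bnti, ids):
        n = len(ids)
        z = np.zeros((n, n))
        return asmb.BetaNtiResult(tuple(ids), z, z, np.ones((n, n)),
                                  bnti, threshold=2.0, n_null=999)

    def test_all_extreme_pairs_fully_deterministic(self):
        bnti = 3.0 * (np.ones((4, 4)) - np.eye(4))
        out = asmb.assembly_fractions(self._result(bnti, list("abcd")),
                                      ["g"] * 4)
        assert out.loc["g", "frac_deterministic"] == 1.0
        assert out.loc["g", "n_pairs"] == 6

    def test_all_central_pairs_fully_stochastic(self):
        bnti = 0.5 * (np.ones((4, 4)) - np.eye(4))
        out = asmb.assembly_fractions(self._result(bnti, list("abcd")),
                                      ["g"] * 4)
        assert out.loc["g", "frac_stochastic"] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(scale=2.5, size=(6, 6))
        bnti = (raw + raw.T) / 2
        np.fill_diagonal(bnti, 0)
        out = asmb.assembly_fractions(self._result(bnti, list("abcdef")),
                                      ["g1"] * 3 + ["g2"] * 3)
        np.testing.assert_allclose(
            out["frac_deterministic"] + out["frac_stochastic"], 1.0)

    def test_single_sample_group_omitted(self):
        bnti = np.zeros((3, 3))
        out = asmb.assembly_fractions(self._result(bnti, list("abc")),
                                      ["g1", "g1", "lonely"])
        assert "lonely" not in out.index
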