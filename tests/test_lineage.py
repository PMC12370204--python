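"""Lineage nesting, threshold assignment, founder-cell inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import floralineage as fl


class TestPermutationZ:
    def test_perfect_correlation_detected(self):
        x = np.linspace(1, 40, 20)
        res = fl.permutation_z(x, x, n_perm=10_000, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["Z"] > 3
        assert res["p"] < 0.001

    def test_null_z_is_approximately_standard_normal(self):
        rng = np.random.default_rng(23)
        zs = []
        for _ in range(300):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            zs.append(fl.permutation_z(a, b, n_perm=300, rng=rng)["Z"])
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.2
        assert 0.8 < zs.std() < 1.25

    def test_small_n_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        res = fl.permutation_z(a, b, n_perm=50_000, seed=1)
        # exhaustive oracle over all 24 label permutations
        r_obs = stats.pearsonr(a, b)[0]
        r_all = [stats.pearsonr(a, np.array(p))[0]
                 for p in itertools.permutations(b)]
        p_exact = np.mean([abs(r) >= abs(r_obs) - 1e-12 for r in r_all])
        assert res["p"] == pytest.approx(p_exact, abs=0.01)

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            fl.permutation_z([1, 2, 3], [1, 2, 3], n_perm=10)
        with pytest.raises(ValueError):
            fl.permutation_z([1, 1, 1, 1], [1, 2, 3, 4], n_perm=10)

    def test_missing_samples_dropped_pairwise(self):
        a = np.array([1, 2, 3, 4, 5, np.nan])
        b = np.array([2, 4, 6, 8, 10, 12])
        res = fl.permutation_z(a, b, n_perm=500, seed=0)
        assert res["n"] == 5
        assert res["r"] == pytest.approx(1.0)


class TestNegativePair:
    def test_complementary_cvfs_give_r_minus_one(self):
        a = np.array([5.0, 8.0, 10.0, 12.0, 6.0, 11.0])
        b = 100 - 2 * a
        res = fl.negative_pair_test(a, b, n_perm=5000, seed=0)
        assert res["r"] == pytest.approx(-1.0)
        assert res["slope_sign"] == -1
        assert res["negative"]

    def test_same_vector_reports_non_negative(self):
        a = np.array([5.0, 8.0, 10.0, 12.0, 6.0, 11.0])
        res = fl.negative_pair_test(a, a, n_perm=1000, seed=0)
        assert res["r"] > 0
        assert not res["negative"]

    def test_simulated_opposite_layer_founders_anticorrelate(self, stochastic_sim):
        _, truth, table = stochastic_sim
        meta = truth.samples
        vaf = fl.vaf_matrix(table.alt, table.total)
        f1 = meta.index[meta["flower"] == "F1"]
        res = fl.negative_pair_test(vaf.loc["F1-FOUNDER-L1", f1],
                                    vaf.loc["F1-FOUNDER-L2", f1],
                                    n_perm=5000, seed=2)
        assert res["r"] < 0


class TestThresholdAssignment:
    def _vaf_meta(self, values, organs):
        cols = [f"s{i}" for i in range(len(organs))]
        vaf = pd.DataFrame([values], index=["m"], columns=cols)
        meta = pd.DataFrame({"organ": organs, "flower": "F1",
                             "is_control": False}, index=cols)
        return vaf, meta

    def test_high_max_nonpetal_joins_group2(self):
        vaf, meta = self._vaf_meta([30.0, 25.0, 10.0, 40.0],
                                   ["sepal", "stamen", "carpel", "petal"])
        res = fl.assign_group_by_threshold(vaf, meta)
        assert res.loc["m", "group"] == "Group2"

    def test_low_max_nonpetal_joins_group1(self):
        vaf, meta = self._vaf_meta([15.0, 8.0, 5.0, 20.0],
                                   ["sepal", "stamen", "carpel", "petal"])
        res = fl.assign_group_by_threshold(vaf, meta)
        assert res.loc["m", "group"] == "Group1"
        assert res.loc["m", "max_nonpetal_vaf"] == 15.0

    def test_petal_only_unassigned(self):
        vaf, meta = self._vaf_meta([12.0, 9.0, 14.0],
                                   ["petal", "petal", "petal"])
        res = fl.assign_group_by_threshold(vaf, meta)
        assert res.loc["m", "group"] == "unassigned"
        assert "petal" in res.loc["m", "reason"]

    def test_two_or_fewer_records_unassigned(self):
        vaf, meta = self._vaf_meta([30.0, 25.0, 0.0, 0.0],
                                   ["sepal", "stamen", "carpel", "petal"])
        res = fl.assign_group_by_threshold(vaf, meta)
        assert res.loc["m", "group"] == "unassigned"

    def test_threshold_recomputed_from_flowerwide_group1(self):
        cols = [f"s{i}" for i in range(4)]
        vaf = pd.DataFrame(
            [[10.0, 18.5, 12.0, 25.0],   # flower-wide Group 1 reference
             [19.0, 17.0, 16.0, 30.0]],  # candidate under test
            index=["ref", "m"], columns=cols,
        )
        meta = pd.DataFrame({"organ": ["sepal", "stamen", "carpel", "petal"],
                             "flower": "F1", "is_control": False}, index=cols)
        res = fl.assign_group_by_threshold(vaf, meta, mutations=["m"],
                                           group1_flowerwide=("ref",))
        assert res.attrs["threshold"] == 18.5  # petal value ignored
        assert res.loc["m", "group"] == "Group2"  # 19.0 > 18.5

    def test_accuracy_on_simulated_truth(self, stochastic_sim):
        _, truth, table = stochastic_sim
        vaf = fl.vaf_matrix(table.alt, table.total)
        res = fl.assign_group_by_threshold(vaf, truth.samples)
        assigned = res[res["group"] != "unassigned"]
        truth_group = truth.mutations.loc[assigned.index, "layer"].map(
            {"L1": "Group1", "L2": "Group2"})
        assert (assigned["group"] == truth_group).mean() >= 0.9


class TestFounderClassification:
    def test_mutation_against_itself_is_exactly_one(self, stochastic_sim):
        _, truth, table = stochastic_sim
        vaf = fl.vaf_matrix(table.alt, table.total)
        res = fl.founder_classify(vaf, "ANCHOR-L2-main", "ANCHOR-L2-main")
        assert res["median_ratio"] == pytest.approx(1.0)
        assert res["label"] == "founder_event"

    def test_simulated_founder_and_first_daughter(self, stochastic_sim):
        _, truth, table = stochastic_sim
        meta = truth.samples
        vaf = fl.vaf_matrix(table.alt, table.total)
        f2 = meta.index[meta["flower"] == "F2"]
        founder = fl.founder_classify(
            vaf, "F2-FOUNDER-L2", ("ANCHOR-L2-main", "ANCHOR-L2-sub"), samples=f2
        )
        assert founder["label"] == "founder_event"
        daughter = fl.founder_classify(
            vaf, "F2-FD-L1", ("ANCHOR-L1-main", "ANCHOR-L1-sub"), samples=f2
        )
        assert daughter["label"] == "first_daughter"

    def test_zero_anchor_rejected(self):
        vaf = pd.DataFrame([[10.0, 12.0, 9.0], [0.0, 0.0, 0.0]],
                           index=["m", "anc"], columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            fl.founder_classify(vaf, "m", "anc")

    def test_too_few_shared_samples_rejected(self):
        vaf = pd.DataFrame([[10.0, np.nan, np.nan], [20.0, 21.0, 22.0]],
                           index=["m", "anc"], columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            fl.founder_classify(vaf, "m", "anc")


class TestNesting:
    def test_flower_mutations_nest_into_their_layers(self):
        # deeper sequencing than the 64x study default, so the correlation
        # signal dominates read noise and the truth comparison is sharp
        cfg = fl.default_two_flower_config(seed=6, depth_mean=300.0)
        truth, table = fl.simulate_dataset(cfg)
        vaf = fl.vaf_matrix(table.alt, table.total)
        anchors = fl.AnchorSet(group1=("ANCHOR-L1-main", "ANCHOR-L1-sub"),
                               group2=("ANCHOR-L2-main", "ANCHOR-L2-sub"))
        cands = ["F1-FOUNDER-L1", "F1-FOUNDER-L2", "F2-FOUNDER-L2", "F2-FD-L1"]
        nest = fl.nest_mutations(vaf, cands, anchors, n_perm=2000, seed=6)
        truth_group = truth.mutations.loc[nest.index, "layer"].map(
            {"L1": "Group1", "L2": "Group2"})
        assert (nest["group"] == truth_group).all()

    def test_uncorrelated_candidate_stays_ungrouped(self):
        rng = np.random.default_rng(44)
        cols = [f"s{i}" for i in range(30)]
        vaf = pd.DataFrame(
            {"a1": rng.uniform(5, 45, 30), "a2": rng.uniform(5, 45, 30),
             "cand": rng.uniform(5, 45, 30)}
        ).T
        vaf.columns = cols
        anchors = fl.AnchorSet(group1=("a1",), group2=("a2",))
        nest = fl.nest_mutations(vaf, ["cand"], anchors, n_perm=2000, seed=0)
        assert nest.loc["cand", "group"] == "ungrouped"

    def test_anchor_candidate_skips_self_test(self, stochastic_sim):
        _, truth, table = stochastic_sim
        vaf = fl.vaf_matrix(table.alt, table.total)
        anchors = fl.AnchorSet(group1=("ANCHOR-L1-main",), group2=("ANCHOR-L2-main",))
        nest = fl.nest_mutations(vaf, ["ANCHOR-L1-main"], anchors, n_perm=200, seed=0)
        # no self-correlation column, and no trivial self-membership
        assert "r_ANCHOR-L1-main" not in nest.columns
        assert nest.loc["ANCHOR-L1-main", "group"] != "Group1"

    def test_disjoint_anchor_groups_enforced(self):
        with pytest.raises(ValueError):
            fl.AnchorSet(group1=("a",), group2=("a", "b"))
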