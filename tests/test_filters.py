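"""Filter cascade: parental screen, local quality, hard thresholds, de novo."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import floralineage as fl
from floralineage.filters import DEFAULT_HARD_THRESHOLDS

from conftest import make_table

SAMPLES = ["c1", "c2", "c3", "c4", "s1", "s2"]
CONTROLS = ["c1", "c2", "c3", "c4"]


def table_from_alt(alt_rows, depth=60, **kw):
    idx = [f"m{i}" for i in range(len(alt_rows))]
    alt = pd.DataFrame(alt_rows, index=idx, columns=SAMPLES)
    total = pd.DataFrame(depth, index=idx, columns=SAMPLES)
    return make_table(alt, total, **kw)


class TestParental:
    def test_three_alt_reads_in_one_control_removed(self):
        t = table_from_alt([[3, 0, 0, 0, 20, 20]])
        kept, rep = fl.filter_parental(t, CONTROLS)
        assert len(kept) == 0
        assert rep.reasons["m0"] == "parental:control_depth"

    def test_clean_controls_retained(self):
        t = table_from_alt([[0, 0, 0, 0, 20, 20]])
        kept, _ = fl.filter_parental(t, CONTROLS)
        assert list(kept.site_ids) == ["m0"]

    def test_toy_table_enumeration(self):
        # 4 sites with one alt read in all four controls (4 > max_cmp_total=3)
        # -> removed; 6 clean sites -> retained
        rows = [[1, 1, 1, 1, 10, 0]] * 4 + [[0, 0, 0, 0, 10, 0]] * 6
        t = table_from_alt(rows)
        kept, rep = fl.filter_parental(t, CONTROLS)
        assert len(kept) == 6
        assert rep.steps[0] == {"step": "parental", "input": 10,
                                "removed": 4, "retained": 6}

    def test_boundary_counts_pass(self):
        # exactly 2 alt reads in a control, in exactly 3 controls: both at limit
        t = table_from_alt([[2, 2, 2, 0, 20, 20]])
        kept, _ = fl.filter_parental(t, CONTROLS)
        assert len(kept) == 1

    def test_requires_controls(self):
        t = table_from_alt([[0, 0, 0, 0, 5, 5]])
        with pytest.raises(ValueError):
            fl.filter_parental(t, [])


class TestLocalQuality:
    def test_best_carrier_four_alt_reads_removed(self):
        t = table_from_alt([[0, 0, 0, 0, 4, 3]])
        kept, rep = fl.filter_local_quality(t, CONTROLS)
        assert len(kept) == 0
        assert rep.reasons["m0"] == "quality:no_support"

    def test_site_near_indel_removed(self):
        t = table_from_alt([[0, 0, 0, 0, 20, 20]], indel_dist=2)
        kept, rep = fl.filter_local_quality(t, CONTROLS)
        assert len(kept) == 0
        assert rep.reasons["m0"] == "quality:near_indel"
        far = table_from_alt([[0, 0, 0, 0, 20, 20]], indel_dist=6)
        kept, _ = fl.filter_local_quality(far, CONTROLS)
        assert len(kept) == 1

    def test_missing_in_four_controls_removed(self):
        idx = ["m0"]
        alt = pd.DataFrame([[0, 0, 0, 0, 20, 20]], index=idx, columns=SAMPLES)
        total = pd.DataFrame([[0, 0, 0, 0, 60, 60]], index=idx, columns=SAMPLES)
        t = make_table(alt, total)
        kept, rep = fl.filter_local_quality(t, CONTROLS)
        assert rep.reasons["m0"] == "quality:missing_controls"

    def test_triallelic_removed(self):
        t = table_from_alt([[0, 0, 0, 0, 20, 20]], n_alleles=[3])
        kept, rep = fl.filter_local_quality(t, CONTROLS)
        assert rep.reasons["m0"] == "quality:multiallelic"

    def test_strand_bias_matches_fisher_oracle(self):
        # all alt reads forward in every carrier vs balanced ref reads
        idx = ["m0"]
        alt = pd.DataFrame([[0, 0, 0, 0, 10, 10]], index=idx, columns=SAMPLES)
        total = pd.DataFrame(60, index=idx, columns=SAMPLES)
        t = make_table(alt, total, alt_fwd=alt.copy())
        p_oracle = stats.fisher_exact([[20, 0], [50, 50]])[1]
        assert p_oracle < 0.001  # the chosen alpha
        kept, rep = fl.filter_local_quality(t, CONTROLS)
        assert rep.reasons["m0"] == "quality:strand_bias"
        # balanced strands at the same depth pass
        t2 = table_from_alt([[0, 0, 0, 0, 10, 10]])
        kept2, _ = fl.filter_local_quality(t2, CONTROLS)
        assert len(kept2) == 1


class TestHardThresholds:
    def test_low_qd_removed(self):
        t = table_from_alt([[0, 0, 0, 0, 20, 20]], annotations={"QD": 1.5})
        kept, rep = fl.filter_hard_thresholds(t)
        assert len(kept) == 0
        assert rep.reasons["m0"].startswith("hard:QD")

    def test_boundary_values_pass(self):
        ann = {"QD": 2.0, "QUAL": 30.0, "SOR": 4.0, "FS": 60.0, "MQ": 40.0,
               "MQRankSum": -12.5, "ReadPosRankSum": -8.0}
        t = table_from_alt([[0, 0, 0, 0, 20, 20]], annotations=ann)
        kept, _ = fl.filter_hard_thresholds(t)
        assert len(kept) == 1

    def test_missing_ranksums_pass(self):
        t = table_from_alt([[0, 0, 0, 0, 20, 20]],
                           annotations={"MQRankSum": np.nan,
                                        "ReadPosRankSum": np.nan})
        kept, _ = fl.filter_hard_thresholds(t)
        assert len(kept) == 1

    def test_random_table_matches_predicate_oracle(self):
        rng = np.random.default_rng(21)
        n = 100
        ann = {
            "QD": rng.uniform(0, 10, n),
            "QUAL": rng.uniform(0, 100, n),
            "SOR": rng.uniform(0, 8, n),
            "FS": rng.uniform(0, 120, n),
            "MQ": rng.uniform(20, 60, n),
            "MQRankSum": rng.normal(-6, 6, n),
            "ReadPosRankSum": rng.normal(-4, 4, n),
        }
        t = table_from_alt([[0, 0, 0, 0, 20, 20]] * n, annotations=ann)
        kept, _ = fl.filter_hard_thresholds(t)
        # brute-force application of the seven printed predicates
        keep_oracle = [
            sid for i, sid in enumerate(t.site_ids)
            if not (ann["QD"][i] < 2.0 or ann["QUAL"][i] < 30.0
                    or ann["SOR"][i] > 4.0 or ann["FS"][i] > 60.0
                    or ann["MQ"][i] < 40.0 or ann["MQRankSum"][i] < -12.5
                    or ann["ReadPosRankSum"][i] < -8.0)
        ]
        assert list(kept.site_ids) == keep_oracle


class TestCascadeOnSimulatorOutput:
    def test_planted_classes_removed_exactly(self, audit_sim):
        cfg, truth, table = audit_sim
        controls = list(truth.samples.index[truth.samples["is_control"]])
        kept, report = fl.run_filter_cascade(table, controls)
        d = cfg.decoys
        steps = {s["step"]: s for s in report.steps}
        assert steps["parental"]["removed"] == d.n_parental
        assert steps["local_quality"]["removed"] == (
            d.n_no_support + d.n_missing_controls + d.n_strand_bias
            + d.n_triallelic + d.n_indel_adjacent
        )
        assert steps["hard_thresholds"]["removed"] == d.n_hard_fail
        assert (kept.sites["truth_class"] == "true").all()
        assert len(kept) == len(truth.mutations)

    def test_count_conservation_and_chaining(self, audit_sim):
        _, truth, table = audit_sim
        controls = list(truth.samples.index[truth.samples["is_control"]])
        _, report = fl.run_filter_cascade(table, controls)
        assert report.check_conservation()
        assert report.steps[0]["input"] == len(table)

    def test_cascade_deterministic(self, audit_sim):
        _, truth, table = audit_sim
        controls = list(truth.samples.index[truth.samples["is_control"]])
        k1, r1 = fl.run_filter_cascade(table, controls)
        k2, r2 = fl.run_filter_cascade(table, controls)
        assert list(k1.site_ids) == list(k2.site_ids)
        assert r1.steps == r2.steps and r1.reasons == r2.reasons


class TestDeNovoCalls:
    def _meta(self):
        return pd.DataFrame(
            {"flower": [None, None, None, None, "F1", "F2"],
             "is_control": [True] * 4 + [False] * 2},
            index=SAMPLES,
        )

    def test_flower_specific_presence(self):
        t = table_from_alt([[0, 0, 0, 0, 12, 0]])
        presence, denovo = fl.call_denovo(t, self._meta())
        assert denovo["m0"] == "F1"

    def test_present_in_both_flowers_fails_specificity(self):
        t = table_from_alt([[0, 0, 0, 0, 12, 12]])
        _, denovo = fl.call_denovo(t, self._meta())
        assert pd.isna(denovo["m0"])

    def test_zero_coverage_is_missing_not_absent(self):
        idx = ["m0"]
        alt = pd.DataFrame([[0, 0, 0, 0, 12, 0]], index=idx, columns=SAMPLES)
        total = pd.DataFrame([[60, 60, 60, 60, 60, 0]], index=idx, columns=SAMPLES)
        t = make_table(alt, total)
        presence, denovo = fl.call_denovo(t, self._meta())
        assert np.isnan(presence.loc["m0", "s2"])
        assert denovo["m0"] == "F1"  # the uncovered sample is no counter-evidence

    def test_simulator_planted_mutations_recovered(self, audit_sim):
        _, truth, table = audit_sim
        controls = list(truth.samples.index[truth.samples["is_control"]])
        kept, _ = fl.run_filter_cascade(table, controls)
        _, denovo = fl.call_denovo(kept, truth.samples)
        planted = truth.mutations[truth.mutations["flower"].notna()]
        called = denovo.dropna()
        assert set(called.index) == set(planted.index)
        assert (called == planted.loc[called.index, "flower"]).all()
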