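"""Homogeneity statistics, permutation p-values, min-p correction, resampling."""

import numpy as np
import pandas as pd
import pytest

import mitorisk as mr
from mitorisk.association import CladeLevelTable, _LevelDesign
from mitorisk.errors import DataError


def table(level, branches, counts):
    return CladeLevelTable(level=level, branches=branches, counts=np.array(counts))


class TestHomogeneityStatistic:
    def test_observed_clade_table(self):
        # affected/unaffected mean counts observed at the first level of the
        # clade-T analysis: three branches, chi-square ~ 9.49 with 2 df
        stat, df = mr.homogeneity_statistic(
            table(1, ["T1a1", "T2", "T"], [[32, 47], [217, 148], [13, 11]])
        )
        assert df == 2
        assert stat == pytest.approx(9.4937, abs=2e-3)

    def test_homogeneous_table_gives_zero(self):
        stat, df = mr.homogeneity_statistic(
            table(1, ["a", "b", "c"], [[10, 30], [5, 15], [20, 60]])
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_two_by_two_extreme(self):
        stat, df = mr.homogeneity_statistic(table(1, ["a", "b"], [[2, 0], [0, 2]]))
        assert (stat, df) == (4.0, 1)

    def test_agrees_with_scipy_chi2_contingency(self, rng):
        from scipy.stats import chi2_contingency

        counts = rng.integers(1, 40, size=(4, 2))
        stat, df = mr.homogeneity_statistic(table(1, list("abcd"), counts))
        ref = chi2_contingency(counts.T, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert df == ref.dof

    def test_empty_branch_pruned(self):
        stat, df = mr.homogeneity_statistic(
            table(1, ["a", "b", "c"], [[2, 0], [0, 0], [0, 2]])
        )
        assert (stat, df) == (4.0, 1)

    def test_zero_status_marginal_rejected(self):
        with pytest.raises(DataError):
            mr.homogeneity_statistic(table(1, ["a", "b"], [[3, 0], [5, 0]]))


class TestLevelTables:
    def test_paragroup_forms_own_branch(self, curated):
        tree, _ = curated
        assignments = {"s1": "T", "s2": "T1a1", "s3": "T2a", "s4": "T2b"}
        statuses = {"s1": 1, "s2": 0, "s3": 1, "s4": 0}
        tables = mr.level_tables(tree, assignments, statuses, "T")
        level1 = tables[0]
        assert level1.branches == ["T", "T1", "T2"]
        assert level1.counts.tolist() == [[1, 0], [0, 1], [1, 1]]

    def test_single_branch_level_skipped(self, curated):
        tree, _ = curated
        assignments = {"s1": "T1a1", "s2": "T1a1", "s3": "T1a"}
        statuses = {"s1": 1, "s2": 0, "s3": 1}
        tables = mr.level_tables(tree, assignments, statuses, "T")
        # levels 1 and 2 have a single occupied branch (T1 / T1a)
        assert [t.level for t in tables] == [3]
        assert tables[0].branches == ["T1a", "T1a1"]

    def test_collapse_matches_explicit_ancestor_walk(self, curated):
        tree, _ = curated
        rng = np.random.default_rng(0)
        t_nodes = tree.subtree_nodes("T")
        samples = {f"s{i}": t_nodes[rng.integers(len(t_nodes))] for i in range(60)}
        statuses = {s: int(rng.random() < 0.4) for s in samples}
        tables = mr.level_tables(tree, samples, statuses, "T")
        root_depth = tree.depth["T"]
        for t in tables:
            expected: dict = {}
            for s, lab in samples.items():
                rel = tree.depth[lab] - root_depth
                if rel < t.level:
                    branch = lab
                else:
                    branch = tree.root_path(lab)[root_depth + t.level]
                a, u = expected.get(branch, (0, 0))
                expected[branch] = (a + statuses[s], u + 1 - statuses[s])
            got = dict(zip(t.branches, map(tuple, t.counts.tolist())))
            assert got == expected

    def test_outside_clade_rejected(self, curated):
        tree, _ = curated
        with pytest.raises(DataError):
            mr.level_tables(tree, {"s": "H1"}, {"s": 1}, "T")


class TestPermutationTest:
    def test_exhaustive_two_branch_worked_example(self, curated):
        tree, _ = curated
        # 2 cases in one branch, 2 controls in the other; C(4,2)=6 placements,
        # the two extreme ones reach the observed statistic
        assignments = {"a": "T1a1", "b": "T1a1", "c": "T2a", "d": "T2a"}
        statuses = {"a": 1, "b": 1, "c": 0, "d": 0}
        res = mr.permutation_test(tree, assignments, statuses, "T", B=10)
        assert res.mode == "exhaustive"
        level1 = [l for l in res.levels if l.level == 1][0]
        assert level1.raw_p == pytest.approx(2 / 6)

    def test_single_level_corrected_equals_raw(self, curated):
        tree, _ = curated
        # clade J1 has a single level (J1 paragroup vs J1c)
        assignments = {"a": "J1", "b": "J1", "c": "J1c", "d": "J1c", "e": "J1c"}
        statuses = {"a": 1, "b": 0, "c": 0, "d": 1, "e": 0}
        res = mr.permutation_test(tree, assignments, statuses, "J1", B=10)
        assert res.mode == "exhaustive"
        assert res.n_levels == 1
        assert res.corrected_p == pytest.approx(res.levels[0].raw_p)

    def test_all_affected_degenerate(self, curated):
        tree, _ = curated
        assignments = {"a": "T1", "b": "T2", "c": "T2"}
        statuses = {"a": 1, "b": 1, "c": 1}
        with pytest.warns(UserWarning):
            res = mr.permutation_test(tree, assignments, statuses, "T", B=50)
        assert all(l.raw_p == 1.0 for l in res.levels)
        assert res.corrected_p == 1.0

    def test_sampled_agrees_with_exhaustive(self, curated):
        tree, _ = curated
        rng = np.random.default_rng(3)
        nodes = ["T", "T1a1", "T2a", "T2b", "T2c"]
        assignments = {f"s{i}": nodes[rng.integers(len(nodes))] for i in range(9)}
        statuses = {s: int(rng.random() < 0.5) for s in assignments}
        if sum(statuses.values()) in (0, 9):
            statuses["s0"] = 1 - statuses["s0"]
        exact = mr.permutation_test(tree, assignments, statuses, "T", B=10,
                                    exhaustive_cap=1000)
        sampled = mr.permutation_test(tree, assignments, statuses, "T", B=4000,
                                      seed=5, exhaustive_cap=0)
        assert exact.mode == "exhaustive" and sampled.mode == "sampled"
        for le, ls in zip(exact.levels, sampled.levels):
            se = 3 * np.sqrt(le.raw_p * (1 - le.raw_p) / 4000) + 1e-3
            assert abs(le.raw_p - ls.raw_p) < se
        assert abs(exact.corrected_p - sampled.corrected_p) < 0.05

    def test_corrected_never_below_min_raw(self, curated):
        tree, _ = curated
        rng = np.random.default_rng(17)
        t_nodes = tree.subtree_nodes("T")
        for trial in range(5):
            assignments = {
                f"s{i}": t_nodes[rng.integers(len(t_nodes))] for i in range(40)
            }
            statuses = {s: int(rng.random() < 0.5) for s in assignments}
            res = mr.permutation_test(
                tree, assignments, statuses, "T", B=200, seed=trial
            )
            if res.mode == "degenerate":
                continue
            assert res.corrected_p >= res.min_raw_p - 1e-12
            assert 0 < res.corrected_p <= 1

    def test_null_raw_p_super_uniform(self, curated):
        # under permuted labels the raw p at a level rejects at <= alpha
        tree, _ = curated
        rng = np.random.default_rng(23)
        t_nodes = tree.subtree_nodes("T")
        rejections = 0
        trials = 120
        for trial in range(trials):
            assignments = {
                f"s{i}": t_nodes[rng.integers(len(t_nodes))] for i in range(30)
            }
            statuses = {s: int(rng.random() < 0.4) for s in assignments}
            if sum(statuses.values()) in (0, 30):
                continue
            res = mr.permutation_test(
                tree, assignments, statuses, "T", B=99, seed=trial, exhaustive_cap=0
            )
            rejections += res.levels[0].raw_p <= 0.05
        # binomial(120, 0.05): P(X >= 14) < 1e-3
        assert rejections <= 13


class TestResampling:
    def make_data(self):
        return pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d", "e"],
                "family_id": ["f1", "f1", "f1", "f2", "f3"],
                "short_haplotype": ["h1", "h1", "h2", "h1", "h3"],
                "haplogroup": ["T1", "T1", "T2", "T1", "T2"],
                "status": [1, 0, 1, 0, 1],
            }
        )

    def test_one_per_family_haplotype_group(self):
        data = self.make_data()
        rng = np.random.default_rng(0)
        sub = mr.resample_independent(data, rng)
        # f1/h1 collapses to one of {a,b}; all other groups are singletons
        assert len(sub) == 4
        assert set(sub["sample_id"]) >= {"c", "d", "e"}
        assert len({"a", "b"} & set(sub["sample_id"])) == 1

    def test_all_singletons_identity(self):
        data = self.make_data().iloc[2:]
        sub = mr.resample_independent(data, np.random.default_rng(1))
        assert list(sub["sample_id"]) == ["c", "d", "e"]

    def test_same_family_different_haplotypes_both_kept(self):
        data = self.make_data().iloc[[0, 2]]  # f1/h1 and f1/h2
        sub = mr.resample_independent(data, np.random.default_rng(2))
        assert len(sub) == 2

    def test_selection_is_uniform(self):
        data = self.make_data()
        rng = np.random.default_rng(3)
        picks = [
            mr.resample_independent(data, rng)["sample_id"].iloc[0]
            for _ in range(400)
        ]
        frac_a = np.mean([p == "a" for p in picks])
        assert 0.4 < frac_a < 0.6


class TestResampledAssociation:
    def setup_data(self, seed=21, n=120, hr=None):
        tree, panel = mr.curated_tree()
        cfg = mr.SimConfig(
            n_individuals=n,
            hazard_ratios=hr or {},
            missing_rate=0,
            het_rate=0,
            error_rate=0,
        )
        gm, meta, truth = mr.simulate_cohort(tree, panel, cfg, seed=seed)
        clean, _ = mr.run_qc(gm, tree)
        index = mr.build_short_haplotype_index(tree, clean.panel)
        from mitorisk.assign import assignments_to_frame

        df = assignments_to_frame(mr.assign_individuals(clean, index))
        return tree, df[df["matched"]].merge(meta, on="sample_id")

    def test_r1_equals_single_test(self, curated):
        tree, data = self.setup_data()
        plan = mr.ResamplingPlan(R=1, seed=5)
        agg = mr.run_resampled_association(tree, data, "T", plan=plan, B=99)
        assert len(agg.corrected_p_values) == 1
        assert agg.mean_corrected_p == agg.corrected_p_values[0]

    def test_same_seed_identical_aggregates(self, curated):
        tree, data = self.setup_data()
        kw = dict(plan=mr.ResamplingPlan(R=5, seed=9), B=99)
        a = mr.run_resampled_association(tree, data, "T", **kw)
        b = mr.run_resampled_association(tree, data, "T", **kw)
        assert a.corrected_p_values == b.corrected_p_values
        assert a.branches.equals(b.branches)

    def test_branch_means_lie_within_ranges(self, curated):
        tree, data = self.setup_data(seed=30, n=200)
        agg = mr.run_resampled_association(
            tree, data, "T", plan=mr.ResamplingPlan(R=10, seed=2), B=99
        )
        br = agg.branches
        assert (br["mean_affected"] >= br["min_affected"]).all()
        assert (br["mean_affected"] <= br["max_affected"]).all()
        assert (br["mean_unaffected"] >= br["min_unaffected"]).all()
        assert (br["mean_unaffected"] <= br["max_unaffected"]).all()
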