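"""Panel scores, k-means subgroups, Kaplan-Meier / log-rank, and DMR ROC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methdriver import stratify
from methdriver.errors import ValidationError
from methdriver.simulate import SimConfig, generate_survival

from conftest import make_sheet


def brute_force_km(times, events):
    """Direct product-limit evaluation at each distinct event time."""
    times = np.asarray(times)
    events = np.asarray(events)
    out = {}
    s = 1.0
    for t in np.unique(times):
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & (events == 1)).sum())
        if deaths:
            s *= 1.0 - deaths / at_risk
        out[float(t)] = s
    return out


def surv_frame(times, events, prefix="s"):
    return pd.DataFrame({
        "sample": [f"{prefix}{i}" for i in range(len(times))],
        "time_days": times,
        "event": events,
    })


class TestPanelScore:
    EXPR = pd.DataFrame(
        {"s1": [2.0, 4.0, 6.0], "s2": [1.0, 1.0, 1.0]},
        index=["gA", "gB", "gC"],
    )

    def test_score_is_unweighted_mean(self):
        scores = stratify.panel_score(self.EXPR, ["gA", "gB", "gC"])
        assert scores["s1"] == pytest.approx(4.0)

    def test_single_gene_panel_is_identity(self):
        scores = stratify.panel_score(self.EXPR, ["gB"])
        assert scores["s1"] == 4.0

    def test_panel_order_irrelevant(self):
        a = stratify.panel_score(self.EXPR, ["gA", "gC", "gB"])
        b = stratify.panel_score(self.EXPR, ["gB", "gA", "gC"])
        pd.testing.assert_series_equal(a, b)

    def test_missing_panel_gene_named_in_error(self):
        with pytest.raises(ValidationError, match="gZ"):
            stratify.panel_score(self.EXPR, ["gA", "gZ"])


class TestClusterSubgroups:
    def _separable(self, n_per=10, seed=0):
        rng = np.random.default_rng(seed)
        levels = {"C1": 1000.0, "C2": 100.0, "C3": 10.0}
        cols, truth = {}, {}
        for grp, level in levels.items():
            for i in range(n_per):
                sid = f"{grp}_{i}"
                cols[sid] = level * rng.uniform(0.95, 1.05, 3)
                truth[sid] = grp
        return pd.DataFrame(cols, index=["gA", "gB", "gC"]), truth

    def test_well_separated_clusters_recovered_exactly(self):
        expr, truth = self._separable()
        labels = stratify.cluster_subgroups(expr, ["gA", "gB", "gC"], seed=3)
        assert all(labels[sid] == grp for sid, grp in truth.items())

    def test_k_one_collapses_to_single_group(self):
        expr, _ = self._separable()
        labels = stratify.cluster_subgroups(expr, ["gA", "gB", "gC"], k=1, seed=0)
        assert set(labels) == {"C1"}

    def test_same_seed_reproduces_assignment(self):
        expr, _ = self._separable(seed=4)
        a = stratify.cluster_subgroups(expr, ["gA", "gB", "gC"], seed=11)
        b = stratify.cluster_subgroups(expr, ["gA", "gB", "gC"], seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_silhouette_diagnostic_peaks_at_true_k(self):
        """Three planted clusters give k=3 the best silhouette; the
        diagnostic reports widths without choosing k."""
        expr, _ = self._separable(seed=2)
        sil = stratify.silhouette_by_k(expr, ["gA", "gB", "gC"], seed=1)
        assert sil.idxmax() == 3
        assert ((sil > -1) & (sil < 1)).all()

    def test_fewer_distinct_profiles_than_k_rejected(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [1.0, 1.0], "s3": [1.0, 1.0]},
            index=["gA", "gB"],
        )
        with pytest.raises(ValidationError, match="distinct"):
            stratify.cluster_subgroups(expr, ["gA", "gB"], k=3)


class TestFollowupFilter:
    def test_thirty_day_boundary(self):
        surv = surv_frame([29, 30, 400], [1, 1, 0])
        kept = stratify.filter_survival(surv)
        assert kept["time_days"].tolist() == [30, 400]

    def test_missing_fields_dropped(self):
        surv = surv_frame([100.0, np.nan], [1, 1])
        assert len(stratify.filter_survival(surv)) == 1


class TestKaplanMeier:
    def test_two_deaths_no_censoring_hand_example(self):
        surv = surv_frame([10, 20], [1, 1])
        groups = pd.Series(["g"] * 2, index=surv["sample"])
        res = stratify.km_estimate(surv, groups)["g"]
        curve = res["curve"].set_index("time")["survival"]
        assert curve.loc[10] == pytest.approx(0.5)
        assert curve.loc[20] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        surv = surv_frame([50, 80, 120], [0, 0, 0])
        groups = pd.Series(["g"] * 3, index=surv["sample"])
        res = stratify.km_estimate(surv, groups)["g"]
        assert (res["curve"]["survival"] == 1.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_product_limit_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        times = rng.integers(30, 2000, n)
        events = rng.integers(0, 2, n)
        surv = surv_frame(times, events)
        groups = pd.Series(["g"] * n, index=surv["sample"])
        curve = stratify.km_estimate(surv, groups)["g"]["curve"] \
            .set_index("time")["survival"]
        oracle = brute_force_km(times, events)
        for t, s in oracle.items():
            assert curve.loc[t] == pytest.approx(s)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        surv = pd.concat([
            surv_frame([100, 200, 300], [1, 1, 0], prefix="a"),
            surv_frame([100, 200, 300], [1, 1, 0], prefix="b"),
        ], ignore_index=True)
        groups = pd.Series(
            ["A"] * 3 + ["B"] * 3,
            index=surv["sample"],
        )
        res = stratify.logrank_test(surv, groups)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_three_groups_have_two_degrees_of_freedom(self):
        surv = pd.concat([
            surv_frame([100, 200], [1, 1], prefix="a"),
            surv_frame([150, 250], [1, 0], prefix="b"),
            surv_frame([120, 220], [1, 1], prefix="c"),
        ], ignore_index=True)
        groups = pd.Series(["A", "A", "B", "B", "C", "C"], index=surv["sample"])
        assert stratify.logrank_test(surv, groups)["df"] == 2

    def test_no_events_reported_undefined(self):
        surv = pd.concat([
            surv_frame([100, 200], [0, 0], prefix="a"),
            surv_frame([150, 250], [0, 0], prefix="b"),
        ], ignore_index=True)
        groups = pd.Series(["A", "A", "B", "B"], index=surv["sample"])
        res = stratify.logrank_test(surv, groups)
        assert not res["defined"] and np.isnan(res["p_value"])

    @pytest.mark.parametrize("seed", range(5))
    def test_separated_hazards_detected(self, seed):
        """Hazard ratio 5 at n=100/arm is reliably significant."""
        cfg = SimConfig(seed=seed, survival_hazards={"A": 1 / 1000, "B": 5 / 1000},
                        censoring_rate=1 / 5000)
        ids = [f"s{i}" for i in range(200)]
        assign = pd.Series(["A"] * 100 + ["B"] * 100, index=ids)
        surv = generate_survival(cfg, assign)
        filtered = stratify.filter_survival(surv)
        res = stratify.logrank_test(filtered, assign)
        assert res["p_value"] < 0.01


class TestDmrRoc:
    def _matrix(self, tumor_scores, normal_scores):
        cols = {f"T{i + 1:02d}": [v] for i, v in enumerate(tumor_scores)}
        cols.update({f"N{i + 1:02d}": [v] for i, v in enumerate(normal_scores)})
        index = pd.MultiIndex.from_tuples([("chr1", 100)], names=["chrom", "pos"])
        return pd.DataFrame(cols, index=index)

    DMR = {"chrom": "chr1", "start": 50, "end": 150, "dmr_class": "hyper"}

    def test_perfect_separation_gives_auc_one(self):
        mat = self._matrix([0.9, 0.8], [0.1, 0.2])
        res = stratify.dmr_roc(mat, self.DMR, make_sheet(2, 2))
        assert res["auc"] == 1.0
        assert res["sensitivity"] == 1.0 and res["specificity"] == 1.0

    def test_partial_overlap_counts_concordant_pairs(self):
        mat = self._matrix([3.0, 1.0], [2.0, 0.0])
        res = stratify.dmr_roc(mat, self.DMR, make_sheet(2, 2))
        assert res["auc"] == 0.75

    def test_hypo_dmr_orientation_flips_scores(self):
        mat = self._matrix([10.0, 20.0], [80.0, 90.0])
        hypo = dict(self.DMR, dmr_class="hypo")
        res = stratify.dmr_roc(mat, hypo, make_sheet(2, 2))
        assert res["auc"] == 1.0

    def test_label_shuffles_center_auc_at_half(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(0, 100, 20)
        aucs = []
        for _ in range(100):
            perm = rng.permutation(20)
            mat = self._matrix(scores[perm[:10]], scores[perm[10:]])
            aucs.append(stratify.dmr_roc(mat, self.DMR, make_sheet(10, 10))["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestSubgroupReport:
    def test_disjoint_score_ranges_are_detected(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(90)]
        assignments = pd.Series(["C1"] * 30 + ["C2"] * 30 + ["C3"] * 30, index=ids)
        scores = pd.Series(
            np.concatenate([
                rng.uniform(20, 30, 30), rng.uniform(10, 20, 30),
                rng.uniform(0, 10, 30),
            ]),
            index=ids,
        )
        res = stratify.subgroup_report(assignments, scores, None)
        assert res["score_kruskal_p"] < 0.01
        assert res["per_subgroup"].loc["C1", "n"] == 30

    def test_single_subgroup_skips_comparisons(self):
        ids = ["a", "b", "c"]
        res = stratify.subgroup_report(
            pd.Series(["C1"] * 3, index=ids),
            pd.Series([1.0, 2.0, 3.0], index=ids),
            None,
        )
        assert np.isnan(res["score_kruskal_p"])

    def test_label_permutation_preserves_kruskal_statistic(self):
        rng = np.random.default_rng(10)
        ids = [f"s{i}" for i in range(60)]
        scores = pd.Series(rng.uniform(0, 50, 60), index=ids)
        labels = pd.Series(["C1"] * 20 + ["C2"] * 20 + ["C3"] * 20, index=ids)
        swapped = labels.map({"C1": "C3", "C2": "C1", "C3": "C2"})
        a = stratify.subgroup_report(labels, scores, None)["score_kruskal_p"]
        b = stratify.subgroup_report(swapped, scores, None)["score_kruskal_p"]
        assert a == pytest.approx(b)

    def test_misaligned_sample_ids_rejected(self):
        with pytest.raises(ValidationError, match="orphan|misaligned"):
            stratify.subgroup_report(
                pd.Series(["C1"], index=["a"]),
                pd.Series([1.0], index=["b"]),
                None,
            )
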