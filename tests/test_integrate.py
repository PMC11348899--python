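"""TPM computation, DEG calling, and methylation-expression integration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from methdriver import integrate
from methdriver.errors import ValidationError
from methdriver.simulate import generate_expression

from conftest import make_sheet


def tpm_frame(tumor_rows, normal_rows, genes=None):
    tumor_rows = np.atleast_2d(tumor_rows).astype(float)
    normal_rows = np.atleast_2d(normal_rows).astype(float)
    genes = genes or [f"g{i}" for i in range(tumor_rows.shape[0])]
    data = {}
    for j in range(tumor_rows.shape[1]):
        data[f"T{j + 1:02d}"] = tumor_rows[:, j]
    for j in range(normal_rows.shape[1]):
        data[f"N{j + 1:02d}"] = normal_rows[:, j]
    return pd.DataFrame(data, index=genes)


class TestComputeTpm:
    def test_equal_lengths_reduce_to_proportions(self):
        counts = pd.DataFrame({"s1": [10, 20, 70]}, index=["a", "b", "c"])
        lengths = pd.Series([1000, 1000, 1000], index=["a", "b", "c"])
        tpm = integrate.compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm["s1"], [1e5, 2e5, 7e5])

    def test_doubling_length_halves_rate_before_renormalization(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        t1 = integrate.compute_tpm(counts, pd.Series([1000, 1000], index=["a", "b"]))
        t2 = integrate.compute_tpm(counts, pd.Series([2000, 1000], index=["a", "b"]))
        assert t2.loc["a", "s1"] / t2.loc["b", "s1"] == pytest.approx(
            0.5 * t1.loc["a", "s1"] / t1.loc["b", "s1"]
        )

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 500, (40, 6)))
        counts.iloc[0] += 1  # avoid an all-zero library
        lengths = pd.Series(rng.integers(200, 5000, 40), index=counts.index)
        tpm = integrate.compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="zero library"):
            integrate.compute_tpm(counts, pd.Series([100, 100], index=["a", "b"]))


class TestDegTest:
    def test_mean_tpm_below_ten_excluded_before_testing(self):
        tpm = tpm_frame([[9.99, 9.99, 9.99], [100, 100, 100]],
                        [[9.99, 9.99, 9.99], [10, 10, 10]])
        res = integrate.deg_test(tpm, make_sheet(3, 3))
        assert "g0" not in res.index and "g1" in res.index

    def test_exact_p_and_up_direction_at_three_vs_three(self):
        tpm = tpm_frame([[100, 110, 120]], [[10, 11, 12]])
        res = integrate.deg_test(tpm, make_sheet(3, 3), fdr_threshold=0.2)
        assert res["p_value"].iloc[0] == pytest.approx(0.1)
        assert res["direction"].iloc[0] == "up"

    def test_identical_groups_not_significant(self):
        tpm = tpm_frame([[50, 60, 70]], [[50, 60, 70]])
        res = integrate.deg_test(tpm, make_sheet(3, 3))
        assert res["direction"].iloc[0] == "ns"

    def test_bh_denominator_is_filtered_gene_count(self):
        """Adding filtered-out genes must not change the adjusted p-values."""
        rng = np.random.default_rng(8)
        strong = tpm_frame(rng.uniform(100, 200, (20, 5)),
                           rng.uniform(10, 20, (20, 5)))
        res_small = integrate.deg_test(strong, make_sheet(5, 5))
        weak = tpm_frame(rng.uniform(0, 5, (30, 5)), rng.uniform(0, 5, (30, 5)),
                         genes=[f"w{i}" for i in range(30)])
        res_big = integrate.deg_test(pd.concat([strong, weak]), make_sheet(5, 5))
        assert len(res_big) == len(res_small)
        np.testing.assert_allclose(res_big["fdr"], res_small["fdr"])


class TestClassifyMethyDeg:
    def _dmrs(self):
        return pd.DataFrame([
            {"chrom": "chr1", "start": 100, "end": 200, "n_cpgs": 4,
             "span_bp": 101, "delta": 30.0, "mean_adjacent_gap_bp": 25.0,
             "dmr_class": "hyper"},
            {"chrom": "chr1", "start": 500, "end": 600, "n_cpgs": 4,
             "span_bp": 101, "delta": -40.0, "mean_adjacent_gap_bp": 25.0,
             "dmr_class": "hypo"},
        ])

    def _deg(self, direction):
        return pd.DataFrame(
            {"mean_tpm_all": [50.0], "p_value": [0.001], "fdr": [0.004],
             "direction": [direction]},
            index=["gA"],
        )

    def test_hyper_down_is_candidate(self):
        assoc = pd.DataFrame([{"dmr_index": 0, "gene_id": "gA",
                               "region": "upstream_regulatory"}])
        out = integrate.classify_methy_deg(self._deg("down"), assoc, self._dmrs())
        assert out["category"].tolist() == ["hyper-down"]
        assert bool(out["candidate"].iloc[0])

    def test_hyper_up_is_not_candidate(self):
        assoc = pd.DataFrame([{"dmr_index": 0, "gene_id": "gA",
                               "region": "upstream_regulatory"}])
        out = integrate.classify_methy_deg(self._deg("up"), assoc, self._dmrs())
        assert out["category"].tolist() == ["hyper-up"]
        assert not bool(out["candidate"].iloc[0])

    def test_gene_without_associated_dmr_absent(self):
        out = integrate.classify_methy_deg(
            self._deg("down"),
            pd.DataFrame(columns=["dmr_index", "gene_id", "region"]),
            self._dmrs(),
        )
        assert out.empty

    def test_ambiguous_gene_resolved_by_larger_absolute_delta(self):
        assoc = pd.DataFrame([
            {"dmr_index": 0, "gene_id": "gA", "region": "upstream_regulatory"},
            {"dmr_index": 1, "gene_id": "gA", "region": "upstream_regulatory"},
        ])
        out = integrate.classify_methy_deg(self._deg("up"), assoc, self._dmrs())
        assert out["meth_direction"].tolist() == ["hypo"]  # |-40| > |30|
        assert bool(out["ambiguous"].iloc[0])
        assert bool(out["candidate"].iloc[0])  # hypo-up

    def test_candidate_set_is_exactly_hyper_down_union_hypo_up(self):
        dmrs = self._dmrs()
        # (gene, expression direction, linked DMR: 0 = hyper, 1 = hypo)
        rows = [("g1", "down", 0), ("g2", "up", 0), ("g3", "down", 1),
                ("g4", "up", 1)]
        deg = pd.DataFrame(
            {"mean_tpm_all": 50.0, "p_value": 0.001, "fdr": 0.004,
             "direction": [r[1] for r in rows]},
            index=[r[0] for r in rows],
        )
        assoc = pd.DataFrame([
            {"dmr_index": r[2], "gene_id": r[0], "region": "upstream_regulatory"}
            for r in rows
        ])
        out = integrate.classify_methy_deg(deg, assoc, dmrs)
        expected = {("g1", True), ("g2", False), ("g3", False), ("g4", True)}
        assert set(zip(out["gene_id"], out["candidate"])) == expected


class TestCorrelationProfile:
    def test_perfectly_antimonotone_vectors_give_rho_minus_one(self, small_cohort):
        genome = small_cohort["genome"]
        gid = small_cohort["drivers"][0]
        gene = genome.gene(gid)
        matrix = small_cohort["matrix"]
        samples = matrix.columns
        # overwrite one promoter CpG with a strictly decreasing pattern
        matrix = matrix.copy()
        lo, hi = gene.promoter_window
        sub = matrix.xs(gene.chrom, level="chrom")
        target_pos = sub.index[(sub.index >= lo) & (sub.index <= hi)][0]
        matrix.loc[(gene.chrom, target_pos), :] = np.arange(len(samples), dtype=float)
        tpm = pd.DataFrame(
            [np.arange(len(samples), 0, -1, dtype=float)],
            index=[gid], columns=samples,
        )
        prof = integrate.dmr_expression_correlation(
            matrix, tpm, genome, gid, (gene.chrom, target_pos, target_pos)
        )
        row = prof[prof["pos"] == target_pos].iloc[0]
        assert row["rho"] == pytest.approx(-1.0)
        assert bool(row["in_dmr"])

    def test_driver_in_dmr_cpgs_predominantly_negative(self, small_cohort):
        cfg, genome = small_cohort["config"], small_cohort["genome"]
        matrix = small_cohort["matrix"]
        tpm = generate_expression(cfg, genome, matrix)
        gid = small_cohort["drivers"][0]
        planted = next(
            d for d in cfg.planted_dmrs
            if d.chrom == genome.gene(gid).chrom
            and d.start_bp >= genome.gene(gid).promoter_window[0] - 1
        )
        prof = integrate.dmr_expression_correlation(
            matrix, tpm, genome, gid, (planted.chrom, planted.start_bp, planted.end_bp)
        )
        in_dmr = prof[prof["in_dmr"]]["rho"].dropna()
        assert len(in_dmr) >= 3
        assert (in_dmr < 0).mean() > 0.5

    def test_too_few_shared_samples_rejected(self, small_cohort):
        genome = small_cohort["genome"]
        gid = small_cohort["drivers"][0]
        matrix = small_cohort["matrix"]
        tpm = pd.DataFrame(
            [[1.0, 2.0]], index=[gid], columns=matrix.columns[:2]
        )
        with pytest.raises(ValidationError, match="shared samples"):
            integrate.dmr_expression_correlation(
                matrix, tpm, genome, gid, ("chr1", 1, 2)
            )
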