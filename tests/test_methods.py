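"""DE method behaviour: aggregation arithmetic, oracles, calibration, contracts."""

import dataclasses

import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm

from scdebench import (GeneTruth, PseudobulkMatrix, SimParams,
                       aggregate_pseudobulk, normalize_cpm, run_all_methods,
                       simulate_dataset)
from scdebench import methods as dm
from scdebench.simulate import SimulatedDataset


def _toy_dataset(counts, cell_individual, group):
    counts = np.asarray(counts)
    n_genes = counts.shape[0]
    return SimulatedDataset(
        counts=counts,
        cell_individual=np.asarray(cell_individual),
        individual_group=np.asarray(group),
        truth=GeneTruth(is_de=np.zeros(n_genes, bool), fold_change=np.ones(n_genes)),
        params=SimParams(n_genes=n_genes, n_cases=1, n_controls=1),
        seed_used=0,
    )


class TestAggregation:
    def test_sum_and_mean_arithmetic(self):
        ds = _toy_dataset([[2, 3, 5]], [0, 0, 0], ["case"])
        assert aggregate_pseudobulk(ds, "sum").values[0, 0] == 10
        assert aggregate_pseudobulk(ds, "mean").values[0, 0] == pytest.approx(10 / 3)

    def test_balanced_sum_is_n_times_mean(self, small_dataset):
        pb_sum = aggregate_pseudobulk(small_dataset, "sum")
        pb_mean = aggregate_pseudobulk(small_dataset, "mean")
        np.testing.assert_allclose(pb_sum.values, 20 * pb_mean.values)

    def test_zero_cell_individual_rejected(self):
        ds = _toy_dataset([[1, 2]], [0, 0], ["case", "control"])
        with pytest.raises(ValueError):
            aggregate_pseudobulk(ds, "sum")

    def test_unknown_aggregation_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            aggregate_pseudobulk(small_dataset, "median")

    def test_sum_scales_with_cells_but_mean_does_not(self):
        # an individual's sum column is its cell count times its mean column
        ds = _toy_dataset([[1, 2, 3, 4, 10, 20]], [0, 0, 0, 0, 1, 1],
                          ["case", "control"])
        pb_sum = aggregate_pseudobulk(ds, "sum")
        pb_mean = aggregate_pseudobulk(ds, "mean")
        np.testing.assert_allclose(pb_sum.values, pb_mean.values * np.array([4, 2]))


class TestCPM:
    def test_arithmetic(self):
        pb = PseudobulkMatrix(values=np.array([[1.0], [3.0]]),
                              individual_group=np.array(["case"]),
                              aggregation="sum")
        out = normalize_cpm(pb)
        np.testing.assert_allclose(out.values[:, 0], [250_000.0, 750_000.0])
        assert out.normalized

    def test_idempotent_and_scale_invariant(self):
        vals = np.array([[1.0, 2.0], [3.0, 6.0]])
        pb = PseudobulkMatrix(values=vals, individual_group=np.array(["case", "control"]),
                              aggregation="sum")
        once = normalize_cpm(pb)
        twice = normalize_cpm(once)
        np.testing.assert_allclose(once.values, twice.values)
        # proportional columns become identical
        np.testing.assert_allclose(once.values[:, 0], once.values[:, 1])

    def test_zero_column_rejected(self):
        pb = PseudobulkMatrix(values=np.array([[0.0], [0.0]]),
                              individual_group=np.array(["case"]),
                              aggregation="sum")
        with pytest.raises(ValueError):
            normalize_cpm(pb)

    def test_cpm_sum_equals_cpm_mean(self, small_dataset):
        # each sum column is a scalar multiple of its mean column, so CPM
        # collapses both to the same composition — balanced or not
        a = normalize_cpm(aggregate_pseudobulk(small_dataset, "sum"))
        b = normalize_cpm(aggregate_pseudobulk(small_dataset, "mean"))
        np.testing.assert_allclose(a.values, b.values)


def _welch_oracle(x, y):
    """Textbook Welch t: statistic, Satterthwaite df, two-sided p."""
    n1, n2 = len(x), len(y)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2 * scipy.stats.t.sf(abs(t), df)


class TestPseudobulk:
    def test_matches_welch_oracle(self):
        case, ctrl = np.array([8.0, 9.0, 10.0]), np.array([1.0, 2.0, 3.0])
        pb = PseudobulkMatrix(values=np.array([np.r_[case, ctrl]]),
                              individual_group=np.array(["case"] * 3 + ["control"] * 3),
                              aggregation="mean")
        res = dm.test_pseudobulk(pb)
        expected = _welch_oracle(np.log2(case + 1), np.log2(ctrl + 1))
        assert res.p_values[0] == pytest.approx(expected, abs=1e-10)
        assert res.method_name == "Pseudobulk: Mean"

    def test_identical_groups_give_p_one(self):
        vals = np.array([[3.0, 5.0, 7.0, 3.0, 5.0, 7.0]])
        pb = PseudobulkMatrix(values=vals,
                              individual_group=np.array(["case"] * 3 + ["control"] * 3),
                              aggregation="mean")
        assert dm.test_pseudobulk(pb).p_values[0] == pytest.approx(1.0)

    def test_constant_gene_gets_p_one(self):
        vals = np.full((1, 6), 2.0)
        pb = PseudobulkMatrix(values=vals,
                              individual_group=np.array(["case"] * 3 + ["control"] * 3),
                              aggregation="mean")
        assert dm.test_pseudobulk(pb).p_values[0] == 1.0

    def test_requires_two_per_group(self):
        pb = PseudobulkMatrix(values=np.array([[1.0, 2.0]]),
                              individual_group=np.array(["case", "control"]),
                              aggregation="mean")
        with pytest.raises(ValueError):
            dm.test_pseudobulk(pb)


class TestModifiedT:
    def test_equals_pseudobulk_with_one_cell_per_individual(self):
        params = SimParams(n_genes=40, prop_de=0.2, n_cases=8, n_controls=8,
                           cells_per_individual_case=1,
                           cells_per_individual_control=1, master_seed=5)
        ds = simulate_dataset(params)
        mt = dm.test_modified_t(ds)
        pb = dm.test_pseudobulk(aggregate_pseudobulk(ds, "mean"))
        np.testing.assert_allclose(mt.p_values, pb.p_values, equal_nan=True)

    def test_type1_inflation_with_donor_effects(self, null_dataset):
        res = dm.test_modified_t(null_dataset)
        rate = (res.p_values <= 0.05).mean()
        n = null_dataset.n_genes
        assert rate > 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_identical_cell_vectors_give_p_one(self):
        row = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        ds = _toy_dataset([row], [0, 0, 0, 0, 1, 1, 1, 1], ["case", "control"])
        assert dm.test_modified_t(ds).p_values[0] == pytest.approx(1.0)


class TestTobit:
    def test_matches_ols_when_no_censoring(self):
        rng = np.random.default_rng(8)
        n = 120
        grp = np.repeat([0.0, 1.0], n // 2)
        counts = np.round(20 + 6 * grp + rng.normal(0, 3, n)).astype(int)
        assert (counts > 0).all()
        ds = _toy_dataset([counts], np.arange(n) // (n // 2), ["control", "case"])
        res = dm.test_tobit(ds)
        # OLS Wald oracle with the ML variance estimate
        y = np.log2(counts + 1.0)
        case = ds.cell_is_case.astype(float)
        X = np.column_stack([np.ones(n), case])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        s2 = np.mean((y - X @ beta) ** 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p_ols = 2 * scipy.stats.norm.sf(abs(beta[1] / se))
        assert res.p_values[0] == pytest.approx(p_ols, abs=1e-6)

    def test_all_zero_gene_is_missing(self):
        ds = _toy_dataset([[0] * 8], [0] * 4 + [1] * 4, ["case", "control"])
        res = dm.test_tobit(ds)
        assert np.isnan(res.p_values[0])
        assert res.n_failed == 1

    def test_symmetric_groups_near_one(self):
        row = np.array([0, 0, 2, 5, 9, 0, 0, 2, 5, 9])
        ds = _toy_dataset([row], [0] * 5 + [1] * 5, ["case", "control"])
        res = dm.test_tobit(ds)
        assert res.p_values[0] > 0.5
        assert abs(res.effect_estimates[0]) < 1e-4


class TestHurdle:
    def test_all_detected_reduces_to_part_b(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(1, 30, size=(5, 60))  # no zeros: part A degenerate
        ds = _toy_dataset(counts, np.arange(60) // 30, ["case", "control"])
        res = dm.test_two_part_hurdle(ds, corrected=False)
        case = ds.cell_is_case
        for g in range(5):
            y = np.log2(counts[g].astype(float))
            rss1 = np.sum((y[case] - y[case].mean()) ** 2) + \
                np.sum((y[~case] - y[~case].mean()) ** 2)
            rss0 = np.sum((y - y.mean()) ** 2)
            lr = 60 * np.log(rss0 / rss1)
            expected = scipy.stats.chi2.sf(lr, 1)
            assert res.p_values[g] == pytest.approx(expected, rel=1e-6)

    def test_identical_groups_near_one(self):
        row = np.array([0, 1, 3, 8, 0, 1, 3, 8])
        ds = _toy_dataset([row], [0] * 4 + [1] * 4, ["case", "control"])
        for corrected in (False, True):
            res = dm.test_two_part_hurdle(ds, corrected=corrected)
            assert res.p_values[0] > 0.9

    def test_never_detected_gene_missing(self):
        counts = np.array([[0] * 8, [1, 2, 0, 3, 2, 0, 1, 4]])
        ds = _toy_dataset(counts, [0] * 4 + [1] * 4, ["case", "control"])
        res = dm.test_two_part_hurdle(ds, corrected=False)
        assert np.isnan(res.p_values[0])
        assert np.isfinite(res.p_values[1])
        assert res.n_failed == 1

    def test_type1_inflation_with_donor_effects(self, null_dataset):
        for corrected in (False, True):
            res = dm.test_two_part_hurdle(null_dataset, corrected=corrected)
            p = res.p_values
            rate = (p[np.isfinite(p)] <= 0.05).mean()
            n = np.isfinite(p).sum()
            assert rate > 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


class TestGEE:
    def test_cluster_size_one_equals_robust_ols(self):
        params = SimParams(n_genes=30, prop_de=0.0, n_cases=12, n_controls=12,
                           cells_per_individual_case=1,
                           cells_per_individual_control=1, master_seed=9)
        ds = simulate_dataset(params)
        res = dm.test_gee1(ds)
        Y = np.log2(ds.counts + 1.0)
        X = sm.add_constant(ds.cell_is_case.astype(float))
        for g in range(ds.n_genes):
            if np.ptp(Y[g]) == 0:
                assert res.p_values[g] == 1.0
                continue
            ols = sm.OLS(Y[g], X).fit(cov_type="HC0")
            assert res.p_values[g] == pytest.approx(ols.pvalues[1], abs=1e-6)

    def test_identical_groups_near_one(self):
        row = np.tile([0, 2, 5, 9], 4)
        ds = _toy_dataset([row], np.arange(16) // 4,
                          ["case", "case", "control", "control"])
        res = dm.test_gee1(ds)
        assert res.p_values[0] > 0.9

    def test_nominal_calibration_and_ordering(self, null_dataset):
        gee = dm.test_gee1(null_dataset)
        mt = dm.test_modified_t(null_dataset)
        pb = dm.test_pseudobulk(aggregate_pseudobulk(null_dataset, "mean"))
        n = null_dataset.n_genes
        r_gee = (gee.p_values <= 0.05).mean()
        r_mt = (mt.p_values <= 0.05).mean()
        r_pb = (pb.p_values <= 0.05).mean()
        sigma = np.sqrt(0.05 * 0.95 / n)
        # cluster-aware test stays near nominal while cell-level t explodes
        assert r_gee < 0.05 + 6 * sigma
        assert r_gee < r_mt
        assert r_pb <= r_gee + 2 * sigma


class TestRunAll:
    FAST = ("Pseudobulk: Mean", "Pseudobulk: Sum", "Modified t")

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            run_all_methods(small_dataset, roster=("DESeq2",))
        with pytest.raises(ValueError):
            run_all_methods(small_dataset, roster=())

    def test_single_method_roster(self, small_dataset):
        out = run_all_methods(small_dataset, roster=("Pseudobulk: Mean",))
        assert list(out) == ["Pseudobulk: Mean"]

    def test_deterministic_and_order_independent(self, small_dataset):
        a = run_all_methods(small_dataset, roster=self.FAST)
        b = run_all_methods(small_dataset, roster=self.FAST[::-1])
        for name in self.FAST:
            np.testing.assert_array_equal(a[name].p_values, b[name].p_values)

    def test_checksum_identical_across_methods(self, small_dataset):
        out = run_all_methods(small_dataset, roster=self.FAST)
        sums = {r.dataset_checksum for r in out.values()}
        assert len(sums) == 1 and sums.pop() == small_dataset.checksum()

    def test_all_pvalues_in_unit_interval(self, small_dataset):
        out = run_all_methods(small_dataset)
        for res in out.values():
            p = res.p_values
            assert p.shape == (small_dataset.n_genes,)
            finite = p[np.isfinite(p)]
            assert finite.min() >= 0 and finite.max() <= 1
            assert res.n_failed == int(np.isnan(p).sum())
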