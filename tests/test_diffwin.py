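import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from phasitrack.diffwin import (
    bh_adjust,
    call_differential,
    count_windows,
    estimate_common_dispersion,
    filter_low_windows,
    nb_test,
    size_class_ttest,
    size_totals,
)
from phasitrack.srio import AlignmentRecord


def _mat(rows, cols=("wt1", "wt2", "wt3", "m1", "m2", "m3")):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", 500 * i) for i in range(len(rows))], names=["chrom", "start"]
    )
    return pd.DataFrame(rows, index=idx, columns=list(cols))


DESIGN = {
    "wt1": "wildtype", "wt2": "wildtype", "wt3": "wildtype",
    "m1": "mutant", "m2": "mutant", "m3": "mutant",
}


class TestCountWindows:
    def test_half_open_window_boundary(self, records_factory):
        recs = {"lib": records_factory([499, 500])}
        mat = count_windows(recs, 500, 21)
        assert mat.loc[("chr1", 0), "lib"] == 1
        assert mat.loc[("chr1", 500), "lib"] == 1

    def test_minus_strand_assigned_by_five_prime(self):
        # leftmost 490, length 21, minus: 5' end = 510 -> window [500,1000)
        recs = {"lib": [AlignmentRecord("chr1", 490, 21, "-")]}
        mat = count_windows(recs, 500, 21)
        assert mat.index.tolist() == [("chr1", 500)]

    def test_size_partition_and_empty_library(self, records_factory):
        recs = {
            "a": records_factory([10, 20, 30], length=22),
            "b": [],
        }
        m22 = count_windows(recs, 500, 22)
        m21 = count_windows(recs, 500, 21)
        assert m22.loc[("chr1", 0), "a"] == 3
        assert m22.loc[("chr1", 0), "b"] == 0
        assert m21.empty

    def test_counts_conserve_retained_reads(self, dataset):
        for k in (21, 22, 24):
            mat = count_windows(dataset["reads"], 500, k)
            for lib, recs in dataset["reads"].items():
                assert mat[lib].sum() == sum(
                    r.copies for r in recs if r.length == k
                )


class TestFilterLowWindows:
    def test_boundary_at_min_total(self):
        mat = _mat([[3, 3, 3, 0, 0, 0], [4, 3, 3, 0, 0, 0]])
        kept = filter_low_windows(mat, 10)
        assert kept.index.tolist() == [("chr1", 500)]

    def test_all_below_threshold_warns_and_empties(self, caplog):
        mat = _mat([[1, 0, 0, 0, 0, 0]])
        with caplog.at_level("WARNING"):
            assert filter_low_windows(mat, 10).empty
        assert "below min_total" in caplog.text


class TestNbTest:
    def test_identical_counts_are_null(self):
        res = nb_test(_mat([[20, 20, 20, 20, 20, 20]]), DESIGN, dispersion=0.1)
        assert res.loc[0, "log2fc"] == 0
        assert res.loc[0, "pvalue"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_wildtype_fold_change_uses_pseudocount(self):
        res = nb_test(_mat([[0, 0, 0, 50, 60, 55]]), DESIGN, dispersion=0.1)
        # log2((55 + 0.5) / (0 + 0.5)) of the normalized group means
        assert res.loc[0, "log2fc"] == pytest.approx(np.log2(55.5 / 0.5), abs=1e-6)
        assert res.loc[0, "direction"] == "up_in_mutant"
        assert res.loc[0, "pvalue"] < 1e-6

    def test_label_swap_flips_sign_and_keeps_p(self):
        mat = _mat([[30, 25, 40, 5, 8, 3], [10, 12, 9, 30, 28, 35]])
        res = nb_test(mat, DESIGN, dispersion=0.1)
        swapped = {
            k: ("mutant" if v == "wildtype" else "wildtype") for k, v in DESIGN.items()
        }
        res2 = nb_test(mat, swapped, dispersion=0.1)
        assert np.allclose(res["pvalue"], res2["pvalue"])
        assert np.allclose(res["log2fc"], -res2["log2fc"])

    def test_matches_independent_exact_test_implementation(self):
        # expected p-values computed with edgeR 4.0.16 exactTest
        # (dispersion fixed at 0.1, equal library sizes)
        mat = _mat(
            [
                [30, 25, 40, 5, 8, 3],
                [100, 90, 110, 95, 105, 100],
                [0, 2, 1, 50, 60, 55],
                [10, 12, 9, 11, 10, 12],
                [200, 150, 180, 20, 30, 25],
            ]
        )
        expected = [1.29962692e-06, 1.0, 1.667934285e-17, 0.9310420137, 5.923702442e-11]
        res = nb_test(mat, DESIGN, dispersion=0.1)
        assert np.allclose(res["pvalue"], expected, rtol=1e-6)

    def test_missing_genotype_is_hard_error(self):
        mat = _mat([[1, 2, 3, 4, 5, 6]])
        with pytest.raises(ValueError):
            nb_test(mat, {c: "wildtype" for c in mat.columns})

    def test_common_dispersion_recovered_from_simulation(self):
        rng = np.random.default_rng(11)
        phi, mu = 0.1, 100.0
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(2000, 6))
        mat = _mat(counts.tolist())
        est = estimate_common_dispersion(mat, DESIGN)
        assert est == pytest.approx(phi, rel=0.15)

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(5)
        phi, mu, n_windows = 0.1, 50.0, 2000
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(n_windows, 6))
        res = nb_test(_mat(counts.tolist()), DESIGN, dispersion=phi)
        alpha = 0.05
        rate = (res["pvalue"] < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / n_windows)
        # exact-test discreteness makes the test conservative; the empirical
        # rate must not exceed nominal by more than binomial noise
        assert rate < alpha + 3 * se
        assert rate > 0.01


class TestBhAdjust:
    def test_step_up_oracle(self):
        # direct step-up: q_(i) = min_{j>=i} m p_(j) / j
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]).tolist() == [0.2]
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_direct_computation_on_random_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(q_sorted, 0, 1)
        assert np.allclose(bh_adjust(p), expected)

    def test_out_of_range_p_is_hard_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDifferential:
    def _results(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 500, 1000],
                "log2fc": [0.9, 3.0, 3.0],
                "pvalue": [0.001, 0.001, 0.001],
                "qvalue": [0.001, 0.049, 0.049],
                "direction": ["up_in_mutant"] * 3,
            }
        )

    def test_threshold_logic(self):
        calls = call_differential(self._results())
        assert calls["passes"].tolist() == [False, True, True]
        assert calls.loc[0, "reason"] == "fold"

    def test_excluded_region_overrides_pass(self):
        calls = call_differential(self._results(), exclude=[("chr1", 1050, 1100)])
        assert calls["passes"].tolist() == [False, True, False]
        assert calls.loc[2, "reason"] == "excluded_region"


class TestSizeClassTtest:
    def _totals(self, wt, mut):
        return pd.DataFrame(
            {"wt1": wt, "wt2": wt, "wt3": wt, "m1": mut, "m2": mut, "m3": mut},
            index=[21],
        )

    def test_identical_groups_give_p_one(self):
        res = size_class_ttest(self._totals([100], [100]), DESIGN)
        assert res.loc[21, "pvalue"] == 1.0

    def test_strong_difference_is_significant(self):
        totals = pd.DataFrame(
            {
                "wt1": [100.0], "wt2": [101.0], "wt3": [99.0],
                "m1": [50.0], "m2": [51.0], "m3": [49.0],
            },
            index=[21],
        )
        res = size_class_ttest(totals, DESIGN)
        assert res.loc[21, "pvalue"] < 0.001
        # Welch formula oracle
        wt, mut = np.array([100.0, 101, 99]), np.array([50.0, 51, 49])
        t = (mut.mean() - wt.mean()) / np.sqrt(
            wt.var(ddof=1) / 3 + mut.var(ddof=1) / 3
        )
        assert res.loc[21, "t"] == pytest.approx(t)

    def test_single_library_per_group_is_error(self):
        totals = pd.DataFrame({"wt1": [100], "m1": [50]}, index=[21])
        with pytest.raises(ValueError):
            size_class_ttest(totals, {"wt1": "wildtype", "m1": "mutant"})

    def test_size_totals_tallies_copies(self, records_factory):
        recs = {
            "a": records_factory([0, 30], length=21, copies=2)
            + records_factory([60], length=24),
        }
        tot = size_totals(recs)
        assert tot.loc[21, "a"] == 4
        assert tot.loc[24, "a"] == 1
        assert tot.loc[22, "a"] == 0
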