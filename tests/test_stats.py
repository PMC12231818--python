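"""Normality gating, group comparisons, partial correlation, and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from iscn.stats import (
    compare_groups,
    fdr_bh,
    normality_gate,
    partial_correlation,
    run_association_analysis,
    spearman_screen,
)

from oracles import bh_adjust_brute


class TestNormalityGate:
    def test_gaussian_samples_usually_pass(self):
        verdicts = [
            normality_gate([np.random.default_rng(s).normal(size=100) for _ in range(2)])
            for s in range(20)
        ]
        assert verdicts.count("normal") >= 18

    def test_skewed_samples_usually_fail(self):
        verdicts = [
            normality_gate([np.random.default_rng(s).exponential(size=50)])
            for s in range(20)
        ]
        assert verdicts.count("non-normal") >= 18

    def test_degenerate_groups_warn(self):
        with pytest.warns(UserWarning, match="constant"):
            assert normality_gate([np.ones(10)]) == "non-normal"
        with pytest.warns(UserWarning, match="size 2"):
            assert normality_gate([np.array([1.0, 2.0])]) == "non-normal"


class TestCompareGroups:
    def test_identical_groups(self):
        x = np.arange(20, dtype=float)
        result = compare_groups(x, x.copy())
        assert result.test == "t"
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_raw == pytest.approx(1.0, abs=1e-9)

    def test_large_shift_detected(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = compare_groups(rng.normal(0, 1, 50), rng.normal(2, 1, 50))
            detected += res.p_raw < 0.001
        assert detected >= 19

    def test_label_swap_flips_t_statistic(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        a = compare_groups(x, y)
        b = compare_groups(y, x)
        assert a.p_raw == pytest.approx(b.p_raw, rel=1e-12)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)

    def test_skewed_data_routed_to_rank_test(self, rng):
        res = compare_groups(rng.exponential(1, 60), rng.exponential(1, 60) + 1)
        assert res.test == "wilcoxon-mann-whitney"

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups([1.0], [1.0, 2.0])


class TestSpearmanScreen:
    def test_perfect_monotone_pairs(self):
        x = pd.DataFrame({"s": [1, 2, 3, 4, 5]})
        table = spearman_screen(x, pd.DataFrame({"up": [2, 4, 9, 16, 30], "down": [5, 4, 3, 2, 1]}))
        rho = table.set_index("variable")["rho"]
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        table = spearman_screen(
            pd.DataFrame({"s": [1, 2, 3, 4]}), pd.DataFrame({"v": [7, 7, 7, 7]})
        )
        assert bool(table["undefined"].iloc[0])
        assert np.isnan(table["rho"].iloc[0])

    def test_null_pairs_rarely_large(self):
        large = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = spearman_screen(
                pd.DataFrame({"s": rng.normal(size=100)}),
                pd.DataFrame({"v": rng.normal(size=100)}),
            )
            large += abs(t["rho"].iloc[0]) >= 0.3
        assert large <= 1


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=50), rng.normal(size=50)
            r, p = partial_correlation(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_confounder_removed(self, rng):
        z = rng.normal(size=300)
        x = -3 * z + 0.1 * rng.normal(size=300)
        y = 2 * z + 0.1 * rng.normal(size=300)
        r_partial, _ = partial_correlation(x, y, z)
        r_marginal = np.corrcoef(x, y)[0, 1]
        assert abs(r_partial) < abs(r_marginal)
        assert abs(r_partial) < 0.2

    def test_matches_explicit_residual_regression_oracle(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        cov = rng.normal(size=(60, 3))
        r, _ = partial_correlation(x, y, cov)
        design = np.column_stack([np.ones(60), cov])
        beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
        oracle = sps.pearsonr(x - design @ beta_x, y - design @ beta_y).statistic
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = pd.DataFrame(
            {
                "x": rng.normal(size=80),
                "y": rng.normal(size=80),
                "c1": rng.normal(size=80),
                "c2": rng.normal(size=80),
            }
        )
        data["x"] += 0.5 * data["c1"]
        data["y"] += 0.5 * data["c1"]
        ref = pingouin.partial_corr(data, x="x", y="y", covar=["c1", "c2"])
        r, p = partial_correlation(data["x"], data["y"], data[["c1", "c2"]])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        cov = rng.normal(size=(50, 2))
        r1, p1 = partial_correlation(x, y, cov)
        r2, p2 = partial_correlation(3 * x - 1, -0.5 * y + 4, 10 * cov + 2)
        assert abs(r1) == pytest.approx(abs(r2), abs=1e-10)
        assert np.sign(r2) == -np.sign(r1)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_spearman_variant_is_rank_based(self, rng):
        x = rng.normal(size=60)
        y = np.exp(x) + 0.1 * rng.normal(size=60)  # monotone, nonlinear link
        r_rank, _ = partial_correlation(x, y, method="spearman")
        assert r_rank == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)
        cov = rng.normal(size=(60, 2))
        r, _ = partial_correlation(x, y, cov, method="spearman")
        oracle, _ = partial_correlation(
            sps.rankdata(x),
            sps.rankdata(y),
            np.column_stack([sps.rankdata(cov[:, j]) for j in range(2)]),
        )
        assert r == pytest.approx(oracle, abs=1e-12)
        with pytest.raises(ValueError, match="method"):
            partial_correlation(x, y, method="kendall")

    def test_collinear_covariates_rejected(self, rng):
        z = rng.normal(size=30)
        cov = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(rng.normal(size=30), rng.normal(size=30), cov)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            partial_correlation(np.ones(4), np.ones(4), np.ones((4, 2)))


class TestFdrBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_saturated_vectors(self):
        assert fdr_bh([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(fdr_bh(p), bh_adjust_brute(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_bh([0.5, 1.2])


class TestRunAssociationAnalysis:
    @staticmethod
    def make_inputs(rng, n=60, n_regions=5):
        subjects = [f"S{i:03d}" for i in range(n)]
        signal = rng.normal(size=n)
        rows = []
        for j in range(n_regions):
            auc_val = (signal if j == 0 else rng.normal(size=n)) + 0.3 * rng.normal(size=n)
            for i, sid in enumerate(subjects):
                rows.append((sid, f"R{j:03d}", "degree", auc_val[i]))
        auc = pd.DataFrame(rows, columns=["subject_id", "region_label", "metric", "auc"])
        clinical = pd.DataFrame(
            {
                "subject_id": subjects,
                "mbic_total": 5 * signal + rng.normal(size=n),
                "sex": rng.choice(["M", "F"], size=n),
                "age": rng.normal(70, 5, n),
                "disease_duration": rng.gamma(2, 1.5, n),
                "mmse": rng.normal(22, 3, n),
            }
        )
        return auc, clinical

    def test_detects_signal_region_and_orders_p(self, rng):
        auc, clinical = self.make_inputs(rng)
        table = run_association_analysis(
            auc, clinical, scores=("mbic_total",), metrics=("degree",)
        )
        assert len(table) == 5
        assert np.all(table["p_fdr"] >= table["p_raw"] - 1e-15)
        assert np.all(table["R"].abs() <= 1)
        best = table.sort_values("p_fdr").iloc[0]
        assert best["region_label"] == "R000" and best["significant"]

    def test_missing_covariates_dropped_listwise(self, rng):
        auc, clinical = self.make_inputs(rng)
        clinical.loc[:4, "mmse"] = np.nan
        table = run_association_analysis(
            auc, clinical, scores=("mbic_total",), metrics=("degree",)
        )
        assert (table["n"] == 55).all()

    def test_unknown_metric_rejected(self, rng):
        auc, clinical = self.make_inputs(rng)
        with pytest.raises(ValueError, match="efficiency"):
            run_association_analysis(
                auc, clinical, scores=("mbic_total",), metrics=("efficiency",)
            )
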