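import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from sexshift.deg import (AnalysisConfig, EstimationError, compare_deg_sets,
                          compare_groups, fc_cutoff_diagnostic, filter_degs,
                          fit_moderated_model, fold_changes, summarize_deg_sets,
                          trigamma_inverse)
from sexshift.io import DesignError, GroupSpec
from conftest import make_dataset

F_CTRL = GroupSpec.parse("F:control")
M_CTRL = GroupSpec.parse("M:control")


def _deg_frame(p_values, mean_a, mean_b):
    n = len(p_values)
    mean_a, mean_b = np.asarray(mean_a, float), np.asarray(mean_b, float)
    return pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "mean_a": mean_a, "mean_b": mean_b,
        "sd_a": 0.3, "sd_b": 0.3, "n_a": 5, "n_b": 3,
        "t_stat": 1.0, "df": 6.0, "p_value": p_values,
        "direction": np.where(mean_a > mean_b, "up", "down"),
        "max_group_mean": np.maximum(mean_a, mean_b),
    })


class TestModeratedVarianceModel:
    def test_trigamma_inverse_inverts_trigamma(self):
        for x in np.logspace(-5, 6, 23):
            y = trigamma_inverse(x)
            assert special.polygamma(1, y) == pytest.approx(x, rel=1e-6)

    def test_identical_variances_give_infinite_prior(self):
        model = fit_moderated_model(np.full(100, 0.25), 6.0)
        assert model.infinite_prior
        np.testing.assert_allclose(model.s_tilde_sq, model.s0_sq)
        assert model.s0_sq == pytest.approx(0.25)

    def test_zero_prior_df_disables_shrinkage(self, rng):
        s2 = rng.uniform(0.01, 1.0, 50)
        model = fit_moderated_model(s2, 6.0, d0=0.0)
        np.testing.assert_allclose(model.s_tilde_sq, s2)

    def test_posterior_between_prior_and_sample_variance(self, rng):
        s2 = rng.chisquare(4, 200) * 0.05
        model = fit_moderated_model(s2, 6.0)
        lo = np.minimum(s2, model.s0_sq)
        hi = np.maximum(s2, model.s0_sq)
        assert ((model.s_tilde_sq >= lo - 1e-12) & (model.s_tilde_sq <= hi + 1e-12)).all()

    def test_recovers_planted_scaled_f_prior(self):
        # variances drawn from the scaled-F marginal with d0=4, s0^2=0.04
        d0_true, s0_true, dg = 4.0, 0.04, 6.0
        rng = np.random.default_rng(11)
        d0_est, s0_est = [], []
        for _ in range(20):
            sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 500)
            s2 = sigma2 * rng.chisquare(dg, 500) / dg
            model = fit_moderated_model(s2, dg)
            d0_est.append(model.d0)
            s0_est.append(model.s0_sq)
        assert np.mean(d0_est) == pytest.approx(d0_true, rel=0.25)
        assert np.mean(s0_est) == pytest.approx(s0_true, rel=0.25)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(EstimationError):
            fit_moderated_model(np.zeros(10), 6.0)


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self, rng):
        block = rng.uniform(2, 12, (20, 3))
        matrix, design = make_dataset({("F", "control"): block,
                                       ("M", "control"): block.copy()})
        res = compare_groups(matrix, design, F_CTRL, M_CTRL)
        np.testing.assert_allclose(res["t_stat"], 0.0)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_student_t_textbook_fixture(self):
        matrix, design = make_dataset({
            ("F", "control"): np.array([[1, 2, 3], [1, 2, 3]]),
            ("M", "control"): np.array([[4, 5, 6], [4, 5, 6]]),
        })
        res = compare_groups(matrix, design, F_CTRL, M_CTRL,
                             AnalysisConfig(test="student"))
        np.testing.assert_allclose(res["t_stat"], -3.674, atol=5e-4)
        np.testing.assert_allclose(res["p_value"], 0.0214, atol=5e-4)
        assert (res["df"] == 4).all()
        assert (res["direction"] == "down").all()

    def test_moderated_with_zero_prior_df_equals_student(self, rng):
        matrix, design = make_dataset({
            ("F", "control"): rng.uniform(2, 12, (50, 5)),
            ("M", "control"): rng.uniform(2, 12, (50, 3)),
        })
        student = compare_groups(matrix, design, F_CTRL, M_CTRL,
                                 AnalysisConfig(test="student"))
        moderated = compare_groups(matrix, design, F_CTRL, M_CTRL, d0=0.0)
        np.testing.assert_allclose(moderated["p_value"], student["p_value"],
                                   atol=1e-12)

    def test_infinite_prior_df_pools_all_probes(self, rng):
        matrix, design = make_dataset({
            ("F", "control"): rng.uniform(2, 12, (50, 5)),
            ("M", "control"): rng.uniform(2, 12, (50, 3)),
        })
        res = compare_groups(matrix, design, F_CTRL, M_CTRL, d0=np.inf)
        # one shared variance: t proportional to the mean difference
        se_implied = (res["mean_a"] - res["mean_b"]) / res["t_stat"]
        np.testing.assert_allclose(se_implied, se_implied.iloc[0], atol=1e-10)

    def test_direction_matches_sign_of_mean_difference(self, rng):
        matrix, design = make_dataset({
            ("F", "control"): rng.uniform(2, 12, (30, 3)),
            ("M", "control"): rng.uniform(2, 12, (30, 3)),
        })
        res = compare_groups(matrix, design, F_CTRL, M_CTRL)
        expected = np.where(res["mean_a"] > res["mean_b"], "up", "down")
        assert (res["direction"] == expected).all()
        np.testing.assert_allclose(
            res["max_group_mean"], np.maximum(res["mean_a"], res["mean_b"]))

    def test_overlapping_groups_rejected(self, small_dataset):
        matrix, design = small_dataset
        both = GroupSpec.parse("F:control,M:control")
        with pytest.raises(DesignError, match="share"):
            compare_groups(matrix, design, both, F_CTRL)

    def test_single_sample_group_rejected(self, rng):
        matrix, design = make_dataset({
            ("F", "control"): rng.uniform(2, 12, (5, 1)),
            ("M", "control"): rng.uniform(2, 12, (5, 3)),
        })
        with pytest.raises(DesignError, match="need >= 2"):
            compare_groups(matrix, design, F_CTRL, M_CTRL)


@pytest.mark.parametrize("n_a,n_b", [(5, 3), (4, 4)])
def test_moderated_t_matches_limma_reference(tmp_path, n_a, n_b):
    """Cross-check the full empirical-Bayes stage against Bioconductor limma."""
    rng = np.random.default_rng(101)
    g = 200
    sigma2 = 0.04 * 4.0 / rng.chisquare(4.0, g)
    mu = rng.uniform(3, 9, g)
    effect = np.where(rng.random(g) < 0.2, rng.normal(0, 1, g), 0.0)
    a = mu[:, None] + effect[:, None] + rng.normal(0, 1, (g, n_a)) * np.sqrt(sigma2)[:, None]
    b = mu[:, None] + rng.normal(0, 1, (g, n_b)) * np.sqrt(sigma2)[:, None]
    matrix, design = make_dataset({("F", "control"): a, ("M", "control"): b})
    res = compare_groups(matrix, design, F_CTRL, M_CTRL)

    mat_path = tmp_path / "mat.tsv"
    matrix.values.to_csv(mat_path, sep="\t")
    out_path = tmp_path / "limma.tsv"
    script = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{mat_path}", row.names=1))
    design <- cbind(A=c(rep(1,{n_a}),rep(0,{n_b})), B=c(rep(0,{n_a}),rep(1,{n_b})))
    fit <- eBayes(contrasts.fit(lmFit(x, design), c(1,-1)))
    write.table(data.frame(t=fit$t, p=fit$p.value), "{out_path}",
                sep="\\t", row.names=FALSE, quote=FALSE)
    """
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(out_path, sep="\t")
    np.testing.assert_allclose(res["t_stat"], ref["t"], atol=1e-8)
    np.testing.assert_allclose(res["p_value"], ref["p"], atol=1e-8)


class TestFilterDegs:
    def test_expression_filter_and_p_threshold(self):
        records = _deg_frame([0.04, 0.04, 0.2, 0.05],
                             mean_a=[1.4, 1.6, 5.0, 5.0],
                             mean_b=[1.2, 0.2, 5.0, 4.0])
        out = filter_degs(records)
        # p=0.04 & max mean 1.4 -> removed; p=0.04 & 1.6 -> kept;
        # p=0.2 -> removed; p exactly alpha -> removed (strict <)
        assert out["probe_id"].tolist() == ["p1"]

    def test_subset_idempotent_and_sorted(self, rng):
        records = _deg_frame(rng.uniform(size=200),
                             rng.uniform(0.5, 12, 200), rng.uniform(0.5, 12, 200))
        once = filter_degs(records)
        twice = filter_degs(once)
        pd.testing.assert_frame_equal(once, twice)
        assert set(once["probe_id"]) <= set(records["probe_id"])
        assert once["p_value"].is_monotonic_increasing

    def test_null_retention_decomposes_into_alpha_and_filter(self):
        # no true effects: P(retained) = P(p < alpha) * P(pass filter | p < alpha).
        # The two events are positively dependent (a significant difference
        # inflates the max group mean), so the conditional form is the right
        # factorization; the rejection rate itself must match alpha.
        rng = np.random.default_rng(5)
        g, alpha = 10_000, 0.05
        base = rng.uniform(0.5, 3.0, g)
        f = base[:, None] + rng.normal(0, 0.3, (g, 5))
        m = base[:, None] + rng.normal(0, 0.3, (g, 3))
        matrix, design = make_dataset({("F", "control"): f, ("M", "control"): m})
        records = compare_groups(matrix, design, F_CTRL, M_CTRL)
        kept = filter_degs(records)
        sig = records["p_value"] < alpha
        assert abs(sig.mean() - alpha) < 2.576 * np.sqrt(alpha * (1 - alpha) / g)
        pass_given_sig = (records.loc[sig, "max_group_mean"] >= 1.5).mean()
        assert len(kept) == round(sig.sum() * pass_given_sig)
        # dependence direction: selection enriches for high expression
        assert pass_given_sig >= (records["max_group_mean"] >= 1.5).mean()


class TestSummaries:
    @pytest.mark.parametrize("total,up,up_pct,down_pct", [
        (2585, 2135, 83, 17),   # control-F vs control-M
        (1690, 813, 48, 52),    # BPA50-M vs BPA50-F
        (10, 10, 100, 0),
    ])
    def test_percentages_round_half_up(self, total, up, up_pct, down_pct):
        df = _deg_frame(np.full(total, 0.01), np.ones(total), np.ones(total) * 2)
        df["direction"] = ["up"] * up + ["down"] * (total - up)
        summary = summarize_deg_sets({"set": df}).iloc[0]
        assert summary["up_percent"] == up_pct
        assert summary["down_percent"] == down_pct
        assert summary["up"] + summary["down"] == summary["total"] == total

    def test_empty_set_flagged(self):
        summary = summarize_deg_sets({"empty": _deg_frame([], [], [])}).iloc[0]
        assert summary["total"] == 0 and summary["empty"]
        assert summary["up_percent"] == 0

    def test_percentages_sum_to_100_within_rounding(self, rng):
        for _ in range(10):
            n = rng.integers(1, 400)
            df = _deg_frame(np.full(n, 0.01), np.ones(n), np.ones(n) * 2)
            df["direction"] = rng.choice(["up", "down"], n)
            s = summarize_deg_sets({"x": df}).iloc[0]
            assert abs(s["up_percent"] + s["down_percent"] - 100) <= 1


class TestCompareDegSets:
    def test_identical_sets(self):
        df = _deg_frame([0.01] * 5, np.arange(5) + 2.0, np.arange(5) + 1.0)
        res = compare_deg_sets(df, df.copy())
        assert res["overlap_count"] == 5
        assert res["overlap_fraction_a"] == res["overlap_fraction_b"] == 1.0
        assert res["direction_match_fraction"] == 1.0

    def test_disjoint_sets_have_undefined_match(self):
        a = _deg_frame([0.01] * 3, [2, 2, 2], [1, 1, 1])
        b = a.copy().assign(probe_id=["q0", "q1", "q2"])
        res = compare_deg_sets(a, b)
        assert res["overlap_count"] == 0
        assert np.isnan(res["direction_match_fraction"])

    def test_planted_overlap_and_agreement(self, rng):
        n, overlap_frac, agree_frac = 1000, 0.4, 0.7
        n_overlap = int(n * overlap_frac)
        ids_a = [f"a{i}" for i in range(n)]
        shared = ids_a[:n_overlap]
        ids_b = shared + [f"b{i}" for i in range(n - n_overlap)]
        dirs_a = rng.choice(["up", "down"], n)
        agree = rng.random(n_overlap) < agree_frac
        dirs_b = np.concatenate([
            np.where(agree, dirs_a[:n_overlap],
                     np.where(dirs_a[:n_overlap] == "up", "down", "up")),
            rng.choice(["up", "down"], n - n_overlap),
        ])
        a = _deg_frame([0.01] * n, np.full(n, 2.0), np.ones(n)).assign(
            probe_id=ids_a, direction=dirs_a)
        b = _deg_frame([0.01] * n, np.full(n, 2.0), np.ones(n)).assign(
            probe_id=ids_b, direction=dirs_b)
        res = compare_deg_sets(a, b)
        assert res["overlap_count"] == n_overlap
        ci = 2.576 * np.sqrt(agree_frac * (1 - agree_frac) / n_overlap)
        assert abs(res["direction_match_fraction"] - agree.mean()) < 1e-12
        assert abs(res["direction_match_fraction"] - agree_frac) < ci


class TestFCDiagnostic:
    def test_fold_change_arithmetic(self):
        records = _deg_frame([0.01, 0.01], [3.0, 10.0], [2.4, 9.0])
        fc = fold_changes(records)
        np.testing.assert_allclose(fc, [1.25, 10.0 / 9.0])
        diag = fc_cutoff_diagnostic(records, AnalysisConfig(fc_cutoff=1.2))
        assert diag["n_before"] == 2 and diag["n_after"] == 1
        assert diag["percent_removed"] == 50

    def test_nonpositive_group_mean_excluded(self):
        records = _deg_frame([0.01, 0.01], [3.0, 2.0], [0.0, 1.0])
        diag = fc_cutoff_diagnostic(records, AnalysisConfig(fc_cutoff=1.2))
        assert diag["n_excluded_undefined_fc"] == 1
        assert diag["n_before"] == 1

    def test_level_independent_shifts_bias_cutoff_to_low_expression(self, rng):
        # constant absolute difference => high-expression probes have small FC,
        # so the cutoff preferentially drops them and expr_ratio < 1
        base = rng.uniform(1.5, 12, 4000)
        records = _deg_frame(np.full(4000, 0.01), base + 0.5, base)
        diag = fc_cutoff_diagnostic(records, AnalysisConfig(fc_cutoff=1.2))
        assert 0 < diag["n_after"] < diag["n_before"]
        assert diag["expr_ratio"] < 1.0
        assert diag["mean_expr_after"] < diag["mean_expr_before"]
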