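import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oscimap import clinstats


class TestInverseNormal:
    def test_rank_preservation(self):
        rng = np.random.default_rng(0)
        v = rng.exponential(size=150)
        out = clinstats.normalize_to_normal(v)
        assert stats.spearmanr(v, out).statistic == 1.0

    def test_ks_against_standard_normal(self):
        rng = np.random.default_rng(1)
        out = clinstats.normalize_to_normal(rng.exponential(size=200) ** 2)
        stat = stats.kstest(out, "norm").statistic
        assert stat < 1.6276 / np.sqrt(200)  # alpha = 0.01 critical value

    def test_output_sums_to_zero_by_quantile_symmetry(self):
        rng = np.random.default_rng(2)
        out = clinstats.normalize_to_normal(rng.random(173))
        assert abs(out.sum()) < 1e-10

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            clinstats.normalize_to_normal(np.ones(10))


class TestSummaryTTest:
    def test_mmse_group_comparison(self):
        res = clinstats.summary_t_test(28.68, 1.03, 25, 28.76, 1.05, 25)
        assert res["df"] == 48
        assert abs(res["t"]) == pytest.approx(0.27, abs=0.005)
        assert res["p"] > 0.5

    def test_identical_groups_give_zero(self):
        res = clinstats.summary_t_test(10.0, 2.0, 12, 10.0, 2.0, 12)
        assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_vanishing_sds_blow_up_t(self):
        res = clinstats.summary_t_test(11.0, 1e-12, 10, 10.0, 1e-12, 10)
        assert abs(res["t"]) > 1e10

    def test_matches_raw_data_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(20) + 0.5, rng.standard_normal(25)
        res = clinstats.summary_t_test(a.mean(), a.std(ddof=1), len(a),
                                       b.mean(), b.std(ddof=1), len(b))
        ref = stats.ttest_ind(a, b)  # pooled-variance Student t
        assert res["t"] == pytest.approx(ref.statistic, rel=1e-10)
        assert res["p"] == pytest.approx(ref.pvalue, rel=1e-10)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = np.random.default_rng(4).standard_normal(25)
        res = clinstats.oneway_anova(g, g.copy(), g.copy())
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_dfs_for_three_groups_of_25(self):
        rng = np.random.default_rng(5)
        res = clinstats.oneway_anova(*[rng.poisson(100, 25) for _ in range(3)])
        assert (res["df1"], res["df2"]) == (2, 72)

    def test_matches_bruteforce_sums_of_squares(self):
        rng = np.random.default_rng(6)
        groups = [rng.standard_normal(n) + m for n, m in ((10, 0), (12, 0.5), (9, 1))]
        res = clinstats.oneway_anova(*groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ssb / 2) / (ssw / (len(allv) - 3))
        assert res["F"] == pytest.approx(f, abs=1e-10)


class TestLMM:
    def test_exact_fit_recovers_slope(self):
        x = np.linspace(-2, 2, 30)
        d = pd.DataFrame({"y": 2.0 * x, "x": x,
                          "subject_id": [f"s{i}" for i in range(30)]})
        res = clinstats.fit_lmm(d, "y", ("x",))
        assert res.boundary  # singleton groups -> flagged boundary solution
        assert res.params["x"] == pytest.approx(2.0, abs=1e-10)

    def test_boundary_solution_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        y = 1.5 + 0.7 * x + rng.standard_normal(40)
        d = pd.DataFrame({"y": y, "x": x, "subject_id": np.arange(40)})
        res = clinstats.fit_lmm(d, "y", ("x",))
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ref.params, atol=1e-6)

    def test_estimate_within_exact_sampling_interval(self):
        """Monte-Carlo oracle: ~95% of ML estimates fall inside the exact
        conditional 95% interval around the generating slope."""
        rng = np.random.default_rng(8)
        beta, n, reps = 0.5, 25, 200
        inside = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = beta * x + rng.standard_normal(n)
            d = pd.DataFrame({"y": y, "x": x, "subject_id": np.arange(n)})
            res = clinstats.fit_lmm(d, "y", ("x",))
            half = stats.t.ppf(0.975, n - 2) / np.sqrt(((x - x.mean()) ** 2).sum())
            inside += abs(res.params["x"] - beta) <= half
        frac = inside / reps
        assert 0.90 <= frac <= 0.99  # 3 sigma band around 0.95

    def test_rank_deficient_design_names_columns(self):
        x = np.random.default_rng(9).standard_normal(30)
        d = pd.DataFrame({"y": x * 2, "a": x, "b": 2 * x,
                          "subject_id": np.arange(30)})
        with pytest.raises(ValueError, match="collinear"):
            clinstats.fit_lmm(d, "y", ("a", "b"))

    def test_random_intercept_recovered_with_repeated_measures(self):
        rng = np.random.default_rng(10)
        n_sub, per = 30, 4
        u = 2.0 * rng.standard_normal(n_sub)
        rows = []
        for i in range(n_sub):
            x = rng.standard_normal(per)
            y = 1.0 + 0.8 * x + u[i] + 0.5 * rng.standard_normal(per)
            for xx, yy in zip(x, y):
                rows.append({"y": yy, "x": xx, "subject_id": f"s{i}"})
        d = pd.DataFrame(rows)
        res = clinstats.fit_lmm(d, "y", ("x",))
        assert not res.boundary
        assert res.params["x"] == pytest.approx(0.8, abs=0.15)
        assert res.re_variance > 1.0  # true variance 4


class TestLRT:
    def test_identical_models_give_zero(self):
        d = _assoc_data(seed=11)
        full = clinstats.fit_lmm(d, "y", ("age",))
        chi2, df, p = clinstats.lrt(full, full)
        assert chi2 == 0.0 and p == 1.0

    @pytest.mark.parametrize("chi2, expected_p", [(4.60, 0.032), (4.04, 0.044)])
    def test_chi2_tail_pairings(self, chi2, expected_p):
        assert stats.chi2.sf(chi2, 1) == pytest.approx(expected_p, abs=5e-4)

    def test_non_nested_rejected(self):
        d = _assoc_data(seed=12)
        a = clinstats.fit_lmm(d, "y", ("age",))
        b = clinstats.fit_lmm(d, "y", ("power",))
        with pytest.raises(ValueError):
            clinstats.lrt(a, b)

    def test_chi2_invariant_to_predictor_rescaling(self):
        d = _assoc_data(seed=13, effect=0.5)
        _, chi2_a, _, _ = clinstats.lrt_for_predictor(d, "y", ("age", "power"), "power")
        d2 = d.assign(power=d["power"] * 37.5)
        _, chi2_b, _, _ = clinstats.lrt_for_predictor(d2, "y", ("age", "power"), "power")
        assert chi2_a == pytest.approx(chi2_b, rel=1e-8)


def _assoc_data(seed=0, n=40, effect=0.0):
    rng = np.random.default_rng(seed)
    age = rng.standard_normal(n)
    power = rng.standard_normal(n)
    y = 0.2 * age + effect * power + rng.standard_normal(n)
    return pd.DataFrame({"y": y, "age": age, "power": power,
                         "subject_id": np.arange(n)})


class TestCalibration:
    def test_null_rejection_rate_near_nominal_quick(self):
        res = clinstats.simulate_null_lrt(n_subjects=100, n_replicates=200, seed=0)
        assert 0.01 <= res["rejection_rate"] <= 0.10  # loose screen; exact in acceptance

    def test_sign_recovery_quick(self):
        res = clinstats.simulate_sign_recovery(n_replicates=25, seed=1)
        assert res["sign_recovery_rate"] >= 0.8


class TestAssociationSuite:
    def test_recovers_strong_coupling_and_structure(self):
        from oscimap import synth

        rng = np.random.default_rng(14)
        n = 40
        z_theta = rng.standard_normal(n)
        z_beta = rng.standard_normal(n)
        gains = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "z_op_beta_off": z_beta,
            "z_motor_beta_off": rng.standard_normal(n),
            "z_fp_theta_on": z_theta,
        })
        model = synth.ClinicalModel(
            updrs_off=synth.Coupling("op_beta", "off", -0.9, 24.0, 8.0),
            dupdrs=synth.Coupling("fp_theta", "on", -0.9, -5.0, 4.0),
        )
        clinical = synth.simulate_clinical(gains, model, rng)
        clinical["cohort"] = "PD"
        feats = []
        for cid, state, z in (("op_beta", "off", z_beta), ("fp_theta", "on", z_theta)):
            for i in range(n):
                feats.append({"subject_id": f"s{i}", "cluster_id": cid,
                              "state": state,
                              "median_power": z[i] + 0.1 * rng.standard_normal()})
        report = clinstats.association_suite(
            pd.DataFrame(feats), clinical,
            off_clusters=("op_beta",), on_theta_cluster="fp_theta")
        off = report[(report.outcome == "updrs_motor_off") & (report.cluster == "op_beta")]
        assert off["p"].iloc[0] < 0.01 and off["estimate"].iloc[0] < 0
        on = report[report.outcome == "delta_updrs"]
        assert on["p"].iloc[0] < 0.01 and on["estimate"].iloc[0] < 0
        ledd = report[report.outcome == "ledd"]
        assert len(ledd) == 1  # modelled, with unadjusted p reported
        assert "p_bh_supplementary" in report.columns
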