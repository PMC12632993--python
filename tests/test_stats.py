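"""Correlations, mixed model, penalized-spline GAM and bootstrap contrast."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata

from lossycomp import stats as st
from lossycomp.containers import ValidationError


class TestSpearman:
    def test_monotone_sequences(self):
        assert st.spearman_corr([1, 2, 3, 4], [2, 4, 9, 11])[0] == 1.0
        assert st.spearman_corr([1, 2, 3, 4], [5, 3, 2, 1])[0] == -1.0

    def test_hand_ranked_example(self):
        rho, _ = st.spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_agrees_with_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rho, _ = st.spearman_corr(x, y)
            oracle = pearsonr(rankdata(x), rankdata(y)).statistic
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.raises(st.UndefinedStatisticError):
            st.spearman_corr([1, 1, 1], [1, 2, 3])


class TestAdjustPvalues:
    def test_bonferroni_multiplication(self):
        out = st.adjust_pvalues([0.01, 0.02, 0.03], "bonferroni")
        assert np.allclose(out, [0.03, 0.06, 0.09])

    def test_bh_step_up_hand_computation(self):
        out = st.adjust_pvalues([0.01, 0.04, 0.03, 0.005], "fdr")
        assert np.allclose(out, [0.02, 0.04, 0.04, 0.02])

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "fdr"):
            assert st.adjust_pvalues([0.037], method)[0] == pytest.approx(0.037)

    def test_outputs_bounded_and_bonferroni_dominates(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 30)
        for method in ("bonferroni", "fdr"):
            out = st.adjust_pvalues(p, method)
            assert (out >= 0).all() and (out <= 1).all()
        assert (st.adjust_pvalues(p, "bonferroni") >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            st.adjust_pvalues([0.5, 1.2], "fdr")


def _mixed_sim(seed, n_part=100, re_sd=0.2, noise_sd=0.05, beta1=0.5, age=False):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_part):
        u = rng.normal(0, re_sd)
        a = rng.uniform(18, 80)
        for b in range(5):
            x = 0.1 + 0.2 * b
            y = 0.1 + beta1 * x + (0.002 * a if age else 0.0) + u + rng.normal(0, noise_sd)
            rows.append({"participant": f"p{p}", "ldi": y, "lossiness": x, "age": a})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_noiseless_exact_recovery(self):
        df = _mixed_sim(0, n_part=20, re_sd=0.0, noise_sd=0.0)
        fit = st.fit_mixed_ldi(df)
        assert fit.beta1 == pytest.approx(0.5, abs=1e-6)
        assert fit.singular and fit.fallback_ols is not None

    def test_noisy_estimate_within_two_se(self):
        fit = st.fit_mixed_ldi(_mixed_sim(42))
        est = fit.params.loc["lossiness", "estimate"]
        se = fit.params.loc["lossiness", "se"]
        assert abs(est - 0.5) <= 2 * se
        assert fit.random_intercept_var > 0

    def test_include_age_controls_formula(self):
        with_age = st.fit_mixed_ldi(_mixed_sim(1, age=True), include_age=True)
        without = st.fit_mixed_ldi(_mixed_sim(1, age=True), include_age=False)
        assert "age" in with_age.params.index
        assert "age" not in without.params.index

    def test_too_few_participants_rejected(self):
        df = _mixed_sim(0, n_part=1)
        with pytest.raises(ValidationError):
            st.fit_mixed_ldi(df)


def _gam_sim(seed, n=1000, modulated=True):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    age = rng.uniform(18, 80, n)
    steep = 1 + (3 * (age - 18) / 62 if modulated else 0.0)
    y = 0.1 + 0.5 * (1 - np.exp(-steep * x)) + rng.normal(0, 0.08, n)
    return pd.DataFrame({"ldi": y, "lossiness": x, "age": age})


class TestGAM:
    def test_linear_relation_degenerates_to_linear_smooth(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 400)
        y = 0.2 + 0.6 * x + rng.normal(0, 0.05, 400)
        df = pd.DataFrame({"ldi": y, "lossiness": x})
        fit = st.fit_gam_ldi(df)
        smooth = fit.terms["s(lossiness)"]
        assert smooth.edf < 1.5
        lin = np.polyval(np.polyfit(x, y, 1), x)
        rmse = np.sqrt(np.mean((fit.predict(df) - lin) ** 2))
        assert rmse / np.std(y) < 0.02  # within 2% of the response scale

    def test_age_modulation_detected(self):
        detections = sum(
            st.fit_gam_ldi(_gam_sim(seed)).terms["s(lossiness):age"].p < 0.05
            for seed in range(10)
        )
        assert detections >= 9

    def test_no_modulation_not_overdetected(self):
        false_hits = sum(
            st.fit_gam_ldi(_gam_sim(seed, modulated=False)).terms["s(lossiness):age"].p < 0.05
            for seed in range(10)
        )
        assert false_hits <= 3

    def test_constant_response_near_zero_f(self):
        df = pd.DataFrame(
            {"ldi": np.zeros(60), "lossiness": np.linspace(0, 1, 60)}
        )
        fit = st.fit_gam_ldi(df)
        assert fit.terms["s(lossiness)"].F < 1e-6

    def test_too_few_unique_values_rejected(self):
        df = pd.DataFrame({"ldi": np.arange(9.0), "lossiness": [0.1, 0.2, 0.3] * 3})
        with pytest.raises(st.BasisError):
            st.fit_gam_ldi(df)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_mgcv_fitted_values(self, tmp_path):
        df = _gam_sim(7, n=400)
        csv = tmp_path / "gam.csv"
        out = tmp_path / "fitted.csv"
        df.assign(agec=df["age"] - df["age"].mean()).to_csv(csv, index=False)
        script = (
            "d <- read.csv('%s');"
            "library(mgcv);"
            "m <- gam(ldi ~ s(lossiness, k=4, bs='cr')"
            " + s(lossiness, by=agec, k=4, bs='cr'), data=d, method='REML');"
            "write.csv(data.frame(fit=fitted(m)), '%s', row.names=FALSE)" % (csv, out)
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        mgcv_fit = pd.read_csv(out)["fit"].to_numpy()
        ours = st.fit_gam_ldi(df).predict(df)
        rmse = np.sqrt(np.mean((ours - mgcv_fit) ** 2))
        # different spline bases (P-spline vs cr), same model: close fits
        assert rmse < 0.05 * np.std(df["ldi"])
        assert np.corrcoef(ours, mgcv_fit)[0, 1] > 0.99


class TestBootstrapContrast:
    def _values(self, seed=2, offset=-0.2, n=60):
        rng = np.random.default_rng(seed)
        vals = {f"R{i}": rng.normal(-0.35, 0.1, n) for i in range(4)}
        vals["ref"] = rng.normal(-0.35 + offset, 0.1, n)
        return vals

    def test_null_contrast_ci_contains_zero(self):
        vals = self._values(offset=0.0)
        vals["ref"] = np.mean([vals[f"R{i}"] for i in range(4)], axis=0)
        bc = st.bootstrap_contrast(vals, "ref", n_iter=500, seed=1)
        assert bc.ci_low <= 0.0 <= bc.ci_high

    def test_planted_offset_detected(self):
        bc = st.bootstrap_contrast(self._values(), "ref", n_iter=2000, seed=3)
        assert bc.ci_high < 0.0
        assert bc.p_value < 0.01
        assert bc.ci_low < bc.observed < bc.ci_high

    def test_single_iteration_degenerate_flagged(self):
        with pytest.warns(UserWarning):
            bc = st.bootstrap_contrast(self._values(), "ref", n_iter=1, seed=0)
        assert bc.degenerate
        assert bc.ci_low == bc.ci_high

    def test_misaligned_participants_rejected(self):
        vals = self._values()
        vals["R0"] = vals["R0"][:-5]
        with pytest.raises(st.AlignmentError):
            st.bootstrap_contrast(vals, "ref", n_iter=10, seed=0)
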