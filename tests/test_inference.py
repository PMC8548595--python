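"""Transform selection, mixed-model fitting and likelihood-ratio tests."""

import numpy as np
import pytest
from scipy import stats

from dyadgaze import SimConfig, fit_srt_model, select_transform, simulate_trial_table
from dyadgaze.inference import (InsufficientDataError, TransformSpec,
                                apply_transform, likelihood_ratio_test)


def _boxcox_llf_oracle(lmbda, x):
    """Independent profile log-likelihood at a reduced grid point."""
    n = len(x)
    logx = np.log(x)
    if abs(lmbda) < 1e-12:
        y = logx
    else:
        y = (x**lmbda - 1) / lmbda
    return (lmbda - 1) * logx.sum() - n / 2 * np.log(np.var(y))


class TestSelectTransform:
    def test_squared_normal_prefers_sqrt(self):
        rng = np.random.default_rng(0)
        x = rng.normal(20, 2, 500) ** 2
        spec = select_transform(x)
        # reduced-grid oracle: the profile likelihood peaks nearer 0.5
        # than 0 or 1 on coarse candidates
        cand = [0.0, 0.5, 1.0]
        best = max(cand, key=lambda l: _boxcox_llf_oracle(l, x))
        assert best == 0.5
        assert spec.family == "sqrt"

    def test_lognormal_prefers_log10(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(0, 0.5, 500))
        spec = select_transform(x)
        best = max([0.0, 0.5, 1.0], key=lambda l: _boxcox_llf_oracle(l, x))
        assert best == 0.0
        assert spec.family == "log10"

    def test_normal_data_keeps_identity(self):
        # wide enough spread that lambda is well identified
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(50, 15, 500))
        assert select_transform(x).family == "identity"

    def test_lambda_agrees_with_scipy_boxcox(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 10.0, 800)
        spec = select_transform(x)
        lmbda_scipy = stats.boxcox_normmax(x, method="mle")
        assert spec.lmbda == pytest.approx(lmbda_scipy, abs=0.02)

    def test_nonpositive_rejected_naming_count(self):
        with pytest.raises(ValueError, match="2 value"):
            select_transform(np.array([1.0, -1.0, 0.0] + [2.0] * 20))

    def test_apply_transform_families(self):
        x = np.array([100.0, 400.0])
        assert np.allclose(apply_transform(x, TransformSpec("sqrt", 0.5)), [10, 20])
        assert np.allclose(apply_transform(x, TransformSpec("log10", 0.0)), [2, np.log10(400)])
        assert np.allclose(apply_transform(x, TransformSpec("identity", 1.0)), x)
        assert np.allclose(apply_transform(x, TransformSpec("power", 0.3)),
                           (x**0.3 - 1) / 0.3)


class _Fit:
    """Minimal stand-in exposing the attributes the LRT consumes."""

    def __init__(self, llf, k, nobs):
        self.llf = llf
        self.fe_params = np.zeros(k)
        self.nobs = nobs


class TestLikelihoodRatio:
    def test_null_vs_null_is_zero(self):
        f = _Fit(-100.0, 1, 50)
        chi2, df, p, ev = likelihood_ratio_test(f, f)
        assert chi2 == 0.0 and p == 1.0 and ev == pytest.approx(1.0)

    def test_chi2_identity_and_p_from_survival_function(self):
        null, full = _Fit(-102.805, 1, 50), _Fit(-100.0, 2, 50)
        chi2, df, p, ev = likelihood_ratio_test(null, full)
        assert chi2 == pytest.approx(5.61, abs=1e-9)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(5.61, 1), abs=1e-12)
        assert p == pytest.approx(0.0179, abs=1e-3)
        assert ev == pytest.approx(np.exp(2.805), rel=1e-12)
        # the evidence ratio is exp(chi2/2), not the chi2 statistic
        assert ev == pytest.approx(np.exp(chi2 / 2), rel=1e-12)

    def test_differing_row_counts_refused(self):
        with pytest.raises(ValueError, match="row counts"):
            likelihood_ratio_test(_Fit(-10, 1, 50), _Fit(-9, 2, 49))

    def test_pure_noise_covariate_is_chi2_distributed(self):
        """Adding the congruency factor under a null benefit produces LRT
        statistics that follow chi2(1) (QQ agreement at key quantiles)."""
        rng = np.random.default_rng(6)
        cfg = SimConfig(n_pairs=8, trials_per_pair=20, srt_congruency_benefit=0.0)
        tspec = TransformSpec("sqrt", 0.5)
        chis = []
        for _ in range(120):
            tab = simulate_trial_table(cfg, rng)
            r = fit_srt_model(tab, transform=tspec)
            chis.append(max(r.chi2, 0.0))
        chis = np.sort(chis)
        for q in (0.5, 0.8):
            emp = np.quantile(chis, q)
            theo = stats.chi2.ppf(q, 1)
            assert abs(emp - theo) < 0.5, (q, emp, theo)


class TestFitSrtModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = SimConfig(n_pairs=12, trials_per_pair=40, seed=3)
        tab = simulate_trial_table(cfg)
        return tab, fit_srt_model(tab, transform="sqrt")

    def test_reports_consistent_summaries(self, fitted):
        tab, res = fitted
        assert res.chi2 == pytest.approx(2 * (res.llf_full - res.llf_null), abs=1e-8)
        assert res.evidence_ratio == pytest.approx(np.exp(res.chi2 / 2), rel=1e-9)
        assert res.t == pytest.approx(res.b / res.se)
        assert res.n_obs <= len(tab)
        assert set(res.descriptives) == {"congruent", "incongruent"}
        assert res.transform.family == "sqrt"

    def test_sign_of_b_matches_raw_mean_difference(self, fitted):
        _, res = fitted
        d = res.descriptives
        raw_diff = d["incongruent"]["mean_ms"] - d["congruent"]["mean_ms"]
        assert np.sign(res.b) == np.sign(raw_diff)

    def test_matches_lme4_frozen_values(self):
        """Frozen cross-check: on one fixed dataset the ML fit agrees with
        lme4 (same model, same data) to 4 decimals.

        Frozen from: lmer(srt_ms ~ congruency + (1|pair/subject) + (1|trial),
        REML=FALSE) on the identity scale, seed-123 table below.
        """
        rng = np.random.default_rng(123)
        tab = simulate_trial_table(SimConfig(n_pairs=50, trials_per_pair=54), rng)
        res = fit_srt_model(tab, transform="identity")
        assert res.b == pytest.approx(44.9636, abs=2e-3)
        assert res.se == pytest.approx(6.2367, abs=2e-3)
        assert res.llf_full == pytest.approx(-15736.263, abs=2e-2)
        assert res.chi2 == pytest.approx(51.391, abs=2e-2)
        vc = res.vc_estimates
        assert vc["pair"] == pytest.approx(2505.98, rel=2e-2)
        assert vc["subject"] == pytest.approx(1649.37, rel=2e-2)
        assert vc["trial"] == pytest.approx(286.27, rel=2e-2)
        assert vc["residual"] == pytest.approx(22684.48, rel=2e-2)

    def test_degenerate_identical_srts(self):
        cfg = SimConfig(n_pairs=3, trials_per_pair=10, srt_sd=0.0, subject_sd=0.0,
                        pair_sd=0.0, trial_sd=0.0, srt_congruency_benefit=0.0)
        tab = simulate_trial_table(cfg, np.random.default_rng(0))
        res = fit_srt_model(tab, transform="identity")
        assert res.b == 0.0 and res.t == 0.0 and res.p == 1.0

    def test_insufficient_strata_raise(self):
        cfg = SimConfig(n_pairs=1, trials_per_pair=10)
        tab = simulate_trial_table(cfg, np.random.default_rng(0))
        with pytest.raises(InsufficientDataError):
            fit_srt_model(tab)
        tab2 = simulate_trial_table(SimConfig(n_pairs=4, trials_per_pair=10,
                                              p_congruent=1.0,
                                              p_uncharacterizable=0.0),
                                    np.random.default_rng(0))
        with pytest.raises(InsufficientDataError):
            fit_srt_model(tab2)

    def test_stratum_filters(self):
        cfg = SimConfig(n_pairs=8, trials_per_pair=30, seed=4)
        tab = simulate_trial_table(cfg)
        r_all = fit_srt_model(tab, "all", transform="sqrt")
        r_ov = fit_srt_model(tab, "overt", transform="sqrt")
        r_no = fit_srt_model(tab, "not_overt", transform="sqrt")
        assert r_ov.n_obs + r_no.n_obs == r_all.n_obs

    def test_random_intercept_sds_recovered(self):
        """Subject and pair random-intercept SDs are recovered (averaged
        variance estimates over replicates, identity scale)."""
        rng = np.random.default_rng(21)
        cfg = SimConfig(n_pairs=50, trials_per_pair=54)
        est = {"pair": [], "subject": []}
        for _ in range(20):
            tab = simulate_trial_table(cfg, rng)
            r = fit_srt_model(tab, transform="identity")
            for k in est:
                est[k].append(r.vc_estimates[k])
        for k, true_sd in (("pair", cfg.pair_sd), ("subject", cfg.subject_sd)):
            sd_hat = np.sqrt(np.mean(est[k]))
            assert abs(sd_hat - true_sd) / true_sd < 0.25, (k, sd_hat)
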