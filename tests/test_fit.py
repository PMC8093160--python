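"""Tests for covariance-structure ML fitting."""

import numpy as np
import pytest

from pgsnurture.fit import (
    DatasetMoments,
    FitOptions,
    fit_model,
    neg2_loglik,
    report_quantities,
    sample_moments,
)
from pgsnurture.moments import MODELS, true_parameter_values
from pgsnurture.sim import SimConfig, simulate_trios


def _moments_from(cov, n):
    p = cov.shape[0]
    return DatasetMoments(n=n, variables=tuple(f"x{i}" for i in range(p)),
                          cov=np.asarray(cov, dtype=float),
                          means=np.zeros(p))


class TestNeg2Loglik:
    def test_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 5))
        S = A @ A.T + 5 * np.eye(5)
        mom = _moments_from(S, 100)
        assert neg2_loglik(mom, S) == pytest.approx(0.0, abs=1e-10)

    def test_scalar_case(self):
        # p=1, S=2, Sigma=1, n=2: (ln 1 + 2 - ln 2 - 1) = 1 - ln 2
        mom = _moments_from(np.array([[2.0]]), 2)
        assert neg2_loglik(mom, np.array([[1.0]])) == pytest.approx(
            1.0 - np.log(2.0))

    def test_linear_in_sample_size(self):
        mom2 = _moments_from(np.array([[2.0]]), 2)
        mom3 = _moments_from(np.array([[2.0]]), 3)
        sigma = np.array([[1.0]])
        assert neg2_loglik(mom3, sigma) == pytest.approx(
            2.0 * neg2_loglik(mom2, sigma))

    def test_singular_implied_raises(self):
        mom = _moments_from(np.eye(2), 10)
        with pytest.raises(np.linalg.LinAlgError):
            neg2_loglik(mom, np.zeros((2, 2)))


class TestSampleMoments:
    def test_dimensions_per_model(self, trios_central):
        assert sample_moments(trios_central, MODELS["0"]).cov.shape == (5, 5)
        assert sample_moments(trios_central, MODELS["2e"]).cov.shape == (7, 7)

    def test_theta_nt_matches_direct_computation(self, trios_central):
        mom = sample_moments(trios_central, MODELS["2e"])
        idx = {v: i for i, v in enumerate(mom.variables)}
        theta_nt = (mom.cov[idx["NT_p"], idx["Y_o"]]
                    + mom.cov[idx["NT_m"], idx["Y_o"]])
        direct = np.cov(trios_central["NT_p"] + trios_central["NT_m"],
                        trios_central["Y_o"], ddof=1)[0, 1]
        assert theta_nt == pytest.approx(direct)

    def test_missing_parental_rows_dropped_only_when_used(self, trios_central):
        trios = trios_central.copy()
        trios.loc[trios.index[:100], "Y_p"] = np.nan
        assert sample_moments(trios, MODELS["0"]).n == len(trios)
        mom7 = sample_moments(trios, MODELS["2e"])
        assert mom7.n == len(trios) - 100
        assert mom7.n_dropped == 100

    def test_insufficient_rows(self, trios_central):
        with pytest.raises(ValueError):
            sample_moments(trios_central.head(4), MODELS["0"])


class TestFitModel:
    def test_null_vf_recovery(self):
        # no VT, no AM, PGS explains all h2: M0 should put V_F at ~0
        cfg = SimConfig(n_fam=8000, r_mate=0.0, vf_t0=0.0,
                        r2_pgs_t0=0.5, h2_t0=0.5, seed=55)
        trios = simulate_trios(cfg)
        fit = fit_model("0", sample_moments(trios, MODELS["0"]),
                        FitOptions(jitter_seed=1))
        assert fit.converged
        se = fit.se.get("v_f", np.nan)
        assert fit.estimates["v_f"] == pytest.approx(0.0, abs=max(3 * se, 0.02))
        assert fit.estimates["delta"] == pytest.approx(1.0, abs=0.05)

    def test_m0_tracks_truth_without_am(self, trios_noam, noam_4k):
        _, state = true_parameter_values(noam_4k)
        fit = fit_model("0", sample_moments(trios_noam, MODELS["0"]),
                        FitOptions(jitter_seed=2))
        assert fit.converged
        assert fit.estimates["v_f"] == pytest.approx(
            state.v_f, abs=4 * fit.se["v_f"])
        assert fit.estimates["w"] == pytest.approx(
            state.w, abs=4 * fit.se["w"])

    def test_likelihood_at_truth_not_below_optimum(self, trios_central,
                                                   central_4k):
        params, _ = true_parameter_values(central_4k)
        mom = sample_moments(trios_central, MODELS["2e"])
        fit = fit_model("2e", mom, FitOptions(jitter_seed=3,
                                              compute_se=False))
        from pgsnurture.moments import implied_covariance
        ll_truth = neg2_loglik(mom, implied_covariance(MODELS["2e"], params))
        assert fit.converged
        assert ll_truth >= fit.minus2ll - 1e-6

    def test_dimension_mismatch_raises(self, trios_central):
        mom5 = sample_moments(trios_central, MODELS["0"])
        with pytest.raises(ValueError):
            fit_model("2e", mom5)


class TestStandardize:
    def test_variance_decomposition_sums_to_one(self, trios_central):
        mom = sample_moments(trios_central, MODELS["2e"])
        fit = fit_model("2e", mom, FitOptions(jitter_seed=4,
                                              compute_se=False))
        s = fit.std_estimates
        total = (s["v_pgs"] + s["v_lgs"] + s["v_cross"] + s["v_nurture"]
                 + s["v_f"] + s["v_eps"])
        assert total == pytest.approx(1.0, abs=1e-8)
        assert s["v_y"] == pytest.approx(1.0)

    def test_identity_when_vy_is_one(self):
        # a fit whose implied V_Y is 1 keeps variance estimates unchanged
        cfg = SimConfig(n_fam=6000, r_mate=0.0, vf_t0=0.0, r2_pgs_t0=0.5,
                        seed=66)
        trios = simulate_trios(cfg)
        fit = fit_model("0", sample_moments(trios, MODELS["0"]),
                        FitOptions(jitter_seed=5, compute_se=False))
        assert fit.estimates["v_y"] == pytest.approx(1.0, abs=0.05)
        ratio = fit.std_estimates["v_pgs"] / fit.estimates["v_pgs"]
        assert ratio == pytest.approx(1.0 / fit.estimates["v_y"])

    def test_mu_standardizes_to_mate_correlation(self, trios_central):
        mom = sample_moments(trios_central, MODELS["2e"])
        fit = fit_model("2e", mom, FitOptions(jitter_seed=6,
                                              compute_se=False))
        assert fit.std_estimates["mu"] == pytest.approx(0.25, abs=0.06)


def test_se_reported_for_derived_quantities(trios_central):
    mom = sample_moments(trios_central, MODELS["2e"])
    fit = fit_model("2e", mom, FitOptions(jitter_seed=7))
    for key in ("v_f", "w", "v_pgs", "v_lgs"):
        assert np.isfinite(fit.se[key]) and fit.se[key] > 0
    # standardized V_F precision at 4K is in the expected range (paper-
    # scale SEs are a few hundredths at these sample sizes)
    assert fit.se["v_f"] / fit.estimates["v_y"] < 0.2


def test_hessian_se_calibration():
    """In a well-specified scenario the mean Hessian SE tracks the
    empirical dispersion of estimates across replicates."""
    cfg = SimConfig(n_fam=2000, r_mate=0.0, r2_pgs_t0=0.5, h2_t0=0.5,
                    generations=5)
    ests, ses = [], []
    for r in range(50):
        trios = simulate_trios(cfg.replace(seed=7000 + r))
        fit = fit_model("0", sample_moments(trios, MODELS["0"]),
                        FitOptions(jitter_seed=r))
        if fit.converged and "v_f" in fit.se:
            ests.append(fit.estimates["v_f"])
            ses.append(fit.se["v_f"])
    assert len(ests) >= 45
    ratio = np.mean(ses) / np.std(ests, ddof=1)
    # 50 replicates put ~15% Monte Carlo noise on the dispersion itself
    assert 0.65 < ratio < 1.45, f"SE calibration ratio {ratio:.2f}"


def test_report_quantities_respects_structural_zeros():
    params_truth, _ = true_parameter_values(SimConfig())
    rep = report_quantities(MODELS["1e"], params_truth)
    assert rep["a"] == 0.0 and rep["v_lgs"] == 0.0
    rep0 = report_quantities(MODELS["0"], params_truth)
    assert rep0["mu"] == 0.0 and rep0["g_x"] == 0.0
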