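"""Tests for the moment recursion and model-implied covariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgsnurture.moments import (
    MODELS,
    NonConvergenceError,
    ParamVector,
    base_state,
    equilibrium_state,
    implied_covariance,
    predicted_vf_underestimate,
    recurse_one_generation,
    true_parameter_values,
)
from pgsnurture.sim import SimConfig


CENTRAL = ParamVector(delta=1.0, a=3.0, f=np.sqrt(0.075), mu=0.118,
                      v_eps=0.5, v_t=0.025)


def test_trivial_fixed_point_without_vt_or_am():
    params = ParamVector(delta=0.8, a=1.3, f=0.0, mu=0.0, v_eps=0.4,
                         v_t=0.03)
    state = equilibrium_state(params)
    base = base_state(params)
    for field in ("g", "g_x", "h", "h_x", "i", "i_x", "w", "v", "v_f"):
        assert getattr(state, field) == 0.0
    assert state.v_y == pytest.approx(base.v_y)


def test_fixed_point_is_stationary():
    state = equilibrium_state(CENTRAL, tol=1e-12)
    again = recurse_one_generation(state, CENTRAL)
    np.testing.assert_allclose(again.core(), state.core(), atol=1e-10)


def test_equilibrium_cis_equals_trans():
    state = equilibrium_state(CENTRAL, tol=1e-12)
    assert state.g == pytest.approx(state.g_x, abs=1e-9)
    assert state.h == pytest.approx(state.h_x, abs=1e-9)
    assert state.i == pytest.approx(state.i_x, abs=1e-9)


def test_vf_structural_relation_after_one_step():
    # V_F' = 2 f^2 (V_Y + mu V_Y^2) holds after a single generation
    params = CENTRAL
    base = base_state(params)
    one = recurse_one_generation(base, params)
    expect = 2 * params.f**2 * (base.v_y + params.mu * base.v_y**2)
    assert one.v_f == pytest.approx(expect)
    # with mu = 0, V_F after one step from the fixed point equals the
    # fixed-point V_F exactly (no phenotypic-variance drift left)
    eq = equilibrium_state(params, mu=0.0, tol=1e-12)
    step = recurse_one_generation(eq, params, mu=0.0)
    assert step.v_f == pytest.approx(eq.v_f, rel=1e-8)


def test_nonconvergence_raises_with_state():
    # runaway VT feedback (2 f^2 plus the nurture covariances exceed 1)
    explosive = ParamVector(delta=1.0, a=1.0, f=0.68, mu=0.0, v_eps=0.5,
                            v_t=0.5)
    with pytest.raises(NonConvergenceError) as err:
        equilibrium_state(explosive)
    assert err.value.state is not None
    # an inadmissible copath (implied mate correlation >= 1) also refuses
    inadmissible = ParamVector(delta=2.0, a=0.0, f=0.0, mu=0.25, v_eps=1.0,
                               v_t=0.5)
    with pytest.raises(NonConvergenceError):
        equilibrium_state(inadmissible)


def test_theta_difference_isolates_direct_effect():
    # theta_T - theta_NT = 2 delta v_t under every model and regime
    for model_id in MODELS:
        imp = implied_covariance(MODELS[model_id], CENTRAL)
        S = imp.to_frame()
        theta_t = S.loc["T_p", "Y_o"] + S.loc["T_m", "Y_o"]
        theta_nt = S.loc["NT_p", "Y_o"] + S.loc["NT_m", "Y_o"]
        assert theta_t - theta_nt == pytest.approx(
            2 * CENTRAL.delta * CENTRAL.v_t), model_id


def test_no_am_collapse():
    # with mu = 0 the disequilibrium and equilibrium variants coincide
    params = ParamVector(delta=1.0, a=3.0, f=np.sqrt(0.075), mu=0.0,
                         v_eps=0.5, v_t=0.025)
    for d_id, e_id in (("1d", "1e"), ("2d", "2e")):
        Sd = implied_covariance(MODELS[d_id], params).matrix
        Se = implied_covariance(MODELS[e_id], params).matrix
        np.testing.assert_allclose(Sd, Se, atol=1e-12)
        assert implied_covariance(MODELS[e_id], params).offspring_state.g == 0


def test_m0_structure_without_vt():
    params = ParamVector(delta=0.9, a=0.0, f=0.0, mu=0.0, v_eps=0.6,
                         v_t=0.05)
    S = implied_covariance(MODELS["0"], params).to_frame()
    assert S.loc["NT_p", "Y_o"] == pytest.approx(0.0, abs=1e-14)
    assert S.loc["T_p", "Y_o"] == pytest.approx(0.9 * 0.05)
    assert S.loc["T_p", "T_p"] == pytest.approx(0.05)


def test_identification_constraint_holds_by_construction():
    # w/delta = v/a at the equilibrium fixed point and after one
    # assortative step from the VT-only fixed point
    for model_id in ("2e", "2d"):
        imp = implied_covariance(MODELS[model_id], CENTRAL)
        o = imp.offspring_state
        assert o.w / CENTRAL.delta == pytest.approx(o.v / CENTRAL.a,
                                                    rel=1e-8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    delta=st.floats(0.2, 2.0),
    a=st.floats(0.0, 4.0),
    f=st.floats(0.0, 0.4),
    mu=st.floats(-0.2, 0.3),
    v_eps=st.floats(0.05, 2.0),
    v_t=st.floats(0.005, 0.5),
)
def test_implied_covariance_is_psd(delta, a, f, mu, v_eps, v_t):
    params = ParamVector(delta=delta, a=a, f=f, mu=mu, v_eps=v_eps, v_t=v_t)
    for model_id in ("0", "1e", "2e", "2d"):
        try:
            S = implied_covariance(MODELS[model_id], params).matrix
        except NonConvergenceError:
            continue  # explosive corner of the box; nothing to check
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        eigvals = np.linalg.eigvalsh(S)
        assert eigvals.min() > -1e-9


def test_true_parameter_mapping():
    cfg = SimConfig(vf_t0=0.15, h2_t0=0.5, r2_pgs_t0=0.05)
    params, state = true_parameter_values(cfg)
    assert params.f == pytest.approx(np.sqrt(0.075))
    assert params.f == pytest.approx(0.27386, abs=5e-6)
    assert params.delta == 1.0
    assert params.a == pytest.approx(3.0)
    assert params.v_t == pytest.approx(0.025)
    # with neither AM nor VT the truth stays at base values
    cfg0 = SimConfig(r_mate=0.0, vf_t0=0.0)
    p0, s0 = true_parameter_values(cfg0)
    assert p0.mu == 0.0
    assert s0.v_y == pytest.approx(1.0)
    assert s0.v_f == 0.0 and s0.w == 0.0


def test_truth_equilibrium_mu_consistency():
    cfg = SimConfig(r_mate=0.25)
    params, state = true_parameter_values(cfg)
    # at (near) equilibrium the copath times the *parental* V_Y gives the
    # mate correlation; parental and offspring V_Y agree to the transient
    assert params.mu * state.v_y == pytest.approx(0.25, rel=1e-4)


def test_predicted_vf_underestimate_values():
    assert predicted_vf_underestimate(0.3, 0.3, 1.0, 0.5) == 0.0
    assert predicted_vf_underestimate(0.3, 0.1, 1.0, 0.0) == pytest.approx(0.02)
    assert predicted_vf_underestimate(0.3, 0.1, 1.2, 0.25) == pytest.approx(
        0.0312)
    with pytest.raises(ValueError):
        predicted_vf_underestimate(0.3, 0.1, 0.0)


def test_np_model_latent_effect_resolution():
    model = MODELS["2e-np"].with_fixed_h2(0.5)
    # truth-scale parameters: v_eps=.5 -> V_Y0=1, PGS explains .05, so the
    # latent effect must supply .45 of base variance: a = 3 at v_t=.025
    a = model.resolve_a(delta=1.0, v_eps=0.5, v_t=0.025)
    assert a == pytest.approx(3.0)
    # assumed h2 below what the PGS explains clips at zero
    assert model.with_fixed_h2(0.04).resolve_a(1.0, 0.5, 0.025) == 0.0


def test_oracle_equivalence_moderate():
    """Implied covariance at generative truth tracks a moderate simulated
    sample entrywise (the large-sample check lives in the acceptance
    suite)."""
    from pgsnurture.sim import simulate_trios
    from pgsnurture.moments import _observed_matrix
    import pgsnurture.moments as M

    cfg = SimConfig(n_fam=30000, r_mate=0.25, seed=909)
    trios = simulate_trios(cfg)
    cols = ["T_p", "NT_p", "T_m", "NT_m", "Y_o", "Y_p", "Y_m"]
    S = np.cov(trios[cols].to_numpy().T)
    params, _ = true_parameter_values(cfg)
    state = M.base_state(params)
    mu_last = 0.0
    for gen in range(cfg.generations - 1):
        mu_last = cfg.r_mate / state.v_y
        state = M.recurse_one_generation(state, params, mu=mu_last)
    mu_final = cfg.r_mate / state.v_y
    off = M.recurse_one_generation(state, params, mu=mu_final)
    Sigma = _observed_matrix(params, state, off, mu_final, True)
    se = np.sqrt((np.outer(np.diag(Sigma), np.diag(Sigma)) + Sigma**2)
                 / (cfg.n_fam - 1))
    assert np.max(np.abs(S - Sigma) / se) < 5.0
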