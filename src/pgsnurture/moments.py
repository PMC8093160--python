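"""Model-implied second moments for the trio genetic-nurture models.

The generative system tracked here is a polygenic trait with vertical
transmission (VT) and primary phenotypic assortative mating (AM).  Each
person carries two haplotypes; the measured polygenic score (PGS) and the
latent genetic score (LGS, the genetic component orthogonal to the PGS in
the base population) are each split into two haplotypic parts.  The
phenotype is assembled as

    Y = delta * (s_P + s_M) + a * (l_P + l_M) + F + eps,

where ``s`` / ``l`` are haplotypic PGS / LGS values, ``F = f*Y_p + f*Y_m``
is the familial (VT) score, and eps is residual environment with variance
``v_eps``.  AM is modeled with a copath coefficient ``mu`` on the
phenotypic covariance scale: the mate phenotypic covariance is
``mu * V_Y**2`` and, for any pair of traits A (father) and B (mother),

    cov(A, B) = mu * cov(A, Y) * cov(B, Y).

All second moments of a generation follow from their parents' moments by a
deterministic recursion (free recombination of unlinked causal variants,
gametic transmission, VT, phenotype assembly).  One iteration gives the
disequilibrium (single-generation-of-AM) expectations; iterating to a
fixed point gives the equilibrium expectations.

Scale conventions
-----------------
* ``v_t`` is the base-population variance of one haplotypic PGS; the
  latent haplotypic LGS base variance is tied to the same ``v_t`` and
  ``a`` carries its effect.  With this convention the identification
  constraint w/delta = v/a (equal nurture-to-direct-effect ratio for
  observed and latent scores) holds automatically at every fixed point of
  the recursion and after a single assortative generation.
* ``w = cov(s, F)`` and ``v = cov(l, F)`` are per-haplotype genetic-nurture
  covariances, so that with no AM the nontransmitted-PGS covariance is
  ``theta_NT = 2*w`` (the Kong et al. convention).
* cis covariances ``g, h, i`` are the AM-induced within-haplotype
  (cross-locus) covariance sums; ``g_x, h_x, i_x`` are their within-person
  cross-haplotype counterparts, equal between mates ("trans") at the
  mating that produced the person.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "AMRegime",
    "ParamVector",
    "MomentState",
    "ModelSpec",
    "MODELS",
    "ImpliedCov",
    "NonConvergenceError",
    "base_state",
    "recurse_one_generation",
    "equilibrium_state",
    "implied_covariance",
    "true_parameter_values",
    "true_implied_covariance",
    "state_quantities",
    "predicted_vf_underestimate",
]


class NonConvergenceError(RuntimeError):
    """Fixed-point iteration failed; carries the last state reached."""

    def __init__(self, message: str, state: "MomentState | None" = None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class ParamVector:
    """Structural parameters of the causal system.

    delta : per-haplotype direct effect of the PGS on the phenotype
    a     : per-haplotype effect of the latent genetic score (0 in models
            that assume the PGS captures all genetic variance)
    f     : VT path from each parental phenotype to the offspring F score
    mu    : AM copath coefficient (mate phenotypic covariance = mu*V_Y**2)
    v_eps : residual environmental variance (constant across generations)
    v_t   : base-population haplotypic PGS variance (also the latent
            haplotypic LGS base variance; see module docstring)
    """

    delta: float
    a: float
    f: float
    mu: float
    v_eps: float
    v_t: float

    def validate(self) -> None:
        if self.v_eps < 0 or self.v_t < 0:
            raise ValueError("variances v_eps and v_t must be non-negative")


@dataclass(frozen=True)
class MomentState:
    """Second moments of one generation.

    ``g/h/i`` are cis (within-haplotype) covariance inflations for
    PGS/LGS/cross; ``g_x/h_x/i_x`` the within-person cross-haplotype ones.
    ``w``/``v`` are per-haplotype nurture covariances cov(s,F)/cov(l,F);
    ``v_f`` = var(F); the remaining fields are assembled observables.
    """

    g: float
    g_x: float
    h: float
    h_x: float
    i: float
    i_x: float
    w: float
    v: float
    v_f: float
    # assembled quantities (functions of the above and the parameters)
    v_y: float
    sigma_sy: float  # cov(one haplotypic PGS, own phenotype)
    sigma_ly: float
    v_pgs: float  # variance due to the direct PGS effect, delta^2*var(s_P+s_M)
    v_lgs: float
    theta_t: float  # cov(T_p + T_m, Y_o)
    theta_nt: float  # cov(NT_p + NT_m, Y_o)

    def core(self) -> np.ndarray:
        return np.array(
            [self.g, self.g_x, self.h, self.h_x, self.i, self.i_x,
             self.w, self.v, self.v_f]
        )


def _assemble(params: ParamVector, g, g_x, h, h_x, i, i_x, w, v, v_f) -> MomentState:
    d, a, vt = params.delta, params.a, params.v_t
    sigma_sy = d * (vt + g + g_x) + a * (i + i_x) + w
    sigma_ly = a * (vt + h + h_x) + d * (i + i_x) + v
    v_pgs = d * d * (2.0 * (vt + g) + 2.0 * g_x)
    v_lgs = a * a * (2.0 * (vt + h) + 2.0 * h_x)
    v_y = (
        v_pgs
        + v_lgs
        + 4.0 * d * a * (i + i_x)
        + 4.0 * d * w
        + 4.0 * a * v
        + v_f
        + params.v_eps
    )
    theta_t = 2.0 * (d * (vt + g + g_x) + a * (i + i_x) + w)
    theta_nt = theta_t - 2.0 * d * vt
    return MomentState(
        g=g, g_x=g_x, h=h, h_x=h_x, i=i, i_x=i_x, w=w, v=v, v_f=v_f,
        v_y=v_y, sigma_sy=sigma_sy, sigma_ly=sigma_ly,
        v_pgs=v_pgs, v_lgs=v_lgs, theta_t=theta_t, theta_nt=theta_nt,
    )


def base_state(params: ParamVector) -> MomentState:
    """Moments of the base population (no AM or VT has acted yet)."""
    return _assemble(params, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _step_core(core: tuple, params: ParamVector, mu: float) -> tuple:
    """One generation on the nine core moments, as plain floats.

    ``core`` is (g, g_x, h, h_x, i, i_x, w, v, v_f).  Kept free of any
    object construction: this is the inner loop of both the equilibrium
    solver and the ML objective.
    """
    g, g_x, h, h_x, i, i_x, w, v, v_f = core
    d, a, f, vt, veps = (params.delta, params.a, params.f,
                         params.v_t, params.v_eps)
    sy = d * (vt + g + g_x) + a * (i + i_x) + w
    ly = a * (vt + h + h_x) + d * (i + i_x) + v
    v_y = (d * d * (2.0 * (vt + g) + 2.0 * g_x)
           + a * a * (2.0 * (vt + h) + 2.0 * h_x)
           + 4.0 * d * a * (i + i_x)
           + 4.0 * d * w + 4.0 * a * v + v_f + veps)
    if abs(mu) * v_y >= 1.0:
        # the copath would imply |mate correlation| >= 1; the parameter
        # point is inadmissible (the implied structure cannot be PSD)
        raise NonConvergenceError(
            "implied mate correlation reached 1", state=None
        )
    amp = 1.0 + mu * v_y
    return (
        0.5 * (g + g_x), mu * sy * sy,
        0.5 * (h + h_x), mu * ly * ly,
        0.5 * (i + i_x), mu * sy * ly,
        f * amp * sy, f * amp * ly,
        2.0 * f * f * (v_y + mu * v_y * v_y),
    )


def recurse_one_generation(
    state: MomentState, params: ParamVector, mu: Optional[float] = None
) -> MomentState:
    """Advance the moment state by one generation.

    ``mu`` overrides ``params.mu`` for this mating (used to mirror a
    simulator that targets a constant mate *correlation*, so that the
    effective copath varies during the transient).

    The step applies, in order: assortative mating of the parental
    generation with copath ``mu``; gametic transmission with free
    recombination (cis covariances move halfway toward the within-person
    cross-haplotype values, new cross-haplotype covariances are the
    mate-trans covariances); vertical transmission F = f*(Y_p + Y_m); and
    phenotype assembly.
    """
    if mu is None:
        mu = params.mu
    core = _step_core(
        (state.g, state.g_x, state.h, state.h_x, state.i, state.i_x,
         state.w, state.v, state.v_f),
        params, mu,
    )
    out = _assemble(params, *core)
    if not np.isfinite(out.v_y) or out.v_y > 1e12 or out.v_y < 0:
        raise NonConvergenceError(
            "moment recursion diverged (phenotypic variance left [0, 1e12])",
            state=out,
        )
    return out


def equilibrium_state(
    params: ParamVector,
    tol: float = 1e-10,
    max_iter: int = 200,
    mu: Optional[float] = None,
) -> MomentState:
    """Fixed point of the one-generation recursion, started from base.

    Raises :class:`NonConvergenceError` (carrying the last state) if the
    maximum absolute change across the nine core moments has not dropped
    below ``tol`` within ``max_iter`` iterations.
    """
    if mu is None:
        mu = params.mu
    core = (0.0,) * 9
    for _ in range(max_iter):
        new = _step_core(core, params, mu)
        v_f = new[8]
        if not math.isfinite(v_f) or v_f > 1e12:
            raise NonConvergenceError(
                "moment recursion diverged", state=_assemble(params, *new)
            )
        if max(abs(x - y) for x, y in zip(new, core)) < tol:
            return _assemble(params, *new)
        core = new
    raise NonConvergenceError(
        f"no fixed point within {max_iter} iterations",
        state=_assemble(params, *core),
    )


# ---------------------------------------------------------------------------
# model catalogue
# ---------------------------------------------------------------------------


class AMRegime(str, Enum):
    NONE = "none"
    EQUILIBRIUM = "equilibrium"
    DISEQUILIBRIUM = "disequilibrium"


@dataclass(frozen=True)
class ModelSpec:
    """One of the seven trio causal models.

    ``assumes_pgs_explains_h2`` marks the models that set a = 0 (Models 0,
    1e, 1d); ``fixed_h2_t0`` is the assumed base-population heritability
    used by the no-parental-phenotype Model 2 variants, in which the
    latent-score effect ``a`` is derived rather than free.
    """

    model_id: str
    am_regime: AMRegime
    uses_parental_phenotypes: bool
    assumes_pgs_explains_h2: bool
    fixed_h2_t0: Optional[float] = None
    free_params: tuple[str, ...] = field(default=(), compare=False)

    @property
    def n_vars(self) -> int:
        return 7 if self.uses_parental_phenotypes else 5

    @property
    def variables(self) -> tuple[str, ...]:
        base = ("T_p", "NT_p", "T_m", "NT_m", "Y_o")
        return base + ("Y_p", "Y_m") if self.uses_parental_phenotypes else base

    def with_fixed_h2(self, h2: float) -> "ModelSpec":
        if self.fixed_h2_t0 is None and "np" not in self.model_id:
            raise ValueError(f"model {self.model_id} takes no fixed h2_t0")
        return replace(self, fixed_h2_t0=h2)

    def resolve_a(self, delta: float, v_eps: float, v_t: float) -> float:
        """Latent-score effect implied by an assumed base heritability.

        With base phenotypic variance V_Y0 = v_eps/(1 - h2) and base PGS
        variance 2*delta^2*v_t, the latent contribution must make up the
        remainder of h2*V_Y0; the square root is clipped at zero when the
        assumed h2 is smaller than what the PGS already explains.
        """
        h2 = self.fixed_h2_t0
        if h2 is None:
            raise ValueError(f"model {self.model_id} requires fixed_h2_t0")
        if not 0 < h2 < 1:
            raise ValueError("fixed_h2_t0 must lie in (0, 1)")
        v_y0 = v_eps / (1.0 - h2)
        a2 = (h2 * v_y0 - 2.0 * delta * delta * v_t) / (2.0 * v_t)
        return float(np.sqrt(max(a2, 0.0)))


_M = ModelSpec
MODELS: dict[str, ModelSpec] = {
    "0": _M("0", AMRegime.NONE, False, True,
            free_params=("delta", "f", "v_eps", "v_t")),
    "1e": _M("1e", AMRegime.EQUILIBRIUM, False, True,
             free_params=("delta", "f", "mu", "v_eps", "v_t")),
    "1d": _M("1d", AMRegime.DISEQUILIBRIUM, False, True,
             free_params=("delta", "f", "mu", "v_eps", "v_t")),
    "2e": _M("2e", AMRegime.EQUILIBRIUM, True, False,
             free_params=("delta", "a", "f", "mu", "v_eps", "v_t")),
    "2d": _M("2d", AMRegime.DISEQUILIBRIUM, True, False,
             free_params=("delta", "a", "f", "mu", "v_eps", "v_t")),
    "2e-np": _M("2e-np", AMRegime.EQUILIBRIUM, False, False, fixed_h2_t0=0.5,
                free_params=("delta", "f", "mu", "v_eps", "v_t")),
    "2d-np": _M("2d-np", AMRegime.DISEQUILIBRIUM, False, False, fixed_h2_t0=0.5,
                free_params=("delta", "f", "mu", "v_eps", "v_t")),
}


# ---------------------------------------------------------------------------
# implied covariance of the observed trio vector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImpliedCov:
    """Model-implied covariance matrix of the observed trio variables."""

    variables: tuple[str, ...]
    matrix: np.ndarray
    parent_state: MomentState
    offspring_state: MomentState

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.variables,
                            columns=self.variables)


def _states_for(model: ModelSpec, params: ParamVector,
                tol: float = 1e-10, max_iter: int = 200):
    """Parental state, offspring state and the copath applied at the last
    mating, under the model's AM regime.

    * no-AM (Model 0): fixed point with mu = 0; the last mating is random.
    * equilibrium: fixed point with the model's mu; the offspring state
      equals the parental state.
    * disequilibrium: VT-equilibrium (mu = 0) parental generation, one
      assortative mating with the model's mu.
    """
    if model.am_regime is AMRegime.EQUILIBRIUM:
        parent = equilibrium_state(params, tol=tol, max_iter=max_iter)
        mu_step = params.mu
    else:
        parent = equilibrium_state(params, tol=tol, max_iter=max_iter, mu=0.0)
        mu_step = 0.0 if model.am_regime is AMRegime.NONE else params.mu
    offspring = recurse_one_generation(parent, params, mu=mu_step)
    return parent, offspring, mu_step


def _observed_matrix(params: ParamVector, parent: MomentState,
                     offspring: MomentState, mu_step: float,
                     with_parents: bool) -> np.ndarray:
    d, a, f, vt = params.delta, params.a, params.f, params.v_t
    o = offspring
    var_t = vt + o.g
    cis = o.g  # cov(T, NT) within one parent
    trans = o.g_x  # any father-haplotype x mother-haplotype PGS covariance
    cov_t_yo = d * (vt + o.g + o.g_x) + a * (o.i + o.i_x) + o.w
    cov_nt_yo = cov_t_yo - d * vt
    p = 7 if with_parents else 5
    S = np.empty((p, p))
    # order: T_p, NT_p, T_m, NT_m, Y_o [, Y_p, Y_m]
    pg = np.array([[var_t, cis, trans, trans],
                   [cis, var_t, trans, trans],
                   [trans, trans, var_t, cis],
                   [trans, trans, cis, var_t]])
    S[:4, :4] = pg
    S[:4, 4] = [cov_t_yo, cov_nt_yo, cov_t_yo, cov_nt_yo]
    S[4, :4] = S[:4, 4]
    S[4, 4] = o.v_y
    if with_parents:
        sy, vyp = parent.sigma_sy, parent.v_y
        own = sy  # cov(T or NT, own parent's phenotype)
        other = mu_step * sy * vyp
        cov_yo_yp = (1.0 + mu_step * vyp) * (
            d * sy + a * parent.sigma_ly + f * vyp
        )
        S[:4, 5] = [own, own, other, other]
        S[:4, 6] = [other, other, own, own]
        S[5, :4] = S[:4, 5]
        S[6, :4] = S[:4, 6]
        S[4, 5] = S[5, 4] = cov_yo_yp
        S[4, 6] = S[6, 4] = cov_yo_yp
        S[5, 5] = S[6, 6] = vyp
        S[5, 6] = S[6, 5] = mu_step * vyp * vyp
    return S


def implied_covariance(
    model: ModelSpec, params: ParamVector,
    tol: float = 1e-10, max_iter: int = 200,
) -> ImpliedCov:
    """Implied covariance of (T_p, NT_p, T_m, NT_m, Y_o[, Y_p, Y_m]).

    Structural zeros are enforced: models 0/1 have ``a = 0``; model 0 has
    ``mu = 0``; the NP variants derive ``a`` from their assumed base
    heritability.  The VT/AM structure (and hence the w/delta = v/a
    identification constraint) is built in through the recursion.
    """
    params.validate()
    if model.assumes_pgs_explains_h2:
        params = replace(params, a=0.0)
    if model.fixed_h2_t0 is not None:
        params = replace(
            params, a=model.resolve_a(params.delta, params.v_eps, params.v_t)
        )
    if model.am_regime is AMRegime.NONE:
        params = replace(params, mu=0.0)
    parent, offspring, mu_step = _states_for(model, params, tol, max_iter)
    S = _observed_matrix(params, parent, offspring, mu_step,
                         model.uses_parental_phenotypes)
    return ImpliedCov(model.variables, S, parent, offspring)


# ---------------------------------------------------------------------------
# generative truth
# ---------------------------------------------------------------------------


def true_parameter_values(config) -> tuple[ParamVector, MomentState]:
    """Structural truth and final-generation moments for a simulation
    configuration.

    The simulator standardizes the base phenotype to unit variance and
    targets a constant mate *correlation* each generation, so the
    recursion is run with a per-generation copath mu_t = r_mate / V_Y(t).
    The returned ``mu`` is the copath of the final mating (the one that
    produced the trio offspring); at equilibrium it is the constant
    r_mate / V_Y*.
    """
    if config.f_p != config.f_m:
        raise NotImplementedError(
            "truth recursion assumes equal maternal and paternal VT paths"
        )
    h2, r2 = config.h2_t0, config.r2_pgs_t0
    if r2 <= 0:
        raise ValueError("truth mapping requires r2_pgs_t0 > 0")
    params = ParamVector(
        delta=1.0,
        a=float(np.sqrt((h2 - r2) / r2)),
        f=config.f_p,
        mu=0.0,
        v_eps=1.0 - h2,
        v_t=r2 / 2.0,
    )
    state = base_state(params)
    mu_last = 0.0
    for gen in range(config.vt_burnin + config.generations):
        r = 0.0 if gen < config.vt_burnin else config.r_mate
        mu_last = r / state.v_y
        state = recurse_one_generation(state, params, mu=mu_last)
    return replace(params, mu=mu_last), state


def true_implied_covariance(config, with_parents: bool = True) -> ImpliedCov:
    """Trio covariance implied by the generative truth of a simulation
    configuration, mirroring the simulator generation by generation
    (adaptive copath so the mate correlation is r_mate each generation)."""
    params, _ = true_parameter_values(config)
    state = base_state(params)
    mu_last = 0.0
    total = config.vt_burnin + config.generations
    for gen in range(total - 1):
        r = 0.0 if gen < config.vt_burnin else config.r_mate
        mu_last = r / state.v_y
        state = recurse_one_generation(state, params, mu=mu_last)
    mu_final = config.r_mate / state.v_y
    offspring = recurse_one_generation(state, params, mu=mu_final)
    variables = ("T_p", "NT_p", "T_m", "NT_m", "Y_o", "Y_p", "Y_m")
    if not with_parents:
        variables = variables[:5]
    S = _observed_matrix(params, state, offspring, mu_final, with_parents)
    return ImpliedCov(variables, S, state, offspring)


def state_quantities(params: ParamVector, state: MomentState) -> dict:
    """Flat dictionary of all reported quantities for a (params, state)
    pair — the common report vector for fits and generative truths."""
    d, a = params.delta, params.a
    o = state
    return {
        "delta": d, "a": a, "f": params.f, "mu": params.mu,
        "v_eps": params.v_eps, "v_t": params.v_t,
        "v_pgs": o.v_pgs, "v_lgs": o.v_lgs, "v_f": o.v_f,
        "w": o.w, "v": o.v,
        "g": o.g, "g_x": o.g_x, "h": o.h, "h_x": o.h_x,
        "i": o.i, "i_x": o.i_x,
        "theta_t": o.theta_t, "theta_nt": o.theta_nt,
        "theta_diff": o.theta_t - o.theta_nt,
        "v_nurture": 4.0 * (d * o.w + a * o.v),
        "v_cross": 4.0 * d * a * (o.i + o.i_x),
        "v_y": o.v_y,
    }


def predicted_vf_underestimate(f_p: float, f_m: float, v_y: float,
                               mu: float = 0.0) -> float:
    """Approximate deficit V_F - V̂_F when maternal and paternal VT paths
    differ but a model with a single f is fitted.

    With F = f_p*Y_p + f_m*Y_m the true V_F is (f_p^2+f_m^2)(V_Y + V_Y^2 mu)
    while the single-f model recovers f ≈ (f_p+f_m)/2, so the deficit is
    (f_p - f_m)^2 / 2 * (V_Y + V_Y^2 mu) >= 0.
    """
    if v_y <= 0:
        raise ValueError("v_y must be positive")
    return 0.5 * (f_p - f_m) ** 2 * (v_y + v_y * v_y * mu)
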