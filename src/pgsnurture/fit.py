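"""Maximum-likelihood fitting of the trio models to observed covariances.

The models are covariance-structure models: under multivariate normality
with saturated means, full-information ML is equivalent to minimizing the
Wishart discrepancy

    F = (n-1) * [ln det Sigma + tr(S Sigma^-1) - ln det S - p]

over the model's free parameters, where S is the (n-1)-denominator sample
covariance of the observed trio vector and Sigma the model-implied one.
Standard errors come from the inverse numerical Hessian of F/2 at the
optimum; derived quantities (V_F, w, v, V_PGS, V_LGS, theta's, ...) get
delta-method standard errors through a finite-difference Jacobian.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .moments import (
    MODELS,
    AMRegime,
    ImpliedCov,
    ModelSpec,
    MomentState,
    NonConvergenceError,
    ParamVector,
    implied_covariance,
)

__all__ = [
    "DatasetMoments",
    "FitOptions",
    "FitResult",
    "sample_moments",
    "neg2_loglik",
    "fit_model",
    "standardize",
    "report_quantities",
]

logger = logging.getLogger(__name__)

_PENALTY = 1e12

#: quantities that scale as variances/covariances of Y (divided by V_Y when
#: standardizing); paths and mu are handled separately.
_VARIANCE_SCALE = (
    "v_pgs", "v_lgs", "v_f", "v_eps", "w", "v", "theta_t", "theta_nt",
    "theta_diff", "g", "g_x", "i", "i_x", "h", "h_x", "v_nurture", "v_cross",
    "v_y",
)

_BOUNDS = {
    "delta": (-20.0, 20.0),
    "a": (0.0, 100.0),
    "f": (0.0, 0.65),
    "mu": (-2.0, 2.0),
    "v_eps": (1e-8, 50.0),
    "v_t": (1e-10, 10.0),
}


@dataclass(frozen=True)
class DatasetMoments:
    """Sample covariance (and means, kept for diagnostics) of the observed
    trio variables in the model's fixed variable order."""

    n: int
    variables: tuple[str, ...]
    cov: np.ndarray
    means: np.ndarray
    n_dropped: int = 0


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 3
    jitter_seed: int = 0
    maxiter: int = 400
    recursion_tol: float = 1e-10
    recursion_max_iter: int = 200
    compute_se: bool = True


@dataclass
class FitResult:
    """Estimates, derived quantities and diagnostics for one model fit."""

    model_id: str
    params: ParamVector
    estimates: dict[str, float]
    se: dict[str, float]
    std_estimates: dict[str, float]
    minus2ll: float
    n: int
    converged: bool
    boundary: list[str] = field(default_factory=list)
    message: str = ""
    n_starts_used: int = 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            rows.append({
                "parameter": name,
                "estimate": est,
                "std_estimate": self.std_estimates.get(name, np.nan),
                "se": self.se.get(name, np.nan),
            })
        return pd.DataFrame(rows)


def sample_moments(trios: pd.DataFrame, model: ModelSpec) -> DatasetMoments:
    """Unbiased sample covariance of the variables the model uses.

    Rows with missing required values are dropped (with a logged count);
    parental phenotypes are required only by models that use them.
    """
    cols = list(model.variables)
    missing = [c for c in cols if c not in trios.columns]
    if missing:
        raise ValueError(f"trio table lacks required column(s): {missing}")
    data = trios[cols]
    complete = data.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropping %d incomplete rows of %d", n_dropped, len(data))
    data = data[complete].to_numpy(dtype=float)
    n = data.shape[0]
    if n < len(cols) + 1:
        raise ValueError(
            f"need at least {len(cols) + 1} complete rows, found {n}"
        )
    return DatasetMoments(
        n=n, variables=tuple(cols), cov=np.cov(data.T, ddof=1),
        means=data.mean(axis=0), n_dropped=n_dropped,
    )


def neg2_loglik(moments: DatasetMoments, implied: ImpliedCov | np.ndarray) -> float:
    """Wishart ML discrepancy; zero iff the implied matrix equals S."""
    sigma = implied.matrix if isinstance(implied, ImpliedCov) else implied
    S = moments.cov
    p = S.shape[0]
    if sigma.shape != S.shape:
        raise ValueError("implied matrix dimension does not match data")
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance is not positive definite")
    sign_s, logdet_s = np.linalg.slogdet(S)
    trace = float(np.trace(np.linalg.solve(sigma, S)))
    return (moments.n - 1) * (logdet_sigma + trace - logdet_s - p)


def report_quantities(model: ModelSpec, params: ParamVector,
                      tol: float = 1e-10, max_iter: int = 200) -> dict[str, float]:
    """Full vector of reported quantities implied by a parameter vector.

    Includes the structural parameters (with structural zeros and the NP
    models' derived ``a`` resolved), the final-generation moment state and
    the variance decomposition of V_Y.
    """
    from dataclasses import replace as _replace

    from .moments import state_quantities

    implied = implied_covariance(model, params, tol=tol, max_iter=max_iter)
    a = 0.0 if model.assumes_pgs_explains_h2 else params.a
    if model.fixed_h2_t0 is not None:
        a = model.resolve_a(params.delta, params.v_eps, params.v_t)
    mu = 0.0 if model.am_regime is AMRegime.NONE else params.mu
    resolved = _replace(params, a=a, mu=mu)
    return state_quantities(resolved, implied.offspring_state)


def _pack(model: ModelSpec, params: ParamVector) -> np.ndarray:
    return np.array([getattr(params, k) for k in model.free_params])


def _unpack(model: ModelSpec, x: np.ndarray) -> ParamVector:
    kw = dict(delta=0.0, a=0.0, f=0.0, mu=0.0, v_eps=1.0, v_t=0.01)
    kw.update(dict(zip(model.free_params, (float(v) for v in x))))
    return ParamVector(**kw)


def _objective(model: ModelSpec, moments: DatasetMoments,
               options: FitOptions):
    def fun(x: np.ndarray) -> float:
        try:
            implied = implied_covariance(
                model, _unpack(model, x),
                tol=options.recursion_tol,
                max_iter=options.recursion_max_iter,
            )
            val = neg2_loglik(moments, implied)
        except (NonConvergenceError, np.linalg.LinAlgError, ValueError):
            return _PENALTY
        if not math.isfinite(val):
            return _PENALTY
        return val

    return fun


def _start_values(model: ModelSpec, moments: DatasetMoments) -> ParamVector:
    """Moment-based initial values.

    delta from (theta_T - theta_NT) / (2 var(T)); mu from the mate
    phenotypic covariance when parental phenotypes are observed, else from
    the cross-parental PGS covariances; v_eps from the residual offspring
    variance.
    """
    S = pd.DataFrame(moments.cov, index=moments.variables,
                     columns=moments.variables)
    var_t = float(np.mean([S.loc[c, c] for c in ("T_p", "NT_p", "T_m", "NT_m")]))
    theta_t = S.loc["T_p", "Y_o"] + S.loc["T_m", "Y_o"]
    theta_nt = S.loc["NT_p", "Y_o"] + S.loc["NT_m", "Y_o"]
    delta0 = float((theta_t - theta_nt) / (2.0 * var_t))
    if abs(delta0) < 1e-3:
        delta0 = 0.1
    v_y = float(S.loc["Y_o", "Y_o"])
    if model.uses_parental_phenotypes:
        mu0 = float(S.loc["Y_p", "Y_m"] / S.loc["Y_p", "Y_p"] ** 2)
    else:
        trans = float(np.mean([S.loc["T_p", "T_m"], S.loc["T_p", "NT_m"],
                               S.loc["NT_p", "T_m"], S.loc["NT_p", "NT_m"]]))
        sy = max(float(S.loc["T_p", "Y_o"]), 1e-4)
        mu0 = float(np.clip(trans / sy**2, -1.0, 1.0))
    a0 = 0.0
    if not model.assumes_pgs_explains_h2 and model.fixed_h2_t0 is None:
        # latent effect sized so the latent score explains roughly the gap
        # between half the offspring variance and the PGS contribution
        a0 = float(np.sqrt(max(
            (0.4 * v_y - 2.0 * delta0**2 * var_t) / (2.0 * var_t), 0.04
        )))
    v_eps0 = 0.5 * v_y
    if model.fixed_h2_t0 is not None:
        # v_eps pins the base-population variance (and hence the derived
        # latent effect) in the NP models; start below the observed
        # offspring variance since VT/AM inflate V_Y above its base value
        v_eps0 = (1.0 - model.fixed_h2_t0) * v_y / 1.8
    return ParamVector(delta=delta0, a=a0, f=0.2, mu=mu0,
                       v_eps=v_eps0, v_t=var_t)


def fit_model(
    model: ModelSpec | str,
    moments: DatasetMoments,
    options: FitOptions = FitOptions(),
    fixed_h2_t0: Optional[float] = None,
) -> FitResult:
    """Fit one causal model by ML on the observed covariance structure.

    Multi-start local optimization (L-BFGS-B from a moment-based start
    plus jittered restarts); non-convergence is flagged on the result, not
    raised.  Variance parameters are bounded at zero and f at zero (VT
    reflection non-identifiability), so V_F = 2 f^2 (V_Y + mu V_Y^2) is
    non-negative by construction; boundary-hugging optima are flagged.
    """
    if isinstance(model, str):
        model = MODELS[model]
    if fixed_h2_t0 is not None:
        model = model.with_fixed_h2(fixed_h2_t0)
    if len(moments.variables) != model.n_vars:
        raise ValueError(
            f"model {model.model_id} expects {model.n_vars} variables, "
            f"moments have {len(moments.variables)}"
        )
    fun = _objective(model, moments, options)
    bounds = [_BOUNDS[k] for k in model.free_params]
    x0 = _pack(model, _start_values(model, moments))
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    rng = np.random.default_rng(options.jitter_seed)
    best = None
    starts = [x0]
    for _ in range(options.n_starts - 1):
        jit = x0 * rng.uniform(0.6, 1.5, size=len(x0)) + rng.normal(
            0.0, 0.02, size=len(x0))
        starts.append(np.clip(jit, [b[0] for b in bounds],
                              [b[1] for b in bounds]))
    n_used = 0
    for start in starts:
        n_used += 1
        # repair infeasible starts (explosive VT/AM feedback) by shrinking
        # the feedback-carrying parameters toward zero
        for _ in range(8):
            if fun(start) < _PENALTY:
                break
            start = start.copy()
            for j, name in enumerate(model.free_params):
                if name in ("f", "mu"):
                    start[j] *= 0.5
                elif name == "v_eps":
                    start[j] *= 0.7
        res = optimize.minimize(
            fun, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success and best.fun < _PENALTY:
            break  # the Nelder-Mead polish below still verifies the optimum
    # Nelder-Mead polish: robust to the line-search failures L-BFGS-B can
    # hit with finite-difference gradients near the optimum, and the
    # criterion for declaring convergence
    polish = optimize.minimize(
        fun, best.x, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000,
                 "maxfev": 6000},
    )
    if polish.fun <= best.fun:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        polish.x = np.clip(polish.x, lo, hi)
        best = polish
        converged = bool(polish.success and best.fun < _PENALTY)
    else:
        converged = bool(best.success and best.fun < _PENALTY)
    params = _unpack(model, best.x)
    boundary = [
        name for name, (lo, hi), val in
        zip(model.free_params, bounds, best.x)
        if min(val - lo, hi - val) < 1e-6 * max(1.0, hi - lo)
    ]
    try:
        estimates = report_quantities(model, params,
                                      tol=options.recursion_tol,
                                      max_iter=options.recursion_max_iter)
    except NonConvergenceError:
        estimates = {}
        converged = False
    se: dict[str, float] = {}
    if options.compute_se and converged and estimates:
        se = _delta_method_se(model, moments, best.x, options)
    result = FitResult(
        model_id=model.model_id, params=params, estimates=estimates, se=se,
        std_estimates={}, minus2ll=float(best.fun), n=moments.n,
        converged=converged, boundary=boundary,
        message=str(best.message), n_starts_used=n_used,
    )
    return standardize(result)


def standardize(fit: FitResult) -> FitResult:
    """Attach standardized estimates (variance scale divided by fitted V_Y,
    mu expressed as the implied mate correlation mu*V_Y, paths rescaled to
    a unit-variance phenotype)."""
    est = fit.estimates
    if not est:
        return fit
    v_y = est.get("v_y", np.nan)
    if not (v_y and v_y > 0):
        return fit
    std = {}
    for name, val in est.items():
        if name in _VARIANCE_SCALE:
            std[name] = val / v_y
        elif name == "mu":
            std[name] = val * v_y
        elif name == "delta":
            std[name] = val * math.sqrt(est["v_t"] / v_y)
        elif name == "a":
            std[name] = val * math.sqrt(est["v_t"] / v_y)
        else:  # f is already a phenotype-to-phenotype path
            std[name] = val
    fit.std_estimates = std
    return fit


# ---------------------------------------------------------------------------
# standard errors: finite-difference Hessian + delta method
# ---------------------------------------------------------------------------


def _fd_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 0.05)
    H = np.empty((k, k))
    f0 = fun(x)
    for a in range(k):
        for b in range(a, k):
            if a == b:
                xp, xm = x.copy(), x.copy()
                xp[a] += h[a]
                xm[a] -= h[a]
                H[a, a] = (fun(xp) - 2.0 * f0 + fun(xm)) / h[a] ** 2
            else:
                xpp, xpm, xmp, xmm = (x.copy() for _ in range(4))
                xpp[[a, b]] += [h[a], h[b]]
                xpm[a] += h[a]; xpm[b] -= h[b]
                xmp[a] -= h[a]; xmp[b] += h[b]
                xmm[[a, b]] -= [h[a], h[b]]
                H[a, b] = H[b, a] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4.0 * h[a] * h[b])
    return H


def _fd_jacobian(model: ModelSpec, x: np.ndarray, names: list[str],
                 options: FitOptions, rel_step: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 0.05)
    J = np.empty((len(names), k))
    for a in range(k):
        xp, xm = x.copy(), x.copy()
        xp[a] += h[a]
        xm[a] -= h[a]
        try:
            rp = report_quantities(model, _unpack(model, xp),
                                   tol=options.recursion_tol,
                                   max_iter=options.recursion_max_iter)
            rm = report_quantities(model, _unpack(model, xm),
                                   tol=options.recursion_tol,
                                   max_iter=options.recursion_max_iter)
        except NonConvergenceError:
            J[:, a] = np.nan
            continue
        J[:, a] = [(rp[n] - rm[n]) / (2.0 * h[a]) for n in names]
    return J


def _delta_method_se(model: ModelSpec, moments: DatasetMoments,
                     x: np.ndarray, options: FitOptions) -> dict[str, float]:
    """SEs of all reported quantities from the inverse Hessian of half the
    -2lnL, propagated through the parameter-to-report map."""
    # a tighter fixed-point tolerance keeps finite-difference noise well
    # below the step sizes used here
    options = FitOptions(
        n_starts=options.n_starts, jitter_seed=options.jitter_seed,
        maxiter=options.maxiter, recursion_tol=1e-13,
        recursion_max_iter=max(options.recursion_max_iter, 400),
        compute_se=options.compute_se,
    )
    fun = _objective(model, moments, options)
    H = 0.5 * _fd_hessian(fun, x)
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.min(eigvals) <= 0:
            raise np.linalg.LinAlgError("Hessian not positive definite")
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("Hessian not positive definite; SEs unavailable")
        return {}
    names = list(report_quantities(model, _unpack(model, x),
                                   tol=options.recursion_tol,
                                   max_iter=options.recursion_max_iter))
    J = _fd_jacobian(model, x, names, options)
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    return {n: float(np.sqrt(v)) if v >= 0 and np.isfinite(v) else np.nan
            for n, v in zip(names, var)}
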