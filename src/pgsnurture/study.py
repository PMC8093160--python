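"""Monte Carlo bias / precision studies over simulate→fit pipelines.

A study is a grid of cells, each a simulation scenario plus a list of
models to fit; every cell is replicated ``n_reps`` times with
deterministically derived child seeds, so results are byte-identical for
a given root seed regardless of the number of workers.  Summaries follow
the boxplot convention of the figures (quartiles, 2.5%/97.5% quantiles)
and the empirical standard error is the root-mean-square deviation of the
*standardized* estimates about the true standardized value (an RMSE about
truth, not a dispersion about the mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fit import FitOptions, fit_model, sample_moments
from .moments import MODELS, state_quantities, true_parameter_values
from .sim import SimConfig, simulate_trios

__all__ = [
    "StudyCell",
    "StudyDesign",
    "run_study",
    "truth_quantities",
    "empirical_se",
    "summarize_bias",
    "estimate_correlations",
    "se_curves",
]

#: quantities carried into replicate tables and summaries
REPORT_KEYS = (
    "delta", "a", "f", "mu", "v_eps", "v_t", "v_pgs", "v_lgs", "v_f",
    "w", "v", "theta_t", "theta_nt", "theta_diff", "v_y",
)


@dataclass(frozen=True)
class StudyCell:
    name: str
    config: SimConfig
    models: tuple[str, ...]
    fixed_h2_t0: Optional[float] = None


@dataclass(frozen=True)
class StudyDesign:
    cells: tuple[StudyCell, ...]
    n_reps: int
    seed: int
    n_jobs: int = 1

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")


def _replicate_seed(root: int, cell_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence(root, spawn_key=(cell_idx, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def truth_quantities(config: SimConfig) -> dict[str, float]:
    """Generative truth for every reported quantity (raw and standardized),
    from the moment recursion that mirrors the simulator."""
    params, state = true_parameter_values(config)
    raw = state_quantities(params, state)
    out = {k: raw[k] for k in REPORT_KEYS}
    v_y = raw["v_y"]
    for k in REPORT_KEYS:
        if k in ("delta", "a"):
            out["std_" + k] = raw[k] * np.sqrt(raw["v_t"] / v_y)
        elif k == "mu":
            out["std_mu"] = raw["mu"] * v_y
        elif k == "f":
            out["std_f"] = raw["f"]
        else:
            out["std_" + k] = raw[k] / v_y
    return out


def _run_one(cell_idx: int, cell: StudyCell, rep: int, root_seed: int,
             fit_options: FitOptions) -> list[dict]:
    seed = _replicate_seed(root_seed, cell_idx, rep)
    trios = simulate_trios(cell.config.replace(seed=seed))
    rows = []
    for model_id in cell.models:
        model = MODELS[model_id]
        if cell.fixed_h2_t0 is not None and model.fixed_h2_t0 is not None:
            model = model.with_fixed_h2(cell.fixed_h2_t0)
        row = {"cell": cell.name, "model": model_id, "rep": rep,
               "seed": seed, "converged": False, "minus2ll": np.nan}
        try:
            moments = sample_moments(trios, model)
            fit = fit_model(
                model, moments,
                FitOptions(
                    n_starts=fit_options.n_starts,
                    jitter_seed=seed ^ 0x5F5F5F,
                    maxiter=fit_options.maxiter,
                    recursion_tol=fit_options.recursion_tol,
                    recursion_max_iter=fit_options.recursion_max_iter,
                    compute_se=fit_options.compute_se,
                ),
            )
            row["converged"] = fit.converged
            row["minus2ll"] = fit.minus2ll
            for k in REPORT_KEYS:
                row["est_" + k] = fit.estimates.get(k, np.nan)
                row["std_" + k] = fit.std_estimates.get(k, np.nan)
                row["se_" + k] = fit.se.get(k, np.nan)
        except Exception as exc:  # noqa: BLE001 - study must never abort
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return rows


def run_study(design: StudyDesign,
              fit_options: FitOptions = FitOptions(compute_se=False)
              ) -> pd.DataFrame:
    """One row per (cell, replicate, model) with all estimates.

    Individual replicate failures are recorded (``converged=False`` plus
    an ``error`` column), never raised.  With ``n_jobs > 1`` replicates
    run in joblib workers; determinism is unaffected because every
    replicate's seed is pre-derived from the root seed.
    """
    tasks = [
        (ci, cell, rep)
        for ci, cell in enumerate(design.cells)
        for rep in range(design.n_reps)
    ]
    if design.n_jobs > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=design.n_jobs)(
            delayed(_run_one)(ci, cell, rep, design.seed, fit_options)
            for ci, cell, rep in tasks
        )
    else:
        chunks = [_run_one(ci, cell, rep, design.seed, fit_options)
                  for ci, cell, rep in tasks]
    return pd.DataFrame([row for chunk in chunks for row in chunk])


def empirical_se(estimates: Sequence[float], truth: float) -> float:
    """Root-mean-square deviation of estimates about the TRUE value."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise ValueError("empirical_se needs at least one estimate")
    if not np.isfinite(truth):
        raise ValueError("truth must be finite")
    return float(np.sqrt(np.mean((arr - truth) ** 2)))


def summarize_bias(
    replicates: pd.DataFrame,
    truths: dict[str, dict[str, float]],
    params: Sequence[str] = ("v_pgs", "v_lgs", "v_f", "w", "v", "mu"),
    standardized: bool = False,
) -> pd.DataFrame:
    """Per cell/model/parameter summary: truth, mean, bias, quartiles,
    2.5%/97.5% quantiles, empirical SE (RMSE about truth) and the Monte
    Carlo SE of the bias; non-converged replicates are excluded with a
    reported count."""
    prefix = "std_" if standardized else "est_"
    rows = []
    for (cell, model), grp in replicates.groupby(["cell", "model"],
                                                 sort=False):
        ok = grp[grp["converged"].astype(bool)]
        n_excluded = len(grp) - len(ok)
        for param in params:
            col = prefix + param
            truth_key = ("std_" + param) if standardized else param
            truth = truths.get(cell, {}).get(truth_key, np.nan)
            if col not in ok.columns or len(ok) < 2:
                rows.append({"cell": cell, "model": model, "param": param,
                             "truth": truth, "n": len(ok),
                             "n_excluded": n_excluded,
                             "available": False})
                continue
            vals = ok[col].dropna().to_numpy()
            if vals.size < 2:
                rows.append({"cell": cell, "model": model, "param": param,
                             "truth": truth, "n": int(vals.size),
                             "n_excluded": n_excluded, "available": False})
                continue
            q = np.quantile(vals, [0.025, 0.25, 0.5, 0.75, 0.975])
            rows.append({
                "cell": cell, "model": model, "param": param,
                "truth": truth,
                "mean": vals.mean(), "bias": vals.mean() - truth,
                "p2.5": q[0], "q1": q[1], "median": q[2], "q3": q[3],
                "p97.5": q[4],
                "emp_se": empirical_se(vals, truth)
                if np.isfinite(truth) else np.nan,
                "mc_se": vals.std(ddof=1) / np.sqrt(vals.size),
                "n": int(vals.size), "n_excluded": n_excluded,
                "available": True,
            })
    return pd.DataFrame(rows)


def estimate_correlations(
    replicates: pd.DataFrame, cell: str, model: str,
    params: Sequence[str] = ("v_pgs", "v_lgs", "v_f", "w", "v"),
) -> pd.DataFrame:
    """Pearson correlations across replicates between model estimates."""
    grp = replicates[(replicates["cell"] == cell)
                     & (replicates["model"] == model)
                     & replicates["converged"].astype(bool)]
    if len(grp) < 10:
        raise ValueError("need at least 10 converged replicates")
    cols = {p: "est_" + p for p in params}
    data = grp[list(cols.values())].rename(
        columns={v: k for k, v in cols.items()})
    return data.corr()


def se_curves(
    replicates: pd.DataFrame,
    truths: dict[str, dict[str, float]],
    level_of: dict[str, float],
    params: Sequence[str] = ("v_pgs", "v_lgs", "v_f", "w"),
) -> pd.DataFrame:
    """Empirical SEs of standardized estimates across design levels.

    ``level_of`` maps cell name to the design level it represents (e.g.
    its n_fam or its r2_pgs_t0).  Returns one row per
    (level, model, param) with the RMSE-about-truth of the standardized
    estimates, for plotting SE-versus-design curves.
    """
    summary = summarize_bias(replicates, truths, params=params,
                             standardized=True)
    summary = summary[summary["available"]]
    out = summary[["cell", "model", "param", "emp_se", "n"]].copy()
    out["level"] = out["cell"].map(level_of)
    return (out.dropna(subset=["level"])
            .sort_values(["param", "model", "level"])
            .reset_index(drop=True))
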