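"""Subject-by-subject maximum-likelihood fitting and model comparison.

Two model variants are compared: the full AN-TN model with task-set
inference (five free parameters: alpha, beta, epsilon, QP, J_INC) and
the associative network alone (three: alpha, beta, epsilon). The
likelihood of a subject's choice sequence is computed by teacher
forcing, and each variant is fitted by a grid search over starting
points followed by bounded local optimization.

Information criteria use the conventions

    BIC = -logL + (k / 2) * ln(n)
    AIC = -logL + k

i.e. the negative of the Laplace-approximation log model evidence,
*not* the also-common ``-2 logL + k ln n`` scaling. Only differences
between models matter for selection, and on that the two scalings
agree up to the factor 2. Lower BIC/AIC means a better fit; ``n`` is
the number of non-lapse trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .agent import BehaviorDataset, ModelParams, teacher_forced_run
from ._kernels import forced_loglik

__all__ = [
    "WITH_INFERENCE",
    "WITHOUT_INFERENCE",
    "FREE_PARAMS",
    "FitResult",
    "negative_log_likelihood",
    "information_criteria",
    "fit_subject",
    "model_recovery",
]

WITH_INFERENCE = "with_inference"
WITHOUT_INFERENCE = "without_inference"

#: Free parameters (and optimization order) of each variant.
FREE_PARAMS = {
    WITH_INFERENCE: ("alpha", "beta", "epsilon", "QP", "J_INC"),
    WITHOUT_INFERENCE: ("alpha", "beta", "epsilon"),
}

#: Box bounds for each free parameter. All rates and probabilities live
#: in [0, 1]; beta is capped well above any plausibly identifiable value.
BOUNDS = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "epsilon": (0.0, 1.0),
    "QP": (0.0, 1.0),
    "J_INC": (0.0, 1.0),
}

#: Default multi-start grid (>= 3 values per free parameter).
DEFAULT_GRID = {
    "alpha": (0.15, 0.4, 0.7),
    "beta": (3.0, 8.0, 20.0),
    "epsilon": (0.02, 0.1, 0.3),
    "QP": (0.08, 0.2, 0.45),
    "J_INC": (0.1, 0.4, 0.8),
}


def _vector_to_params(x, variant: str) -> ModelParams:
    names = FREE_PARAMS[variant]
    kw = dict(zip(names, (float(v) for v in x)))
    return ModelParams(**kw)


def negative_log_likelihood(params: ModelParams, dataset: BehaviorDataset,
                            variant: str) -> float:
    """Negative log-likelihood (nats) of the recorded choices.

    The model is run teacher-forced through the dataset; lapse trials
    contribute neither to the likelihood nor to the state updates.
    """
    if variant not in FREE_PARAMS:
        raise ValueError(f"unknown variant {variant!r}")
    if dataset.n_responses == 0:
        raise ValueError("dataset has no non-lapse trials")
    if variant == WITHOUT_INFERENCE:
        params = params.without_inference()
    return -forced_loglik(params, dataset,
                          with_inference=(variant == WITH_INFERENCE))


def information_criteria(log_likelihood: float, k: int, n: int
                         ) -> tuple[float, float]:
    """(BIC, AIC) under the conventions documented in this module."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    bic = -log_likelihood + 0.5 * k * np.log(n)
    aic = -log_likelihood + k
    return float(bic), float(aic)


@dataclass
class FitResult:
    """Outcome of fitting one variant to one subject's dataset."""

    variant: str
    params: ModelParams
    log_likelihood: float
    n_trials: int
    k: int
    bic: float
    aic: float
    diagnostics: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat summary row (mirrors the per-subject fit table)."""
        p = self.params
        return {
            "variant": self.variant, "df": self.k,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic, "bic": self.bic, "n_trials": self.n_trials,
            "alpha": p.alpha, "decision_noise": 1.0 / p.beta if p.beta else
            np.inf, "epsilon": p.epsilon,
            "QP": p.QP if self.variant == WITH_INFERENCE else np.nan,
            "J_INC": p.J_INC if self.variant == WITH_INFERENCE else np.nan,
        }


def fit_subject(dataset: BehaviorDataset, variant: str,
                grid: dict[str, tuple] | None = None,
                n_starts: int = 3,
                optimizer_options: dict | None = None) -> FitResult:
    """Maximum-likelihood fit of one variant to one dataset.

    A full factorial grid over the starting values is scored first; the
    ``n_starts`` best grid points seed bounded local optimization
    (Nelder-Mead, which tolerates the small steps the TN's activation
    threshold induces in the likelihood surface, followed by an
    L-BFGS-B polish). The global best over grid and local optima is
    returned. The procedure is deterministic for fixed grid, bounds and
    dataset: ties are broken by lower negative log-likelihood, then
    lexicographically by parameter vector.
    """
    if variant not in FREE_PARAMS:
        raise ValueError(f"unknown variant {variant!r}")
    if dataset.n_responses == 0:
        raise ValueError("dataset has no non-lapse trials")
    names = FREE_PARAMS[variant]
    grid = {**DEFAULT_GRID, **(grid or {})}
    bounds = [BOUNDS[nm] for nm in names]

    def nll_vec(x) -> float:
        x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        return negative_log_likelihood(_vector_to_params(x, variant),
                                       dataset, variant)

    grid_points = sorted(itertools.product(*(grid[nm] for nm in names)))
    scored = sorted(((nll_vec(gp), gp) for gp in grid_points),
                    key=lambda t: (t[0], t[1]))
    starts = [gp for _, gp in scored[:n_starts]]

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    candidates: list[tuple[float, tuple, bool]] = [
        (s, gp, True) for s, gp in scored]
    n_converged = 0
    for x0 in starts:
        nm = optimize.minimize(
            nll_vec, np.asarray(x0), method="Nelder-Mead", bounds=bounds,
            options={"maxfev": 600, "xatol": 1e-4, "fatol": 1e-6,
                     **(optimizer_options or {})})
        polish = optimize.minimize(
            nll_vec, np.clip(nm.x, lo, hi), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 100})
        res = polish if polish.fun <= nm.fun else nm
        n_converged += bool(res.success)
        candidates.append(
            (float(res.fun),
             tuple(float(v) for v in np.clip(res.x, lo, hi)),
             bool(res.success)))
    best_nll, best_x, _ = min(candidates, key=lambda t: (t[0], t[1]))

    k = len(names)
    n = dataset.n_responses
    bic, aic = information_criteria(-best_nll, k, n)
    return FitResult(
        variant=variant, params=_vector_to_params(best_x, variant),
        log_likelihood=-best_nll, n_trials=n, k=k, bic=bic, aic=aic,
        diagnostics={"n_starts": len(starts), "n_converged": n_converged,
                     "grid_size": len(grid_points),
                     "grid_best_nll": scored[0][0]})


def fit_both_variants(dataset: BehaviorDataset, **kwargs
                      ) -> dict[str, FitResult]:
    """Fit the with- and without-inference variants to one dataset."""
    return {v: fit_subject(dataset, v, **kwargs)
            for v in (WITH_INFERENCE, WITHOUT_INFERENCE)}


def select_by_bic(fits: dict[str, FitResult]) -> str:
    """Variant with the lower BIC (ties go to the simpler model)."""
    w, wo = fits[WITH_INFERENCE], fits[WITHOUT_INFERENCE]
    return WITH_INFERENCE if w.bic < wo.bic else WITHOUT_INFERENCE


def model_recovery(generators: dict[str, ModelParams], n_subjects: int,
                   rng: np.random.Generator,
                   session_type: str = "recurrent",
                   **fit_kwargs) -> pd.DataFrame:
    """Ex-post model recovery: simulate under each variant, refit both.

    For each generating variant, ``n_subjects`` sessions are simulated
    with the given parameters, both variants are fitted to each, and the
    BIC-selected variant is tallied. Returns a confusion table of
    selection frequencies (rows: generator, columns: selected variant).
    """
    from .environment import SessionConfig, generate_session
    from .agent import simulate_session

    if n_subjects == 0:
        return pd.DataFrame(
            columns=[f"selected_{WITH_INFERENCE}",
                     f"selected_{WITHOUT_INFERENCE}", "n_subjects"])
    rows = []
    for gen_name, gen_params in generators.items():
        counts = {WITH_INFERENCE: 0, WITHOUT_INFERENCE: 0}
        for i in range(n_subjects):
            cfg = SessionConfig(session_type=session_type)
            plan = generate_session(cfg, rng)
            data, _ = simulate_session(
                gen_params, plan,
                with_inference=(gen_name == WITH_INFERENCE), rng=rng,
                subject_id=f"{gen_name}-{i}", collect_trace=False)
            fits = fit_both_variants(data, **fit_kwargs)
            counts[select_by_bic(fits)] += 1
        rows.append({"generator": gen_name,
                     **{f"selected_{k}": (v / n_subjects if n_subjects else
                                          np.nan)
                        for k, v in counts.items()},
                     "n_subjects": n_subjects})
    return pd.DataFrame(rows).set_index("generator")
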