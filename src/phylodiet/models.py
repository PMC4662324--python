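"""Continuous-trait evolutionary models: likelihoods, ML fitting, AICc.

Five models are supported, all Gaussian on the tips with mean ``z0 * 1`` and
covariance ``sigma2 * S(theta)``:

* ``bm``     - Brownian motion, ``S = C`` (the tree covariance).
* ``lambda`` - Pagel's lambda, off-diagonal of ``C`` scaled by ``lambda``.
* ``kappa``  - branch lengths raised to ``kappa`` before path summation.
* ``delta``  - shared depths raised to ``delta`` (max tip depth preserved).
* ``ou``     - Ornstein-Uhlenbeck with attraction ``alpha``; on a possibly
  non-ultrametric tree, ``S_ij = exp(-alpha d_ij) (1 - exp(-2 alpha C_ij))
  / (2 alpha)`` with ``d_ij`` the patristic distance, which reduces to
  Brownian motion as ``alpha -> 0``.

``z0`` and ``sigma2`` are always profiled analytically by GLS; only the
transform parameter is optimized numerically (bounded scalar search seeded
from a fixed grid, hence deterministic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import ConvergenceError, ValidationError
from .trees import Phylogeny

__all__ = [
    "MODELS",
    "PARAM_BOUNDS",
    "ModelFit",
    "ModelSelection",
    "model_loglik",
    "profiled_loglik",
    "fit_model",
    "aicc",
    "select_models",
]

MODELS = ("bm", "ou", "lambda", "kappa", "delta")

#: transform-parameter bounds, matching common fitting-tool defaults so
#: results are comparable with standard analyses
PARAM_BOUNDS: Dict[str, Tuple[float, float]] = {
    "lambda": (0.0, 1.0),
    "kappa": (0.0, 1.0),
    "delta": (1e-5, 3.0),
    "ou": (1e-8, 50.0),
}

PARAM_NAMES = {"lambda": "lambda", "kappa": "kappa", "delta": "delta", "ou": "alpha"}

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ModelFit:
    """One fitted evolutionary model on one tree."""

    model: str
    sigma2: float
    z0: float
    param: Optional[float]  # lambda / kappa / delta / alpha; None for BM
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    bounds_hit: bool = False
    note: str = ""

    @property
    def param_name(self) -> Optional[str]:
        return PARAM_NAMES.get(self.model)


class _TreeMachine:
    """Caches the matrices needed to evaluate every model on one tree."""

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        cov = tree.covariance()
        self.C = cov.matrix
        self.tips = cov.tips
        self.diagC = np.diag(self.C)
        self.d = self.diagC[:, None] + self.diagC[None, :] - 2.0 * self.C
        self.n = len(self.tips)

    def structure(self, model: str, theta: Optional[float]) -> np.ndarray:
        if model == "bm":
            return self.C
        if model == "lambda":
            if not 0.0 <= theta <= 1.0:
                raise ValidationError("lambda must lie in [0, 1]")
            S = theta * self.C
            np.fill_diagonal(S, self.diagC)
            return S
        if model == "delta":
            if theta <= 0:
                raise ValidationError("delta must be > 0")
            hmax = float(self.diagC.max())
            scale = hmax / hmax ** theta if hmax > 0 else 1.0
            S = np.zeros_like(self.C)
            pos = self.C > 0
            S[pos] = (self.C[pos] ** theta) * scale
            return S
        if model == "kappa":
            return self.tree.covariance(kind="kappa", param=theta).matrix
        if model == "ou":
            a = float(theta)
            if a < 0:
                raise ValidationError("alpha must be >= 0")
            if a < 1e-12:
                return self.C
            return np.exp(-a * self.d) * (-np.expm1(-2.0 * a * self.C)) / (2.0 * a)
        raise ValidationError(f"unknown model {model!r}")


def profiled_loglik(x: np.ndarray, S: np.ndarray) -> Tuple[float, float, float]:
    """ML log-likelihood with ``z0`` and ``sigma2`` profiled out by GLS.

    Returns ``(loglik, z0_hat, sigma2_hat)`` where
    ``z0 = (1' S^-1 1)^-1 1' S^-1 x`` and ``sigma2 = r' S^-1 r / n``.
    """
    n = len(x)
    try:
        L = linalg.cholesky(S, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(S)
        raise ValidationError(
            f"singular covariance structure (condition number {cond:.3e})"
        ) from exc
    one = np.ones(n)
    w1 = linalg.cho_solve((L, True), one)
    wx = linalg.cho_solve((L, True), x)
    z0 = float(one @ wx / (one @ w1))
    r = x - z0
    q = float(r @ linalg.cho_solve((L, True), r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if q <= 0:
        # constant trait: degenerate, likelihood unbounded
        return np.inf, z0, 0.0
    sigma2 = q / n
    ll = -0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + n)
    return float(ll), z0, float(sigma2)


def model_loglik(
    trait: Mapping[str, float],
    tree: Phylogeny,
    model: str,
    sigma2: float,
    z0: float,
    param: Optional[float] = None,
) -> float:
    """Exact multivariate-normal log-density of the tip values under a model.

    All parameters supplied (nothing profiled); used mostly for testing and
    profiling cross-checks.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be > 0")
    machine = _TreeMachine(tree)
    x = tree.align_trait(dict(trait))
    S = machine.structure(model, param)
    V = sigma2 * S
    n = len(x)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise ValidationError(
            f"singular covariance (condition number {cond:.3e})"
        ) from exc
    r = x - z0
    q = float(r @ linalg.cho_solve((L, True), r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(-0.5 * (n * _LOG2PI + logdet + q))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2 logL + 2k + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ValidationError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


_N_GRID = 11


def fit_model(
    trait: Mapping[str, float],
    tree: Phylogeny,
    model: str,
    bounds: Optional[Tuple[float, float]] = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model to one trait on one tree.

    The transform parameter is optimized by bounded scalar search started
    from the best point of a fixed grid (log-spaced for the OU attraction
    strength); the root state and rate are profiled analytically at every
    evaluation. Deterministic for fixed inputs.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    machine = _TreeMachine(tree)
    x = tree.align_trait(dict(trait))
    n = machine.n
    k = 2 if model == "bm" else 3
    if n < k:
        raise ValidationError(f"too few tips (n={n}) for a {k}-parameter model")

    def _aicc_or_nan(ll):
        return aicc(ll, k, n) if n - k - 1 > 0 else float("nan")

    if model == "bm":
        ll, z0, s2 = profiled_loglik(x, machine.C)
        return ModelFit("bm", s2, z0, None, ll, 2, n, _aicc_or_nan(ll))

    lo, hi = bounds if bounds is not None else PARAM_BOUNDS[model]
    log_scale = model == "ou"

    def negll(theta):
        th = 10.0 ** theta if log_scale else theta
        try:
            ll, _, _ = profiled_loglik(x, machine.structure(model, th))
        except ValidationError:
            return np.inf
        return -ll

    glo, ghi = (np.log10(lo), np.log10(hi)) if log_scale else (lo, hi)
    grid = np.linspace(glo, ghi, _N_GRID)
    gvals = np.array([negll(g) for g in grid])
    if not np.isfinite(gvals).any():
        raise ConvergenceError(f"{model} likelihood not finite anywhere on the grid")
    ibest = int(np.nanargmin(gvals))
    note = ""
    flat = float(np.nanmax(gvals) - np.nanmin(gvals)) < 1e-8
    if flat:
        note = "flat likelihood: transform parameter unidentifiable on this tree"
    bracket_lo = grid[max(ibest - 1, 0)]
    bracket_hi = grid[min(ibest + 1, _N_GRID - 1)]
    res = optimize.minimize_scalar(
        negll, bounds=(bracket_lo, bracket_hi), method="bounded",
        options={"xatol": 1e-8},
    )
    converged = bool(res.success)
    if res.fun <= gvals[ibest]:
        theta_opt, f_opt = float(res.x), float(res.fun)
    else:  # fall back to the grid point (optimizer worsened the objective)
        theta_opt, f_opt = float(grid[ibest]), float(gvals[ibest])
    th = 10.0 ** theta_opt if log_scale else theta_opt
    ll, z0, s2 = profiled_loglik(x, machine.structure(model, th))
    span = ghi - glo
    bounds_hit = flat or min(theta_opt - glo, ghi - theta_opt) < 1e-6 * span
    return ModelFit(
        model, s2, z0, th, ll, k, n, _aicc_or_nan(ll),
        converged=converged, bounds_hit=bounds_hit, note=note,
    )


@dataclass
class ModelSelection:
    """AICc comparison of the model set across a tree sample."""

    table: pd.DataFrame  # one row per (tree_index, model)
    best_model: pd.Series  # tree_index -> winning model
    proportions: Dict[str, float]
    aicc_mean: Dict[str, float]
    aicc_sd: Dict[str, float]
    n_excluded: int = 0


_K_OF = {m: (2 if m == "bm" else 3) for m in MODELS}


def select_models(
    trees: Sequence[Phylogeny],
    trait: Mapping[str, float],
    models: Sequence[str] = MODELS,
) -> ModelSelection:
    """Fit every model on every tree and tabulate AICc winners.

    Ties below 1e-6 AICc are broken toward the model with fewer parameters
    (then alphabetically) for determinism; non-converged fits are excluded
    from the winner call for that tree with a warning.
    """
    rows = []
    n_excluded = 0
    for ti, tree in enumerate(trees):
        for m in models:
            fit = fit_model(trait, tree, m)
            rows.append(
                {
                    "tree_index": ti,
                    "model": m,
                    "loglik": fit.loglik,
                    "param": fit.param,
                    "sigma2": fit.sigma2,
                    "z0": fit.z0,
                    "k": fit.k,
                    "aicc": fit.aicc,
                    "converged": fit.converged,
                }
            )
    table = pd.DataFrame(rows)
    best = {}
    for ti, sub in table.groupby("tree_index"):
        usable = sub[sub["converged"]]
        if len(usable) < len(sub):
            n_excluded += int(len(sub) - len(usable))
            warnings.warn(
                f"tree {ti}: {len(sub) - len(usable)} non-converged fit(s) excluded"
            )
        if usable.empty:
            continue
        amin = usable["aicc"].min()
        tied = usable[usable["aicc"] <= amin + 1e-6]
        winner = sorted(tied["model"], key=lambda m: (_K_OF[m], m))[0]
        best[ti] = winner
    best_series = pd.Series(best, name="best_model")
    counts = best_series.value_counts()
    proportions = {m: float(counts.get(m, 0)) / max(len(best_series), 1) for m in models}
    aicc_mean = {m: float(table.loc[table.model == m, "aicc"].mean()) for m in models}
    aicc_sd = {m: float(table.loc[table.model == m, "aicc"].std(ddof=1)) for m in models}
    return ModelSelection(table, best_series, proportions, aicc_mean, aicc_sd, n_excluded)
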