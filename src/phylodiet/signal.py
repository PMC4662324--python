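"""Phylogenetic signal statistics: Blomberg's K and Pagel's lambda.

K compares the mean squared tip deviation from the phylogenetically
corrected mean (MSE0) with the GLS mean squared error given the tree
covariance (MSE), scaled by the Brownian-motion expectation of that ratio,
so K = 1 under Brownian motion, K < 1 for less signal than BM and K > 1
for more. Significance comes from a tip-label permutation test on MSE
(signal = smaller MSE than permuted data), with the observed statistic
counted among the permutations.

The lambda statistic reuses the ML lambda fit from the trait-model layer;
its p-value is a likelihood-ratio test of lambda-hat against lambda = 0
(chi-square, 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import linalg, stats

from .errors import ValidationError
from .models import fit_model, profiled_loglik
from .trees import Phylogeny

__all__ = ["SignalResult", "blomberg_k", "lambda_signal"]


@dataclass
class SignalResult:
    statistic: str  # "K" or "lambda"
    estimate: float
    p_value: float
    test: str  # "permutation" or "likelihood-ratio"
    n_perm: Optional[int] = None
    seed: Optional[int] = None


def _k_parts(x: np.ndarray, L, Ci1: np.ndarray, s11: float):
    """(MSE0, MSE) for a tip-value vector given a cached Cholesky factor."""
    n = len(x)
    a0 = float(Ci1 @ x) / s11  # GLS (phylogenetically corrected) mean
    r = x - a0
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ linalg.cho_solve((L, True), r)) / (n - 1)
    return mse0, mse


def blomberg_k(
    trait: Mapping[str, float],
    tree: Phylogeny,
    n_perm: int = 1000,
    seed: int = 0,
) -> SignalResult:
    """Blomberg's K with a one-tailed tip-permutation test.

    K = (MSE0/MSE) / E_BM[MSE0/MSE], where the Brownian expectation is the
    trace form ``(tr C - n / (1' C^-1 1)) / (n - 1)``. Invariant to affine
    transformation of the trait.
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    x = tree.align_trait(dict(trait))
    if np.ptp(x) == 0:
        raise ValidationError("K undefined for a constant trait")
    C = tree.covariance().matrix
    n = len(x)
    L = linalg.cholesky(C, lower=True)
    one = np.ones(n)
    Ci1 = linalg.cho_solve((L, True), one)
    s11 = float(one @ Ci1)
    expected = (float(np.trace(C)) - n / s11) / (n - 1)
    mse0, mse = _k_parts(x, L, Ci1, s11)
    k = (mse0 / mse) / expected

    rng = np.random.default_rng(seed)
    # signal: observed GLS error smaller than under permuted tip labels
    count = 1  # observed counted among the permutations
    for _ in range(n_perm):
        xp = rng.permutation(x)
        _, mse_p = _k_parts(xp, L, Ci1, s11)
        if mse_p <= mse:
            count += 1
    p = count / (n_perm + 1)
    return SignalResult("K", float(k), float(p), "permutation", n_perm, seed)


def lambda_signal(trait: Mapping[str, float], tree: Phylogeny) -> SignalResult:
    """ML Pagel's lambda with a likelihood-ratio test against lambda = 0."""
    x = tree.align_trait(dict(trait))
    if np.ptp(x) == 0:
        raise ValidationError("lambda undefined for a constant trait")
    fit = fit_model(dict(trait), tree, "lambda")
    C = tree.covariance().matrix
    S0 = np.diag(np.diag(C))
    ll0, _, _ = profiled_loglik(x, S0)
    lr = max(2.0 * (fit.loglik - ll0), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)
    return SignalResult("lambda", float(fit.param), p, "likelihood-ratio")
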