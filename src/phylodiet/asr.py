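"""REML ancestral state reconstruction and cross-tree node summaries.

Reconstruction runs on a lambda-rescaled tree (the transform parameter is
fitted per tree upstream and plugged in here): the Brownian rate is
estimated by the restricted-maximum-likelihood (contrasts-based, unbiased)
estimator, and each internal node's state is the GLS/BLUP estimate given
the tip values, with a standard error from the conditional variance plus
the uncertainty of the estimated root mean. 95% intervals use the normal
1.96 multiplier.

Because different trees of a bootstrap sample disagree in topology,
estimates are aggregated only at clades present in every tree (strict
consensus nodes): the per-tree estimates for one such clade are smoothed
with a Gaussian kernel and summarized by the density mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy import linalg, stats

from .contrasts import pic
from .errors import BranchLengthError, NotBinaryError, ValidationError
from .trees import Phylogeny

__all__ = [
    "AncestralEstimate",
    "ConsensusNodeSummary",
    "reml_asr",
    "estimate_at_clade",
    "summarize_consensus_node",
    "inverse_logit",
]

CI_MULTIPLIER = 1.96
KDE_GRID_POINTS = 512
KDE_GRID_PAD_BW = 3.0


def inverse_logit(x):
    """Back-transform from the logit to the proportion scale."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class AncestralEstimate:
    """State estimate at one internal node (on the analysis scale)."""

    clade: frozenset  # descendant tip set identifying the node
    estimate: float
    se: float

    @property
    def ci(self):
        return (self.estimate - CI_MULTIPLIER * self.se,
                self.estimate + CI_MULTIPLIER * self.se)

    def back_transformed(self):
        """Estimate and CI mapped through the inverse logit (monotone, so
        interval endpoints map directly)."""
        lo, hi = self.ci
        return (
            float(inverse_logit(self.estimate)),
            (float(inverse_logit(lo)), float(inverse_logit(hi))),
        )


def reml_asr(
    trait: Mapping[str, float],
    tree: Phylogeny,
    lam: float = 1.0,
) -> List[AncestralEstimate]:
    """Ancestral states for every internal node under a lambda-rescaled BM.

    ``lam`` is the Pagel lambda fitted to this tree/trait (1.0 gives plain
    Brownian motion). The rate is the REML estimator (mean squared
    standardized contrast); node states are GLS estimates and are invariant
    to tip input order.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValidationError("lambda must lie in [0, 1]")
    if not tree.has_branch_lengths:
        raise BranchLengthError(
            "consensus trees carry no branch lengths; reconstruct on each "
            "sample tree and summarize at matched consensus clades instead"
        )
    if not tree.is_binary:
        raise NotBinaryError(
            "reconstruction requires a binary tree; run per sample tree, not "
            "on the consensus topology"
        )
    tree_r = tree.rescale("lambda", lam) if lam != 1.0 else tree
    x = tree_r.align_trait(dict(trait))
    n = len(x)

    if np.ptp(x) == 0:  # degenerate: no variation, rate zero
        v = float(x[0])
        out = []
        for nd in tree_r.dendropy_tree.postorder_internal_node_iter():
            clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            out.append(AncestralEstimate(clade, v, 0.0))
        return out

    cs = pic(dict(trait), tree_r)
    sigma2 = float(np.sum(cs.contrasts**2) / (n - 1))  # REML rate

    cov = tree_r.covariance()
    C = cov.matrix
    tip_index = {lab: i for i, lab in enumerate(cov.tips)}
    L = linalg.cholesky(C, lower=True)
    one = np.ones(n)
    Ci1 = linalg.cho_solve((L, True), one)
    Cix = linalg.cho_solve((L, True), x)
    s11 = float(one @ Ci1)
    z0 = float(one @ Cix) / s11
    r = x - z0
    Cir = linalg.cho_solve((L, True), r)

    depth = tree_r.node_depths()
    arr = tree_r._get_arrays()
    nodes = arr["nodes"]
    out = []
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            continue
        tips_below = [lf.taxon.label for lf in nd.leaf_iter()]
        idx = [tip_index[t] for t in tips_below]
        d_a = float(depth[i])
        # cov(node, tip j) = shared depth: depth of the node itself for
        # descendants, else the tip-pair covariance via any descendant tip
        c = C[idx[0], :].copy()
        c[idx] = d_a
        est = z0 + float(c @ Cir)
        cic = linalg.cho_solve((L, True), c)
        var_cond = d_a - float(c @ cic)
        mean_adj = (1.0 - float(one @ cic)) ** 2 / s11
        se = math.sqrt(sigma2 * max(var_cond + mean_adj, 0.0))
        out.append(AncestralEstimate(frozenset(tips_below), est, se))
    return out


def estimate_at_clade(
    estimates: Sequence[AncestralEstimate], tip_set
) -> Optional[AncestralEstimate]:
    """The estimate whose node subtends exactly ``tip_set``, else None."""
    want = frozenset(tip_set)
    for e in estimates:
        if e.clade == want:
            return e
    return None


@dataclass
class ConsensusNodeSummary:
    """Kernel-density summary of per-tree estimates at one consensus clade."""

    label: str
    estimates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    grid: Optional[np.ndarray]
    density: Optional[np.ndarray]
    mode: float
    #: density grids for the CI-bound distributions (may be None when
    #: degenerate)
    density_low: Optional[np.ndarray] = None
    density_high: Optional[np.ndarray] = None

    @property
    def minmax(self):
        return float(self.estimates.min()), float(self.estimates.max())


def _kde_mode(values: np.ndarray):
    """Gaussian-kernel density on a 512-point grid; mode = argmax (ties to
    the smaller value). Returns (grid, density, mode)."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return None, None, float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    bw = math.sqrt(float(kde.covariance[0, 0]))
    lo = values.min() - KDE_GRID_PAD_BW * bw
    hi = values.max() + KDE_GRID_PAD_BW * bw
    grid = np.linspace(lo, hi, KDE_GRID_POINTS)
    dens = kde(grid)
    mode = float(grid[int(np.argmax(dens))])  # argmax takes the first (smaller) tie
    return grid, dens, mode


def summarize_consensus_node(
    per_tree_estimates: Sequence[AncestralEstimate],
    label: str = "",
) -> ConsensusNodeSummary:
    """Summarize one matched clade's estimates across a tree sample."""
    if len(per_tree_estimates) < 2:
        raise ValidationError("need estimates from at least 2 trees to summarize")
    clades = {e.clade for e in per_tree_estimates}
    if len(clades) != 1:
        raise ValidationError("estimates mix different clades")
    est = np.array([e.estimate for e in per_tree_estimates])
    lo = np.array([e.ci[0] for e in per_tree_estimates])
    hi = np.array([e.ci[1] for e in per_tree_estimates])
    grid, dens, mode = _kde_mode(est)
    _, dlow, _ = _kde_mode(lo)
    _, dhigh, _ = _kde_mode(hi)
    return ConsensusNodeSummary(
        label=label,
        estimates=est,
        ci_low=lo,
        ci_high=hi,
        grid=grid,
        density=dens,
        mode=mode,
        density_low=dlow,
        density_high=dhigh,
    )
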