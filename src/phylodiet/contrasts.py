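"""Phylogenetically independent contrasts and contrast correlation tests.

The contrast recursion follows the classic pruning algorithm: at an
internal node with children carrying values ``x1, x2`` on (variance-
adjusted) branches ``v1, v2`` the standardized contrast is
``(x1 - x2) / sqrt(v1 + v2)``, the node value is the branch-weighted mean,
and the node's parent branch is lengthened by ``v1 v2 / (v1 + v2)``.

Because plain (non-origin) correlation of contrasts depends on the sign
convention, contrasts are always taken as (first child - second child) in
the order children appear in the input tree; this convention is fixed and
asserted by tests.

Correct Brownian standardization implies the absolute contrast is
uncorrelated with its standard deviation; when the diagnostic fails,
branch lengths are transformed over a fixed grid of power and log maps
until both a Pearson (linear) and Kendall (monotone) diagnostic pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import NotBinaryError, ValidationError
from .trees import Phylogeny

__all__ = [
    "ContrastSet",
    "CorrelationResult",
    "pic",
    "standardization_diagnostics",
    "standardize_branches",
    "contrast_correlation",
    "nonphylo_correlation",
    "DEFAULT_TRANSFORM_GRID",
]

#: zero-length internal branches are replaced by this fraction of tree height
ZERO_BRANCH_FRACTION = 1e-8

#: scanned in order: identity first, then power maps t -> t^a (a ascending),
#: then log maps t -> ln(1 + b t)/b (b ascending)
DEFAULT_TRANSFORM_GRID: Tuple[Tuple[str, float], ...] = tuple(
    [("none", 1.0)]
    + [("power", round(a, 1)) for a in np.arange(0.1, 1.0, 0.1)]
    + [("log", b) for b in (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)]
)


@dataclass
class CorrelationResult:
    method: str  # "pearson" or "kendall"
    coefficient: float
    p_value: float
    n: int
    applicable: bool = True


@dataclass
class ContrastSet:
    """Standardized contrasts, one per internal node of a binary tree."""

    contrasts: np.ndarray
    sds: np.ndarray  # sqrt of summed expected variances per contrast
    node_clades: List[frozenset]  # descendant tip set per contrast node
    transform: Tuple[str, float] = ("none", 1.0)
    tree_tag: str = ""

    def __len__(self) -> int:
        return len(self.contrasts)


def _transform_lengths(tree: Phylogeny, kind: str, const: float) -> Phylogeny:
    if kind == "none":
        return tree
    clone = tree.dendropy_tree.clone(depth=1)
    for nd in clone.preorder_node_iter():
        if nd.parent_node is None:
            continue
        t = float(nd.edge.length)
        if kind == "power":
            nd.edge.length = t ** const
        elif kind == "log":
            nd.edge.length = math.log1p(const * t) / const
        else:
            raise ValidationError(f"unknown branch transform {kind!r}")
    return Phylogeny(clone)


def pic(
    trait: Mapping[str, float],
    tree: Phylogeny,
    transform: Tuple[str, float] = ("none", 1.0),
) -> ContrastSet:
    """Standardized independent contrasts of one trait on a binary tree.

    ``transform`` optionally maps every branch length before the recursion
    (see :data:`DEFAULT_TRANSFORM_GRID`). Zero-length internal branches are
    replaced by a tiny fraction of tree height with a warning.
    """
    if not tree.is_binary:
        raise NotBinaryError(
            "contrasts require a fully bifurcating tree; resolve polytomies "
            "(e.g. with zero-length branches) first"
        )
    tree = _transform_lengths(tree, *transform)
    height = tree.height
    floor = ZERO_BRANCH_FRACTION * height
    # pre-pass: replace zero-length internal branches before the recursion
    zero_internal = [
        nd
        for nd in tree.dendropy_tree.preorder_internal_node_iter()
        if nd.parent_node is not None and float(nd.edge.length) <= 0
    ]
    if zero_internal:
        if transform == ("none", 1.0):
            tree = tree.copy()  # never mutate the caller's tree
            zero_internal = [
                nd
                for nd in tree.dendropy_tree.preorder_internal_node_iter()
                if nd.parent_node is not None and float(nd.edge.length) <= 0
            ]
        for nd in zero_internal:
            nd.edge.length = floor
        warnings.warn(
            f"{len(zero_internal)} zero-length internal branch(es) replaced by "
            f"{ZERO_BRANCH_FRACTION:g} x tree height before contrasts"
        )
    values = dict(trait)
    tree.align_trait(values)  # raises if any tip is missing

    contrasts: List[float] = []
    sds: List[float] = []
    clades: List[frozenset] = []
    state: Dict[int, Tuple[float, float, frozenset]] = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            v = float(nd.edge.length)
            state[id(nd)] = (float(values[nd.taxon.label]), v, frozenset([nd.taxon.label]))
            continue
        (x1, v1, c1), (x2, v2, c2) = (state.pop(id(c)) for c in nd.child_nodes())
        if v1 + v2 <= 0:
            raise ValidationError("both child branches have zero length at a node")
        s = math.sqrt(v1 + v2)
        contrasts.append((x1 - x2) / s)
        sds.append(s)
        clades.append(c1 | c2)
        xa = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        extra = v1 * v2 / (v1 + v2)
        vparent = float(nd.edge.length) if nd.parent_node is not None else 0.0
        state[id(nd)] = (xa, vparent + extra, c1 | c2)
    return ContrastSet(
        np.array(contrasts), np.array(sds), clades, transform=transform
    )


def standardization_diagnostics(cs: ContrastSet) -> Dict[str, CorrelationResult]:
    """Garland-style diagnostics: |contrast| vs its SD, Pearson and Kendall.

    A significant trend in either indicates improperly standardized branch
    lengths.
    """
    if len(cs) < 4:
        raise ValidationError("diagnostics need at least 4 contrasts")
    a = np.abs(cs.contrasts)
    s = cs.sds
    out = {}
    if np.ptp(a) == 0 or np.ptp(s) == 0:
        out["pearson"] = CorrelationResult("pearson", np.nan, np.nan, len(cs), False)
        out["kendall"] = CorrelationResult("kendall", np.nan, np.nan, len(cs), False)
        return out
    r, p = stats.pearsonr(a, s)
    out["pearson"] = CorrelationResult("pearson", float(r), float(p), len(cs))
    tau, pk = stats.kendalltau(a, s)  # tau-b, tie-corrected
    out["kendall"] = CorrelationResult("kendall", float(tau), float(pk), len(cs))
    return out


def _passes(diag: Dict[str, CorrelationResult], alpha: float) -> bool:
    return all((not d.applicable) or d.p_value > alpha for d in diag.values())


def standardize_branches(
    trait: Mapping[str, float],
    tree: Phylogeny,
    grid: Sequence[Tuple[str, float]] = DEFAULT_TRANSFORM_GRID,
    alpha: float = 0.05,
):
    """Find the first branch-length transform with clean diagnostics.

    Scans ``grid`` in order (identity first by default) and returns
    ``(contrast_set, diagnostics, trail)`` for the first transform under
    which both diagnostics are non-significant at ``alpha``. Raises with the
    best candidate reported if nothing in the grid passes.
    """
    trail = []
    best = None
    for kind, const in grid:
        cs = pic(trait, tree, transform=(kind, const))
        diag = standardization_diagnostics(cs)
        worst_p = min(
            (d.p_value for d in diag.values() if d.applicable), default=1.0
        )
        trail.append({"transform": (kind, const), "min_p": worst_p})
        if best is None or worst_p > best[0]:
            best = (worst_p, (kind, const))
        if _passes(diag, alpha):
            return cs, diag, trail
    raise ValidationError(
        "no branch-length transform in the grid standardized the contrasts; "
        f"best candidate {best[1]} with min diagnostic p = {best[0]:.4g}"
    )


def contrast_correlation(
    cs_x: ContrastSet,
    cs_y: ContrastSet,
    through_origin: bool = False,
) -> Dict[str, CorrelationResult]:
    """Pearson and Kendall correlation between two contrast sets.

    Contrast sets must come from the same tree topology (node identity by
    descendant tip set). By default plain correlation is used; set
    ``through_origin`` for the origin-forced Pearson variant.
    """
    if [frozenset(c) for c in cs_x.node_clades] != [frozenset(c) for c in cs_y.node_clades]:
        raise ValidationError("contrast sets come from different trees/node sets")
    x, y = cs_x.contrasts, cs_y.contrasts
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 contrasts to correlate")
    out = {}
    if through_origin:
        denom = math.sqrt(float(x @ x) * float(y @ y))
        r = float(x @ y) / denom if denom > 0 else np.nan
        df = n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * math.sqrt(df / max(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(abs(t), df)
        out["pearson"] = CorrelationResult("pearson", r, float(p), n)
    else:
        r, p = stats.pearsonr(x, y)
        out["pearson"] = CorrelationResult("pearson", float(r), float(p), n)
    tau, pk = stats.kendalltau(x, y)
    out["kendall"] = CorrelationResult("kendall", float(tau), float(pk), n)
    return out


def nonphylo_correlation(
    x: Mapping[str, float],
    y: Mapping[str, float],
    exclude: Optional[Sequence[str]] = None,
) -> CorrelationResult:
    """Ordinary Pearson correlation across species (no phylogeny).

    ``exclude`` drops species by exact name or by genus when a name carries
    no epithet (e.g. ``"Tachyeres"`` drops every ``"Tachyeres ..."``).
    """
    xs = dict(x.items()) if hasattr(x, "items") else dict(x)
    ys = dict(y.items()) if hasattr(y, "items") else dict(y)
    shared = [s for s in xs if s in ys]
    if exclude:
        drop = set()
        for pat in exclude:
            for s in shared:
                genus = s.replace("_", " ").split()[0]
                if s == pat or genus == pat:
                    drop.add(s)
        shared = [s for s in shared if s not in drop]
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared species after exclusions")
    xv = np.array([xs[s] for s in shared])
    yv = np.array([ys[s] for s in shared])
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult("pearson", float(r), float(p), len(shared))
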