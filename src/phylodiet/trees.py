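"""Rooted phylogenies: parsing, pruning, consensus, and trait covariance.

Trees are thin wrappers around :class:`dendropy.Tree` with cached integer
arrays (postorder node list, parent pointers, MRCA index matrix) so that the
comparative-methods layers can evaluate covariance matrices under repeated
branch-length transformations without re-walking the tree.

Branch lengths are in the units of the input tree (for the motivating
analysis, expected molecular substitutions per site); trees are *not*
assumed ultrametric anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from .errors import (
    BranchLengthError,
    NewickParseError,
    ValidationError,
)

__all__ = [
    "Phylogeny",
    "CovarianceStructure",
    "parse_newick",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "strict_consensus",
    "transform_cov",
    "validate_tree_sample",
]


@dataclass(frozen=True)
class CovarianceStructure:
    """Tree-implied trait covariance structure.

    ``matrix[i, j]`` is the shared root-to-tip path length of tips ``i`` and
    ``j`` (the covariance Brownian motion with unit rate induces on tip
    values); the diagonal holds root-to-tip distances.
    """

    matrix: np.ndarray
    tips: tuple

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.tips), len(self.tips)):
            raise ValidationError("covariance matrix shape does not match tip count")

    @property
    def n(self) -> int:
        return len(self.tips)

    def patristic(self) -> np.ndarray:
        """Pairwise tip-to-tip path-length (patristic) distances."""
        d = np.diag(self.matrix)
        return d[:, None] + d[None, :] - 2.0 * self.matrix


class Phylogeny:
    """A rooted tree with unique tip labels and (usually) branch lengths."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()
        self._arrays = None

    # ------------------------------------------------------------------ io
    @classmethod
    def parse_newick(cls, text: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise NewickParseError(str(exc)) from exc
        return cls(dtree)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip()

    # ------------------------------------------------------------ validation
    def _validate(self) -> None:
        t = self._tree
        labels = [lf.taxon.label if lf.taxon else None for lf in t.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise ValidationError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        lengths = [nd.edge.length for nd in t.preorder_node_iter() if nd.parent_node]
        if not lengths or all(l is None for l in lengths):
            self._has_lengths = False
        elif any(l is None for l in lengths):
            raise NewickParseError("tree mixes present and missing branch lengths")
        else:
            if any(l < 0 for l in lengths):
                raise ValidationError("negative branch length")
            self._has_lengths = True

    # ------------------------------------------------------------ properties
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def has_branch_lengths(self) -> bool:
        return self._has_lengths

    @property
    def tip_labels(self) -> tuple:
        return tuple(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def is_binary(self) -> bool:
        for nd in self._tree.preorder_internal_node_iter():
            if len(nd.child_nodes()) != 2:
                return False
        return True

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # ------------------------------------------------------------ structure
    def _require_lengths(self):
        if not self._has_lengths:
            raise BranchLengthError(
                "tree carries no branch lengths (e.g. a strict consensus tree); "
                "this operation needs a branch-lengthed tree"
            )

    def _build_arrays(self):
        """Postorder arrays and an MRCA index matrix, cached."""
        nodes = list(self._tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        elen = np.zeros(n_nodes, dtype=float)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                elen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        tip_order = {lab: k for k, lab in enumerate(self.tip_labels)}
        ntips = len(tip_order)
        tipsets: dict = {}
        mrca = np.zeros((ntips, ntips), dtype=np.int64)
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                k = tip_order[nd.taxon.label]
                tipsets[i] = np.array([k], dtype=np.int64)
                mrca[k, k] = i
            else:
                blocks = [tipsets.pop(index[id(c)]) for c in nd.child_nodes()]
                for a in range(len(blocks)):
                    for b in range(a + 1, len(blocks)):
                        mrca[np.ix_(blocks[a], blocks[b])] = i
                        mrca[np.ix_(blocks[b], blocks[a])] = i
                tipsets[i] = np.concatenate(blocks)
        self._arrays = {
            "nodes": nodes,
            "parent": parent,
            "elen": elen,
            "mrca": mrca,
            "tip_order": tip_order,
        }

    def _get_arrays(self):
        if self._arrays is None:
            self._build_arrays()
        return self._arrays

    def node_depths(self, elen: Optional[np.ndarray] = None) -> np.ndarray:
        """Root-to-node path lengths, indexed like the postorder node list."""
        arr = self._get_arrays()
        parent = arr["parent"]
        if elen is None:
            self._require_lengths()
            elen = arr["elen"]
        depth = np.zeros(len(parent))
        # parents appear after children in postorder; walk in reverse
        for i in range(len(parent) - 1, -1, -1):
            if parent[i] >= 0:
                depth[i] = depth[parent[i]] + elen[i]
        return depth

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance."""
        arr = self._get_arrays()
        depth = self.node_depths()
        leaf_idx = [i for i, nd in enumerate(arr["nodes"]) if nd.is_leaf()]
        return float(depth[leaf_idx].max())

    # ------------------------------------------------------------ operations
    def prune_to(self, tip_subset: Iterable[str]) -> "Phylogeny":
        """Induced subtree on ``tip_subset``; unary nodes collapsed with
        branch lengths summed, so retained root-to-tip distances are kept."""
        keep = list(dict.fromkeys(tip_subset))
        have = set(self.tip_labels)
        missing = [t for t in keep if t not in have]
        if missing:
            raise ValidationError(f"tips not in tree: {missing}")
        if len(keep) < 2:
            raise ValidationError("pruning requires at least 2 tips")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(keep)
        # collapse a unary root left behind by pruning
        while len(clone.seed_node.child_nodes()) == 1:
            child = clone.seed_node.child_nodes()[0]
            clone.seed_node = child
            child.parent_node = None
            child.edge.length = None
        clone.purge_taxon_namespace()
        return Phylogeny(clone)

    def match_clade(self, tip_set: Iterable[str]):
        """Node whose descendant tip set equals ``tip_set`` exactly, else None."""
        want = frozenset(tip_set)
        if not want:
            raise ValidationError("empty clade definition")
        unknown = want - set(self.tip_labels)
        if unknown:
            raise ValidationError(f"clade names not in tree: {sorted(unknown)}")
        for nd in self._tree.postorder_node_iter():
            tips = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if tips == want:
                return nd
        return None

    def covariance(self, kind: Optional[str] = None, param: float = 1.0) -> CovarianceStructure:
        """Tree covariance, optionally under a lambda/kappa/delta transform.

        kappa is applied to branch lengths before path summation (0**kappa is
        defined as 0; kappa=0 maps positive lengths to 1); lambda scales the
        off-diagonal; delta raises shared depths to a power and rescales so
        the maximum tip depth is preserved.
        """
        self._require_lengths()
        arr = self._get_arrays()
        if kind == "kappa":
            if param < 0:
                raise ValidationError("kappa must be >= 0")
            elen = arr["elen"]
            tel = np.zeros_like(elen)
            pos = elen > 0
            tel[pos] = elen[pos] ** param
            depth = self.node_depths(elen=tel)
            C = depth[arr["mrca"]]
            return CovarianceStructure(C, self.tip_labels)
        depth = self.node_depths()
        C = depth[arr["mrca"]]
        cov = CovarianceStructure(C, self.tip_labels)
        if kind is None or kind == "bm":
            return cov
        return transform_cov(cov, kind, param)

    def rescale(self, kind: str, param: float) -> "Phylogeny":
        """Return a new tree whose branch lengths realize the transform.

        lambda: internal node depths multiplied by the parameter, terminal
        depths unchanged (terminal branches absorb the difference).
        kappa: each branch length raised to the power.
        delta: node depths raised to the power and rescaled to preserve the
        maximum tip depth.
        """
        self._require_lengths()
        if kind == "kappa":
            if param < 0:
                raise ValidationError("kappa must be >= 0")
            clone = self._tree.clone(depth=1)
            for nd in clone.preorder_node_iter():
                if nd.parent_node is not None:
                    b = nd.edge.length
                    nd.edge.length = float(b) ** param if b > 0 else 0.0
            return Phylogeny(clone)
        if kind == "lambda":
            if not 0.0 <= param <= 1.0:
                raise ValidationError("lambda must lie in [0, 1]")
            clone = self._tree.clone(depth=1)
            depth_of = {}
            for nd in clone.preorder_node_iter():
                d = 0.0 if nd.parent_node is None else depth_of[id(nd.parent_node)] + nd.edge.length
                depth_of[id(nd)] = d
            for nd in clone.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                pd = depth_of[id(nd.parent_node)]
                if nd.is_leaf():
                    nd.edge.length = depth_of[id(nd)] - param * pd
                else:
                    nd.edge.length = param * (depth_of[id(nd)] - pd)
            return Phylogeny(clone)
        if kind == "delta":
            if param <= 0:
                raise ValidationError("delta must be > 0")
            clone = self._tree.clone(depth=1)
            depth_of = {}
            hmax = 0.0
            for nd in clone.preorder_node_iter():
                d = 0.0 if nd.parent_node is None else depth_of[id(nd.parent_node)] + nd.edge.length
                depth_of[id(nd)] = d
                if nd.is_leaf():
                    hmax = max(hmax, d)
            scale = hmax / hmax ** param if hmax > 0 else 1.0
            for nd in clone.preorder_node_iter():
                if nd.parent_node is not None:
                    d0 = depth_of[id(nd.parent_node)] ** param * scale
                    d1 = depth_of[id(nd)] ** param * scale
                    nd.edge.length = d1 - d0
            return Phylogeny(clone)
        raise ValidationError(f"unknown transform kind: {kind!r}")

    # ------------------------------------------------------------ trait glue
    def align_trait(self, values: Mapping[str, float]) -> np.ndarray:
        """Trait values ordered by ``tip_labels``; missing species error."""
        missing = [t for t in self.tip_labels if t not in values]
        if missing:
            raise ValidationError(f"trait missing for tips: {missing[:5]}...")
        return np.array([float(values[t]) for t in self.tip_labels])


def transform_cov(cov: CovarianceStructure, kind: str, param: float) -> CovarianceStructure:
    """Apply a lambda or delta transform directly to a covariance structure."""
    C = cov.matrix
    if kind == "lambda":
        if not 0.0 <= param <= 1.0:
            raise ValidationError("lambda must lie in [0, 1]")
        out = param * C + (1.0 - param) * np.diag(np.diag(C))
        return CovarianceStructure(out, cov.tips)
    if kind == "delta":
        if param <= 0:
            raise ValidationError("delta must be > 0")
        hmax = float(np.max(np.diag(C)))
        scale = hmax / hmax ** param if hmax > 0 else 1.0
        out = np.zeros_like(C)
        pos = C > 0
        out[pos] = (C[pos] ** param) * scale
        return CovarianceStructure(out, cov.tips)
    raise ValidationError(
        f"transform {kind!r} cannot be applied to a covariance matrix directly"
    )


# --------------------------------------------------------------------- io


def parse_newick(text: str) -> Phylogeny:
    return Phylogeny.parse_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_newick_list(path) -> list:
    """One tree per line (blank lines ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_newick(line))
    return out


def validate_tree_sample(trees: Sequence[Phylogeny]) -> None:
    """All trees of a sample must share one tip set."""
    if len(trees) < 1:
        raise ValidationError("empty tree sample")
    ref = set(trees[0].tip_labels)
    for i, t in enumerate(trees[1:], start=2):
        if set(t.tip_labels) != ref:
            raise ValidationError(f"tree {i} has a different tip set")


def strict_consensus(trees: Sequence[Phylogeny]) -> Phylogeny:
    """Strict consensus (clades present in every tree); no branch lengths."""
    if len(trees) < 2:
        raise ValidationError("strict consensus needs at least 2 trees")
    validate_tree_sample(trees)
    ns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=ns)
    for t in trees:
        tl.append(
            dendropy.Tree.get(
                data=t.to_newick(),
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
                taxon_namespace=ns,
            )
        )
    cons = tl.consensus(min_freq=1.0)
    cons.is_rooted = True
    for nd in cons.preorder_node_iter():
        nd.edge.length = None
        if not nd.is_leaf():
            nd.label = None
    return Phylogeny(cons)
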