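"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's cached-array code paths: covariance
is computed by explicit root-to-tip path intersection on the dendropy tree,
and Gaussian densities by explicit inverse and determinant.
"""

import numpy as np

from phylodiet.trees import Phylogeny


def brute_force_cov(tree: Phylogeny):
    """C_ij = summed lengths of edges ancestral to both tips (path walk)."""
    dt = tree.dendropy_tree
    leaves = list(dt.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    paths = []
    for lf in leaves:
        anc = []
        nd = lf
        while nd.parent_node is not None:
            anc.append(nd)
            nd = nd.parent_node
        paths.append(anc)
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = set(id(a) for a in paths[i]) & set(id(a) for a in paths[j])
            C[i, j] = sum(
                float(a.edge.length) for a in paths[i] if id(a) in shared
            )
    return C, labels


def dense_mvn_loglik(x, mean, V):
    """MVN log-density via explicit inverse and (slog)determinant."""
    x = np.asarray(x, float)
    r = x - mean
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    q = float(r @ np.linalg.inv(V) @ r)
    n = len(x)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + q)


def all_bipartitions(tree: Phylogeny):
    """Non-trivial clade tip sets of a rooted tree (brute enumeration)."""
    out = set()
    all_tips = frozenset(tree.tip_labels)
    for nd in tree.dendropy_tree.postorder_internal_node_iter():
        c = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 1 < len(c) < len(all_tips):
            out.add(c)
    return out
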