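"""Brute-force reference implementations used only by the tests.

These enumerate every joint assignment of model states to all nodes of a
tiny tree, so they are independent of the pruning/two-pass code paths they
check.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm


def _setup(tt, q, tips):
    nodes = list(tt.tree.postorder_node_iter())
    pos = {id(n): i for i, n in enumerate(nodes)}
    pmats = {
        i: expm(q * float(n.edge.length))
        for i, n in enumerate(nodes)
        if n.parent_node is not None
    }
    tipvecs = tips.model_vectors()
    return nodes, pos, pmats, tipvecs


def enum_likelihood(tt, q, tips, root_prior="flat"):
    """Total likelihood by summation over all joint node-state assignments."""
    nodes, pos, pmats, tipvecs = _setup(tt, q, tips)
    n = q.shape[0]
    if root_prior == "flat":
        pi = np.full(n, 1.0 / n)
    else:
        pi = np.asarray(root_prior, dtype=float)
    total = 0.0
    for assign in itertools.product(range(n), repeat=len(nodes)):
        p = pi[assign[-1]]  # postorder: root last
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p *= pmats[i][assign[pos[id(node.parent_node)]], assign[i]]
            if node.is_leaf():
                p *= tipvecs[node.taxon.label][assign[i]]
        total += p
    return total


def enum_loglik(tt, q, tips, root_prior="flat"):
    return math.log(enum_likelihood(tt, q, tips, root_prior))


def enum_marginals(tt, q, tips, root_prior="flat"):
    """Per-node marginals over *observed* states by joint enumeration,
    renormalized per node. Keys are node labels (tips included)."""
    nodes, pos, pmats, tipvecs = _setup(tt, q, tips)
    n = q.shape[0]
    pi = np.full(n, 1.0 / n) if root_prior == "flat" else np.asarray(root_prior)
    accum = {i: np.zeros(n) for i in range(len(nodes))}
    for assign in itertools.product(range(n), repeat=len(nodes)):
        p = pi[assign[-1]]
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p *= pmats[i][assign[pos[id(node.parent_node)]], assign[i]]
            if node.is_leaf():
                p *= tipvecs[node.taxon.label][assign[i]]
        for i in range(len(nodes)):
            accum[i][assign[i]] += p
    out = {}
    for i, node in enumerate(nodes):
        vec = accum[i] / accum[i].sum()
        label = node.taxon.label if node.is_leaf() else node.label
        out[label] = tips.space.collapse(vec)
    return out
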