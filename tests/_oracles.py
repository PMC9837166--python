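"""Independent brute-force oracles used to validate the pruning machinery.

These enumerate internal-state assignments explicitly (exponential in the
number of internal nodes) and are only usable on trees with a handful of
tips; they share nothing with the dynamic-programming implementation they
check except the transition matrices themselves.
"""

from __future__ import annotations

import itertools

import numpy as np


def _collect(tree):
    """Postorder nodes, parents, and edge lengths from a PhyloTree."""
    nodes = tree.postorder()
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = [idx[id(n.parent_node)] if n.parent_node else -1 for n in nodes]
    length = [n.edge.length if n.parent_node else None for n in nodes]
    return nodes, parent, length


def enumerate_site_likelihood(tree, site, model, P_of=None):
    """Sum over all internal-state assignments of pi(root) * prod P(t).

    ``site`` maps tip label -> state index, or None/missing for an
    uninformative tip (summed over states).  ``P_of(t)`` may override the
    transition-matrix source (e.g. branch-specific matrices keyed by node).
    """
    n = model.n_states
    nodes, parent, length = _collect(tree)
    free = []  # indices whose state is summed over
    fixed = {}
    for i, node in enumerate(nodes):
        if node.is_leaf():
            s = site.get(node.taxon.label)
            if s is None or s >= n:
                free.append(i)
            else:
                fixed[i] = int(s)
        else:
            free.append(i)
    total = 0.0
    root = len(nodes) - 1
    for combo in itertools.product(range(n), repeat=len(free)):
        states = dict(fixed)
        states.update(dict(zip(free, combo)))
        prob = model.pi.pi[states[root]]
        for i in range(len(nodes)):
            if parent[i] < 0:
                continue
            P = (
                P_of(nodes[i]) if P_of is not None else model.transition_matrix(length[i])
            )
            prob *= P[states[parent[i]], states[i]]
        total += prob
    return float(np.log(total))


def enumerate_clamped_posterior(tree, site, model, node_label):
    """Marginal posterior at one internal node by clamped enumeration."""
    n = model.n_states
    nodes, parent, length = _collect(tree)
    root = len(nodes) - 1
    target = next(
        i
        for i, nd in enumerate(nodes)
        if (not nd.is_leaf()) and tree.node_label(nd) == node_label
    )
    fixed = {}
    free = []
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            s = site.get(nd.taxon.label)
            if s is None or s >= n:
                free.append(i)
            else:
                fixed[i] = int(s)
        elif i != target:
            free.append(i)
    weights = np.zeros(n)
    for x in range(n):
        total = 0.0
        for combo in itertools.product(range(n), repeat=len(free)):
            states = dict(fixed)
            states[target] = x
            states.update(dict(zip(free, combo)))
            prob = model.pi.pi[states[root]]
            for i in range(len(nodes)):
                if parent[i] < 0:
                    continue
                P = model.transition_matrix(length[i])
                prob *= P[states[parent[i]], states[i]]
            total += prob
        weights[x] = total
    return weights / weights.sum()
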