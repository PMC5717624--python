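"""Independent reference implementations used only by the tests.

These deliberately avoid the package's vectorized code paths: tip paths are
re-extracted by walking parent pointers, covariances are accumulated pair by
pair and segment by segment, and the Mk likelihood is an exhaustive sum over
all node-state assignments.
"""

import itertools

import numpy as np
from scipy.linalg import expm


def tip_paths(simmap, tip_order):
    """Per tip, the absolute-time (state, t0, t1) intervals from root to tip,
    tagged with the branch (node id) they lie on."""
    tree = simmap.tree
    depth = tree.depths()
    label_to_node = {tree.labels[i]: i for i in tree.tip_indices}
    paths = []
    for lab in tip_order:
        chain = []
        v = label_to_node[lab]
        while tree.parent[v] >= 0:
            chain.append(v)
            v = tree.parent[v]
        chain.reverse()
        path = []
        for node in chain:
            t = depth[tree.parent[node]]
            for state, dur in simmap.segments[node]:
                path.append((node, state, t, t + dur))
                t += dur
        paths.append(path)
    return paths


def _shared(path_i, path_j):
    """Intervals lying on branches common to both root-to-tip paths."""
    branches_j = {seg[0] for seg in path_j}
    return [seg for seg in path_i if seg[0] in branches_j]


def bm_moments_bruteforce(simmap, tip_order, sigma2_by_regime, root_state):
    paths = tip_paths(simmap, tip_order)
    n = len(tip_order)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for _, state, t0, t1 in _shared(paths[i], paths[j]):
                C[i, j] += sigma2_by_regime[state] * (t1 - t0)
    return np.full(n, root_state), C


def ou_moments_bruteforce(simmap, tip_order, alpha, sigma2, theta_by_regime):
    """Non-stationary-root OU moments accumulated per shared path segment."""
    paths = tip_paths(simmap, tip_order)
    n = len(tip_order)
    T = np.array([p[-1][3] for p in paths])
    root_regime = simmap.node_states[simmap.tree.root]
    mean = np.zeros(n)
    for i, path in enumerate(paths):
        mean[i] = np.exp(-alpha * T[i]) * theta_by_regime[root_regime]
        for _, state, t0, t1 in path:
            mean[i] += theta_by_regime[state] * (
                np.exp(-alpha * (T[i] - t1)) - np.exp(-alpha * (T[i] - t0)))
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for _, _, t0, t1 in _shared(paths[i], paths[j]):
                V[i, j] += sigma2 * np.exp(-alpha * (T[i] + T[j])) * (
                    np.exp(2 * alpha * t1) - np.exp(2 * alpha * t0)) / (2 * alpha)
    return mean, V


def ou_moments_euler(simmap, tip_order, alpha, sigma2, theta_by_regime,
                     root_state, dt=1e-4):
    """Forward-integrate the OU mean and covariance ODEs along the tree.

    dm/dt = alpha (theta - m);  dV_ij/dt = -2 alpha V_ij + sigma2 [i on same
    branch as j], handled by integrating node by node in preorder.
    """
    tree = simmap.tree
    means = {tree.root: root_state}
    # variance of each node and covariance of each node pair, grown branchwise
    var = {tree.root: 0.0}
    cov = {}
    for v in tree.preorder:
        if v == tree.root:
            continue
        p = tree.parent[v]
        m, s = means[p], var[p]
        for state, dur in simmap.segments[v]:
            steps = max(1, int(np.ceil(dur / dt)))
            h = dur / steps
            th = theta_by_regime[state]
            for _ in range(steps):
                m = m + alpha * (th - m) * h
                s = s + (-2 * alpha * s + sigma2) * h
        means[v] = m
        var[v] = s
    # pairwise tip covariance: value at the MRCA decayed along both stems
    depth = tree.depths()
    label_to_node = {tree.labels[i]: i for i in tree.tip_indices}

    def ancestors(v):
        out = []
        while v >= 0:
            out.append(v)
            v = tree.parent[v]
        return out

    n = len(tip_order)
    V = np.zeros((n, n))
    for i, a in enumerate(tip_order):
        for j, b in enumerate(tip_order):
            va, vb = label_to_node[a], label_to_node[b]
            if i == j:
                V[i, j] = var[va]
                continue
            anc = [x for x in ancestors(va) if x in set(ancestors(vb))]
            mrca = anc[0]
            decay = (depth[va] - depth[mrca]) + (depth[vb] - depth[mrca])
            V[i, j] = var[mrca] * np.exp(-alpha * decay)
    mean = np.array([means[label_to_node[a]] for a in tip_order])
    return mean, V


def mk_loglik_enumeration(tree, tip_priors, Q, root_weights):
    """Exhaustive sum over all node state assignments (tips included)."""
    k = Q.shape[0]
    nodes = list(range(tree.n_nodes))
    P = {v: expm(Q * tree.lengths[v]) for v in nodes if v != tree.root}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(nodes)):
        prob = root_weights[assign[tree.root]]
        for v in nodes:
            if v == tree.root:
                continue
            prob *= P[v][assign[tree.parent[v]], assign[v]]
        for i in tree.tip_indices:
            prob *= tip_priors[tree.labels[i]][assign[i]]
        total += prob
    return np.log(total)
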