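"""Mk models and stochastic character mapping.

Discrete characters (pollination mode, island) evolve under a continuous-time
Markov chain with rate matrix Q constrained to ER (one rate), SYM (symmetric)
or ARD (all rates different).  Tip data enter as probability vectors
("tip priors"), which lets field-observed, morphology-inferred and unknown
pollination modes carry different weights.  Full character histories are
sampled conditional on the tips (Bollback-style): conditional likelihoods are
computed by Felsenstein pruning, node states sampled from root to tips, and
each branch's internal history drawn by rejection sampling of forward CTMC
paths with a uniformization fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space
from scipy.optimize import minimize

from .trees import Phylogeny, SimmapTree

__all__ = [
    "POLLINATION_STATES", "ISLAND_STATES", "MkModel",
    "build_tip_priors", "assign_single_island", "build_Q",
    "mk_loglik", "fit_mk", "sample_stochastic_map", "marginal_posteriors",
]

POLLINATION_STATES = ("hummingbird", "bat", "mixed")
ISLAND_STATES = ("Cuba", "Hispaniola", "PuertoRico", "Jamaica")

_SPECIALIST = {"hummingbird", "bat"}
_REJECTION_CAP = 1000


@dataclass
class MkModel:
    states: tuple
    constraint: str              # ER | SYM | ARD
    Q: np.ndarray
    root_treatment: str = "fitzjohn"
    log_likelihood: float = np.nan

    def __post_init__(self):
        q = np.asarray(self.Q, float)
        if not np.allclose(q.sum(axis=1), 0, atol=1e-8):
            raise ValueError("Q rows must sum to 0")
        off = q[~np.eye(len(q), dtype=bool)]
        if (off < -1e-12).any():
            raise ValueError("Q off-diagonals must be >= 0")
        if self.constraint == "SYM" and not np.allclose(q, q.T, atol=1e-8):
            raise ValueError("SYM constraint requires a symmetric Q")


# ----------------------------------------------------------------- tip data
def build_tip_priors(metadata: pd.DataFrame,
                     states: tuple = POLLINATION_STATES) -> dict:
    """Per-species prior probability vectors over pollination modes.

    Field-observed modes get probability 1.  Morphology-inferred specialist
    modes (hummingbird, bat) get 2/3 with 1/6 on each other mode; an inferred
    generalist (mixed) gets 1/2 with 1/4 on each other mode; species with no
    usable shape data get a flat 1/3.
    """
    priors = {}
    idx = {s: i for i, s in enumerate(states)}
    for _, row in metadata.iterrows():
        mode, status = row["pollination_mode"], row["mode_status"]
        v = np.zeros(len(states))
        if status == "unknown" or mode == "unknown":
            v[:] = 1.0 / len(states)
        elif status == "observed":
            if mode not in idx:
                raise ValueError(f"unrecognized pollination mode {mode!r}")
            v[idx[mode]] = 1.0
        elif status == "inferred":
            if mode not in idx:
                raise ValueError(f"unrecognized pollination mode {mode!r}")
            if mode in _SPECIALIST:
                v[:] = 1.0 / 6.0
                v[idx[mode]] = 2.0 / 3.0
            else:                       # inferred generalist
                v[:] = 1.0 / 4.0
                v[idx[mode]] = 1.0 / 2.0
        else:
            raise ValueError(f"unrecognized mode status {status!r}")
        priors[row["species"]] = v
    return priors


def assign_single_island(metadata: pd.DataFrame, rng,
                         states: tuple = ISLAND_STATES) -> dict:
    """One island per species; multi-island species get one of theirs uniformly."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = {}
    for _, row in metadata.iterrows():
        isl = row["islands"]
        if isinstance(isl, str):
            isl = [s for s in isl.split(";") if s]
        isl = sorted(set(isl) & set(states))
        if not isl:
            raise ValueError(f"species {row['species']!r} has an empty island set")
        out[row["species"]] = isl[0] if len(isl) == 1 else isl[int(rng.integers(len(isl)))]
    return out


def delta_priors(assignment: dict, states: tuple) -> dict:
    idx = {s: i for i, s in enumerate(states)}
    out = {}
    for sp, st in assignment.items():
        v = np.zeros(len(states))
        v[idx[st]] = 1.0
        out[sp] = v
    return out


# ------------------------------------------------------------------ Q matrix
def n_free_rates(constraint: str, k: int) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[constraint]


def build_Q(rates, constraint: str, k: int) -> np.ndarray:
    """Assemble a rate matrix from its free off-diagonal rates.

    SYM fills the upper triangle row-wise and mirrors it; ARD fills all
    off-diagonals row-wise; ER uses a single rate everywhere.
    """
    rates = np.asarray(rates, float)
    if len(rates) != n_free_rates(constraint, k):
        raise ValueError("wrong number of free rates for constraint")
    Q = np.zeros((k, k))
    if constraint == "ER":
        Q[:] = rates[0]
    elif constraint == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    else:
        pos = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[pos]
                    pos += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q*t) for every branch length, via eigendecomposition when stable."""
    k = Q.shape[0]
    try:
        lam, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) < 1e8:
            E = np.exp(np.multiply.outer(lengths, lam))         # (B, k)
            P = np.einsum("ij,bj,jl->bil", U, E, Uinv).real
            return np.clip(P, 0.0, None)
    except np.linalg.LinAlgError:
        pass
    P = np.stack([expm(Q * t) for t in lengths])
    return np.clip(P.real, 0.0, None)


def _root_weights(root_partial: np.ndarray, Q: np.ndarray, treatment: str):
    k = len(root_partial)
    if treatment == "uniform":
        return np.full(k, 1.0 / k)
    if treatment == "stationary":
        ns = null_space(Q.T)
        if ns.shape[1] >= 1:
            pi = np.abs(ns[:, 0])
            return pi / pi.sum()
        return np.full(k, 1.0 / k)
    if treatment == "fitzjohn":
        tot = root_partial.sum()
        if tot <= 0:
            return np.full(k, 1.0 / k)
        return root_partial / tot
    raise ValueError(f"unknown root treatment {treatment!r}")


def _pruning_partials(tree: Phylogeny, tip_priors: dict, Q: np.ndarray):
    """Downpass conditional likelihoods with log-scale rescaling.

    Returns (partials, log_scale, P) where ``partials[v]`` is the scaled
    probability of the data below node v given each state at v, and ``P[v]``
    the transition matrix on the branch above v.
    """
    k = Q.shape[0]
    P = _transition_matrices(Q, tree.lengths)
    partials = np.zeros((tree.n_nodes, k))
    log_scale = 0.0
    for v in tree.postorder:
        if not tree.children[v]:
            vec = np.asarray(tip_priors[tree.labels[v]], float)
            if len(vec) != k:
                raise ValueError("tip prior length does not match state count")
            partials[v] = vec
        else:
            vec = np.ones(k)
            for c in tree.children[v]:
                vec = vec * (P[c] @ partials[c])
            m = vec.max()
            if m <= 0:
                return partials, -np.inf, P
            partials[v] = vec / m
            log_scale += np.log(m)
    return partials, log_scale, P


def mk_loglik(tree: Phylogeny, tip_priors: dict, Q: np.ndarray,
              root_treatment: str = "fitzjohn") -> float:
    """Felsenstein pruning log-likelihood of tip priors under Q."""
    partials, log_scale, _ = _pruning_partials(tree, tip_priors, np.asarray(Q, float))
    if not np.isfinite(log_scale):
        return -np.inf
    root = partials[tree.root]
    w = _root_weights(root, np.asarray(Q, float), root_treatment)
    val = float(w @ root)
    return -np.inf if val <= 0 else np.log(val) + log_scale


def fit_mk(tree: Phylogeny, tip_priors: dict, constraint: str,
           states: tuple, root_treatment: str = "fitzjohn",
           restarts: int = 3, seed: int = 0,
           rate_bounds=(1e-6, 1e3)) -> MkModel:
    """ML rate estimation under an ER/SYM/ARD constraint.

    Optimizes log-rates with L-BFGS-B from several starting points spread
    around the heuristic rate ``n_states / total tree length``.
    """
    k = len(states)
    p = n_free_rates(constraint, k)
    present = set()
    for v in tip_priors.values():
        present.update(np.flatnonzero(np.asarray(v) > 0).tolist())
    if len(present) < 2:
        raise ValueError("need at least 2 states with nonzero tip prior mass")
    base = k / max(tree.total_length(), 1e-9)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(rate_bounds[0]), np.log(rate_bounds[1])

    def neg(x):
        Q = build_Q(np.exp(x), constraint, k)
        ll = mk_loglik(tree, tip_priors, Q, root_treatment)
        return 1e10 if not np.isfinite(ll) else -ll

    starts = [np.full(p, np.log(base))]
    for _ in range(max(restarts - 1, 0)):
        starts.append(np.log(base) + rng.uniform(-2.0, 2.0, size=p))
    best, trace = None, []
    for x0 in starts:
        res = minimize(neg, np.clip(x0, lo, hi), method="L-BFGS-B",
                       bounds=[(lo, hi)] * p, options={"maxiter": 200})
        trace.append((res.fun, res.message))
        if np.isfinite(res.fun) and res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"Mk fit failed to converge; restart trace: {trace}")
    Q = build_Q(np.exp(best.x), constraint, k)
    return MkModel(states=tuple(states), constraint=constraint, Q=Q,
                   root_treatment=root_treatment, log_likelihood=-best.fun)


# --------------------------------------------------------------- posteriors
def marginal_posteriors(tree: Phylogeny, tip_priors: dict, Q: np.ndarray,
                        root_treatment: str = "fitzjohn") -> np.ndarray:
    """Marginal posterior state probabilities at every node (up-down pass)."""
    Q = np.asarray(Q, float)
    partials, _, P = _pruning_partials(tree, tip_priors, Q)
    k = Q.shape[0]
    up = np.zeros((tree.n_nodes, k))
    pi = _root_weights(partials[tree.root], Q, root_treatment)
    up[tree.root] = pi
    for v in tree.preorder:
        for c in tree.children[v]:
            other = np.ones(k)
            for s in tree.children[v]:
                if s != c:
                    other = other * (P[s] @ partials[s])
            up[c] = (up[v] * other) @ P[c]
    post = up * partials
    norm = post.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return post / norm


# ----------------------------------------------------------------- sampling
def _sample_forward_path(Q, a, t, rng):
    """Unconditional forward CTMC path from state a over duration t."""
    k = Q.shape[0]
    path = []
    state, remaining = a, t
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            path.append((state, remaining))
            return path
        wait = rng.exponential(1.0 / rate)
        if wait >= remaining:
            path.append((state, remaining))
            return path
        path.append((state, wait))
        remaining -= wait
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = rng.choice(k, p=probs)


def _sample_path_uniformization(Q, a, b, t, rng, max_jumps=500):
    """Exact endpoint-conditioned path via uniformization."""
    k = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        if a != b:
            raise ValueError("zero-rate chain cannot connect distinct endpoints")
        return [(a, t)]
    R = np.eye(k) + Q / mu
    p_ab = expm(Q * t)[a, b]
    if p_ab <= 0:
        raise ValueError("endpoint pair has zero transition probability")
    # sample the number of uniformized jumps
    powers = [np.eye(k)]
    log_pois = -mu * t
    weights = []
    total = 0.0
    u = rng.random()
    n = None
    for m in range(max_jumps + 1):
        if m > 0:
            powers.append(powers[-1] @ R)
            log_pois += np.log(mu * t) - np.log(m)
        w = np.exp(log_pois) * powers[m][a, b] / p_ab
        weights.append(w)
        total += w
        if u <= total:
            n = m
            break
    if n is None:
        n = int(np.argmax(weights))
    # bridge the embedded chain
    states = [a]
    for j in range(1, n + 1):
        prev = states[-1]
        w = R[prev, :] * powers[n - j][:, b]
        s = w.sum()
        probs = np.full(k, 1.0 / k) if s <= 0 else w / s
        states.append(int(rng.choice(k, p=probs)))
    states[-1] = b if n > 0 else states[-1]
    times = np.sort(rng.random(n)) * t if n else np.array([])
    # collapse virtual (self) jumps into segments
    bounds = np.concatenate([[0.0], times, [t]])
    path = []
    for s, lo, hi in zip(states, bounds[:-1], bounds[1:]):
        if hi - lo <= 0:
            continue
        if path and path[-1][0] == s:
            path[-1] = (s, path[-1][1] + (hi - lo))
        else:
            path.append((s, hi - lo))
    if not path:
        path = [(b, t)]
    return path


def _sample_branch_path(Q, a, b, t, rng):
    """Path on one branch conditional on its endpoint states."""
    if np.allclose(Q, 0):
        if a != b:
            raise ValueError("endpoint pair has zero transition probability")
        return [(a, t)]
    for _ in range(_REJECTION_CAP):
        path = _sample_forward_path(Q, a, t, rng)
        if path[-1][0] == b:
            return path
    return _sample_path_uniformization(Q, a, b, t, rng)


def sample_stochastic_map(tree: Phylogeny, model: MkModel, tip_priors: dict,
                          rng) -> SimmapTree:
    """Draw one full character history conditional on the tip priors."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Q = np.asarray(model.Q, float)
    k = Q.shape[0]
    partials, log_scale, P = _pruning_partials(tree, tip_priors, Q)
    if not np.isfinite(log_scale):
        raise ValueError("data have zero likelihood under the supplied model")
    node_states = np.zeros(tree.n_nodes, dtype=int)
    w = _root_weights(partials[tree.root], Q, model.root_treatment) * partials[tree.root]
    w = w / w.sum()
    node_states[tree.root] = rng.choice(k, p=w)
    for v in tree.preorder:
        for c in tree.children[v]:
            w = P[c][node_states[v], :] * partials[c]
            s = w.sum()
            if s <= 0:
                raise ValueError("endpoint pair has zero transition probability")
            node_states[c] = rng.choice(k, p=w / s)
    segments = [[] for _ in range(tree.n_nodes)]
    for v in tree.preorder:
        if v == tree.root:
            continue
        path = _sample_branch_path(Q, node_states[tree.parent[v]],
                                   node_states[v], float(tree.lengths[v]), rng)
        segments[v] = [(model.states[s], d) for s, d in path]
    states = [model.states[s] for s in node_states]
    return SimmapTree(tree, segments, states)
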