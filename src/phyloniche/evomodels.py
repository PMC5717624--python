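"""Multi-regime Brownian-motion / Ornstein-Uhlenbeck models on painted trees.

The six-model set compared throughout is BM1 (one diffusion rate), BM3 / BM4
(one rate per pollination mode / per island), OU1 (one optimum), and OU3 / OU4
(one optimum per pollination mode / per island).  Multi-regime BM varies only
sigma^2 across regimes (shared root state); multi-regime OU varies only the
optimum theta (shared alpha and sigma^2).  The OU root is non-stationary with
the root state fixed at the optimum of the root regime (a stationary-root
variant is selectable).

Tip means and covariances are built in closed form from the painted tree
(Hansen construction), and the same moments feed both the likelihoods used in
fitting and the trait simulator, so simulator and likelihood can never drift
apart.  Models are ranked with small-sample AICc,
AICc = AIC + 2k(k+1)/(n-k-1) with n = species x traits, and Akaike weights
w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize, minimize_scalar

from . import charmap
from .trees import SimmapTree

__all__ = [
    "ModelSpec", "EvoModelFit", "ReplicateConfig", "ReplicateSummary",
    "PaintedStructure", "model_moments", "loglik", "fit_model",
    "fit_model_set", "aicc", "akaike_weights", "run_replicates",
    "DEFAULT_TRAIT_SETS", "TRAIT_SET_LABELS", "SIX_MODELS", "model_name",
]

_LOG2PI = np.log(2.0 * np.pi)
_SINGLE = ("all",)


@dataclass(frozen=True)
class ModelSpec:
    """One of the candidate evolutionary models.

    ``regime_source`` is ``none`` (a single regime), ``pollination`` or
    ``island``; ``regimes`` orders the regime labels (parameter order);
    ``traits`` lists 1 or 2 trait labels.
    """

    family: str
    regime_source: str
    traits: tuple
    regimes: tuple = _SINGLE

    def __post_init__(self):
        if self.family not in ("BM", "OU"):
            raise ValueError("family must be BM or OU")
        if len(self.traits) not in (1, 2):
            raise ValueError("1 or 2 traits required")
        if self.regime_source == "none" and len(self.regimes) != 1:
            object.__setattr__(self, "regimes", _SINGLE)

    @property
    def n_regimes(self) -> int:
        return len(self.regimes)

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def model_name(spec: ModelSpec) -> str:
    return f"{spec.family}{1 if spec.regime_source == 'none' else spec.n_regimes}"


def count_parameters(spec: ModelSpec) -> int:
    """Free-parameter count k entering AICc.

    Univariate: BM has one sigma^2 per regime plus the root state; OU has a
    shared alpha and sigma^2 plus one theta per regime.  Bivariate: BM has a
    symmetric 2x2 rate matrix per regime (3 parameters) plus a 2-vector root;
    OU has a diagonal alpha (2), a shared 2x2 rate matrix (3) and a theta
    2-vector per regime.
    """
    m = spec.n_regimes
    if spec.n_traits == 1:
        return m + 1 if spec.family == "BM" else m + 2
    return 3 * m + 2 if spec.family == "BM" else 5 + 2 * m


class PaintedStructure:
    """Cached geometry of a painted tree used by the moment builders.

    Holds tip depths T, the shared-time matrix S (root-to-MRCA distances),
    per-regime shared-path-length matrices C_r, and the flattened root-to-tip
    segment arrays used for OU means.
    """

    def __init__(self, simmap: SimmapTree, regimes=None, tip_order=None):
        tree = simmap.tree
        self.tree = tree
        self.tip_order = list(tip_order) if tip_order else sorted(tree.tip_labels)
        self.n = len(self.tip_order)
        used = set(simmap.states)
        if regimes is None:
            regimes = tuple(sorted(used))
        if not used.issubset(set(regimes)):
            raise ValueError(
                f"painted regimes {sorted(used)} not covered by {regimes}")
        self.regimes = tuple(regimes)
        idx = {r: i for i, r in enumerate(self.regimes)}
        m = len(self.regimes)

        depth = tree.depths()
        tip_of = {tree.labels[i]: i for i in tree.tip_indices}
        self.T = np.array([depth[tip_of[lab]] for lab in self.tip_order])
        self.S = tree.mrca_depths(self.tip_order)
        below = tree.tips_below(self.tip_order)
        self.C = np.zeros((m, self.n, self.n))
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            b = below[v]
            block = np.ix_(b, b)
            for state, dur in simmap.segments[v]:
                self.C[idx[state]][block] += dur
        # flattened root-to-tip segments for the OU mean
        seg_tip, seg_regime, seg_dur, seg_rem = [], [], [], []
        for t_i, path in enumerate(simmap.tip_path_segments(self.tip_order)):
            for state, start, end in path:
                seg_tip.append(t_i)
                seg_regime.append(idx[state])
                seg_dur.append(end - start)
                seg_rem.append(self.T[t_i] - end)
        self.seg_tip = np.array(seg_tip, dtype=int)
        self.seg_regime = np.array(seg_regime, dtype=int)
        self.seg_dur = np.array(seg_dur)
        self.seg_rem = np.array(seg_rem)
        self.root_regime = idx[simmap.node_states[tree.root]]
        self.C_total = self.C.sum(axis=0)
        self._D1 = self.T[:, None] - self.S      # time from MRCA to tip i
        self._D2 = self.T[None, :] - self.S

    # ------------------------------------------------------------- moments
    def bm_cov(self, sigma2) -> np.ndarray:
        sigma2 = np.atleast_1d(np.asarray(sigma2, float))
        if (sigma2 <= 0).any():
            raise ValueError("sigma2 must be positive")
        return np.tensordot(sigma2, self.C, axes=1)

    def ou_unit_cov(self, alpha: float) -> np.ndarray:
        """OU tip covariance at sigma^2 = 1 (non-stationary root)."""
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        if alpha == 0:
            return self.C_total.copy()
        E = np.exp(-alpha * (self._D1 + self._D2))
        G = -np.expm1(-2.0 * alpha * self.S) / (2.0 * alpha)
        return E * G

    def ou_cross_cov(self, alpha_a: float, alpha_b: float) -> np.ndarray:
        """Unit-rate covariance between trait a at tip i and trait b at tip j."""
        s = alpha_a + alpha_b
        if s == 0:
            return self.C_total.copy()
        E = np.exp(-alpha_a * self._D1 - alpha_b * self._D2)
        G = -np.expm1(-s * self.S) / s
        return E * G

    def ou_design(self, alpha: float) -> np.ndarray:
        """Design matrix mapping per-regime optima to expected tip values.

        The root state is fixed at the root regime's optimum, so its decay
        term e^{-alpha T} loads on the root regime column; each painted
        segment contributes (1 - e^{-alpha dur}) e^{-alpha remaining}.
        """
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        W = np.zeros((self.n, len(self.regimes)))
        contrib = -np.expm1(-alpha * self.seg_dur) * np.exp(-alpha * self.seg_rem)
        np.add.at(W, (self.seg_tip, self.seg_regime), contrib)
        W[:, self.root_regime] += np.exp(-alpha * self.T)
        return W


def _structure_for(simmap: SimmapTree, spec: ModelSpec, tip_order=None):
    if spec.regime_source == "none":
        simmap = SimmapTree.single_regime(simmap.tree, _SINGLE[0])
        return PaintedStructure(simmap, _SINGLE, tip_order)
    return PaintedStructure(simmap, spec.regimes, tip_order)


def model_moments(simmap: SimmapTree, spec: ModelSpec, params: dict,
                  tip_order=None):
    """Exact tip mean vector and covariance implied by a painted model.

    Returns ``(mean, cov, tip_order)`` with the tip-trait vector flattened
    trait-major (all tips for trait 1, then all tips for trait 2).
    """
    st = params.get("_structure") or _structure_for(simmap, spec, tip_order)
    m, p = st.C.shape[0], spec.n_traits
    if spec.family == "BM":
        root = np.atleast_1d(np.asarray(params["root_state"], float))
        sigma2 = np.asarray(params["sigma2"], float)
        if p == 1:
            cov = st.bm_cov(np.broadcast_to(np.atleast_1d(sigma2), (m,)))
            mean = np.full(st.n, root[0])
        else:
            R = sigma2.reshape(-1, 2, 2)
            if R.shape[0] == 1 and m > 1:
                R = np.broadcast_to(R, (m, 2, 2))
            blocks = [[sum(R[r, a, b] * st.C[r] for r in range(m))
                       for b in range(2)] for a in range(2)]
            cov = np.block(blocks)
            mean = np.concatenate([np.full(st.n, root[a]) for a in range(2)])
    else:
        alpha = np.atleast_1d(np.asarray(params["alpha"], float))
        if (alpha < 0).any():
            raise ValueError("alpha must be >= 0")
        theta = np.asarray(params["theta"], float).reshape(m, p)
        if p == 1:
            sigma2 = float(np.asarray(params["sigma2"], float).reshape(()))
            cov = sigma2 * st.ou_unit_cov(float(alpha[0]))
            mean = st.ou_design(float(alpha[0])) @ theta[:, 0]
        else:
            if alpha.size == 1:
                alpha = np.repeat(alpha, 2)
            R = np.asarray(params["sigma2"], float).reshape(2, 2)
            blocks = [[R[a, b] * st.ou_cross_cov(alpha[a], alpha[b])
                       for b in range(2)] for a in range(2)]
            cov = np.block(blocks)
            mean = np.concatenate([st.ou_design(alpha[a]) @ theta[:, a]
                                   for a in range(2)])
    try:
        cholesky(cov + 0.0, lower=True)
    except np.linalg.LinAlgError:
        cond = np.linalg.cond(cov)
        raise ValueError(f"model covariance is not positive definite "
                         f"(condition number {cond:.3g})")
    return mean, cov, st.tip_order


def _align_traits(traits, trait_names, tip_order) -> np.ndarray:
    """Tip x trait matrix aligned to tip order; trait-major flattening is
    ``Y.T.ravel()``."""
    if isinstance(traits, pd.DataFrame):
        Y = traits.loc[list(tip_order), list(trait_names)].to_numpy(float)
    else:
        Y = np.asarray(traits, float).reshape(len(tip_order), len(trait_names))
    if not np.isfinite(Y).all():
        raise ValueError("traits must be finite")
    return Y


def loglik(simmap: SimmapTree, spec: ModelSpec, params: dict, traits) -> float:
    """Gaussian log-density of the tip traits under the painted model."""
    st = params.get("_structure") or _structure_for(simmap, spec)
    mean, cov, tip_order = model_moments(simmap, spec,
                                         {**params, "_structure": st})
    y = _align_traits(traits, spec.traits, tip_order).T.ravel()
    try:
        c, low = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular model covariance: {e}")
    r = y - mean
    q = float(r @ cho_solve((c, low), r))
    logdet = 2.0 * np.log(np.diag(c)).sum()
    return -0.5 * (len(y) * _LOG2PI + logdet + q)


# ====================================================================== fits
def _whiten(cov, X, y):
    L = cholesky(cov, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return Xw, yw, logdet


def _profile_gauss(cov, X, y, profile_scale: bool):
    """GLS coefficients under ``cov``; optionally profile a scalar variance.

    With ``profile_scale`` the covariance is treated as sigma^2 * cov with
    sigma^2 at its ML value.  Returns (loglik, beta, sigma2_hat).
    """
    Xw, yw, logdet = _whiten(cov, X, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    q = float(r @ r)
    n = len(y)
    if profile_scale:
        s2 = max(q / n, 1e-300)
        ll = -0.5 * (n * _LOG2PI + n * np.log(s2) + logdet + n)
        return ll, beta, s2
    ll = -0.5 * (n * _LOG2PI + logdet + q)
    return ll, beta, None


def _default_alpha_bounds(struct) -> tuple:
    depth = float(struct.T.mean())
    return 1e-4 / depth, 50.0 / depth


def _fit_bm_uni(struct, y, restarts, rng):
    n, m = struct.n, struct.C.shape[0]
    ones = np.ones((n, 1))
    if m == 1:
        ll, beta, s2 = _profile_gauss(struct.C_total, ones, y, True)
        return {"sigma2": np.array([s2]), "root_state": float(beta[0])}, ll

    def obj(x):
        try:
            cov = struct.bm_cov(np.exp(x))
            ll, _, _ = _profile_gauss(cov, ones, y, False)
            return -ll
        except np.linalg.LinAlgError:
            return 1e10

    _, _, s2_flat = _profile_gauss(struct.C_total, ones, y, True)
    x0 = np.full(m, np.log(max(s2_flat, 1e-12)))
    best = None
    for j in range(max(restarts, 1)):
        start = x0 if j == 0 else x0 + rng.uniform(-1.5, 1.5, size=m)
        res = minimize(obj, start, method="L-BFGS-B",
                       bounds=[(-30.0, 30.0)] * m, options={"maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    sigma2 = np.exp(best.x)
    _, beta, _ = _profile_gauss(struct.bm_cov(sigma2), ones, y, False)
    return {"sigma2": sigma2, "root_state": float(beta[0])}, -best.fun


def _ou_profile_uni(struct, y, alpha):
    V0 = struct.ou_unit_cov(alpha)
    W = struct.ou_design(alpha)
    try:
        ll, theta, s2 = _profile_gauss(V0, W, y, True)
    except np.linalg.LinAlgError:
        return -1e10, None, None
    return ll, theta, s2


def _fit_ou_uni(struct, y, alpha_bounds, n_grid=12):
    lo, hi = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([_ou_profile_uni(struct, y, np.exp(g))[0] for g in grid])
    j = int(np.argmax(lls))
    bl = grid[max(j - 1, 0)]
    bh = grid[min(j + 1, n_grid - 1)]
    res = minimize_scalar(lambda g: -_ou_profile_uni(struct, y, np.exp(g))[0],
                          bounds=(bl, bh), method="bounded",
                          options={"xatol": 1e-6})
    g = res.x if -res.fun >= lls[j] else grid[j]
    alpha = float(np.exp(g))
    ll, theta, s2 = _ou_profile_uni(struct, y, alpha)
    return {"alpha": alpha, "sigma2": s2, "theta": np.asarray(theta)}, ll


def _bm1_biv_closed(C0, Y):
    """Matrix-normal ML for single-rate bivariate BM (rate matrix profiled)."""
    n = len(Y)
    L = cholesky(C0, lower=True)
    onesw = solve_triangular(L, np.ones((n, 1)), lower=True)
    Yw = solve_triangular(L, Y, lower=True)
    beta, *_ = np.linalg.lstsq(onesw, Yw, rcond=None)
    Ew = Yw - onesw @ beta
    R = (Ew.T @ Ew) / n
    w, V = np.linalg.eigh(R)
    R = (V * np.maximum(w, 1e-12)) @ V.T
    logdetC = 2.0 * np.log(np.diag(L)).sum()
    ll = -0.5 * (2 * n * _LOG2PI + n * np.log(np.linalg.det(R))
                 + 2 * logdetC + 2 * n)
    return {"sigma2": R, "root_state": beta.ravel()}, ll


def _fit_bm_biv(struct, Y, restarts, rng):
    n, m = struct.n, struct.C.shape[0]
    if m == 1:
        return _bm1_biv_closed(struct.C_total, Y)

    X = np.kron(np.eye(2), np.ones((n, 1)))
    y = Y.T.ravel()

    def unpack(x):
        out = np.empty((m, 2, 2))
        for r in range(m):
            s1, s2_, z = np.exp(x[3 * r]), np.exp(x[3 * r + 1]), np.tanh(x[3 * r + 2])
            out[r] = [[s1 ** 2, z * s1 * s2_], [z * s1 * s2_, s2_ ** 2]]
        return out

    def obj(x):
        # profile likelihood and its analytic gradient; the GLS mean is
        # profiled, so the envelope theorem lets us differentiate at beta-hat
        R = unpack(x)
        cov = np.einsum("rab,rij->aibj", R, struct.C).reshape(2 * n, 2 * n)
        try:
            c, low = cho_factor(cov, lower=True)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(3 * m)
        Si = cho_solve((c, low), np.eye(2 * n))
        XtSi = X.T @ Si
        beta = np.linalg.solve(XtSi @ X, XtSi @ y)
        r = y - X @ beta
        u = Si @ r
        logdet = 2.0 * np.log(np.diag(c)).sum()
        ll = -0.5 * (2 * n * _LOG2PI + logdet + r @ u)
        ub = u.reshape(2, n)
        grad = np.zeros(3 * m)
        for reg in range(m):
            Cr = struct.C[reg]
            # dll/dR[a,b] pieces: quadratic term and trace term
            quad = ub @ Cr @ ub.T                       # 2x2
            tr = np.array([[np.sum(Si[b * n:(b + 1) * n, a * n:(a + 1) * n].T * Cr)
                            for b in range(2)] for a in range(2)])
            dll_dR = 0.5 * (quad - tr)
            s1, s2_ = np.exp(x[3 * reg]), np.exp(x[3 * reg + 1])
            t = np.tanh(x[3 * reg + 2])
            Rr = unpack(x)[reg]
            d1 = np.array([[2 * Rr[0, 0], Rr[0, 1]], [Rr[0, 1], 0.0]])
            d2 = np.array([[0.0, Rr[0, 1]], [Rr[0, 1], 2 * Rr[1, 1]]])
            dz = (1 - t ** 2) * s1 * s2_ * np.array([[0.0, 1.0], [1.0, 0.0]])
            grad[3 * reg] = np.sum(dll_dR * d1)
            grad[3 * reg + 1] = np.sum(dll_dR * d2)
            grad[3 * reg + 2] = np.sum(dll_dR * dz)
        return -ll, -grad

    # start from the single-rate closed form
    p0, _ = _bm1_biv_closed(struct.C_total, Y)
    R0 = p0["sigma2"]
    rho0 = np.clip(R0[0, 1] / np.sqrt(R0[0, 0] * R0[1, 1]), -0.99, 0.99)
    x0 = np.tile([0.5 * np.log(R0[0, 0]), 0.5 * np.log(R0[1, 1]),
                  np.arctanh(rho0)], m)
    best = None
    for j in range(max(restarts, 1)):
        start = x0 if j == 0 else x0 + rng.uniform(-1.0, 1.0, size=3 * m)
        res = minimize(obj, start, jac=True, method="L-BFGS-B",
                       bounds=[(-15.0, 15.0)] * (3 * m),
                       options={"maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    R = unpack(best.x)
    cov = np.einsum("rab,rij->aibj", R, struct.C).reshape(2 * n, 2 * n)
    _, beta, _ = _profile_gauss(cov, X, y, False)
    return {"sigma2": R, "root_state": np.asarray(beta)}, -best.fun


def _ou_biv_pieces(struct, x):
    """Covariance blocks and their alpha derivatives for the bivariate OU."""
    a = np.exp(x[:2])
    s1, s2_, z = np.exp(x[2]), np.exp(x[3]), np.tanh(x[4])
    R = np.array([[s1 ** 2, z * s1 * s2_], [z * s1 * s2_, s2_ ** 2]])
    S, D1, D2 = struct.S, struct._D1, struct._D2
    K = [[None, None], [None, None]]
    dK = [[[None, None], [None, None]] for _ in range(2)]  # dK[p][a][b]
    for p in range(2):
        for q in range(2):
            s = a[p] + a[q]
            E = np.exp(-a[p] * D1 - a[q] * D2)
            G = -np.expm1(-s * S) / s
            K[p][q] = E * G
            dG = (S * np.exp(-s * S) - G) / s
            dEG = E * dG
            term1 = -D1 * K[p][q] + dEG
            term2 = -D2 * K[p][q] + dEG
            if p == q:
                dK[p][p][q] = term1 + term2
            else:
                dK[p][p][q] = term1
                dK[q][p][q] = term2
    return a, R, K, dK


def _ou_design_deriv(struct, alpha):
    """d/d(alpha) of the OU mean design matrix."""
    W = np.zeros((struct.n, len(struct.regimes)))
    e_rem = np.exp(-alpha * struct.seg_rem)
    c = (struct.seg_dur * np.exp(-alpha * struct.seg_dur) * e_rem
         - struct.seg_rem * (-np.expm1(-alpha * struct.seg_dur)) * e_rem)
    np.add.at(W, (struct.seg_tip, struct.seg_regime), c)
    W[:, struct.root_regime] += -struct.T * np.exp(-alpha * struct.T)
    return W


def _fit_ou_biv(struct, Y, alpha_bounds, restarts, rng):
    n, m = struct.n, struct.C.shape[0]
    y = Y.T.ravel()
    llo, lhi = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])
    eye = np.eye(2 * n)

    def assemble(R, K):
        return np.block([[R[p][q] * K[p][q] if isinstance(K[p][q], np.ndarray)
                          else R[p, q] * K[p][q] for q in range(2)]
                         for p in range(2)])

    def obj(x):
        # profile likelihood with analytic gradient; theta is profiled by
        # GLS, so the envelope theorem applies at theta-hat
        try:
            a, R, K, dKa = _ou_biv_pieces(struct, x)
            cov = np.block([[R[p, q] * K[p][q] for q in range(2)]
                            for p in range(2)])
            W0, W1 = struct.ou_design(a[0]), struct.ou_design(a[1])
            X = np.zeros((2 * n, 2 * m))
            X[:n, :m] = W0
            X[n:, m:] = W1
            c, low = cho_factor(cov, lower=True)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(5)
        Si = cho_solve((c, low), eye)
        XtSi = X.T @ Si
        beta = np.linalg.lstsq(XtSi @ X, XtSi @ y, rcond=None)[0]
        r = y - X @ beta
        u = Si @ r
        logdet = 2.0 * np.log(np.diag(c)).sum()
        ll = -0.5 * (2 * n * _LOG2PI + logdet + r @ u)

        grad = np.zeros(5)
        t = np.tanh(x[4])
        dRs = (np.array([[2 * R[0, 0], R[0, 1]], [R[0, 1], 0.0]]),
               np.array([[0.0, R[0, 1]], [R[0, 1], 2 * R[1, 1]]]),
               (1 - t ** 2) * np.exp(x[2] + x[3]) * np.array([[0., 1.],
                                                              [1., 0.]]))
        for j, dR in enumerate(dRs):
            dS = np.block([[dR[p, q] * K[p][q] for q in range(2)]
                           for p in range(2)])
            grad[2 + j] = 0.5 * (u @ dS @ u - np.sum(Si * dS))
        zero = np.zeros_like(K[0][0])
        for p in range(2):
            dS = np.block([[R[pp, qq] * (dKa[p][pp][qq]
                                         if dKa[p][pp][qq] is not None
                                         else zero)
                            for qq in range(2)] for pp in range(2)])
            dW = _ou_design_deriv(struct, a[p])
            dmean = np.zeros(2 * n)
            if p == 0:
                dmean[:n] = dW @ beta[:m]
            else:
                dmean[n:] = dW @ beta[m:]
            g = 0.5 * (u @ dS @ u - np.sum(Si * dS)) + dmean @ u
            grad[p] = g * a[p]          # chain rule through x = log(alpha)
        return -ll, -grad

    # initialize from the univariate profiles
    x0 = np.zeros(5)
    for p in range(2):
        est, _ = _fit_ou_uni(struct, Y[:, p], alpha_bounds, n_grid=8)
        x0[p] = np.clip(np.log(est["alpha"]), llo, lhi)
        x0[2 + p] = 0.5 * np.log(max(est["sigma2"], 1e-12))
    bounds = [(llo, lhi)] * 2 + [(-15.0, 15.0)] * 2 + [(-5.0, 5.0)]
    best = None
    for j in range(max(restarts, 1)):
        start = x0 if j == 0 else x0 + rng.uniform(-1.0, 1.0, size=5)
        res = minimize(obj, np.clip(start, [b[0] for b in bounds],
                                    [b[1] for b in bounds]),
                       jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 100, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    a, R, K, _ = _ou_biv_pieces(struct, best.x)
    cov = np.block([[R[p, q] * K[p][q] for q in range(2)] for p in range(2)])
    X = np.zeros((2 * n, 2 * m))
    X[:n, :m] = struct.ou_design(a[0])
    X[n:, m:] = struct.ou_design(a[1])
    _, beta, _ = _profile_gauss(cov, X, y, False)
    theta = np.column_stack([beta[:m], beta[m:]])
    return {"alpha": a, "sigma2": R, "theta": theta}, -best.fun


@dataclass
class EvoModelFit:
    spec: ModelSpec
    name: str
    estimates: dict
    log_likelihood: float
    k: int
    n: int
    aic: float
    aicc: float
    akaike_weight: float = np.nan


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aic = -2.0 * log_likelihood + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    v = np.asarray(aicc_values, float)
    d = v - v.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def fit_model(simmap: SimmapTree, spec: ModelSpec, traits,
              restarts: int = 5, seed: int = 0, alpha_bounds=None,
              tip_order=None, struct: PaintedStructure = None) -> EvoModelFit:
    """ML fit of one evolutionary model on a painted tree.

    ``traits`` is a DataFrame indexed by species (columns must include
    ``spec.traits``) or an aligned array.  Deterministic given ``seed``.
    A precomputed :class:`PaintedStructure` may be supplied to avoid
    rebuilding tree geometry across trait sets.
    """
    if struct is None:
        struct = _structure_for(simmap, spec, tip_order)
    if struct.n < 5:
        raise ValueError("need at least 5 tips")
    Y = _align_traits(traits, spec.traits, struct.tip_order)
    rng = np.random.default_rng(seed)
    if alpha_bounds is None:
        alpha_bounds = _default_alpha_bounds(struct)
    if spec.family == "BM":
        if spec.n_traits == 1:
            est, ll = _fit_bm_uni(struct, Y[:, 0], restarts, rng)
        else:
            est, ll = _fit_bm_biv(struct, Y, restarts, rng)
    else:
        if spec.n_traits == 1:
            est, ll = _fit_ou_uni(struct, Y[:, 0], alpha_bounds,
                                  n_grid=max(3 * restarts, 8))
        else:
            est, ll = _fit_ou_biv(struct, Y, alpha_bounds, restarts, rng)
    if not np.isfinite(ll):
        raise RuntimeError(f"{model_name(spec)} fit failed on all restarts")
    k = count_parameters(spec)
    n = struct.n * spec.n_traits
    return EvoModelFit(spec=spec, name=model_name(spec), estimates=est,
                       log_likelihood=float(ll), k=k, n=n,
                       aic=-2.0 * ll + 2.0 * k, aicc=aicc(ll, k, n))


SIX_MODELS = (
    ("BM", "none"), ("BM", "pollination"), ("BM", "island"),
    ("OU", "none"), ("OU", "pollination"), ("OU", "island"),
)


def six_model_specs(traits: tuple,
                    pollination_states=charmap.POLLINATION_STATES,
                    island_states=charmap.ISLAND_STATES):
    regimes = {"none": _SINGLE, "pollination": tuple(pollination_states),
               "island": tuple(island_states)}
    return [ModelSpec(f, src, tuple(traits), regimes[src])
            for f, src in SIX_MODELS]


def fit_model_set(simmaps: dict, traits, trait_names: tuple,
                  restarts: int = 5, seed: int = 0, alpha_bounds=None,
                  pollination_states=charmap.POLLINATION_STATES,
                  island_states=charmap.ISLAND_STATES,
                  structures: dict = None) -> list:
    """Fit the six-model set and attach Akaike weights.

    ``simmaps`` maps regime sources to painted trees; the key ``none`` (or
    any present painting's underlying tree) provides the single-regime tree.
    ``structures`` may carry precomputed :class:`PaintedStructure` objects
    under the same keys.
    """
    fits = []
    base = simmaps.get("none") or next(iter(simmaps.values()))
    structures = structures or {}
    for spec in six_model_specs(trait_names, pollination_states, island_states):
        sm = base if spec.regime_source == "none" else simmaps[spec.regime_source]
        fits.append(fit_model(sm, spec, traits, restarts=restarts, seed=seed,
                              alpha_bounds=alpha_bounds,
                              struct=structures.get(spec.regime_source)))
    for f, w in zip(fits, akaike_weights([f.aicc for f in fits])):
        f.akaike_weight = float(w)
    return fits


# ============================================================== replication
DEFAULT_TRAIT_SETS = (
    ("identity_pc1",), ("identity_pc2",), ("identity_pc1", "identity_pc2"),
    ("breadth_pc1",), ("breadth_pc2",), ("breadth_pc1", "breadth_pc2"),
    ("identity_pc1", "breadth_pc1"), ("identity_pc2", "breadth_pc2"),
)

TRAIT_SET_LABELS = {
    ("identity_pc1",): "niche identity (PC1)",
    ("identity_pc2",): "niche identity (PC2)",
    ("identity_pc1", "identity_pc2"): "niche identity (PC1 and PC2)",
    ("breadth_pc1",): "niche breadth (PC1)",
    ("breadth_pc2",): "niche breadth (PC2)",
    ("breadth_pc1", "breadth_pc2"): "niche breadth (PC1 and PC2)",
    ("identity_pc1", "breadth_pc1"): "niche identity and breadth (PC1)",
    ("identity_pc2", "breadth_pc2"): "niche identity and breadth (PC2)",
}


@dataclass
class ReplicateConfig:
    n_iterations: int = 50
    trait_sets: tuple = DEFAULT_TRAIT_SETS
    seed: int = 0
    restarts: int = 2
    mk_restarts: int = 2
    root_treatment: str = "fitzjohn"
    jackknife_fraction: float = 0.5
    min_retained: int = 2
    max_failure_fraction: float = 0.1
    alpha_bounds: tuple = None
    pollination_states: tuple = charmap.POLLINATION_STATES
    island_states: tuple = charmap.ISLAND_STATES


@dataclass
class ReplicateSummary:
    """Mean AICc weights with 95% percentile CIs over iterations."""

    summary: pd.DataFrame
    iterations: pd.DataFrame
    failures: list
    config: ReplicateConfig


def _species_scores(occ, space, raster) -> dict:
    from .envspace import dedupe_per_pixel

    occ = dedupe_per_pixel(occ)
    out = {}
    for sp, sub in occ.records.groupby("species", sort=True):
        out[sp] = space.project(raster.env_for_pixels(sub["pixel_id"]))
    return out


def run_replicates(trees, occurrences, metadata, space, config,
                   raster=None) -> ReplicateSummary:
    """Propagate tree, mapping and occurrence uncertainty through the model set.

    Per iteration i: take tree i (cycled), jackknife each species'
    deduplicated records (half, at least ``min_retained``), recompute niche
    identity and breadth, draw one island assignment and one stochastic map
    per regime source, fit the six models on every trait set, and record the
    per-iteration AICc weights.  Failed iterations are logged and skipped;
    the run aborts if more than ``max_failure_fraction`` fail.
    """
    cfg = config
    if raster is None:
        raise ValueError("raster with environmental values is required")
    scores = _species_scores(occurrences, space, raster)
    species = sorted(scores)
    meta = metadata[metadata["species"].isin(species)].reset_index(drop=True)
    rows, failures = [], []
    pruned_cache = {}
    for i in range(cfg.n_iterations):
        try:
            rows.extend(_one_iteration(i, trees, scores, species, meta, cfg,
                                       pruned_cache))
        except Exception as e:   # noqa: BLE001 - iteration isolation
            failures.append({"iteration": i, "error": repr(e)})
    if cfg.n_iterations and len(failures) > cfg.max_failure_fraction * cfg.n_iterations:
        raise RuntimeError(
            f"{len(failures)}/{cfg.n_iterations} iterations failed: "
            f"{failures[:5]}")
    iters = pd.DataFrame(rows)
    grouped = iters.groupby(["trait_set", "model"])["weight"]
    summary = grouped.agg(
        mean_weight="mean",
        ci_low=lambda w: np.percentile(w, 2.5),
        ci_high=lambda w: np.percentile(w, 97.5),
    ).reset_index()
    return ReplicateSummary(summary=summary, iterations=iters,
                            failures=failures, config=cfg)


def _one_iteration(i, trees, scores, species, meta, cfg, pruned_cache):
    rng = np.random.default_rng([cfg.seed, 104729, i])
    tree = trees[i % len(trees)]
    key = i % len(trees)
    if key not in pruned_cache:
        keep = sorted(set(tree.tip_labels) & set(species))
        if set(keep) != set(tree.tip_labels):
            tree = tree.prune_to(keep)
        pruned_cache[key] = tree
    tree = pruned_cache[key]

    # 50% jackknife of the deduplicated records, then niche summaries
    traits = {}
    for sp in species:
        sc = scores[sp]
        keep_n = max(cfg.min_retained, int(len(sc) * cfg.jackknife_fraction))
        idx = rng.choice(len(sc), size=min(keep_n, len(sc)), replace=False)
        sub = sc[np.sort(idx)]
        traits[sp] = {
            "identity_pc1": sub[:, 0].mean(), "identity_pc2": sub[:, 1].mean(),
            "breadth_pc1": sub[:, 0].std(ddof=1),
            "breadth_pc2": sub[:, 1].std(ddof=1),
        }
    traits = pd.DataFrame(traits).T

    # one stochastic map per regime source
    islands = charmap.assign_single_island(meta, rng, cfg.island_states)
    isl_priors = charmap.delta_priors(islands, cfg.island_states)
    isl_model = charmap.fit_mk(tree, isl_priors, "SYM", cfg.island_states,
                               cfg.root_treatment, restarts=cfg.mk_restarts,
                               seed=int(rng.integers(2 ** 31)))
    isl_map = charmap.sample_stochastic_map(tree, isl_model, isl_priors, rng)
    pol_priors = charmap.build_tip_priors(meta, cfg.pollination_states)
    pol_model = charmap.fit_mk(tree, pol_priors, "ARD", cfg.pollination_states,
                               cfg.root_treatment, restarts=cfg.mk_restarts,
                               seed=int(rng.integers(2 ** 31)))
    pol_map = charmap.sample_stochastic_map(tree, pol_model, pol_priors, rng)
    single = SimmapTree.single_regime(tree, _SINGLE[0])
    simmaps = {"none": single, "pollination": pol_map, "island": isl_map}
    structures = {
        "none": PaintedStructure(single, _SINGLE),
        "pollination": PaintedStructure(pol_map, cfg.pollination_states),
        "island": PaintedStructure(isl_map, cfg.island_states),
    }

    rows = []
    seed_i = int(rng.integers(2 ** 31))
    for trait_set in cfg.trait_sets:
        fits = fit_model_set(simmaps, traits, tuple(trait_set),
                             restarts=cfg.restarts, seed=seed_i,
                             alpha_bounds=cfg.alpha_bounds,
                             pollination_states=cfg.pollination_states,
                             island_states=cfg.island_states,
                             structures=structures)
        label = TRAIT_SET_LABELS.get(tuple(trait_set), "+".join(trait_set))
        for f in fits:
            rows.append({"iteration": i, "trait_set": label, "model": f.name,
                         "logL": f.log_likelihood, "k": f.k, "n": f.n,
                         "AICc": f.aicc, "weight": f.akaike_weight})
    return rows
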