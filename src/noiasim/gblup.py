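"""Genomic relationship matrices and average-information REML.

GRMs follow standard GBLUP practice: the additive matrix is the trace-
normalized cross-product of centered gene-content covariates, the dominance
matrix the analog over dominance covariates, and the additive x additive
epistasis matrix the trace-normalized Hadamard square of the additive matrix.
For three-way hybrid plots the dominance rows use the generalized plot
dominance covariate and the plot additive rows are built from parental-line
genotype means; plots link to their two population-2 grandparental lines
through the summed incidence (Z_a + Z_b).

Variance components are re-estimated by average-information REML with an
EM-REML fallback and step halving whenever an AI step would leave the
parameter space or decrease the restricted likelihood. The model is
y = 1*mu + sum_c Z_c g_c + e with g_c ~ N(0, G_c sigma2_c). A single-
genetic-component model takes a fast path: one eigendecomposition of the GRM
turns every REML iteration into O(n) diagonal algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .noia import Anchor, h_d3, statistical_covariates_ipg


class DegenerateMatrixError(ValueError):
    pass


@dataclass
class GRMSet:
    """Labeled relationship matrices with incidence maps to phenotype records."""

    matrices: dict
    incidence: dict = field(default_factory=dict)  # name -> (n_records, n_levels) or None

    def components(self):
        return list(self.matrices.keys())

    def record_covariance(self, name: str) -> np.ndarray:
        """Z G Z' for the named component (identity incidence if None)."""
        G = self.matrices[name]
        Z = self.incidence.get(name)
        return G if Z is None else Z @ G @ Z.T


def _normalize(M: np.ndarray) -> np.ndarray:
    tr = np.trace(M)
    if tr <= 0:
        raise DegenerateMatrixError("relationship matrix has non-positive trace")
    return M * (M.shape[0] / tr)


def _blend(G: np.ndarray, frac: float) -> np.ndarray:
    """(1 - frac) G + frac I: the standard identity blend that keeps marker
    relationship matrices positive definite (they are otherwise singular when
    markers are fewer than individuals). Mixed-model software that inverts G
    always applies such a blend; it is part of the estimation procedure this
    module emulates, and it leaves the trace normalization intact."""
    if frac == 0:
        return G
    return (1.0 - frac) * G + frac * np.eye(len(G))


def build_grms_ipg(dosage: np.ndarray, anchor: Anchor = None, blend: float = 0.05) -> GRMSet:
    """G_A, G_D, G_AA for individual data; QTL serve as the marker panel.

    Anchoring defaults to the observed frequencies of the analyzed individuals
    (genotype-frequency dominance covariates, valid out of HWE). Each matrix is
    blended with `blend` x identity (VanRaden-style 0.95 G + 0.05 I default).
    """
    dosage = np.asarray(dosage)
    if dosage.shape[0] < 2:
        raise DegenerateMatrixError("need at least 2 individuals")
    if anchor is None:
        anchor = Anchor.from_population(dosage, basis="genotype")
    Ha, Hd = statistical_covariates_ipg(dosage, anchor)
    if not np.any(Ha.var(axis=0) > 0):
        raise DegenerateMatrixError("all loci are monomorphic")
    GA = _normalize(Ha @ Ha.T)
    GD = _normalize(Hd @ Hd.T)
    GAA = _normalize(GA * GA)
    mats = {"additive": _blend(GA, blend), "dominance": _blend(GD, blend),
            "epistasis": _blend(GAA, blend)}
    return GRMSet(matrices=mats,
                  incidence={"additive": None, "dominance": None, "epistasis": None})


def _indicator(idx: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(idx), n_levels))
    Z[np.arange(len(idx)), idx] = 1.0
    return Z


def build_grms_ppg(lines1, lines2, plots, qtl_index, q1=None, q2=None,
                   blend: float = 0.05) -> GRMSet:
    """pPG relationship set: G_A1, G_A2 over parental lines; G_D3, G_AA3 over plots.

    `lines1`/`lines2` are Populations; only lines appearing in `plots` enter
    the matrices. q1/q2 default to the observed line allele frequencies.
    G_AA3 is the normalized Hadamard square of the plot additive matrix built
    from parental-line genotype means h_a3 = 1/2(t1 - 2q1) + 1/4(t2a + t2b - 4q2).
    """
    qtl_index = np.asarray(qtl_index, dtype=int)
    used1 = np.unique(plots.i1)
    used2 = np.unique(np.concatenate([plots.i2a, plots.i2b]))
    d1 = lines1.dosage[used1][:, qtl_index].astype(float)
    d2 = lines2.dosage[used2][:, qtl_index].astype(float)
    if q1 is None:
        q1 = d1.mean(0) / 2.0
    if q2 is None:
        q2 = d2.mean(0) / 2.0
    t1l = d1 - 1.0
    t2l = d2 - 1.0
    H1 = t1l - (2.0 * q1 - 1.0)[None, :]  # gene-content centering as in G_A
    H2 = t2l - (2.0 * q2 - 1.0)[None, :]
    GA1 = _normalize(H1 @ H1.T)
    GA2 = _normalize(H2 @ H2.T)

    pos1 = np.searchsorted(used1, plots.i1)
    pos2a = np.searchsorted(used2, plots.i2a)
    pos2b = np.searchsorted(used2, plots.i2b)
    t1 = t1l[pos1]
    t2a, t2b = t2l[pos2a], t2l[pos2b]
    t2 = 0.5 * (t2a + t2b)
    Hd3 = h_d3(t1, t2, q1[None, :], 1 - q1[None, :], q2[None, :], 1 - q2[None, :])
    GD3 = _normalize(Hd3 @ Hd3.T)
    Ha3 = 0.5 * (t1 - 2.0 * q1[None, :]) + 0.25 * (t2a + t2b - 4.0 * q2[None, :])
    GA3 = _normalize(Ha3 @ Ha3.T)
    GAA3 = _normalize(GA3 * GA3)

    Z1 = _indicator(pos1, len(used1))
    Z2 = _indicator(pos2a, len(used2)) + _indicator(pos2b, len(used2))
    return GRMSet(
        matrices={"additive1": _blend(GA1, blend), "additive2": _blend(GA2, blend),
                  "dominance3": _blend(GD3, blend), "epistasis3": _blend(GAA3, blend)},
        incidence={"additive1": Z1, "additive2": Z2, "dominance3": None, "epistasis3": None},
    )


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------


@dataclass
class RemlResult:
    estimates: dict
    std_errors: dict
    loglik: float
    converged: bool
    iterations: int
    trajectory: list = field(default_factory=list)


def _chol_with_bending(V):
    eps = 1e-6 * np.mean(np.diag(V))
    for k in range(8):
        try:
            return cho_factor(V if k == 0 else V + (eps * 10 ** (k - 1)) * np.eye(len(V)), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix not positive definite after bending")


class _DensePieces:
    """Working quantities at one parameter point: restricted log-likelihood and
    a P-apply operator built on the Cholesky factor (no explicit inverse)."""

    def __init__(self, theta, Vcs, y, X):
        n = len(y)
        V = theta[-1] * np.eye(n)
        for t, Vc in zip(theta[:-1], Vcs):
            V += t * Vc
        self.chol = _chol_with_bending(V)
        logdetV = 2.0 * np.sum(np.log(np.diag(self.chol[0])))
        VinvX = cho_solve(self.chol, X)
        self.XtVinvX = X.T @ VinvX
        _, logdetX = np.linalg.slogdet(self.XtVinvX)
        self.VinvX = VinvX
        self.Py = self.P_apply(y)
        self.logL = -0.5 * (logdetV + logdetX + float(y @ self.Py))

    def P_apply(self, v):
        Vinv_v = cho_solve(self.chol, v)
        return Vinv_v - self.VinvX @ np.linalg.solve(self.XtVinvX, self.VinvX.T @ v)

    def traces(self, mats, probes):
        """tr(P Vc) for each Vc: exact via an explicit inverse when `probes` is
        None, else a seeded Hutchinson estimate (logL stays exact either way)."""
        n = len(self.Py)
        if probes is None:
            Vinv = cho_solve(self.chol, np.eye(n))
            P = Vinv - self.VinvX @ np.linalg.solve(self.XtVinvX, self.VinvX.T)
            return np.array([np.sum(P * Vc) for Vc in mats])
        PZ = self.P_apply(probes)
        s = probes.shape[1]
        return np.array([np.sum(PZ * (Vc @ probes)) / s for Vc in mats])


def _aireml_dense(y, Vcs, X, start, max_iter, tol, trace_probes=None):
    n = len(y)
    k = len(Vcs) + 1
    if trace_probes is None and n > 1600:
        trace_probes = 64  # score traces by Hutchinson estimator at large n
    probes = None
    if trace_probes:
        rng = np.random.default_rng(1234 + n)
        probes = rng.choice([-1.0, 1.0], size=(n, int(trace_probes)))
    theta = np.asarray(start, dtype=float)
    floor = 1e-8 * np.var(y)
    cur = _DensePieces(theta, Vcs, y, X)
    trajectory = [(theta.copy(), cur.logL)]
    converged = False
    it = 0
    AI = np.eye(k)
    mats = Vcs + [np.eye(n)]
    for it in range(1, max_iter + 1):
        Py = cur.Py
        T = np.column_stack([Vc @ Py for Vc in mats])  # n x k
        PT = cur.P_apply(T)
        quad = np.array([float(Py @ T[:, c]) for c in range(k)])
        tr = cur.traces(mats, probes)
        score = -0.5 * (tr - quad)
        AI = 0.5 * (T.T @ PT)
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = score / np.maximum(np.diag(AI), 1e-12)
        accepted = False
        step = 1.0
        for _ in range(12):
            th_c = np.maximum(theta + step * delta, floor)
            cand = _DensePieces(th_c, Vcs, y, X)
            if cand.logL >= cur.logL - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM-REML fallback step
            th_c = np.maximum(theta + theta**2 * (quad - tr) / n, floor)
            cand = _DensePieces(th_c, Vcs, y, X)
            if cand.logL < cur.logL - 1e-8:
                break  # cannot improve further
        dl = cand.logL - cur.logL
        theta, cur = th_c, cand
        trajectory.append((theta.copy(), cur.logL))
        if abs(dl) < tol:
            converged = True
            break
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return theta, se, cur.logL, converged, it, trajectory


def _diag_pieces(theta, lam, y, x):
    """REML pieces for V = theta_g diag(lam) + theta_e I in the eigenbasis."""
    w = 1.0 / (theta[0] * lam + theta[1])
    a = w * x
    s = float(x @ a)
    Py = w * y - a * (float(a @ y) / s)
    logL = -0.5 * (-np.sum(np.log(w)) + np.log(s) + float(y @ Py))

    def P_apply(v):
        return w * v - a * (float(a @ v) / s)

    def trace_PD(d):  # tr(P diag(d))
        return float(np.sum(w * d) - (a * a) @ d / s)

    return logL, Py, P_apply, trace_PD


def _aireml_single(y, G, Z, X, start, max_iter, tol):
    """Fast path: one genetic component. Eigendecompose ZGZ' once, iterate O(n)."""
    V1 = G if Z is None else Z @ G @ Z.T
    lam, U = np.linalg.eigh(V1)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    xt = U.T @ X[:, 0]
    theta = np.asarray(start, dtype=float)
    floor = 1e-8 * np.var(y)
    logL, Py, P_apply, trace_PD = _diag_pieces(theta, lam, yt, xt)
    trajectory = [(theta.copy(), logL)]
    converged = False
    it = 0
    AI = np.eye(2)
    one = np.ones_like(lam)
    for it in range(1, max_iter + 1):
        T = np.column_stack([lam * Py, Py])
        PT = np.column_stack([P_apply(T[:, 0]), P_apply(T[:, 1])])
        score = np.array([
            -0.5 * (trace_PD(lam) - float(Py @ (lam * Py))),
            -0.5 * (trace_PD(one) - float(Py @ Py)),
        ])
        AI = 0.5 * (T.T @ PT)
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = score / np.maximum(np.diag(AI), 1e-12)
        accepted = False
        step = 1.0
        for _ in range(20):
            cand = np.maximum(theta + step * delta, floor)
            cand_logL, cand_Py, cand_Pa, cand_tr = _diag_pieces(cand, lam, yt, xt)
            if cand_logL >= logL - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            n = len(y)
            em = theta.copy()
            em[0] = max(theta[0] + theta[0] ** 2 * (float(Py @ (lam * Py)) - trace_PD(lam)) / n, floor)
            em[1] = max(theta[1] + theta[1] ** 2 * (float(Py @ Py) - trace_PD(one)) / n, floor)
            cand = em
            cand_logL, cand_Py, cand_Pa, cand_tr = _diag_pieces(cand, lam, yt, xt)
            if cand_logL < logL - 1e-8:
                break
        dl = cand_logL - logL
        theta, logL, Py, P_apply, trace_PD = cand, cand_logL, cand_Py, cand_Pa, cand_tr
        trajectory.append((theta.copy(), logL))
        if abs(dl) < tol:
            converged = True
            break
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    return theta, se, logL, converged, it, trajectory


def aireml(y, grms: GRMSet, start=None, max_iter: int = 100, tol: float = 1e-6,
           trace_probes=None) -> RemlResult:
    """AI-REML estimates of the variance components in `grms` plus a residual.

    Fixed effects: intercept only. Estimates are boundary-constrained at a
    small positive floor; non-convergence is flagged and the trajectory
    returned either way.
    """
    y = np.asarray(y, dtype=float)
    names = grms.components()
    n = len(y)
    X = np.ones((n, 1))
    k = len(names)
    vy = np.var(y)
    if start is None:
        start = np.full(k + 1, vy / (k + 1))
    start = np.asarray(start, dtype=float)
    if len(names) == 1:
        theta, se, logL, conv, it, traj = _aireml_single(
            y, grms.matrices[names[0]], grms.incidence.get(names[0]), X, start, max_iter, tol
        )
    else:
        Vcs = [grms.record_covariance(nm) for nm in names]
        theta, se, logL, conv, it, traj = _aireml_dense(y, Vcs, X, start, max_iter, tol,
                                                        trace_probes=trace_probes)
    labels = names + ["residual"]
    return RemlResult(
        estimates=dict(zip(labels, map(float, theta))),
        std_errors=dict(zip(labels, map(float, se))),
        loglik=float(logL),
        converged=bool(conv),
        iterations=it,
        trajectory=traj,
    )
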