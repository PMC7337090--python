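"""Random-effect multiple interval mapping: REML and score tests.

The multi-QTL model is y = 1*mu + sum_q g_q + eps with g_q ~ N(0, G_q
sigma_q^2) and eps ~ N(0, I sigma^2).  Rescaling each QTL variance as
sigma_q^2 = sigma^2 * tau_q gives Var(y) = V(tau) sigma^2 with
V(tau) = sum_q G_q tau_q + I.  Projecting y onto error contrasts with an
(n-1) x n matrix A (A 1 = 0, A A' = I) removes mu and profiling removes
sigma^2, leaving the restricted log-likelihood

    l(tau) = -1/2 * { (n-1) log(y~' V~(tau)^-1 y~) + log |V~(tau)| }

with y~ = A y and V~ = A V A'.  Presence of a QTL r is tested with the
score S_r = dl/dtau_r evaluated at the null (tau_r = 0, nuisance tau at
their REML estimates); under the null with normal errors the statistic is
a ratio of quadratic forms in white noise, whose exact tail probability
is a weighted chi-square computation (see :mod:`polyqtl.quadform`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .quadform import tail_probability

__all__ = [
    "restricted_transform",
    "RestrictedData",
    "QTL",
    "QTLModel",
    "REMLOptions",
    "reml_fit",
    "score_statistic",
    "score_pvalue",
    "ScoreResult",
]


def restricted_transform(n: int) -> np.ndarray:
    """Helmert-style orthonormal error contrasts: A (n-1 x n), A1=0, AA'=I.

    Any orthonormal basis of the complement of 1 works; the restricted
    likelihood and the score statistics are invariant to the choice
    (asserted in the test suite).
    """
    if n < 2:
        raise ValueError("restricted transform needs n >= 2")
    A = np.zeros((n - 1, n))
    for i in range(1, n):
        norm = np.sqrt(i * (i + 1.0))
        A[i - 1, :i] = 1.0 / norm
        A[i - 1, i] = -i / norm
    return A


@dataclass
class RestrictedData:
    """Phenotype and kernels mapped to the error-contrast space."""

    A: np.ndarray
    y_tilde: np.ndarray
    G_tilde: list[np.ndarray]

    @classmethod
    def build(cls, y, kernels, A: np.ndarray | None = None) -> "RestrictedData":
        y = np.asarray(y, dtype=float).ravel()
        if A is None:
            A = restricted_transform(y.size)
        G_tilde = []
        for G in kernels:
            G = np.asarray(G, dtype=float)
            if G.shape != (y.size, y.size):
                raise ValueError("kernel dimension does not match phenotype length")
            if not np.allclose(G, G.T, atol=1e-8):
                raise ValueError("kernels must be symmetric")
            G_tilde.append(A @ G @ A.T)
        return cls(A=A, y_tilde=A @ y, G_tilde=G_tilde)

    @property
    def n_tilde(self) -> int:
        return self.y_tilde.size


@dataclass
class QTL:
    lg: int
    pos_cM: float
    index: int  # grid index; -1 when the kernel did not come from a grid
    tau: float = 0.0
    sigma2_q: float = 0.0
    score: float = np.nan
    p_value: float = np.nan
    support: tuple[float, float] | None = None


@dataclass
class QTLModel:
    """A fitted multi-QTL random-effect model."""

    qtl: list[QTL]
    sigma2: float
    mu: float
    n: int
    loglik: float
    tau: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)

    @property
    def positions(self) -> list[tuple[int, float]]:
        return [(q.lg, q.pos_cM) for q in self.qtl]


@dataclass
class REMLOptions:
    starts: tuple[float, ...] = (0.01, 0.5, 2.0)
    gtol: float = 1e-5
    ftol: float = 1e-10
    max_iter: int = 200
    tau_upper: float = 1e4


def _lowrank_reml(y_tilde: np.ndarray, W_cat: np.ndarray, n_blocks: int,
                  ploidy: int, options: "REMLOptions | None" = None,
                  start=None) -> tuple[np.ndarray, float, float]:
    """REML for kernels of the form G~_q = W_q W_q^T / m, via Woodbury.

    ``W_cat`` stacks the Q factors column-wise (nt x 2m*Q).  Every
    objective/gradient evaluation works in the 2m*Q-dimensional inner
    space, so fits stay cheap regardless of n.  Returns (tau, sigma2,
    restricted log-likelihood).
    """
    opts = options or REMLOptions()
    nt = y_tilde.size
    k = W_cat.shape[1] // n_blocks
    C = W_cat.T @ W_cat
    b = W_cat.T @ y_tilde
    yy = float(y_tilde @ y_tilde)
    blocks = [slice(j * k, (j + 1) * k) for j in range(n_blocks)]

    def negll(tau):
        d = np.repeat(tau / ploidy, k)
        Dh = np.sqrt(d)
        K = np.eye(C.shape[0]) + Dh[:, None] * C * Dh[None, :]
        try:
            cho = linalg.cho_factor(K, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, np.full(n_blocks, np.nan)
        t1 = Dh * b
        w = linalg.cho_solve(cho, t1, check_finite=False)
        quad = yy - float(t1 @ w)
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        f = nt * np.log(quad) + logdet
        CD = C * Dh[None, :]
        u = b - CD @ w                      # W' V^-1 y~
        M = C - CD @ linalg.cho_solve(cho, CD.T, check_finite=False)
        grad = np.array([
            np.trace(M[blk, blk]) / ploidy
            - nt * float(u[blk] @ u[blk]) / ploidy / quad
            for blk in blocks
        ])
        return f, grad

    best = None
    starts = [np.full(n_blocks, s) for s in opts.starts]
    if start is not None:
        starts.insert(0, np.asarray(start, dtype=float).clip(0.0, opts.tau_upper))
    for s0 in starts:
        res = optimize.minimize(
            negll, s0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, opts.tau_upper)] * n_blocks,
            options={"maxiter": opts.max_iter, "ftol": opts.ftol, "gtol": opts.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau = np.clip(best.x, 0.0, None)
    f, _ = negll(tau)
    d = np.repeat(tau / ploidy, k)
    Dh = np.sqrt(d)
    K = np.eye(C.shape[0]) + Dh[:, None] * C * Dh[None, :]
    t1 = Dh * b
    quad = yy - float(t1 @ np.linalg.solve(K, t1))
    return tau, quad / nt, -0.5 * f


def _neg_restricted_loglik(tau, data: RestrictedData):
    """-2*l(tau) (up to constants) and its gradient."""
    nt = data.n_tilde
    V = np.eye(nt)
    for t, Gt in zip(tau, data.G_tilde):
        if t != 0.0:
            V += t * Gt
    try:
        L, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, np.full(len(tau), np.nan)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    z = linalg.cho_solve((L, low), data.y_tilde, check_finite=False)
    quad = float(data.y_tilde @ z)
    f = nt * np.log(quad) + logdet
    grad = np.empty(len(tau))
    for q, Gt in enumerate(data.G_tilde):
        Vi_G = linalg.cho_solve((L, low), Gt, check_finite=False)
        grad[q] = np.trace(Vi_G) - nt * float(z @ Gt @ z) / quad
    return f, grad


def reml_fit(y, kernels, options: REMLOptions | None = None,
             start: np.ndarray | None = None) -> QTLModel:
    """REML estimation of variance components for a fixed set of kernels.

    Maximizes the profiled restricted log-likelihood over the variance
    ratios tau_q >= 0 with a box-constrained quasi-Newton optimizer and
    multiple starting points, then recovers sigma^2 by profiling and mu
    by generalized least squares.
    """
    opts = options or REMLOptions()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    Q = len(kernels)
    if Q == 0:
        mu = float(y.mean())
        sigma2 = float(((y - mu) ** 2).sum() / (n - 1))
        ll = -0.5 * ((n - 1) * np.log(sigma2 * (n - 1)) + 0.0)
        return QTLModel(qtl=[], sigma2=sigma2, mu=mu, n=n, loglik=float(ll))

    for G in kernels:
        w = np.linalg.eigvalsh(np.asarray(G, dtype=float))
        if w.min() < -1e-6 * max(1.0, abs(w.max())):
            raise ValueError("kernels must be positive semidefinite")

    data = RestrictedData.build(y, kernels)

    best = None
    starts = [np.full(Q, s) for s in opts.starts]
    if start is not None:
        starts.insert(0, np.asarray(start, dtype=float).clip(0.0, opts.tau_upper))
    for s0 in starts:
        res = optimize.minimize(
            lambda t: _neg_restricted_loglik(t, data),
            s0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, opts.tau_upper)] * Q,
            options={"maxiter": opts.max_iter, "ftol": opts.ftol, "gtol": opts.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimization failed to produce a finite objective")

    tau = np.clip(best.x, 0.0, None)
    nt = data.n_tilde
    V_t = np.eye(nt)
    for t, Gt in zip(tau, data.G_tilde):
        V_t += t * Gt
    L, low = linalg.cho_factor(V_t, lower=True, check_finite=False)
    z = linalg.cho_solve((L, low), data.y_tilde, check_finite=False)
    sigma2 = float(data.y_tilde @ z) / nt

    # GLS mean in the original space: V = sum tau G + I (times sigma^2)
    V = np.eye(n)
    for t, G in zip(tau, kernels):
        V += t * np.asarray(G, dtype=float)
    Vi_1 = np.linalg.solve(V, np.ones(n))
    mu = float(Vi_1 @ y) / float(Vi_1.sum())

    loglik = -0.5 * best.fun
    qtl = [QTL(lg=-1, pos_cM=np.nan, index=-1, tau=float(t),
               sigma2_q=float(t * sigma2)) for t in tau]
    return QTLModel(qtl=qtl, sigma2=sigma2, mu=mu, n=n, loglik=float(loglik), tau=tau)


def _null_pieces(data: RestrictedData, r: int, tau0):
    tau0 = np.asarray(tau0, dtype=float)
    if tau0.shape != (len(data.G_tilde),):
        raise ValueError("tau0 must have one entry per kernel")
    if tau0[r] != 0.0:
        raise ValueError("the tested component of tau0 must be zero")
    nt = data.n_tilde
    V0 = np.eye(nt)
    for q, (t, Gt) in enumerate(zip(tau0, data.G_tilde)):
        if q != r and t != 0.0:
            V0 += t * Gt
    L, low = linalg.cho_factor(V0, lower=True, check_finite=False)
    z = linalg.cho_solve((L, low), data.y_tilde, check_finite=False)
    Vi_G = linalg.cho_solve((L, low), data.G_tilde[r], check_finite=False)
    return (L, low), z, Vi_G


def score_statistic(data: RestrictedData, r: int, tau0) -> float:
    """Linear score S_r = dl/dtau_r at the null (tau_r = 0, nuisance tau0).

    S_r = (n~/2) * (y~' V~^-1 G~_r V~^-1 y~) / (y~' V~^-1 y~)
          - 1/2 * tr(V~^-1 G~_r).
    """
    _, z, Vi_G = _null_pieces(data, r, tau0)
    nt = data.n_tilde
    num = float(z @ data.G_tilde[r] @ z)
    den = float(data.y_tilde @ z)
    return 0.5 * nt * num / den - 0.5 * float(np.trace(Vi_G))


@dataclass
class ScoreResult:
    statistic: float
    p_value: float
    method: str
    tau0: np.ndarray


def score_pvalue(data: RestrictedData, r: int, tau0,
                 method: str = "auto", rng=None) -> ScoreResult:
    """Null P-value of the linear score test for kernel ``r``.

    With no nuisance components the test is exact: under H0 the white
    noise w = V0^{-1/2} y~ / sigma is standard normal and

        S_r > s  <=>  sum_i (lambda_i - c) z_i^2 > 0,

    where lambda_i are the eigenvalues of B = V0^{-1/2} G~_r V0^{-1/2}
    and c = (2 s + tr B) / n~ equals the observed quadratic-form ratio.
    With nuisance components the same representation is evaluated at the
    plugged-in REML estimates; its tail is approximated by a
    cumulant-matched scaled-shifted chi-square (moment method), the
    exact-given-plug-in Imhof evaluation remaining available.
    """
    tau0 = np.asarray(tau0, dtype=float)
    (L, low), z, Vi_G = _null_pieces(data, r, tau0)
    nt = data.n_tilde
    Gr = data.G_tilde[r]
    num = float(z @ Gr @ z)
    den = float(data.y_tilde @ z)
    trace = float(np.trace(Vi_G))
    s = 0.5 * nt * num / den - 0.5 * trace
    c = num / den  # = (2 s + tr) / n~

    # eigenvalues of B = V0^{-1/2} G~_r V0^{-1/2}
    lam = np.linalg.eigvalsh(linalg.solve_triangular(
        L, linalg.solve_triangular(L, Gr, lower=True, check_finite=False).T,
        lower=True, check_finite=False))
    lam = np.clip(lam, 0.0, None)

    has_nuisance = any(t != 0.0 for q, t in enumerate(tau0) if q != r)
    if method == "auto":
        method = "moment" if has_nuisance else "exact"
    p = tail_probability(lam - c, method=method, rng=rng)
    return ScoreResult(statistic=float(s), p_value=p, method=method, tau0=tau0)
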