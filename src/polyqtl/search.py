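"""Genome-wide QTL search for the random-effect multiple-QTL model.

Detection proceeds in three phases:

1. *Forward search* — repeatedly score-test every map position outside a
   window around QTL already in the model, conditional on those QTL
   (nuisance variance ratios re-estimated by REML each round), and add
   the minimum-P position while its P-value beats a permissive
   genome-wide threshold (default alpha 0.20).
2. *Model optimization* — rounds of position refinement (each QTL
   re-scanned conditional on all the others) and backward elimination at
   a stringent threshold (default alpha 0.05), optionally followed by
   renewed forward search at the stringent threshold, until stable.
3. *QTL profiling* — score statistics, P-values and LOP = -log10(P) at
   every position conditional on the final model, each QTL's own
   neighborhood profiled with that QTL excluded; LOP - d support
   intervals are read off the profile.

Genome-wide P-value thresholds come from a score-based resampling null:
standard-normal phenotypes are scanned and the alpha-quantile of the
per-resample genome-wide minimum P-value is the level-alpha threshold.

Scans are cheap because every kernel has the low-rank form
G_q = X_q X_q^T / m with X_q only 2m columns wide: the eigenvalues
needed for each candidate's null distribution come from a 2m x 2m
matrix, never from an n x n one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .feim import _support_interval
from .kinship import KinshipGrid
from .quadform import P_FLOOR, tail_probability
from .remim import QTL, QTLModel, _lowrank_reml, reml_fit, restricted_transform

__all__ = [
    "SearchConfig",
    "ScanProfile",
    "resampling_threshold",
    "forward_search",
    "optimize_model",
    "profile_qtl",
    "lop_support_interval",
    "remim_search",
]


@dataclass(frozen=True)
class SearchConfig:
    forward_alpha: float = 0.20
    backward_alpha: float = 0.05
    window_cM: float = 20.0
    step_cM: float = 1.0
    d: float = 1.5
    n_resamples: int = 1000
    max_rounds: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.backward_alpha <= self.forward_alpha < 1.0):
            raise ValueError("need 0 < backward_alpha <= forward_alpha < 1")
        if min(self.window_cM, self.step_cM, self.d) <= 0:
            raise ValueError("window, step and d must be positive")


@dataclass
class ScanProfile:
    """Per-position score test results conditional on a QTL set."""

    map: object
    score: np.ndarray
    p_value: np.ndarray
    model: QTLModel | None = None

    @property
    def lop(self) -> np.ndarray:
        return -np.log10(np.clip(self.p_value, P_FLOOR, 1.0))


def _helmert_factors(grid: KinshipGrid):
    """Cached restricted-space quantities of a grid.

    Returns (A, W, W_flat, Tdiag): the error-contrast basis, the
    per-position factors W_q = A X_q with G~_q = W_q W_q^T / m, the
    (P*2m x nt) stacked transpose used for batched inner products, and
    the per-position Gram blocks W_q^T W_q.
    """
    cached = getattr(grid, "_restricted", None)
    if cached is None:
        A = restricted_transform(grid.n)
        W = np.einsum("ij,qjk->qik", A, grid.X)
        P, nt, k = W.shape
        W_flat = np.ascontiguousarray(W.transpose(0, 2, 1)).reshape(P * k, nt)
        Tdiag = np.einsum("qia,qib->qab", W, W)
        cached = (A, W, W_flat, Tdiag)
        grid._restricted = cached
    return cached


def _null_eigs(grid: KinshipGrid) -> np.ndarray:
    """Per-position eigenvalues of G~_q (empty model), cached on the grid."""
    lam = getattr(grid, "_null_lam", None)
    if lam is None:
        _, _, _, Tdiag = _helmert_factors(grid)
        lam = np.clip(np.linalg.eigvalsh(Tdiag / grid.space.ploidy), 0.0, None)
        grid._null_lam = lam
    return lam


class ScanContext:
    """Null model fitted once; candidate positions scored against it.

    All per-candidate work happens in the 2m-dimensional inner space of
    the low-rank kernels (Woodbury identities), so one genome scan costs
    a few small eigenproblems per position plus the tail-probability
    evaluations.
    """

    def __init__(self, y, grid: KinshipGrid, model_indices: list[int],
                 warm_start=None):
        self.grid = grid
        self.indices = list(model_indices)
        A, W, W_flat, Tdiag = _helmert_factors(grid)
        self.Tdiag = Tdiag
        y = np.asarray(y, dtype=float).ravel()
        self.y_tilde = A @ y
        self.nt = self.y_tilde.size
        m = grid.space.ploidy
        P, _, k = W.shape
        self.b_all = (W_flat @ self.y_tilde).reshape(P, k)
        yy = float(self.y_tilde @ self.y_tilde)

        if self.indices:
            W_cat = np.concatenate([W[i] for i in self.indices], axis=1)
            tau, sigma2, loglik = _lowrank_reml(
                self.y_tilde, W_cat, len(self.indices), m, start=warm_start)
            self._tau, self.sigma2, self.loglik = tau, sigma2, loglik
            Dh = np.sqrt(np.repeat(tau / m, k))
            C = W_cat.T @ W_cat
            K = np.eye(C.shape[0]) + Dh[:, None] * C * Dh[None, :]
            self._choK = linalg.cho_factor(K, lower=True, check_finite=False)
            t1 = Dh * (W_cat.T @ self.y_tilde)
            self._w = linalg.cho_solve(self._choK, t1, check_finite=False)
            self.den = yy - float(t1 @ self._w)
            # candidate cross-products against the model stack, Dh-scaled
            self._Ar = (W_flat @ W_cat).reshape(P, k, -1) * Dh[None, None, :]
            self.method = "moment"
        else:
            self._tau = np.zeros(0)
            self._choK = None
            self.den = yy
            self.method = "exact"

    @property
    def tau(self) -> np.ndarray:
        return self._tau

    def _pieces(self, r: int) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues of V0^-1/2 G~_r V0^-1/2, vector W_r' V0^-1 y~)."""
        m = self.grid.space.ploidy
        if self._choK is None:
            return _null_eigs(self.grid)[r], self.b_all[r]
        Ar = self._Ar[r]
        M = (self.Tdiag[r]
             - Ar @ linalg.cho_solve(self._choK, Ar.T, check_finite=False)) / m
        lam = np.clip(np.linalg.eigvalsh(0.5 * (M + M.T)), 0.0, None)
        u = self.b_all[r] - Ar @ self._w
        return lam, u

    def score_test(self, r: int, method: str | None = None) -> tuple[float, float]:
        """(score, p_value) for candidate grid position r."""
        m = self.grid.space.ploidy
        lam, u = self._pieces(r)
        num = float(u @ u) / m
        c = num / self.den
        s = 0.5 * self.nt * c - 0.5 * lam.sum()
        delta = np.concatenate([lam - c, [-c]])
        mult = np.concatenate([np.ones(lam.size), [self.nt - lam.size]])
        p = tail_probability(delta, mult, method=method or self.method)
        return s, p


def _candidate_mask(grid: KinshipGrid, indices: list[int],
                    window_cM: float, exclude=()) -> np.ndarray:
    """Positions outside window_cM of every model QTL (minus ``exclude``)."""
    gmap = grid.map
    mask = np.ones(gmap.n_positions, dtype=bool)
    for i in indices:
        if i in exclude:
            continue
        near = (gmap.lg == gmap.lg[i]) & (np.abs(gmap.pos - gmap.pos[i]) <= window_cM)
        mask[near] = False
    return mask


def _best_candidate(ctx: ScanContext, mask: np.ndarray) -> tuple[int, float, float]:
    """Minimum-P candidate; ties broken by lowest LG then lowest cM."""
    gmap = ctx.grid.map
    best = None
    for r in np.where(mask)[0]:
        s, p = ctx.score_test(int(r))
        key = (p, gmap.lg[r], gmap.pos[r])
        if best is None or key < best[0]:
            best = (key, int(r), s, p)
    if best is None:
        return -1, np.nan, np.nan
    return best[1], best[2], best[3]


def resampling_threshold(grid: KinshipGrid, n: int,
                         config: SearchConfig | None = None,
                         rng=None, alphas=None) -> dict[float, float]:
    """Score-based resampling genome-wide P-value thresholds.

    Standard-normal phenotypes are scanned under the no-QTL null; the
    P-value of the genome-wide top score is stored per resample and the
    level-alpha threshold is the alpha-quantile of those minima, so a
    null genome scan crosses it with probability alpha.
    """
    config = config or SearchConfig()
    if alphas is None:
        alphas = (config.forward_alpha, config.backward_alpha)
    alphas = [float(a) for a in np.atleast_1d(alphas)]
    if any(not 0.0 < a < 1.0 for a in alphas):
        raise ValueError("alpha must lie in (0, 1)")
    if config.n_resamples < 100:
        warnings.warn("fewer than 100 resamples gives unstable thresholds")
    if n != grid.n:
        raise ValueError("n must match the number of individuals in the grid")
    rng = np.random.default_rng(rng)

    min_p = np.empty(config.n_resamples)
    for b in range(config.n_resamples):
        ctx = ScanContext(rng.standard_normal(n), grid, [])
        _, _, p = _best_candidate(ctx, np.ones(grid.n_positions, dtype=bool))
        min_p[b] = p
    return {a: float(np.quantile(min_p, a)) for a in alphas}


def forward_search(y, grid: KinshipGrid, model_indices: list[int],
                   p_threshold: float,
                   config: SearchConfig | None = None,
                   warm_start=None) -> list[int]:
    """Add minimum-P positions one at a time while they beat the threshold."""
    config = config or SearchConfig()
    indices = list(model_indices)
    tau = warm_start
    while True:
        ctx = ScanContext(y, grid, indices, warm_start=tau)
        mask = _candidate_mask(grid, indices, config.window_cM)
        if not mask.any():
            break
        r, _, p = _best_candidate(ctx, mask)
        if r < 0 or not (p < p_threshold):
            break
        indices.append(r)
        tau = np.append(ctx.tau, 0.1) if ctx.tau.size else None
    return indices


def optimize_model(y, grid: KinshipGrid, model_indices: list[int],
                   backward_threshold: float,
                   config: SearchConfig | None = None,
                   repeat_forward: bool = True) -> list[int]:
    """Position refinement + backward elimination (+ renewed forward search).

    Iterates until no QTL moves or is dropped; with ``repeat_forward``
    the forward search is then re-run at the backward threshold and the
    optimization repeated until the model is stable.
    """
    config = config or SearchConfig()
    indices = list(model_indices)

    def refine_and_prune(indices: list[int]) -> list[int]:
        seen = {tuple(sorted(indices))}
        for _ in range(config.max_rounds):
            changed = False
            # position refinement, in model-entry order
            for j in range(len(indices)):
                others = indices[:j] + indices[j + 1:]
                ctx = ScanContext(y, grid, others)
                mask = _candidate_mask(grid, others, config.window_cM)
                r, _, _ = _best_candidate(ctx, mask)
                if r >= 0 and r != indices[j]:
                    indices[j] = r
                    changed = True
            # backward elimination: drop the worst failing QTL, one at a time
            worst_j, worst_p = -1, -np.inf
            for j in range(len(indices)):
                others = indices[:j] + indices[j + 1:]
                ctx = ScanContext(y, grid, others)
                _, p = ctx.score_test(indices[j])
                if p >= backward_threshold and p > worst_p:
                    worst_j, worst_p = j, p
            if worst_j >= 0:
                del indices[worst_j]
                changed = True
            if not changed:
                return indices
            state = tuple(sorted(indices))
            if state in seen:  # position-refinement cycle: accept current model
                return indices
            seen.add(state)
        warnings.warn("model optimization did not stabilize within max_rounds")
        return indices

    indices = refine_and_prune(indices)
    if repeat_forward:
        for _ in range(config.max_rounds):
            grown = forward_search(y, grid, indices, backward_threshold, config)
            if grown == indices:
                break
            indices = refine_and_prune(grown)
    return sorted(set(indices))


def _fit_final(y, grid: KinshipGrid, indices: list[int]) -> QTLModel:
    gmap = grid.map
    y = np.asarray(y, dtype=float).ravel()
    if not indices:
        return reml_fit(y, [])
    A, W, _, _ = _helmert_factors(grid)
    m = grid.space.ploidy
    W_cat = np.concatenate([W[i] for i in indices], axis=1)
    tau, sigma2, loglik = _lowrank_reml(A @ y, W_cat, len(indices), m)
    V = np.eye(grid.n)
    for t, i in zip(tau, indices):
        Xi = grid.X[i]
        V += (t / m) * (Xi @ Xi.T)
    Vi_1 = np.linalg.solve(V, np.ones(grid.n))
    mu = float(Vi_1 @ y) / float(Vi_1.sum())
    qtl = [QTL(lg=int(gmap.lg[i]), pos_cM=float(gmap.pos[i]), index=i,
               tau=float(t), sigma2_q=float(t) * sigma2)
           for t, i in zip(tau, indices)]
    return QTLModel(qtl=qtl, sigma2=sigma2, mu=mu, n=grid.n,
                    loglik=loglik, tau=tau)


def profile_qtl(y, grid: KinshipGrid, model_indices: list[int],
                config: SearchConfig | None = None) -> ScanProfile:
    """LOP profile conditional on the final model.

    At each position the conditioning set drops any model QTL within the
    window (so each QTL's own neighborhood is profiled without itself);
    an empty model yields the plain single-QTL genome scan.
    """
    config = config or SearchConfig()
    gmap = grid.map
    P = gmap.n_positions
    score = np.empty(P)
    pval = np.empty(P)

    contexts: dict[frozenset, ScanContext] = {}
    for t in range(P):
        cond = tuple(
            i for i in model_indices
            if gmap.lg[i] != gmap.lg[t] or abs(gmap.pos[i] - gmap.pos[t]) > config.window_cM
        )
        key = frozenset(cond)
        if key not in contexts:
            contexts[key] = ScanContext(y, grid, list(cond))
        score[t], pval[t] = contexts[key].score_test(t)

    model = _fit_final(y, grid, model_indices) if model_indices else None
    profile = ScanProfile(map=gmap, score=score, p_value=pval, model=model)
    if model is not None:
        lop = profile.lop
        for qtl in model.qtl:
            qtl.score, qtl.p_value = score[qtl.index], pval[qtl.index]
            # anchor the support interval at the QTL's own profile peak:
            # hill-climb to the contiguous local maximum around the position
            on_lg = np.where(gmap.lg == qtl.lg)[0]
            j = int(np.where(on_lg == qtl.index)[0][0])
            while j + 1 < on_lg.size and lop[on_lg[j + 1]] > lop[on_lg[j]]:
                j += 1
            while j > 0 and lop[on_lg[j - 1]] > lop[on_lg[j]]:
                j -= 1
            qtl.support = lop_support_interval(profile, int(on_lg[j]), config.d)
    return profile


def lop_support_interval(profile: ScanProfile, peak: int,
                         d: float = 1.5) -> tuple[float, float]:
    """LOP - d support interval around a peak index, clipped at LG ends."""
    gmap = profile.map
    return _support_interval(profile.lop, gmap.lg, gmap.pos, peak, d)


def remim_search(y, grid: KinshipGrid, thresholds: dict[float, float],
                 config: SearchConfig | None = None,
                 repeat_forward: bool = True) -> ScanProfile:
    """Full pipeline: forward search, model optimization, QTL profiling."""
    config = config or SearchConfig()
    t_fwd = thresholds[config.forward_alpha]
    t_bwd = thresholds[config.backward_alpha]
    indices = forward_search(y, grid, [], t_fwd, config)
    indices = optimize_model(y, grid, indices, t_bwd, config,
                             repeat_forward=repeat_forward)
    return profile_qtl(y, grid, indices, config)
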