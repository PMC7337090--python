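"""Fixed-effect interval mapping (FEIM) for autopolyploid full-sib data.

A single-QTL linear model regresses the phenotype on the 2m homolog
inclusion probabilities with one allele effect per homolog; because each
parent's probabilities sum to m/2 across its homologs, the effects of the
first homolog of each parent are constrained to zero, leaving 2m - 2
estimable main effects.  The test at each position is a Gaussian ML
likelihood-ratio against the intercept-only model,

    LRT = n * ln(RSS_0 / RSS_1),    LOD = LRT / (2 ln 10),

with genome-wide significance from permutation of the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinship import KinshipGrid, homolog_dosage
from .statespace import GenotypeStateSpace

__all__ = [
    "FeimDesign",
    "LodProfile",
    "homolog_design",
    "feim_scan",
    "permutation_threshold",
    "lod_support_interval",
    "call_peaks",
]

LOD_SCALE = 2.0 * np.log(10.0)


@dataclass
class FeimDesign:
    """Design matrix of one position after identifiability constraints."""

    X: np.ndarray           # n x (2m - 2) retained effect columns
    dropped: tuple[int, int]
    full: np.ndarray        # n x 2m dosage matrix before dropping

    @property
    def with_intercept(self) -> np.ndarray:
        n = self.X.shape[0]
        return np.column_stack([np.ones(n), self.X])


def homolog_design(Z: np.ndarray, space: GenotypeStateSpace) -> FeimDesign:
    """Build the FEIM design from genotype probabilities at one position."""
    X_full = homolog_dosage(Z, space)
    return design_from_dosage(X_full, space.ploidy)


def design_from_dosage(X_full: np.ndarray, ploidy: int) -> FeimDesign:
    m = ploidy
    keep = [j for j in range(2 * m) if j not in (0, m)]
    return FeimDesign(X=X_full[:, keep], dropped=(0, m), full=X_full)


@dataclass
class LodProfile:
    """Per-position LRT/LOD values over a map, plus an optional threshold."""

    map: "np.ndarray | None"
    lrt: np.ndarray
    lod: np.ndarray
    threshold: float | None = None


def _rss(y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def feim_scan(y, grid: KinshipGrid) -> LodProfile:
    """Gaussian-ML single-QTL scan over every grid position."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    rss0 = float(((y - y.mean()) ** 2).sum())
    lrt = np.empty(grid.n_positions)
    for q in range(grid.n_positions):
        design = design_from_dosage(grid.X[q], grid.space.ploidy).with_intercept
        lrt[q] = n * np.log(rss0 / _rss(y, design))
    lrt = np.clip(lrt, 0.0, None)
    return LodProfile(map=grid.map, lrt=lrt, lod=lrt / LOD_SCALE)


def _projectors(grid: KinshipGrid) -> list[np.ndarray]:
    """Per-position least-squares projectors (pinv) for fast permutation."""
    return [
        np.linalg.pinv(design_from_dosage(grid.X[q], grid.space.ploidy).with_intercept)
        for q in range(grid.n_positions)
    ]


def permutation_threshold(y, grid: KinshipGrid, n_perm: int = 1000,
                          alpha: float = 0.05, rng=None,
                          return_maxima: bool = False):
    """Genome-wide LOD threshold from phenotype permutations.

    Permutes y (designs fixed), records the genome-wide maximum LOD of
    each permutation, and returns the 100(1-alpha) percentile of that
    sample.  ``alpha`` may be a sequence, in which case a dict of
    thresholds is returned.
    """
    alphas = np.atleast_1d(np.asarray(alpha, dtype=float))
    if np.any((alphas <= 0) | (alphas >= 1)):
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size

    Y = np.empty((n, n_perm))
    for b in range(n_perm):
        Y[:, b] = y[rng.permutation(n)]
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    max_lrt = np.full(n_perm, -np.inf)
    for q in range(grid.n_positions):
        design = design_from_dosage(grid.X[q], grid.space.ploidy).with_intercept
        coef = np.linalg.pinv(design) @ Y
        resid = Y - design @ coef
        rss1 = (resid ** 2).sum(axis=0)
        max_lrt = np.maximum(max_lrt, n * np.log(rss0 / rss1))
    max_lod = np.clip(max_lrt, 0.0, None) / LOD_SCALE

    thresholds = {float(a): float(np.quantile(max_lod, 1.0 - a)) for a in alphas}
    out = thresholds if np.ndim(alpha) else thresholds[float(alphas[0])]
    if return_maxima:
        return out, max_lod
    return out


def _support_interval(values: np.ndarray, lg_codes: np.ndarray,
                      pos: np.ndarray, peak: int, d: float) -> tuple[float, float]:
    """Contiguous region around the peak with value >= peak - d, one LG."""
    target = values[peak] - d
    lg = lg_codes[peak]
    on_lg = np.where(lg_codes == lg)[0]
    j = int(np.where(on_lg == peak)[0][0])
    lo = j
    while lo > 0 and values[on_lg[lo - 1]] >= target:
        lo -= 1
    hi = j
    while hi < on_lg.size - 1 and values[on_lg[hi + 1]] >= target:
        hi += 1
    return float(pos[on_lg[lo]]), float(pos[on_lg[hi]])


def lod_support_interval(profile: LodProfile, peak: int, d: float) -> tuple[float, float]:
    """LOD - d support interval around a peak index, clipped at LG ends."""
    gmap = profile.map
    return _support_interval(profile.lod, gmap.lg, gmap.pos, peak, d)


def call_peaks(profile: LodProfile, threshold: float,
               window_cM: float = 20.0) -> list[int]:
    """Greedy peak calling: highest LOD above threshold, mask +/- window, repeat."""
    gmap = profile.map
    lod = profile.lod.copy()
    peaks: list[int] = []
    while True:
        q = int(np.argmax(lod))
        if lod[q] <= threshold or not np.isfinite(lod[q]):
            break
        peaks.append(q)
        mask = (gmap.lg == gmap.lg[q]) & (np.abs(gmap.pos - gmap.pos[q]) <= window_cM)
        lod[mask] = -np.inf
    return peaks
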