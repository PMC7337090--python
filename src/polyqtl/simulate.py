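"""Synthetic autopolyploid full-sib populations and multi-QTL traits.

Meiosis model: at each meiosis the m homologs of a parent pair at random
into m/2 bivalents (a uniform random perfect matching, re-drawn per
meiosis and per chromosome).  Each bivalent transmits one of its two
homologs; along a chromosome the transmitted homolog follows a two-state
Markov chain whose switch probability over an interval of d cM is the
Haldane recombination fraction r(d) = (1 - exp(-2d/100)) / 2.  No
crossover interference, double reduction, or preferential pairing.

Traits are sums of QTL effects drawn directly from their model
distribution g_q ~ N(0, G_q * sigma_q^2) plus iid Gaussian noise, exactly
the generative process the random-effect mapping model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinship import GeneticMap, KinshipGrid
from .statespace import GenotypeStateSpace, build_state_space

__all__ = [
    "MeiosisConfig",
    "TraitSpec",
    "SimTruth",
    "haldane",
    "simulate_gamete",
    "simulate_population",
    "simulate_trait",
    "make_scenario",
    "SimPopulation",
]


def haldane(d_cM) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True)
class MeiosisConfig:
    ploidy: int
    genetic_map: GeneticMap
    n_offspring: int
    seed: int | None = None


@dataclass(frozen=True)
class TraitSpec:
    """QTL architecture of one simulated trait.

    ``qtl`` holds (lg, pos_cM, sigma_q^2) triples; positions must lie on
    the simulation grid.  With residual sigma^2 = 1 the default study
    variances {0.75, 0.50, 0.25} imply heritabilities {0.3, 0.2, 0.1}.
    """

    qtl: tuple[tuple[int, float, float], ...]
    residual_variance: float = 1.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_variance < 0:
            raise ValueError("residual variance must be >= 0")
        for lg, pos, s2 in self.qtl:
            if s2 < 0:
                raise ValueError(f"negative QTL variance at LG {lg} @ {pos} cM")


@dataclass
class SimTruth:
    """Ground truth of one simulated trait: y = mean + sum g_q + eps."""

    y: np.ndarray
    genetic_values: np.ndarray  # (Q, n)
    error: np.ndarray
    spec: TraitSpec

    @property
    def y_offset(self) -> np.ndarray:
        """Error-free phenotype y - eps, for offset experiments."""
        return self.y - self.error


def simulate_gamete(ploidy: int, genetic_map: GeneticMap, rng) -> np.ndarray:
    """One gamete: (n_positions, m/2) transmitted homolog labels (0..m-1)."""
    return _simulate_gametes(ploidy, genetic_map, 1, np.random.default_rng(rng))[0]


def _simulate_gametes(m: int, gmap: GeneticMap, n: int, rng) -> np.ndarray:
    """(n, n_positions, m/2) transmitted labels for n independent meioses."""
    k = m // 2
    out = np.empty((n, gmap.n_positions, k), dtype=np.int64)
    for lg in gmap.groups:
        idx = gmap.indices_of(lg)
        pos = gmap.pos[idx]
        # one random perfect matching per meiosis and per chromosome
        perms = np.stack([rng.permutation(m) for _ in range(n)])  # (n, m)
        bivalents = perms.reshape(n, k, 2)
        side = rng.integers(0, 2, size=(n, k))  # which homolog of each bivalent
        r = haldane(np.diff(pos))
        for j, g in enumerate(idx):
            if j > 0:
                switch = rng.random(size=(n, k)) < r[j - 1]
                side = np.where(switch, 1 - side, side)
            out[:, g, :] = np.take_along_axis(bivalents, side[..., None], axis=2)[..., 0]
    return out


@dataclass
class SimPopulation:
    """True genotype states of a simulated full-sib family plus its grid."""

    config: MeiosisConfig
    states: np.ndarray  # (n, n_positions) state indices
    grid: KinshipGrid

    @property
    def space(self) -> GenotypeStateSpace:
        return self.grid.space


def simulate_population(config: MeiosisConfig,
                        soften: float = 0.0) -> SimPopulation:
    """Simulate n full sibs along the map; Z is one-hot at the true state.

    ``soften`` optionally mixes each probability row with the uniform
    distribution at that weight, emulating residual uncertainty of an
    upstream genotype-probability HMM (default 0: hard truth).
    """
    rng = np.random.default_rng(config.seed)
    space = build_state_space(config.ploidy)
    m, k = config.ploidy, config.ploidy // 2
    gmap = config.genetic_map
    n = config.n_offspring

    gam_a = _simulate_gametes(m, gmap, n, rng)
    gam_b = _simulate_gametes(m, gmap, n, rng)

    lut = np.full(1 << m, -1, dtype=np.int64)  # homolog bitmask -> gamete index
    for i, g in enumerate(space.gamete_index):
        lut[sum(1 << j for j in g)] = i
    mask_a = np.bitwise_or.reduce(1 << gam_a, axis=2)
    mask_b = np.bitwise_or.reduce(1 << gam_b, axis=2)
    ia, ib = lut[mask_a], lut[mask_b]
    states = ia * space.gametes_per_parent + ib  # (n, P)

    # dosage factors X directly from the transmitted labels
    P = gmap.n_positions
    X = np.zeros((P, n, 2 * m))
    rows = np.arange(n)
    for q in range(P):
        for c in range(k):
            X[q, rows, gam_a[:, q, c]] += 1.0
            X[q, rows, m + gam_b[:, q, c]] += 1.0
    if soften > 0.0:
        # uniform Z has homolog inclusion probability 1/2 everywhere
        X = (1.0 - soften) * X + soften * 0.5
    grid = KinshipGrid(gmap, space, X)
    return SimPopulation(config=config, states=states, grid=grid)


def z_from_states(states_q: np.ndarray, space: GenotypeStateSpace,
                  soften: float = 0.0) -> np.ndarray:
    """One-hot (optionally softened) n x p probability matrix at a position."""
    n, p = states_q.size, space.n_states
    Z = np.zeros((n, p))
    Z[np.arange(n), states_q] = 1.0
    if soften > 0.0:
        Z = (1.0 - soften) * Z + soften / p
    return Z


def _draw_mvn(G: np.ndarray, scale: float, rng, jitter: float = 1e-8) -> np.ndarray:
    w, E = np.linalg.eigh(G + jitter * np.eye(G.shape[0]))
    if w.min() < -1e-6:
        raise np.linalg.LinAlgError("kernel not PSD even after jitter")
    w = np.clip(w, 0.0, None)
    return E @ (np.sqrt(w * scale) * rng.standard_normal(w.size))


def simulate_trait(grid: KinshipGrid, spec: TraitSpec, rng=None) -> SimTruth:
    """Draw one trait: g_q ~ N(0, G_q sigma_q^2), eps ~ N(0, sigma^2 I)."""
    rng = np.random.default_rng(rng)
    n = grid.n
    g = np.zeros((len(spec.qtl), n))
    for j, (lg, pos, s2) in enumerate(spec.qtl):
        q = grid.map.locate(lg, pos)
        if s2 > 0:
            g[j] = _draw_mvn(grid.G(q), s2, rng)
    eps = rng.standard_normal(n) * np.sqrt(spec.residual_variance)
    y = spec.mean + g.sum(axis=0) + eps
    return SimTruth(y=y, genetic_values=g, error=eps, spec=spec)


_SCENARIOS = ("unlinked", "random", "linked")


def make_scenario(genetic_map: GeneticMap, scenario: str, rng=None,
                  n_qtl: int = 3) -> list[tuple[int, float]]:
    """Draw QTL positions for one of the three simulation scenarios.

    unlinked: each QTL on a distinct LG.  random: anywhere, but >= 20 cM
    apart when sharing an LG.  linked: two QTL on one LG >= 50 cM apart,
    the remaining QTL on a different LG.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be one of {_SCENARIOS}, got {scenario!r}")
    rng = np.random.default_rng(rng)
    groups = list(genetic_map.groups)

    def draw_on(lg) -> tuple[int, float]:
        idx = genetic_map.indices_of(lg)
        return int(lg), float(genetic_map.pos[rng.choice(idx)])

    if scenario == "unlinked":
        if len(groups) < n_qtl:
            raise ValueError("map needs at least as many LGs as QTL for 'unlinked'")
        chosen = rng.choice(len(groups), size=n_qtl, replace=False)
        return [draw_on(groups[i]) for i in chosen]

    if scenario == "linked":
        lg_pool = [g for g in groups
                   if np.ptp(genetic_map.pos[genetic_map.indices_of(g)]) >= 50.0]
        if not lg_pool or len(groups) < 2:
            raise ValueError("map cannot host two QTL >= 50 cM apart plus a third LG")
        lg1 = lg_pool[rng.integers(len(lg_pool))]
        for _ in range(10_000):
            q1, q2 = draw_on(lg1), draw_on(lg1)
            if abs(q1[1] - q2[1]) >= 50.0:
                break
        else:  # pragma: no cover
            raise ValueError("could not place two QTL >= 50 cM apart")
        others = [g for g in groups if g != lg1]
        extra = [draw_on(others[rng.integers(len(others))])
                 for _ in range(n_qtl - 2)]
        return [q1, q2] + extra

    # random: rejection-sample the 20 cM same-LG separation rule
    for _ in range(10_000):
        qtl = [draw_on(groups[rng.integers(len(groups))]) for _ in range(n_qtl)]
        ok = all(
            a[0] != b[0] or abs(a[1] - b[1]) >= 20.0
            for i, a in enumerate(qtl) for b in qtl[i + 1:]
        )
        if ok:
            return qtl
    raise ValueError("could not satisfy the 20 cM separation rule on this map")
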