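"""Additive relationship (kinship) matrices from genotype probabilities.

At map position q each individual i carries a row ``Z[i]`` of conditional
probabilities over the p genotype states.  The n x n additive relationship
matrix among the full sibs is ``G_q = Z_q Pi Z_q^T``.  Because
``Pi = S S^T / m`` (see :mod:`polyqtl.statespace`), we compute
``G_q = X_q X_q^T / m`` with ``X_q = Z_q S`` the n x 2m matrix of homolog
inclusion probabilities ("dosages") — which is also, up to dropped columns,
the fixed-effect interval mapping design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .statespace import GenotypeStateSpace, PiMatrix

__all__ = [
    "GeneticMap",
    "KinshipGrid",
    "kinship_from_probs",
    "realized_relationship",
    "homolog_dosage",
]

_ROW_SUM_TOL = 1e-6


class InvalidProbabilities(ValueError):
    """A genotype-probability row does not sum to one within tolerance."""


def _check_rows(Z: np.ndarray, tol: float = _ROW_SUM_TOL) -> np.ndarray:
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2:
        raise ValueError("Z must be a 2-D (n x p) matrix")
    sums = Z.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > tol)[0]
    if bad.size:
        raise InvalidProbabilities(
            f"probability rows {bad.tolist()} sum to {sums[bad].tolist()}, "
            f"expected 1 within {tol}"
        )
    return Z / sums[:, None]  # renormalize rounding noise


def homolog_dosage(Z: np.ndarray, space: GenotypeStateSpace) -> np.ndarray:
    """n x 2m homolog inclusion probabilities X = Z S (rows renormalized)."""
    Z = _check_rows(Z)
    if Z.shape[1] != space.n_states:
        raise ValueError(
            f"Z has {Z.shape[1]} columns, state space has {space.n_states} states"
        )
    return Z @ space.incidence()


def kinship_from_probs(Z: np.ndarray, pi: PiMatrix) -> np.ndarray:
    """Additive relationship G = Z Pi Z^T from genotype probabilities.

    Uses the incidence factorization; agrees with the naive double sum
    over all p^2 genotype pairs to 1e-10 (asserted in the test suite).
    """
    X = homolog_dosage(Z, pi.space)
    G = (X @ X.T) / pi.space.ploidy
    return 0.5 * (G + G.T)


@dataclass(frozen=True)
class GeneticMap:
    """Evaluation points of a multi-LG genetic map, positions in cM."""

    lg: np.ndarray  # int codes, one per position
    pos: np.ndarray  # cM within the linkage group

    def __post_init__(self) -> None:
        lg = np.asarray(self.lg, dtype=int)
        pos = np.asarray(self.pos, dtype=float)
        if lg.shape != pos.shape or lg.ndim != 1:
            raise ValueError("lg and pos must be 1-D arrays of equal length")
        for g in np.unique(lg):
            p = pos[lg == g]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions must be strictly increasing within LG {g}")
        object.__setattr__(self, "lg", lg)
        object.__setattr__(self, "pos", pos)

    @classmethod
    def regular_grid(cls, n_lg: int, length_cM: float, step_cM: float) -> "GeneticMap":
        per = np.arange(0.0, length_cM + 1e-9, step_cM)
        return cls(
            lg=np.repeat(np.arange(1, n_lg + 1), per.size),
            pos=np.tile(per, n_lg),
        )

    @property
    def n_positions(self) -> int:
        return self.lg.size

    @property
    def groups(self) -> np.ndarray:
        return np.unique(self.lg)

    def indices_of(self, lg: int) -> np.ndarray:
        return np.where(self.lg == lg)[0]

    def locate(self, lg: int, pos_cM: float, atol: float = 1e-6) -> int:
        """Grid index of an (lg, cM) point; errors if absent."""
        hits = np.where((self.lg == lg) & (np.abs(self.pos - pos_cM) < atol))[0]
        if hits.size != 1:
            raise KeyError(f"position LG {lg} @ {pos_cM} cM not on the map")
        return int(hits[0])


class KinshipGrid:
    """Per-position kinship structure for n individuals along a map.

    Stores the compact n x 2m dosage factors ``X_q``; the dense kernels
    ``G_q = X_q X_q^T / m`` and their restricted-space counterparts are
    materialized on demand and cached, so that hexaploid grids with
    hundreds of positions stay small in memory.
    """

    def __init__(
        self,
        genetic_map: GeneticMap,
        space: GenotypeStateSpace,
        X: np.ndarray,
        Z: Sequence[np.ndarray] | None = None,
        individuals: Sequence[str] | None = None,
    ) -> None:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[0] != genetic_map.n_positions:
            raise ValueError("X must have shape (n_positions, n, 2m)")
        if X.shape[2] != 2 * space.ploidy:
            raise ValueError("X last dimension must equal 2m")
        self.map = genetic_map
        self.space = space
        self.X = X
        self._Z = list(Z) if Z is not None else None
        self.individuals = (
            list(individuals)
            if individuals is not None
            else [f"Ind{i + 1}" for i in range(X.shape[1])]
        )
        self._G_cache: dict[int, np.ndarray] = {}

    @classmethod
    def from_probabilities(
        cls,
        genetic_map: GeneticMap,
        space: GenotypeStateSpace,
        Z_list: Sequence[np.ndarray],
        individuals: Sequence[str] | None = None,
    ) -> "KinshipGrid":
        if len(Z_list) != genetic_map.n_positions:
            raise ValueError("one Z matrix per map position is required")
        S = space.incidence()
        X = np.stack([_check_rows(Z) @ S for Z in Z_list])
        return cls(genetic_map, space, X, Z=Z_list, individuals=individuals)

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def n_positions(self) -> int:
        return self.map.n_positions

    def Z(self, q: int) -> np.ndarray:
        if self._Z is None:
            raise ValueError("this grid was built without stored genotype probabilities")
        return self._Z[q]

    def G(self, q: int) -> np.ndarray:
        """Dense kernel G_q = X_q X_q^T / m (cached)."""
        if q not in self._G_cache:
            Xq = self.X[q]
            G = (Xq @ Xq.T) / self.space.ploidy
            self._G_cache[q] = 0.5 * (G + G.T)
        return self._G_cache[q]

    def iter_G(self) -> Iterator[np.ndarray]:
        for q in range(self.n_positions):
            yield self.G(q)


def realized_relationship(grid: KinshipGrid) -> np.ndarray:
    """Map-averaged relationship matrix, elementwise mean of all G_q.

    Over a dense grid in a full-sib family this approaches 1 on the
    diagonal and 1/2 between any pair of sibs.
    """
    if grid.n_positions == 0:
        raise ValueError("kinship grid is empty")
    total = np.zeros((grid.n, grid.n))
    for q in range(grid.n_positions):
        Xq = grid.X[q]
        total += (Xq @ Xq.T) / grid.space.ploidy
    return total / grid.n_positions
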