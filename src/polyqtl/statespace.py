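"""Genotype state space for autopolyploid full-sib families.

An autopolyploid parent of even ploidy m transmits, under random bivalent
pairing, a gamete holding m/2 of its m labeled homologs; each of the
C(m, m/2) possible gametes is equally likely.  A cross between two such
parents therefore segregates p = C(m, m/2)^2 distinct offspring genotype
classes at any locus (400 for a hexaploid, 36 for a tetraploid, 4,900 for
an octoploid).

The IBD genotype-relationship matrix ``Pi`` records, for every ordered pair
of genotype classes, the proportion of the m homologs they share identical
by descent.  Writing S for the p x 2m binary state-by-homolog incidence
matrix, ``Pi = S S^T / m``, a factorization exploited throughout the
package so that kinship matrices never require the dense p x p product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "GenotypeStateSpace",
    "PiMatrix",
    "enumerate_gametes",
    "build_state_space",
    "build_pi_matrix",
]


def _validate_ploidy(ploidy: int) -> int:
    if not isinstance(ploidy, (int, np.integer)):
        raise ValueError(f"ploidy must be an integer, got {ploidy!r}")
    if ploidy < 2 or ploidy % 2 != 0:
        raise ValueError(f"ploidy must be an even integer >= 2, got {ploidy}")
    return int(ploidy)


def enumerate_gametes(ploidy: int) -> list[tuple[int, ...]]:
    """All size-(m/2) homolog subsets one parent can transmit.

    Homologs are labeled 0..m-1; subsets are returned in lexicographic
    order of their sorted indices, which fixes the gamete indexing used
    everywhere else (I/O, ``Z`` columns, tests).
    """
    m = _validate_ploidy(ploidy)
    return list(combinations(range(m), m // 2))


def homolog_letters(ploidy: int) -> list[str]:
    """Display labels: a..(parent A homologs) then continuing for parent B."""
    m = _validate_ploidy(ploidy)
    return [chr(ord("a") + i) for i in range(2 * m)]


@dataclass(frozen=True)
class GenotypeStateSpace:
    """Combinatorics of one locus in a full-sib autopolyploid cross.

    Parent A owns homologs 0..m-1 (displayed a..), parent B owns
    m..2m-1.  Genotype states are ordered row-major over (parent-A
    gamete, parent-B gamete) with gametes in lexicographic order.
    """

    ploidy: int
    gamete_index: list[tuple[int, ...]] = field(repr=False)

    def __post_init__(self) -> None:
        _validate_ploidy(self.ploidy)

    @property
    def gametes_per_parent(self) -> int:
        return comb(self.ploidy, self.ploidy // 2)

    @property
    def n_states(self) -> int:
        return self.gametes_per_parent ** 2

    @property
    def state_index(self) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
        """Ordered (parent-A gamete, parent-B gamete) pairs.

        Parent-B homolog labels are offset by m so the union of the two
        gametes is a set of m distinct labels out of 2m.
        """
        m = self.ploidy
        return [
            (ga, tuple(j + m for j in gb))
            for ga in self.gamete_index
            for gb in self.gamete_index
        ]

    def state_of(self, gamete_a: int, gamete_b: int) -> int:
        """Row-major state index from the two parental gamete indices."""
        return gamete_a * self.gametes_per_parent + gamete_b

    def state_label(self, state: int) -> str:
        """Human-readable label, e.g. ``'abc|ghi'`` for hexaploids."""
        letters = homolog_letters(self.ploidy)
        ga, gb = self.state_index[state]
        return "".join(letters[i] for i in ga) + "|" + "".join(letters[i] for i in gb)

    def state_from_label(self, label: str) -> int:
        letters = {c: i for i, c in enumerate(homolog_letters(self.ploidy))}
        part_a, part_b = label.split("|")
        m, k = self.ploidy, self.ploidy // 2
        ga = tuple(sorted(letters[c] for c in part_a))
        gb = tuple(sorted(letters[c] - m for c in part_b))
        if len(ga) != k or len(gb) != k:
            raise ValueError(f"state label {label!r} does not hold {k}+{k} homologs")
        lut = {g: i for i, g in enumerate(self.gamete_index)}
        return self.state_of(lut[ga], lut[gb])

    def incidence(self) -> np.ndarray:
        """p x 2m binary matrix S: S[j, h] = 1 iff state j carries homolog h."""
        m = self.ploidy
        S = np.zeros((self.n_states, 2 * m), dtype=np.float64)
        for j, (ga, gb) in enumerate(self.state_index):
            S[j, list(ga)] = 1.0
            S[j, list(gb)] = 1.0
        return S


def build_state_space(ploidy: int) -> GenotypeStateSpace:
    """Construct the ordered genotype state space for an even ploidy."""
    m = _validate_ploidy(ploidy)
    return GenotypeStateSpace(ploidy=m, gamete_index=enumerate_gametes(m))


@dataclass(frozen=True)
class PiMatrix:
    """Dense p x p IBD-sharing matrix with entries k/m, k in 0..m."""

    values: np.ndarray = field(repr=False)
    space: GenotypeStateSpace = field(repr=False)

    @property
    def n_states(self) -> int:
        return self.values.shape[0]


def build_pi_matrix(space: GenotypeStateSpace) -> PiMatrix:
    """IBD genotype-relationship matrix Pi.

    Entry (j, j') is the number of homolog labels the two states share,
    divided by m.  Constructed from exact integer counts via the
    incidence factorization Pi = S S^T / m.
    """
    S = space.incidence()
    counts = S @ S.T  # exact small integers in float form
    return PiMatrix(values=counts / space.ploidy, space=space)
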