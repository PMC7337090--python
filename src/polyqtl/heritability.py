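"""Broad-sense heritability on an entry-mean basis.

For a trait evaluated in L environments with unbalanced replication, the
entry-mean broad-sense heritability is

    H^2 = sigma_g^2 / (sigma_g^2 + sigma_ge^2 / L + sigma_eps^2 / (Kbar L))

where Kbar is the harmonic mean of the number of replicates across
environments.  The variance components come from an externally fitted
multi-environment mixed model; only the ratio is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HeritabilityInputs", "harmonic_mean", "broad_sense_H2"]


def harmonic_mean(counts) -> float:
    """L / sum(1/k) over the replicate counts k."""
    counts = list(counts)
    if not counts or any(k <= 0 for k in counts):
        raise ValueError("replicate counts must be positive")
    return len(counts) / sum(1.0 / k for k in counts)


@dataclass(frozen=True)
class HeritabilityInputs:
    sigma_g2: float
    sigma_ge2: float
    sigma_eps2: float
    n_environments: int
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if min(self.sigma_g2, self.sigma_ge2, self.sigma_eps2) < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_environments != len(self.replicates):
            raise ValueError("one replicate count per environment is required")


def broad_sense_H2(inputs: HeritabilityInputs) -> float:
    """Entry-mean broad-sense heritability, in percent."""
    if inputs.sigma_g2 + inputs.sigma_ge2 + inputs.sigma_eps2 == 0:
        raise ValueError("all variance components are zero")
    L = inputs.n_environments
    kbar = harmonic_mean(inputs.replicates)
    denom = inputs.sigma_g2 + inputs.sigma_ge2 / L + inputs.sigma_eps2 / (kbar * L)
    return 100.0 * inputs.sigma_g2 / denom
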