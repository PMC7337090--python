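"""Characterization of a final multi-QTL model.

Given REML variance components, each QTL's heritability is its variance
component over the total (sum of QTL components plus residual).  BLUPs of
the p genotype-class effects follow the mixed-model equations,

    u_hat_q = sigma_q^2 * Pi Z_q' V^-1 (y - 1 mu_hat),

the individual genetic values are g_hat_q = Z_q u_hat_q, additive allele
effects are means of u_hat over the genotype classes carrying each
homolog (each parent's effects sum to zero), and QTL-based breeding
values are the per-individual sums of g_hat_q across QTL.

All p-dimensional quantities are computed through the incidence
factorization Pi Z' = S (Z S)' / m, so the dense p x p matrix is never
formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import KinshipGrid
from .remim import QTLModel
from .statespace import homolog_letters

__all__ = [
    "QTLSummary",
    "EffectsTable",
    "summarize_model",
    "compute_blups",
    "allele_effects",
    "breeding_values",
]


@dataclass
class QTLSummary:
    """Per-QTL variance components and heritabilities of a fitted model."""

    table: pd.DataFrame  # lg, pos_cM, lower, upper, score, p_value, sigma2_q, h2_pct
    sigma2: float
    total_variance: float

    @property
    def n_qtl(self) -> int:
        return len(self.table)


def summarize_model(model: QTLModel) -> QTLSummary:
    """QTL table with h_q^2 = sigma_q^2 / (sum_q sigma_q^2 + sigma^2)."""
    total = sum(q.sigma2_q for q in model.qtl) + model.sigma2
    rows = []
    for k, q in enumerate(model.qtl, start=1):
        lo, hi = q.support if q.support is not None else (np.nan, np.nan)
        rows.append({
            "qtl": k, "lg": q.lg, "pos_cM": q.pos_cM,
            "ci_lower_cM": lo, "ci_upper_cM": hi,
            "score": q.score, "p_value": q.p_value,
            "sigma2_q": q.sigma2_q, "h2_pct": 100.0 * q.sigma2_q / total,
        })
    cols = ["qtl", "lg", "pos_cM", "ci_lower_cM", "ci_upper_cM",
            "score", "p_value", "sigma2_q", "h2_pct"]
    return QTLSummary(table=pd.DataFrame(rows, columns=cols),
                      sigma2=model.sigma2, total_variance=total)


@dataclass
class EffectsTable:
    """BLUPs and derived effects of every QTL in a model (trait units)."""

    u_hat: np.ndarray            # (Q, p) genotype-class effects
    g_hat: np.ndarray            # (Q, n) individual genetic values
    allele: pd.DataFrame         # Q rows x 2m homolog columns
    individuals: list[str]

    @property
    def n_qtl(self) -> int:
        return self.u_hat.shape[0]


def compute_blups(y, grid: KinshipGrid, model: QTLModel) -> EffectsTable:
    """BLUPs of genotype effects and genetic values for every model QTL."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    m = grid.space.ploidy
    S = grid.space.incidence()

    V = np.eye(n) * model.sigma2
    for q in model.qtl:
        V += q.sigma2_q * grid.G(q.index)
    v = np.linalg.solve(V, y - model.mu)

    Q = len(model.qtl)
    u_hat = np.zeros((Q, grid.space.n_states))
    g_hat = np.zeros((Q, n))
    for j, q in enumerate(model.qtl):
        Xq = grid.X[q.index]
        w = Xq.T @ v                       # 2m-vector
        u_hat[j] = (q.sigma2_q / m) * (S @ w)
        g_hat[j] = (q.sigma2_q / m) * (Xq @ w)

    allele = pd.DataFrame(
        [allele_effects(u, grid.space) for u in u_hat],
        columns=homolog_letters(m),
        index=[f"QTL{j + 1}" for j in range(Q)],
    )
    return EffectsTable(u_hat=u_hat, g_hat=g_hat, allele=allele,
                        individuals=list(grid.individuals))


def allele_effects(u_hat: np.ndarray, space) -> np.ndarray:
    """Additive effect of each homolog: mean of u_hat over states carrying it.

    Every homolog appears in exactly half of the p states, and the
    effects within each parent sum to zero.
    """
    u_hat = np.asarray(u_hat, dtype=float).ravel()
    S = space.incidence()
    if u_hat.size != S.shape[0]:
        raise ValueError("u_hat length does not match the number of genotype states")
    return (S.T @ u_hat) / S.sum(axis=0)


def breeding_values(effects: EffectsTable) -> pd.DataFrame:
    """Per-individual QTL-based breeding values, summed over QTL."""
    if effects.n_qtl == 0:
        raise ValueError("breeding values require at least one QTL")
    totals = effects.g_hat.sum(axis=0)
    return pd.DataFrame({"individual": effects.individuals, "breeding_value": totals})


def breeding_value_correlations(tables: dict[str, EffectsTable]) -> pd.DataFrame:
    """Correlation matrix of breeding values across traits."""
    data = {name: t.g_hat.sum(axis=0) for name, t in tables.items()}
    return pd.DataFrame(data).corr()
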