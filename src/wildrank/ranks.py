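"""Pooled mid-ranks, relative marginal effects, and their covariance estimator.

All observed measurements — across every group and time point — are ranked
jointly with average (mid-) ranks under ties.  The relative marginal effect of
cell (i, j),

    p_ij = ∫ H dF_ij,

measures the tendency of that cell's distribution F_ij against the weighted
pooled distribution H = N^{-1} Σ λ_ijk F_ij; p_ij > 1/2 means cell (i, j)
tends to larger values than the pooled experiment.  With mid-ranks R_ijk the
estimator is the rank average

    p̂_ij = (1/λ_ij·) Σ_k λ_ijk (R_ijk − 1/2) / N .

The covariance estimator of √n (p̂ − p) is group-block-diagonal,
V̂_n = ⊕_i (n / n_i) V̂_i, with entries built from rank deviations over the
observed (and, off-diagonal, pairwise-observed) subjects only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import DesignMeta, IncompleteFactorialData

__all__ = [
    "RankTable",
    "EffectVector",
    "CovarianceEstimate",
    "midranks",
    "relative_effects",
    "covariance_estimate",
]

logger = logging.getLogger(__name__)


@dataclass
class RankTable:
    """Pooled mid-ranks.

    ``R[i]`` is an ``(n_i, d)`` array; entries are mid-ranks among all N
    observed values where observed, and exactly 0 where unobserved (a
    sentinel that multiplies a zero mask in every downstream sum).
    """

    R: list
    observed: list
    N: int

    def rbar(self, lambda_dot: np.ndarray) -> np.ndarray:
        """(a, d) table of per-cell rank means R̄_ij·."""
        sums = np.array([r.sum(axis=0) for r in self.R])
        return sums / lambda_dot


@dataclass
class EffectVector:
    """Relative marginal effect estimates, group-major order (11..1d, 21..ad)."""

    p_hat: np.ndarray
    a: int
    d: int

    def as_table(self) -> np.ndarray:
        return self.p_hat.reshape(self.a, self.d)


@dataclass
class CovarianceEstimate:
    """Block-diagonal V̂_n and its diagonal part D̂_n (both (a·d, a·d))."""

    V_hat: np.ndarray
    D_hat: np.ndarray
    blocks: list


def midranks(data: IncompleteFactorialData) -> RankTable:
    """Mid-ranks of every observed value among all N pooled observations.

    Equivalent to R_ijk = 1/2 + Σ_lms c(X_ijk − X_lms) with the normalized
    counting function c(u) = 0, 1/2, 1 for u < 0, = 0, > 0 summed over all
    observed values; computed by sorting with average tie assignment.
    """
    pooled = np.concatenate([v[m] for v, m in zip(data.values, data.observed)])
    N = pooled.size
    if N < 1:
        raise ValueError("no observed values to rank")
    ranks = rankdata(pooled, method="average")
    R, pos = [], 0
    for v, m in zip(data.values, data.observed):
        r = np.zeros_like(v, dtype=float)
        cnt = int(m.sum())
        r[m] = ranks[pos : pos + cnt]
        pos += cnt
        R.append(r)
    return RankTable(R=R, observed=[m.copy() for m in data.observed], N=N)


def relative_effects(rt: RankTable, meta: DesignMeta) -> EffectVector:
    """Estimate p_ij = ∫ H dF_ij for every cell from the pooled mid-ranks."""
    lam = meta.lambda_dot
    if (lam < 1).any():
        i, j = np.argwhere(lam < 1)[0]
        raise ValueError(f"empty cell (group index {i}, time index {j})")
    a, d = lam.shape
    # R stores 0 at unobserved entries, so a plain sum is the masked sum;
    # subtracting lambda/2 accounts for the -1/2 at observed entries only.
    sums = np.array([r.sum(axis=0) for r in rt.R])
    p = (sums - lam / 2.0) / (lam * rt.N)
    return EffectVector(p_hat=p.reshape(-1), a=a, d=d)


def _group_covariance(
    Z: np.ndarray,
    lam: np.ndarray,
    delta: np.ndarray,
    n_i: int,
    N: int,
) -> np.ndarray:
    """d×d block V̂_i from masked deviations Z (zeros at unobserved entries).

    Diagonal denominator: λ_j (λ_j − 1); off-diagonal:
    (λ_j − 1)(λ_j' − 1) + Δ_jj' − 1.  A non-positive off-diagonal denominator
    (possible only for tiny, barely-overlapping cells) zeroes that entry.
    """
    S = Z.T @ Z  # masked cross-products; the mask is burnt into Z
    lamf = lam.astype(float)
    denom = (lamf[:, None] - 1.0) * (lamf[None, :] - 1.0) + delta - 1.0
    np.fill_diagonal(denom, lamf * (lamf - 1.0))
    bad = denom <= 0
    if bad.any():
        logger.warning(
            "zeroing %d covariance entr(ies) with non-positive denominator",
            int(bad.sum()),
        )
        denom = np.where(bad, np.inf, denom)
    return n_i * S / (N**2 * denom)


def covariance_estimate(rt: RankTable, meta: DesignMeta) -> CovarianceEstimate:
    """Assemble V̂_n = ⊕_i (n/n_i) V̂_i and D̂_n = diag(V̂_n)."""
    lam = meta.lambda_dot
    if (lam < 2).any():
        i, j = np.argwhere(lam < 2)[0]
        raise ValueError(
            f"cell (group index {i}, time index {j}) has fewer than 2 observed "
            "subjects; covariance estimation impossible"
        )
    a, d = lam.shape
    rbar = rt.rbar(lam)
    blocks = []
    for i in range(a):
        m = rt.observed[i].astype(float)
        Z = m * (rt.R[i] - rbar[i][None, :])
        Vi = _group_covariance(Z, lam[i], meta.delta[i].astype(float), int(meta.n[i]), rt.N)
        blocks.append((meta.n_total / meta.n[i]) * Vi)
    V = np.zeros((a * d, a * d))
    for i, b in enumerate(blocks):
        V[i * d : (i + 1) * d, i * d : (i + 1) * d] = b
    return CovarianceEstimate(V_hat=V, D_hat=np.diag(np.diag(V)), blocks=blocks)
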