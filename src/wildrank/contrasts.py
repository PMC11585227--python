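"""Contrast matrices for factorial repeated-measures hypotheses.

A null hypothesis about the vector F = (F_11, ..., F_ad) of cell
distribution functions is written C F = 0 with a contrast matrix C
(rows summing to zero).  With P_m = I_m − J_m/m the centering matrix and
J_m the all-ones matrix, the three standard factorial hypotheses are

    no group effect        C = P_a ⊗ J_d/d
    no time effect         C = J_a/a ⊗ P_d
    no interaction         C = P_a ⊗ P_d

Only the row space of C matters: the projection T = Cᵀ(CCᵀ)⁺C defines the
same hypothesis for every C with that row space, and it is T (plus
f = rank C) that the test statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContrastSpec", "build_contrast", "custom_contrast", "moore_penrose"]

RANK_RTOL = 1e-10  # relative eigen/singular value cutoff


def moore_penrose(M: np.ndarray, rtol: float = RANK_RTOL) -> np.ndarray:
    """Spectral Moore–Penrose pseudoinverse of a symmetric matrix.

    Eigenvalues with magnitude below ``rtol`` times the largest magnitude
    are treated as exact zeros (the zero matrix maps to the zero matrix).
    """
    M = np.asarray(M, dtype=float)
    w, v = np.linalg.eigh(0.5 * (M + M.T))
    keep = np.abs(w) > rtol * np.abs(w).max(initial=0.0)
    winv = np.zeros_like(w)
    winv[keep] = 1.0 / w[keep]
    return (v * winv) @ v.T


@dataclass
class ContrastSpec:
    """A contrast matrix C with its projection T = Cᵀ(CCᵀ)⁺C and f = rank C."""

    C: np.ndarray
    T: np.ndarray
    f: int
    hypothesis: str

    @property
    def dim(self) -> int:
        return self.C.shape[1]


def _finalize(C: np.ndarray, tag: str) -> ContrastSpec:
    C = np.asarray(C, dtype=float)
    sv = np.linalg.svd(C, compute_uv=False)
    f = int(np.sum(sv > RANK_RTOL * sv.max(initial=0.0)))
    T = C.T @ moore_penrose(C @ C.T) @ C
    return ContrastSpec(C=C, T=T, f=f, hypothesis=tag)


def build_contrast(hypothesis: str, a: int, d: int) -> ContrastSpec:
    """Contrast for one of the standard hypotheses ``group|time|interaction``."""
    if a < 1 or d < 1:
        raise ValueError("a and d must be positive")
    P = {m: np.eye(m) - np.ones((m, m)) / m for m in (a, d)}
    J = {m: np.ones((m, m)) / m for m in (a, d)}
    if hypothesis == "group":
        if a < 2:
            raise ValueError("group hypothesis needs at least 2 groups")
        C = np.kron(P[a], J[d])
    elif hypothesis == "time":
        if d < 2:
            raise ValueError("time hypothesis needs at least 2 time points")
        C = np.kron(J[a], P[d])
    elif hypothesis == "interaction":
        if a < 2 or d < 2:
            raise ValueError("interaction hypothesis needs a >= 2 and d >= 2")
        C = np.kron(P[a], P[d])
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    return _finalize(C, hypothesis)


def custom_contrast(C, atol: float = 1e-12) -> ContrastSpec:
    """Validate and wrap a user-supplied contrast matrix (rows sum to 0)."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    rowsums = C.sum(axis=1)
    if np.abs(rowsums).max(initial=0.0) > atol:
        raise ValueError(
            f"not a contrast matrix: row sums {rowsums} exceed tolerance {atol}"
        )
    return _finalize(C, "custom")
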