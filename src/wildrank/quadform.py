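"""Quadratic-form test statistics on the relative-effect scale.

Three statistics test H0: C F = 0 via the estimated effects p̂ and the
covariance estimators V̂_n / D̂_n = diag(V̂_n):

* Wald-type (WTS)   T_W = n (Cp̂)ᵀ [C V̂_n Cᵀ]⁺ (Cp̂),
  asymptotically χ²_f with f = rank(C);
* ANOVA-type (ATS)  T_A = n p̂ᵀ T p̂ / tr(T V̂_n),
  approximated by F(f̂, ∞) with the Box-type
  f̂ = tr(T V̂_n)² / tr(T V̂_n T V̂_n);
* modified ANOVA-type (MATS)  T_M = n (Cp̂)ᵀ [C D̂_n Cᵀ]⁺ (Cp̂),
  whose limit is a weight-dependent mixture of χ²_1 variables — no usable
  asymptotic p-value exists and the wild bootstrap is the only calibration.

The ATS and MATS remain valid when V is singular; the WTS needs V > 0 and is
known to be liberal in small samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contrasts import ContrastSpec, moore_penrose
from .ranks import CovarianceEstimate, EffectVector

__all__ = ["TestResult", "wts", "ats", "mats"]


@dataclass
class TestResult:
    """Outcome of one quadratic-form test.

    ``p_asymptotic`` is None for MATS (its limit law has unknown weights)
    and ``p_bootstrap``/``B``/``weight_scheme``/``seed`` are filled only
    after a wild-bootstrap calibration.
    """

    method: str
    statistic: float
    p_asymptotic: float | None = None
    f: int | None = None
    f_hat: float | None = None
    p_bootstrap: float | None = None
    B: int | None = None
    weight_scheme: str | None = None
    seed: int | None = None
    degenerate_replicates: int = 0

    def to_json(self) -> str:
        def clean(x):
            return None if x is None else (float(x) if not isinstance(x, str) else x)

        return json.dumps(
            {
                "method": self.method,
                "statistic": float(self.statistic),
                "p_asymptotic": clean(self.p_asymptotic),
                "f": None if self.f is None else int(self.f),
                "f_hat": clean(self.f_hat),
                "p_bootstrap": clean(self.p_bootstrap),
                "B": None if self.B is None else int(self.B),
                "weight_scheme": self.weight_scheme,
                "seed": None if self.seed is None else int(self.seed),
                "degenerate_replicates": int(self.degenerate_replicates),
            }
        )

    def report_line(self) -> str:
        df = self.f if self.method == "WTS" else self.f_hat
        fmt = lambda x: "NA" if x is None else f"{x:.6g}"
        return "\t".join(
            [
                self.method,
                f"{self.statistic:.6g}",
                fmt(df),
                fmt(self.p_asymptotic),
                fmt(self.p_bootstrap),
            ]
        )


def _as_vec(p_hat) -> np.ndarray:
    return p_hat.p_hat if isinstance(p_hat, EffectVector) else np.asarray(p_hat, float)


def _as_V(cov) -> np.ndarray:
    return cov.V_hat if isinstance(cov, CovarianceEstimate) else np.asarray(cov, float)


def wts(p_hat, cov, cs: ContrastSpec, n: int) -> TestResult:
    """Wald-type statistic with its χ²_{rank C} asymptotic p-value."""
    p, V = _as_vec(p_hat), _as_V(cov)
    Cp = cs.C @ p
    M = moore_penrose(cs.C @ V @ cs.C.T)
    stat = float(n * Cp @ M @ Cp)
    return TestResult(
        method="WTS",
        statistic=stat,
        f=cs.f,
        p_asymptotic=float(stats.chi2.sf(stat, cs.f)),
    )


def ats(p_hat, cov, cs: ContrastSpec, n: int) -> TestResult:
    """ANOVA-type statistic with the Box-type F(f̂, ∞) approximation.

    F(f̂, ∞) is the law of χ²_{f̂}/f̂ with (generically non-integer) degrees
    of freedom f̂, so the p-value is P(χ²_{f̂} > f̂ · T_A).
    """
    p, V = _as_vec(p_hat), _as_V(cov)
    TV = cs.T @ V
    tr = float(np.trace(TV))
    if tr <= 0:
        raise ValueError("tr(T V̂) <= 0: degenerate design for the ATS")
    stat = float(n * p @ cs.T @ p / tr)
    f_hat = tr**2 / float(np.trace(TV @ TV))
    return TestResult(
        method="ATS",
        statistic=stat,
        f_hat=f_hat,
        p_asymptotic=float(stats.chi2.sf(f_hat * stat, f_hat)),
    )


def mats(p_hat, cov, cs: ContrastSpec, n: int) -> TestResult:
    """Modified ANOVA-type statistic (diagonal studentization, bootstrap-only).

    ``cov`` may be a CovarianceEstimate (its D̂ part is used) or a diagonal
    matrix.  Requires every diagonal variance to be positive.
    """
    p = _as_vec(p_hat)
    D = cov.D_hat if isinstance(cov, CovarianceEstimate) else np.asarray(cov, float)
    diag = np.diag(D)
    if np.any(diag <= 0):
        idx = int(np.argmin(diag))
        raise ValueError(
            f"MATS assumptions fail: estimated variance of cell {idx} is not "
            "positive (e.g. a degenerate, all-tied cell)"
        )
    Cp = cs.C @ p
    M = moore_penrose(cs.C @ D @ cs.C.T)
    stat = float(n * Cp @ M @ Cp)
    return TestResult(method="MATS", statistic=stat, p_asymptotic=None)
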