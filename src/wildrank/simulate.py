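"""Synthetic data generators and Monte Carlo studies.

Continuous repeated measures are generated through a Gaussian copula: a
multivariate normal vector with a chosen correlation structure is mapped
through the standard normal CDF to uniforms and then through the inverse CDF
of the target marginal, so the dependence structure and the marginal law can
be varied independently.  Three covariance settings are provided —

    AR  autoregressive, Σ_lj = 0.6^|l−j|
    CS  independent coordinates, Σ = I_d
    TP  linear Toeplitz, Σ_lj = d − |l−j|

(the copula consumes the correlation matrix Σ_lj / Σ_11).  Ordinal outcomes
on a four-point scale are built from a shared subject-level uniform plus an
independent per-time uniform, giving a compound-symmetric dependence.

Missingness is imposed on complete data either completely at random (MCAR:
every coordinate independently missing with probability r) or at random
conditional on a fully observed "determining" coordinate (MAR1 stratifies
by ±2σ̂, MAR2 by the median).  Masks leaving any (group, time) cell with
fewer than two observed subjects are redrawn, because the covariance
estimator — and hence every test — needs at least two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .bootstrap import run_all_tests
from .contrasts import build_contrast
from .data import IncompleteFactorialData

__all__ = [
    "ScenarioConfig",
    "covariance_matrix",
    "generate_continuous",
    "generate_ordinal",
    "apply_mcar",
    "apply_mar1",
    "apply_mar2",
    "generate_scenario",
    "run_type1_study",
    "run_power_study",
]

MAX_MASK_RETRIES = 1000

MAR_PAIRS = {4: [(0, 1), (2, 3)], 8: [(0, 1), (0, 2), (5, 6), (5, 7)]}

_MARGINAL_PPF = {
    "normal": ndtri,
    "double_exponential": lambda u: stats.laplace.ppf(u),
    "lognormal": lambda u: np.exp(ndtri(u)),
    "chisq15": lambda u: stats.chi2.ppf(u, df=15),
}


def covariance_matrix(setting: str, d: int) -> np.ndarray:
    """Covariance Σ for one of the settings AR, CS, TP (see module docstring)."""
    idx = np.arange(d)
    lag = np.abs(idx[:, None] - idx[None, :])
    if setting == "AR":
        return 0.6**lag
    if setting == "CS":
        return np.eye(d)
    if setting == "TP":
        return (d - lag).astype(float)
    raise ValueError(f"unknown covariance setting {setting!r}")


def _correlation(setting: str, d: int) -> np.ndarray:
    sigma = covariance_matrix(setting, d)
    s = np.sqrt(np.diag(sigma))
    return sigma / np.outer(s, s)


def generate_continuous(
    group_sizes,
    d: int,
    marginal: str = "normal",
    cov_setting: str = "AR",
    shift=None,
    rng: np.random.Generator | None = None,
) -> IncompleteFactorialData:
    """Complete continuous data from a Gaussian copula (no missingness yet).

    ``shift`` (length d) is added on the final scale after the marginal
    transform — a location alternative for power studies.
    """
    rng = np.random.default_rng(rng)
    if marginal not in _MARGINAL_PPF:
        raise ValueError(f"unknown marginal {marginal!r}")
    corr = _correlation(cov_setting, d)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"correlation matrix for setting {cov_setting!r} is not positive "
            "definite"
        ) from None
    ppf = _MARGINAL_PPF[marginal]
    mu = np.zeros(d) if shift is None else np.asarray(shift, dtype=float)
    if mu.shape != (d,):
        raise ValueError("shift must have length d")
    values = []
    for n_i in group_sizes:
        z = rng.standard_normal((n_i, d)) @ L.T
        x = ppf(ndtr(z)) + mu
        values.append(x)
    return IncompleteFactorialData(
        values=values, observed=[np.ones_like(v, dtype=bool) for v in values]
    )


def generate_ordinal(
    group_sizes, d: int, c: float = 1.0, rng: np.random.Generator | None = None
) -> IncompleteFactorialData:
    """Ordinal data X = int(4(cZ + Y)/(c + 1)) + 1 on the scale 1..4.

    Z is uniform per subject (shared over time points), Y uniform per
    measurement; c > 0 tunes the within-subject correlation (compound
    symmetric), with c → 0 giving independent coordinates.
    """
    if c <= 0:
        raise ValueError("c must be > 0")
    rng = np.random.default_rng(rng)
    values = []
    for n_i in group_sizes:
        z = rng.random((n_i, 1))
        y = rng.random((n_i, d))
        x = np.floor(4.0 * (c * z + y) / (c + 1.0)) + 1.0
        values.append(np.minimum(x, 4.0))  # boundary event (cZ+Y = c+1) has mass 0
    return IncompleteFactorialData(
        values=values, observed=[np.ones_like(v, dtype=bool) for v in values]
    )


# ---------------------------------------------------------------------------
# missingness mechanisms
# ---------------------------------------------------------------------------

def _with_mask(data: IncompleteFactorialData, masks) -> IncompleteFactorialData:
    return IncompleteFactorialData(
        values=[v.copy() for v in data.values],
        observed=masks,
        group_labels=list(data.group_labels),
        time_labels=list(data.time_labels),
        subject_labels=None
        if data.subject_labels is None
        else [list(s) for s in data.subject_labels],
    )


def _retry_masks(draw, shapes, max_retries=MAX_MASK_RETRIES):
    """Redraw whole mask sets until every cell keeps >= 2 observed subjects."""
    for attempt in range(max_retries):
        masks = draw()
        if all(m.sum(axis=0).min() >= 2 for m in masks):
            return masks, attempt
    raise RuntimeError(
        f"could not draw a valid missingness mask in {max_retries} attempts; "
        "the design is too small for this missingness rate"
    )


def apply_mcar(
    data: IncompleteFactorialData, r: float, rng: np.random.Generator | None = None
) -> IncompleteFactorialData:
    """Delete each coordinate independently with probability r (MCAR)."""
    if not 0 <= r < 1:
        raise ValueError("missing probability r must be in [0, 1)")
    rng = np.random.default_rng(rng)
    if r == 0:
        return _with_mask(data, [np.ones_like(v, dtype=bool) for v in data.values])

    def draw():
        return [rng.random(v.shape) >= r for v in data.values]

    masks, _ = _retry_masks(draw, None)
    return _with_mask(data, masks)


def _apply_mar(data, rng, stratum_probs):
    if data.d not in MAR_PAIRS:
        raise ValueError("MAR mechanisms are defined for d in {4, 8}")
    pairs = MAR_PAIRS[data.d]
    rng = np.random.default_rng(rng)

    def draw():
        masks = []
        for v in data.values:
            m = np.ones(v.shape, dtype=bool)
            for det, tgt in pairs:
                p_miss = stratum_probs(v[:, det])
                m[:, tgt] &= rng.random(v.shape[0]) >= p_miss
            masks.append(m)
        return masks

    masks, _ = _retry_masks(draw, None)
    return _with_mask(data, masks)


def apply_mar1(
    data: IncompleteFactorialData, rng: np.random.Generator | None = None
) -> IncompleteFactorialData:
    """MAR with ±2σ̂ strata on the determining coordinate of each pair.

    The target coordinate is deleted with probability 15% for subjects in
    the outer strata (beyond two standard deviations of the determining
    coordinate) and 30% in the central stratum.
    """

    def probs(x):
        s = np.std(x, ddof=1)
        inner = np.abs(x) <= 2 * s
        return np.where(inner, 0.30, 0.15)

    return _apply_mar(data, rng, probs)


def apply_mar2(
    data: IncompleteFactorialData, rng: np.random.Generator | None = None
) -> IncompleteFactorialData:
    """MAR with median split: 10% deletion at or below the median, 30% above."""

    def probs(x):
        return np.where(x <= np.median(x), 0.10, 0.30)

    return _apply_mar(data, rng, probs)


# ---------------------------------------------------------------------------
# scenarios and studies
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Configuration of one simulation scenario.

    ``missing`` is one of none/mcar/mar1/mar2 (``r`` applies to MCAR only);
    ``shift`` (length d, added post-copula) makes it a power scenario, the
    all-zero shift the corresponding null.  ``kind`` selects the continuous
    copula generator or the four-point ordinal generator.
    """

    a: int = 1
    d: int = 4
    n: tuple = (15,)
    kind: str = "continuous"
    marginal: str = "normal"
    cov_setting: str = "AR"
    ordinal_c: float = 1.0
    missing: str = "mcar"
    r: float = 0.1
    hypothesis: str = "time"
    shift: tuple = None
    nsim: int = 1000
    B: int = 499
    alpha: float = 0.05
    scheme: str = "rademacher"
    seed: int = 0

    def __post_init__(self):
        self.n = tuple(int(x) for x in np.atleast_1d(self.n))
        if len(self.n) != self.a:
            raise ValueError("len(n) must equal a")
        if not 0 <= self.r < 1:
            raise ValueError("r must be in [0, 1)")
        if self.nsim < 1:
            raise ValueError("nsim must be >= 1")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.missing not in ("none", "mcar", "mar1", "mar2"):
            raise ValueError(f"unknown missing mechanism {self.missing!r}")
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown data kind {self.kind!r}")
        if self.shift is not None:
            self.shift = tuple(float(x) for x in self.shift)
            if len(self.shift) != self.d:
                raise ValueError("shift must have length d")

    @property
    def is_null(self) -> bool:
        return self.shift is None or not any(self.shift)


def generate_scenario(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> IncompleteFactorialData:
    """One dataset under the scenario: generate values, then impose missingness."""
    if cfg.kind == "ordinal":
        data = generate_ordinal(cfg.n, cfg.d, c=cfg.ordinal_c, rng=rng)
    else:
        data = generate_continuous(
            cfg.n, cfg.d, marginal=cfg.marginal, cov_setting=cfg.cov_setting,
            shift=cfg.shift, rng=rng,
        )
    if cfg.missing == "mcar":
        data = apply_mcar(data, cfg.r, rng=rng)
    elif cfg.missing == "mar1":
        data = apply_mar1(data, rng=rng)
    elif cfg.missing == "mar2":
        data = apply_mar2(data, rng=rng)
    return data


STUDY_METHODS = ("WTS_asym", "ATS_asym", "WTS_boot", "ATS_boot", "MATS_boot")


def _study_rejections(cfg: ScenarioConfig) -> dict:
    """Rejection indicators per method over nsim simulated datasets."""
    cs = build_contrast(cfg.hypothesis, cfg.a, cfg.d)
    root = np.random.SeedSequence(cfg.seed)
    rej = {m: np.zeros(cfg.nsim, dtype=bool) for m in STUDY_METHODS}
    for s, child in enumerate(root.spawn(cfg.nsim)):
        rng = np.random.default_rng(child)
        data = generate_scenario(cfg, rng)
        res = run_all_tests(
            data, cs, methods=("WTS", "ATS", "MATS"), scheme=cfg.scheme,
            B=cfg.B, rng=rng,
        )
        rej["WTS_asym"][s] = res["WTS"].p_asymptotic <= cfg.alpha
        rej["ATS_asym"][s] = res["ATS"].p_asymptotic <= cfg.alpha
        rej["WTS_boot"][s] = res["WTS"].p_bootstrap < cfg.alpha
        rej["ATS_boot"][s] = res["ATS"].p_bootstrap < cfg.alpha
        rej["MATS_boot"][s] = res["MATS"].p_bootstrap < cfg.alpha
    return rej


def _rates_frame(rej: dict, nsim: int, extra: dict | None = None) -> pd.DataFrame:
    rows = []
    for method, ind in rej.items():
        rate = float(np.mean(ind))
        rows.append(
            {
                **(extra or {}),
                "method": method,
                "nsim": nsim,
                "rate_percent": 100.0 * rate,
                "mc_se_percent": 100.0 * np.sqrt(rate * (1.0 - rate) / nsim),
            }
        )
    return pd.DataFrame(rows)


def run_type1_study(cfg: ScenarioConfig) -> pd.DataFrame:
    """Empirical type-I error (×100, with Monte Carlo SE) per method."""
    if not cfg.is_null:
        raise ValueError("type-I error study requires a null scenario (no shift)")
    return _rates_frame(_study_rejections(cfg), cfg.nsim)


def run_power_study(
    cfg: ScenarioConfig, zeta_grid, pattern=(0.0, 0.0, 1.0, 1.0)
) -> pd.DataFrame:
    """Rejection rates along a grid of location shifts ζ · pattern.

    The default pattern shifts the last two of four time points (the
    "late-onset effect" alternative); ζ = 0 reproduces the null scenario.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (cfg.d,):
        raise ValueError("pattern must have length d")
    frames = []
    for zeta in zeta_grid:
        cfg_z = ScenarioConfig(
            **{
                **cfg.__dict__,
                "shift": tuple(zeta * pattern),
                "n": cfg.n,
            }
        )
        rej = _study_rejections(cfg_z)
        frames.append(_rates_frame(rej, cfg.nsim, extra={"zeta": float(zeta)}))
    return pd.concat(frames, ignore_index=True)
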