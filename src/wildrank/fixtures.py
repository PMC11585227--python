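"""Small built-in datasets for demonstrations and worked examples."""

from __future__ import annotations

import numpy as np

from .data import IncompleteFactorialData
from .simulate import apply_mcar, generate_continuous

__all__ = ["worked_example", "demo_dataset"]


def worked_example() -> IncompleteFactorialData:
    """One group, four subjects, two time points, one missing value.

    The pooled observed values (1, 3, 2, 4, 2, 3, 5) have mid-ranks
    (1, 4.5, 2.5, 6, 2.5, 4.5, 7), giving relative effects
    p̂ = (12/28, 12.5/21) ≈ (0.4286, 0.5952) — small enough to verify by
    hand, with ties and a missing entry exercising every estimator.
    """
    values = np.array([[1.0, 3.0], [2.0, np.nan], [4.0, 2.0], [3.0, 5.0]])
    return IncompleteFactorialData(values=[values], observed=[~np.isnan(values)])


def demo_dataset(seed: int = 20240) -> IncompleteFactorialData:
    """Synthetic two-group, four-time demo with 10% MCAR missingness."""
    rng = np.random.default_rng(seed)
    data = generate_continuous(
        (12, 15), 4, marginal="lognormal", cov_setting="AR", rng=rng
    )
    return apply_mcar(data, 0.1, rng=rng)
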