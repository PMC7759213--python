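"""Error propagation for fold differences (ligand / vehicle ratios).

All fold differences in this package divide a ligand-treated summary
statistic by the matched vehicle-treated one and carry a first-order
(delta-method) standard error:

    SE_F = F * sqrt((SE_num / num)^2 + (SE_den / den)^2)

A parametric bootstrap of the same ratio is provided as an independent
cross-check of the delta-method formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FoldDifference", "fold_difference", "bootstrap_fold_se"]


@dataclass(frozen=True)
class FoldDifference:
    """A ratio of two uncertain quantities with propagated standard error."""

    value: float
    se: float
    defined: bool = True


def fold_difference(
    numerator: float,
    numerator_se: float,
    denominator: float,
    denominator_se: float,
) -> FoldDifference:
    """Ratio ``numerator / denominator`` with first-order SE propagation.

    The fold is flagged undefined (NaN value and SE) when the denominator
    is nonpositive or nonfinite, mirroring how a vehicle-arm signal at or
    below background makes a fold change meaningless.
    """
    if not np.isfinite(denominator) or denominator <= 0:
        return FoldDifference(float("nan"), float("nan"), defined=False)
    fold = numerator / denominator
    if numerator == 0:
        # relative error of a zero numerator is ill-defined; propagate absolutely
        return FoldDifference(0.0, float(numerator_se / denominator), True)
    rel = (numerator_se / numerator) ** 2 + (denominator_se / denominator) ** 2
    return FoldDifference(float(fold), float(abs(fold) * np.sqrt(rel)), True)


def bootstrap_fold_se(
    numerator: float,
    numerator_se: float,
    denominator: float,
    denominator_se: float,
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap SE of a ratio of two normal summary statistics.

    Draws are Gaussian around the observed summaries; draws with a
    nonpositive denominator are discarded (they correspond to an undefined
    fold). Used to cross-check :func:`fold_difference`.
    """
    rng = np.random.default_rng(seed)
    num = rng.normal(numerator, numerator_se, n_draws)
    den = rng.normal(denominator, denominator_se, n_draws)
    ok = den > 0
    if not ok.any():
        return float("nan")
    return float(np.std(num[ok] / den[ok], ddof=1))
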