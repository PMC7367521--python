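"""Interrater reliability: 3-way percent agreement and multi-rater Gwet AC1.

Results are deemed acceptable when 3-way agreement exceeds 90% and the
Gwet AC1 coefficient exceeds 0.60. AC1 is chance-corrected agreement with
a chance term built from category prevalences, which keeps it stable when
one category dominates (as it does for rare key risks) -- exactly the
regime where kappa-type coefficients collapse.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

PERCENT_THRESHOLD = 90.0
AC1_THRESHOLD = 0.60

_N_RATERS = 3
_N_CATEGORIES = 2


def _validate(matrix) -> np.ndarray:
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[1] != _N_RATERS:
        raise ValueError(f"rater matrix must be items x {_N_RATERS}, got shape {m.shape}")
    if m.shape[0] < 1:
        raise ValueError("rater matrix must contain at least one item")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return m.astype(int)


def percent_agreement_3way(matrix) -> float:
    """Percentage of items on which all three raters agree."""
    m = _validate(matrix)
    unanimous = (m[:, 0] == m[:, 1]) & (m[:, 1] == m[:, 2])
    return 100.0 * float(unanimous.mean())


def gwet_ac1(matrix) -> float:
    """Multi-rater Gwet AC1 for three raters and two categories.

    AC1 = (Pa - Pe) / (1 - Pe), where Pa is the mean over items of
    sum_k r_ik (r_ik - 1) / (r (r - 1)) with r_ik the raters choosing
    category k on item i, and Pe = 1/(q-1) * sum_k pi_k (1 - pi_k) with
    pi_k the mean of r_ik / r. For binary labels Pe <= 0.5, so the
    denominator never degenerates.
    """
    m = _validate(matrix)
    yes = m.sum(axis=1)
    counts = np.stack([_N_RATERS - yes, yes], axis=1)
    pa = float((counts * (counts - 1)).sum(axis=1).mean()) / (_N_RATERS * (_N_RATERS - 1))
    pi = counts.mean(axis=0) / _N_RATERS
    pe = float((pi * (1 - pi)).sum()) / (_N_CATEGORIES - 1)
    assert pe < 1.0, "Pe cannot reach 1 for binary categories"
    return (pa - pe) / (1.0 - pe)


@dataclasses.dataclass
class AgreementResult:
    """Agreement summary for one coded variable."""

    variable: str
    percent_agreement: float
    ac1: float

    @property
    def acceptable(self) -> bool:
        return self.percent_agreement > PERCENT_THRESHOLD and self.ac1 > AC1_THRESHOLD


def assess_agreement(matrices: dict) -> pd.DataFrame:
    """Agreement table over several variables' rater matrices."""
    rows = []
    for variable, matrix in matrices.items():
        result = AgreementResult(
            variable=variable,
            percent_agreement=percent_agreement_3way(matrix),
            ac1=gwet_ac1(matrix),
        )
        rows.append(
            {
                "variable": result.variable,
                "percent_agreement": result.percent_agreement,
                "ac1": result.ac1,
                "acceptable": result.acceptable,
            }
        )
    return pd.DataFrame(rows)
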