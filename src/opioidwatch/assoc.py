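"""Origin contrasts: weighted logistic odds ratios per drug x risk.

The risk indicator is regressed on an origin indicator (social media = 1)
by iteratively reweighted least squares with the sampling weights; with a
single binary predictor the fitted odds ratio is algebraically identical
to the cross-product ratio of the weighted 2x2 table, which is asserted.
Because the weights are design weights rather than frequency weights, the
CI uses a weight-robust sandwich standard error. Odds ratios above 1
indicate higher odds that a risk post originated from social media.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constants import SOCIAL_MEDIA, mention_col

logger = logging.getLogger(__name__)

_MAX_ITER = 100
_TOL = 1e-10


@dataclasses.dataclass
class ORResult:
    """Odds ratio with CI; OR > 1 means higher odds of social-media origin."""

    drug: str
    risk: str
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    log_or: float
    se: float
    note: str = "OR > 1 indicates social media origin"

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_lo <= self.odds_ratio <= self.ci_hi):
            raise ValueError("CI must bracket the odds ratio")


def _irls_logistic(y: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Weighted logistic fit of y on [1, x]; returns (beta, sandwich cov)."""
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    beta = np.zeros(2)
    for _ in range(_MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wls = w * mu * (1.0 - mu)
        score = X.T @ (w * (y - mu))
        info = (X * wls[:, None]).T @ X
        step = np.linalg.solve(info, score)
        beta_new = beta + step
        denom = max(1.0, float(np.abs(beta_new).max()))
        if float(np.abs(step).max()) / denom < _TOL:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = (X * (w * mu * (1.0 - mu))[:, None]).T @ X
    resid = w * (y - mu)
    meat = (X * (resid**2)[:, None]).T @ X
    bread = np.linalg.inv(info)
    cov = bread @ meat @ bread
    return beta, cov


def weighted_2x2(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> dict:
    """Weighted cells: a = risk&social, b = risk&blog, c = no-risk&social,
    d = no-risk&blog."""
    y = y.astype(bool)
    x = x.astype(bool)
    return {
        "a": float(w[y & x].sum()),
        "b": float(w[y & ~x].sum()),
        "c": float(w[~y & x].sum()),
        "d": float(w[~y & ~x].sum()),
    }


def weighted_or(
    sample: pd.DataFrame,
    drug: str,
    risk: str,
    alpha: float = 0.05,
) -> ORResult:
    """Weighted logistic odds ratio for one drug x risk contrast.

    Falls back to a Haldane-Anscombe 0.5 correction on the weighted table
    (with a Woolf-style SE on the corrected cells, logged) only when a
    weighted cell is zero.
    """
    col = mention_col(drug)
    sub = sample[sample[col]] if col in sample.columns else sample
    if len(sub) == 0:
        raise ValueError(f"no posts for drug {drug}")
    y = sub[risk].to_numpy(dtype=float)
    x = (sub["origin_class"] == SOCIAL_MEDIA).to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    cells = weighted_2x2(y, x, w)
    if (cells["a"] + cells["c"]) == 0 or (cells["b"] + cells["d"]) == 0:
        raise ValueError(
            f"{drug}/{risk}: an origin class is empty (cells={cells}); OR undefined"
        )
    z = norm.ppf(1 - alpha / 2)
    if min(cells.values()) == 0.0:
        logger.warning(
            "%s/%s: zero weighted cell %s; applying Haldane-Anscombe 0.5 correction",
            drug,
            risk,
            cells,
        )
        corrected = {k: v + 0.5 for k, v in cells.items()}
        log_or = math.log(
            corrected["a"] * corrected["d"] / (corrected["b"] * corrected["c"])
        )
        se = math.sqrt(sum(1.0 / v for v in corrected.values()))
        note = "continuity-corrected (zero weighted cell)"
    else:
        beta, cov = _irls_logistic(y, x, w)
        log_or = float(beta[1])
        cross = math.log(cells["a"] * cells["d"] / (cells["b"] * cells["c"]))
        assert abs(log_or - cross) < 1e-8, (
            f"logistic OR {log_or} deviates from cross-product {cross}"
        )
        se = float(math.sqrt(cov[1, 1]))
        note = "OR > 1 indicates social media origin"
    return ORResult(
        drug=drug,
        risk=risk,
        odds_ratio=math.exp(log_or),
        ci_lo=math.exp(log_or - z * se),
        ci_hi=math.exp(log_or + z * se),
        log_or=log_or,
        se=se,
        note=note,
    )


def or_table(samples: dict, risks=("misuse", "abuse", "addiction", "overdose", "death")) -> pd.DataFrame:
    """Forest-plot-ready table over per-drug coded samples.

    ``samples`` maps drug -> coded sample frame. Contrasts whose 2x2 table
    is degenerate are reported with missing values and a diagnostic note.
    """
    rows = []
    for drug, sample in samples.items():
        for risk in risks:
            try:
                res = weighted_or(sample, drug, risk)
                rows.append(
                    {
                        "drug": drug,
                        "risk": risk,
                        "odds_ratio": res.odds_ratio,
                        "ci_lo": res.ci_lo,
                        "ci_hi": res.ci_hi,
                        "note": res.note,
                    }
                )
            except ValueError as exc:
                rows.append(
                    {
                        "drug": drug,
                        "risk": risk,
                        "odds_ratio": np.nan,
                        "ci_lo": np.nan,
                        "ci_hi": np.nan,
                        "note": str(exc),
                    }
                )
    return pd.DataFrame(rows)
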