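"""Design-based estimation from the coded, weighted sample.

Point estimates are Horvitz-Thompson expansions (sum of weight x
indicator); variances use the stratified formula with finite-population
correction. Strata that contribute a single sampled unit have no
within-stratum variance estimate, so they are collapsed with the adjacent
stratum of the same origin for variance computation only (a standard
collapsed-stratum device; slightly conservative when stratum means
differ). Confidence intervals are normal-approximation at 95%, truncated
at zero for count scales.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from decimal import Decimal, ROUND_HALF_UP
from scipy.stats import norm

from .constants import BLOGS_FORUMS, RISKS
from .design import StratumSpec

logger = logging.getLogger(__name__)

Z975 = float(norm.ppf(0.975))


@dataclasses.dataclass
class Estimate:
    """A point estimate with its standard error and 95% CI."""

    label: str
    point: float
    se: float
    ci_lo: float
    ci_hi: float
    scale: str  # "count" | "proportion" | "per_10k"
    n_sample: int

    def __post_init__(self):
        if not (self.ci_lo <= self.point + 1e-9 and self.point <= self.ci_hi + 1e-9):
            raise ValueError("CI must bracket the point estimate")


def _variance_groups(strata: Sequence[StratumSpec]) -> np.ndarray:
    """Group index per stratum, merging single-unit strata with a
    neighbouring stratum of the same origin for variance estimation."""
    order = sorted(range(len(strata)), key=lambda i: (strata[i].origin_class, strata[i].start))
    group = np.arange(len(strata))
    by_origin: dict[str, list[int]] = {}
    for i in order:
        by_origin.setdefault(strata[i].origin_class, []).append(i)
    for members in by_origin.values():
        for pos, i in enumerate(members):
            spec = strata[i]
            needs_merge = (spec.n_h or 0) == 1 and spec.N_h > (spec.n_h or 0)
            if needs_merge:
                if pos + 1 < len(members):
                    group[i] = group[members[pos + 1]]
                elif pos > 0:
                    group[i] = group[members[pos - 1]]
    # resolve chains (singleton merged into a singleton merged into ...)
    for i in range(len(strata)):
        g = group[i]
        while group[g] != g:
            g = group[g]
        group[i] = g
    return group


def _grouped_variance(z: np.ndarray, stratum_ids: np.ndarray, strata: Sequence[StratumSpec]) -> float:
    """Stratified variance of a Horvitz-Thompson total from the weighted
    values z_i = w_i * y_i, with FPC, using collapsed variance groups.

    Per group g: V_g = (1 - n_g/N_g) * n_g/(n_g-1) * sum (z_i - zbar_g)^2,
    which reduces to the textbook N^2 (1-f) s^2 / n within one stratum.
    """
    groups = _variance_groups(strata)
    sample_groups = groups[stratum_ids]
    frame = pd.DataFrame({"g": sample_groups, "z": z})
    var = 0.0
    group_N = {}
    for si, spec in enumerate(strata):
        group_N[groups[si]] = group_N.get(groups[si], 0) + spec.N_h
    for g, sub in frame.groupby("g"):
        n_g = len(sub)
        N_g = group_N[g]
        if n_g <= 1:
            if N_g > n_g:
                logger.warning(
                    "variance group with a single sampled unit and N=%d; contributes 0", N_g
                )
            continue
        fpc = 1.0 - n_g / N_g
        zc = sub["z"].to_numpy() - sub["z"].mean()
        var += fpc * n_g / (n_g - 1) * float((zc**2).sum())
    return var


def _check_strata(strata: Sequence[StratumSpec]):
    for spec in strata:
        if (spec.n_h or 0) == 0 and spec.N_h > 0:
            raise ValueError(f"stratum with N_h={spec.N_h} but no sample: weight undefined")


def weighted_total(
    sample: pd.DataFrame,
    indicator: str,
    strata: Sequence[StratumSpec],
    label: Optional[str] = None,
) -> Estimate:
    """Horvitz-Thompson estimate of the population count of posts with a
    positive ``indicator`` column, with FPC stratified variance."""
    _check_strata(strata)
    y = sample[indicator].to_numpy(dtype=float)
    w = sample["weight"].to_numpy(dtype=float)
    sid = sample["stratum"].to_numpy(dtype=int)
    z = w * y
    point = float(z.sum())
    var = _grouped_variance(z, sid, strata)
    se = float(np.sqrt(var))
    ci_lo = max(0.0, point - Z975 * se)
    ci_hi = point + Z975 * se
    return Estimate(
        label=label or indicator,
        point=point,
        se=se,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        scale="count",
        n_sample=len(sample),
    )


def sample_percentage(numerator: int, denominator: int) -> float:
    """Sample percentage rounded half-up to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _quarter_of(ts: pd.Timestamp) -> str:
    return str(pd.Period(ts, freq="Q"))


def quarterly_series(
    sample: pd.DataFrame,
    strata: Sequence[StratumSpec],
    drug: str,
    risk: str,
) -> pd.DataFrame:
    """Estimated posts per 10,000 posts, by calendar quarter.

    The denominator per quarter is the exact population size (sum of N_h;
    the Horvitz-Thompson total of the constant 1 has zero variance), so
    the delta-method CI reduces to scaling the numerator's CI. Folded
    strata spanning a quarter boundary are assigned to the quarter of
    their interval start. Quarters with zero denominator are omitted.
    """
    _check_strata(strata)
    quarters = np.array([_quarter_of(s.start) for s in strata])
    sid = sample["stratum"].to_numpy(dtype=int)
    rows = []
    for q in sorted(set(quarters)):
        in_q = np.flatnonzero(quarters == q)
        denom = sum(strata[i].N_h for i in in_q)
        if denom == 0:
            continue
        mask = np.isin(sid, in_q)
        sub = sample.loc[mask]
        sub_strata = [strata[i] for i in in_q]
        remap = {int(i): j for j, i in enumerate(in_q)}
        z = sub["weight"].to_numpy() * sub[risk].to_numpy(dtype=float)
        local_sid = np.array([remap[int(s)] for s in sub["stratum"]], dtype=int)
        total = float(z.sum())
        var = _grouped_variance(z, local_sid, sub_strata)
        rate = 1e4 * total / denom
        se = 1e4 * float(np.sqrt(var)) / denom
        rows.append(
            {
                "drug": drug,
                "risk": risk,
                "quarter": q,
                "rate": rate,
                "se": se,
                "ci_lo": max(0.0, rate - Z975 * se),
                "ci_hi": min(1e4, rate + Z975 * se),
                "n_sample": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def origin_share(
    sample: pd.DataFrame,
    strata: Sequence[StratumSpec],
    drug: str,
) -> Estimate:
    """Weighted proportion of key-risk posts originating from blogs and
    forums, with a delta-method (ratio estimator) CI."""
    _check_strata(strata)
    risk_any = (
        (sample["misuse_abuse"] != "none")
        | sample["addiction"]
        | sample["overdose"]
        | sample["death"]
    ).to_numpy()
    if not risk_any.any():
        raise ValueError(f"no key-risk posts for {drug}; share undefined")
    blog = (sample["origin_class"] == BLOGS_FORUMS).to_numpy() & risk_any
    w = sample["weight"].to_numpy(dtype=float)
    sid = sample["stratum"].to_numpy(dtype=int)
    y_r = float((w * risk_any).sum())
    y_b = float((w * blog).sum())
    ratio = y_b / y_r
    u = w * (blog.astype(float) - ratio * risk_any.astype(float))
    var_u = _grouped_variance(u, sid, strata)
    se = float(np.sqrt(var_u)) / y_r
    return Estimate(
        label=f"{drug}:blogs_forums_share",
        point=ratio,
        se=se,
        ci_lo=max(0.0, ratio - Z975 * se),
        ci_hi=min(1.0, ratio + Z975 * se),
        scale="proportion",
        n_sample=int(risk_any.sum()),
    )


def table2_shape(estimates: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy estimates (drug, risk, k_sample, point, ci_lo, ci_hi)
    into the report layout: rows = risks, columns = drugs, cells =
    'sample n | estimate (lo-hi)'."""
    cells = {}
    for row in estimates.itertuples(index=False):
        cells.setdefault(row.risk, {})[row.drug] = (
            f"{int(row.k_sample)} | {row.point:.0f} ({row.ci_lo:.0f}-{row.ci_hi:.0f})"
        )
    drugs = sorted({row.drug for row in estimates.itertuples(index=False)})
    out = pd.DataFrame(
        [[cells.get(r, {}).get(d, "") for d in drugs] for r in RISKS],
        index=list(RISKS),
        columns=drugs,
    )
    out.index.name = "risk"
    return out
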