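"""Stratified sample design: week x origin strata, biweekly folding,
hypergeometric-precision sample sizing, proportional allocation, SRSWOR.

The population of screened, retained posts for a drug is partitioned into
strata by 7-day week (half-open blocks counted from the window start) and
origin class. A week cell holding fewer than 2 posts is folded forward
into the next cell of the same origin until the merged cell reaches 2; a
deficient trailing cell folds backward. The per-drug sample size is the
smallest n for which, under a planning hypergeometric model with
K = round(p0*N) population successes, at least ``coverage`` of the exact
tail-inversion confidence intervals attain half-width <= d. Allocation is
proportional with largest-remainder rounding (minimum 1 per nonempty
stratum), and samples are simple random draws without replacement carrying
weight N_h/n_h.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .constants import ORIGINS, mention_col


@dataclasses.dataclass
class DesignParams:
    """Planning parameters for the sample-size solver.

    ``p0`` is the expected proportion, ``d`` the target half-width of the
    95% hypergeometric CI, ``coverage`` the required probability of
    attaining that precision, ``alpha`` the CI level. ``exact_threshold``
    switches the half-width computation to a normal approximation for
    populations larger than the threshold.
    """

    p0: float = 0.05
    d: float = 0.015
    coverage: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    exact_threshold: int = 1_000_000

    def __post_init__(self):
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0,1)")
        if not 0.0 < self.d < 0.5:
            raise ValueError("d must be in (0,0.5)")
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must be in (0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")


@dataclasses.dataclass
class StratumSpec:
    """One (drug, time-interval, origin) sampling cell."""

    drug: str
    start: pd.Timestamp
    end: pd.Timestamp  # exclusive
    origin_class: str
    N_h: int
    n_h: Optional[int] = None

    @property
    def weight(self) -> float:
        if not self.n_h:
            raise ValueError("allocation not filled for stratum")
        return self.N_h / self.n_h


def strata_frame(strata: Sequence[StratumSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug": [s.drug for s in strata],
            "start": [s.start for s in strata],
            "end": [s.end for s in strata],
            "origin_class": [s.origin_class for s in strata],
            "N_h": [s.N_h for s in strata],
            "n_h": [s.n_h for s in strata],
        }
    )


def build_strata(
    screened: pd.DataFrame,
    drug: str,
    window: tuple[datetime.date, datetime.date],
) -> list[StratumSpec]:
    """Count retained drug-flagged posts per week x origin and fold
    deficient cells (N < 2) into neighbouring weeks.

    Returns strata ordered by (origin, start). A drug absent from the
    corpus yields an empty list.
    """
    from .synth import week_bounds  # local import avoids a module cycle

    weeks = week_bounds(window[0], window[1])
    col = mention_col(drug)
    if col not in screened.columns:
        return []
    mask = (~screened["excluded"]) & screened[col]
    sub = screened.loc[mask, ["timestamp", "origin_class"]]
    if sub.empty:
        return []
    start_ts = pd.Timestamp(window[0])
    widx = (
        (pd.to_datetime(sub["timestamp"]) - start_ts).dt.days // 7
    ).clip(upper=len(weeks) - 1)
    strata: list[StratumSpec] = []
    for origin in ORIGINS:
        counts = (
            widx[sub["origin_class"] == origin].value_counts().reindex(range(len(weeks)), fill_value=0)
        )
        merged: list[list] = []  # [start_wi, end_wi, N]
        current: Optional[list] = None
        for wi in range(len(weeks)):
            n_wi = int(counts.iloc[wi])
            if current is None:
                current = [wi, wi, n_wi]
            else:
                current[1] = wi
                current[2] += n_wi
            if current[2] >= 2:
                merged.append(current)
                current = None
        if current is not None:
            # trailing deficient cell merges backward when possible
            if merged:
                merged[-1][1] = current[1]
                merged[-1][2] += current[2]
            elif current[2] > 0:
                merged.append(current)
        for wi_a, wi_b, n_cell in merged:
            if n_cell == 0:
                continue
            strata.append(
                StratumSpec(
                    drug=drug,
                    start=weeks[wi_a][0],
                    end=weeks[wi_b][1],
                    origin_class=origin,
                    N_h=n_cell,
                )
            )
    strata.sort(key=lambda s: (s.origin_class, s.start))
    return strata


# ---------------------------------------------------------------------------
# hypergeometric precision
#
# Exact tail inversion over the population success count K is the inner
# loop of the sample-size solver, evaluated for thousands of (k, K) pairs;
# the tails are computed here from a cached log-factorial table with
# windowed summation (terms more than ~30 SDs from the mean contribute
# < 1e-100 and cannot affect a comparison with alpha/2).

_LNFACT: dict = {"size": -1, "table": None}
_TAIL_WINDOW_SD = 30.0


def _lnfact_table(N: int) -> np.ndarray:
    """table[m + 1] = ln m! for m in 0..N (cached, grown on demand)."""
    if _LNFACT["size"] < N:
        _LNFACT["table"] = gammaln(np.arange(N + 2, dtype=float))
        _LNFACT["size"] = N
    return _LNFACT["table"]


def _hyper_upper_tail(ks: np.ndarray, Ks: np.ndarray, N: int, ns) -> np.ndarray:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), vectorised over
    (k, K, n) triples."""
    tbl = _lnfact_table(N)
    ks = np.asarray(ks, dtype=np.int64)
    Ks = np.asarray(Ks, dtype=np.int64)
    ns = np.broadcast_to(np.asarray(ns, dtype=np.int64), ks.shape)
    x_min = np.maximum(0, ns - (N - Ks))
    x_max = np.minimum(ns, Ks)
    out = np.empty(ks.shape, dtype=float)
    out[ks > x_max] = 0.0
    out[ks <= x_min] = 1.0
    mid = (ks <= x_max) & (ks > x_min)
    if not mid.any():
        return out
    k_m, K_m, n_m = ks[mid], Ks[mid], ns[mid]
    mu = n_m * K_m / N
    var = n_m * (K_m / N) * (1 - K_m / N) * ((N - n_m) / max(N - 1, 1))
    sd = np.maximum(np.sqrt(var), 1.0)
    vals = np.zeros(k_m.shape, dtype=float)
    far_below = k_m < mu - _TAIL_WINDOW_SD * sd  # tail mass within 1e-100 of 1
    far_above = k_m > mu + _TAIL_WINDOW_SD * sd  # tail mass < 1e-100
    vals[far_below] = 1.0
    vals[far_above] = 0.0
    win = ~(far_below | far_above)
    if win.any():
        k_w, K_w, n_w = k_m[win], K_m[win], n_m[win]
        lo_x = k_w
        hi_x = np.minimum(
            x_max[mid][win], np.ceil(mu[win] + _TAIL_WINDOW_SD * sd[win]).astype(np.int64)
        )
        length = int((hi_x - lo_x).max()) + 1
        x = lo_x[:, None] + np.arange(length)[None, :]
        valid = x <= hi_x[:, None]
        xc = np.where(valid, x, lo_x[:, None])
        Kc = K_w[:, None]
        nc = n_w[:, None]
        lpmf = (
            (tbl[Kc + 1] - tbl[xc + 1] - tbl[Kc - xc + 1])
            + (tbl[N - Kc + 1] - tbl[nc - xc + 1] - tbl[N - Kc - (nc - xc) + 1])
            - (tbl[N + 1] - tbl[nc + 1] - tbl[N - nc + 1])
        )
        vals[win] = np.where(valid, np.exp(lpmf), 0.0).sum(axis=1)
    out[mid] = np.clip(vals, 0.0, 1.0)
    return out


def _hyper_lower_tail(ks: np.ndarray, Ks: np.ndarray, N: int, ns) -> np.ndarray:
    """P(X <= k), via the complement-count symmetry n - X ~ Hyp(N, N-K, n)."""
    ks = np.asarray(ks)
    ns = np.broadcast_to(np.asarray(ns, dtype=np.int64), ks.shape)
    return _hyper_upper_tail(ns - ks, N - np.asarray(Ks), N, ns)


def _hyper_pmf(ks: np.ndarray, K: int, N: int, n) -> np.ndarray:
    tbl = _lnfact_table(N)
    ks = np.asarray(ks, dtype=np.int64)
    ns = np.broadcast_to(np.asarray(n, dtype=np.int64), ks.shape)
    ok = (ks >= np.maximum(0, ns - (N - K))) & (ks <= np.minimum(ns, K))
    kc = np.where(ok, ks, 0)
    nc = np.maximum(ns, kc)
    lpmf = (
        tbl[K + 1]
        - tbl[kc + 1]
        - tbl[K - kc + 1]
        + tbl[N - K + 1]
        - tbl[nc - kc + 1]
        - tbl[N - K - (nc - kc) + 1]
        - (tbl[N + 1] - tbl[nc + 1] - tbl[N - nc + 1])
    )
    return np.where(ok, np.exp(lpmf), 0.0)


def _halfwidths_exact(ks: np.ndarray, ns, N: int, alpha: float) -> np.ndarray:
    """Exact tail-inversion CI half-widths, vectorised over (k, n) pairs,
    via binary search over the population success count K (tail
    probabilities are monotone in K)."""
    ks = np.asarray(ks, dtype=np.int64)
    ns = np.broadcast_to(np.asarray(ns, dtype=np.int64), ks.shape)
    a2 = alpha / 2.0
    lo = np.zeros_like(ks)
    hi = np.full_like(ks, N)
    while np.any(lo < hi):
        mid = (lo + hi) // 2
        pred = _hyper_upper_tail(ks, mid, N, ns) > a2
        hi = np.where(pred, mid, hi)
        lo = np.where(pred, lo, mid + 1)
    k_lo = lo
    lo = np.zeros_like(ks)
    hi = np.full_like(ks, N)
    while np.any(lo < hi):
        mid = (lo + hi + 1) // 2
        pred = _hyper_lower_tail(ks, mid, N, ns) > a2
        lo = np.where(pred, mid, lo)
        hi = np.where(pred, hi, mid - 1)
    k_hi = lo
    return (k_hi - k_lo) / (2.0 * N)


def halfwidth(k: int, n: int, N: int, alpha: float = 0.05, exact_threshold: int = 1_000_000) -> float:
    """Half the width of the exact hypergeometric CI for a proportion.

    Lower bound: smallest K/N with upper-tail P(X >= k) > alpha/2; upper
    bound: largest K/N with lower-tail P(X <= k) > alpha/2, for
    X ~ Hypergeometric(N, K, n). A census (n = N) has zero half-width.
    Populations above ``exact_threshold`` use a Wald half-width with
    finite-population correction instead of exact inversion.
    """
    if not (0 <= k <= n <= N) or N < 1:
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if n == N:
        return 0.0
    if N > exact_threshold:
        p = k / n
        z = norm.ppf(1 - alpha / 2)
        return float(z * np.sqrt(p * (1 - p) / n * (1 - n / N)))
    return float(_halfwidths_exact(np.array([k]), n, N, alpha)[0])


def attained_coverage(n: int, N: int, K: int, d: float, alpha: float = 0.05) -> float:
    """P(half-width <= d) when k ~ Hypergeometric(N, K, n).

    Support points with probability mass below 1e-12 are dropped and
    counted as failures (a conservative truncation of order 1e-9).
    """
    if n >= N:
        return 1.0
    k_min = max(0, n - (N - K))
    k_max = min(n, K)
    ks = np.arange(k_min, k_max + 1)
    pmf = _hyper_pmf(ks, K, N, n)
    keep = pmf > 1e-12
    ks, pmf = ks[keep], pmf[keep]
    if ks.size == 0:
        return 0.0
    if N > 1_000_000:
        p = ks / n
        z = norm.ppf(1 - alpha / 2)
        hw = z * np.sqrt(p * (1 - p) / n * (1 - n / N))
    else:
        hw = _halfwidths_exact(ks, n, N, alpha)
    return float(pmf[hw <= d].sum())


def sample_size(N: int, params: DesignParams) -> int:
    """Smallest n whose attained precision coverage meets ``coverage``.

    Scans n upward; n = N always succeeds because a census has zero
    half-width. A cheap rejection step (half-width at the modal k) skips
    full enumeration for clearly insufficient n.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    K = int(np.floor(params.p0 * N + 0.5))
    chunk = 256
    start = 1
    while start <= N:
        ns = np.arange(start, min(start + chunk, N + 1), dtype=np.int64)
        k_min = np.maximum(0, ns - (N - K))
        k_max = np.minimum(ns, K)
        modes = np.clip(((ns + 1) * (K + 1)) // (N + 2), k_min, k_max)
        if N > params.exact_threshold:
            p = np.where(ns > 0, modes / ns, 0.0)
            z = norm.ppf(1 - params.alpha / 2)
            hw = z * np.sqrt(p * (1 - p) / ns * (1 - ns / N))
        else:
            hw = _halfwidths_exact(modes, ns, N, params.alpha)
        pmf_mode = _hyper_pmf(modes, K, N, ns)
        # if the half-width at the modal k misses d and the mode alone holds
        # more mass than the allowed failure rate, coverage cannot be met
        candidate = (hw <= params.d) | (pmf_mode <= 1.0 - params.coverage) | (ns == N)
        for idx in np.flatnonzero(candidate):
            n = int(ns[idx])
            if attained_coverage(n, N, K, params.d, params.alpha) >= params.coverage:
                return n
        start += chunk
    return N


# ---------------------------------------------------------------------------
# allocation and sampling


def allocate(strata: Sequence[StratumSpec], n_total: int) -> list[StratumSpec]:
    """Proportional allocation with largest-remainder rounding.

    Every nonempty stratum receives at least 1; allocations are capped at
    N_h with the surplus redistributed by largest remainder. Ties break on
    stratum order. Returns new StratumSpec instances with n_h filled.
    """
    specs = [s for s in strata]
    sizes = np.array([s.N_h for s in specs], dtype=float)
    total_N = sizes.sum()
    nonempty = sizes > 0
    if n_total > total_N:
        raise ValueError(f"n_total={n_total} exceeds population {int(total_N)}")
    if n_total < int(nonempty.sum()):
        raise ValueError(
            f"n_total={n_total} below the number of nonempty strata ({int(nonempty.sum())})"
        )
    quotas = n_total * sizes / total_N
    alloc = np.floor(quotas).astype(int)
    remainders = quotas - alloc
    leftover = n_total - int(alloc.sum())
    order = sorted(range(len(specs)), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        alloc[i] += 1
    # cap at N_h, redistribute surplus by largest remainder among uncapped
    while True:
        over = alloc - sizes.astype(int)
        surplus = int(over[over > 0].sum())
        if surplus == 0:
            break
        alloc = np.minimum(alloc, sizes.astype(int))
        room = sizes.astype(int) - alloc
        candidates = sorted(
            (i for i in range(len(specs)) if room[i] > 0),
            key=lambda i: (-remainders[i], i),
        )
        ci = 0
        while surplus > 0:
            i = candidates[ci % len(candidates)]
            if alloc[i] < sizes[i]:
                alloc[i] += 1
                surplus -= 1
            ci += 1
    # minimum 1 per nonempty stratum; donors are strata with n >= 2,
    # smallest remainder first (inverse largest-remainder principle)
    while True:
        zeros = [i for i in range(len(specs)) if nonempty[i] and alloc[i] == 0]
        if not zeros:
            break
        donors = sorted(
            (i for i in range(len(specs)) if alloc[i] >= 2),
            key=lambda i: (remainders[i], -i),
        )
        if not donors:
            raise ValueError("cannot satisfy minimum-1 allocation")
        alloc[zeros[0]] = 1
        alloc[donors[0]] -= 1
    out = []
    for spec, n_h in zip(specs, alloc):
        out.append(dataclasses.replace(spec, n_h=int(n_h)))
    return out


class StratifiedSampler:
    """Reusable SRSWOR sampler over a fixed screened corpus and design.

    Precomputes the member rows of each stratum once so repeated draws
    (replicate studies) stay cheap. Draws are deterministic given the seed.
    """

    def __init__(self, strata: Sequence[StratumSpec], screened: pd.DataFrame):
        self.strata = list(strata)
        self._screened = screened.reset_index(drop=True)
        if not self.strata:
            self._members: list[np.ndarray] = []
            return
        drug = self.strata[0].drug
        col = mention_col(drug)
        mask = ((~self._screened["excluded"]) & self._screened[col]).to_numpy()
        rows = np.flatnonzero(mask)
        timestamps = pd.to_datetime(self._screened["timestamp"]).to_numpy()[rows]
        origins = self._screened["origin_class"].to_numpy()[rows]
        members: list[Optional[np.ndarray]] = [None] * len(self.strata)
        by_origin: dict[str, list[int]] = {}
        for i, spec in enumerate(self.strata):
            by_origin.setdefault(spec.origin_class, []).append(i)
        for origin, indices in by_origin.items():
            indices = sorted(indices, key=lambda i: self.strata[i].start)
            starts = np.array([self.strata[i].start for i in indices], dtype="datetime64[ns]")
            ends = np.array([self.strata[i].end for i in indices], dtype="datetime64[ns]")
            sel = np.flatnonzero(origins == origin)
            ts = timestamps[sel]
            pos = np.searchsorted(starts, ts, side="right") - 1
            valid = (pos >= 0) & (ts < ends[np.clip(pos, 0, len(indices) - 1)])
            pos, sel = pos[valid], sel[valid]
            order = np.argsort(pos, kind="stable")
            pos, sel = pos[order], sel[order]
            cuts = np.searchsorted(pos, np.arange(len(indices) + 1))
            for j, i in enumerate(indices):
                members[i] = rows[sel[cuts[j] : cuts[j + 1]]]
        for spec, rows_h in zip(self.strata, members):
            found = 0 if rows_h is None else len(rows_h)
            if found != spec.N_h:
                raise ValueError(
                    f"stratum {spec} expects N_h={spec.N_h} but corpus holds {found} posts"
                )
        self._members = members

    def draw(self, seed: int) -> pd.DataFrame:
        """One stratified sample; attaches ``stratum``, ``weight``,
        ``sample_drug`` columns."""
        rng = np.random.default_rng(seed)
        picks = []
        stratum_ids = []
        weights = []
        for si, spec in enumerate(self.strata):
            if spec.n_h is None:
                raise ValueError("allocation not filled; run allocate() first")
            if spec.n_h > spec.N_h:
                raise ValueError(f"allocation {spec.n_h} exceeds stratum population {spec.N_h}")
            chosen = rng.choice(self._members[si], size=spec.n_h, replace=False)
            picks.append(np.sort(chosen))
            stratum_ids.append(np.full(spec.n_h, si))
            weights.append(np.full(spec.n_h, spec.N_h / spec.n_h))
        if not picks:
            out = self._screened.iloc[[]].copy()
            out["stratum"] = np.array([], dtype=int)
            out["weight"] = np.array([], dtype=float)
            return out
        idx = np.concatenate(picks)
        out = self._screened.take(idx).copy()
        out["stratum"] = np.concatenate(stratum_ids)
        out["weight"] = np.concatenate(weights)
        out["sample_drug"] = self.strata[0].drug
        dup = out["post_id"].duplicated()
        assert not dup.any(), "duplicate post ids in without-replacement sample"
        return out


def draw_sample(strata: Sequence[StratumSpec], screened: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One-shot stratified SRSWOR; see :class:`StratifiedSampler`."""
    return StratifiedSampler(strata, screened).draw(seed)
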