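import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

import opioidwatch as ow
from opioidwatch.design import attained_coverage

WINDOW = (datetime.date(2015, 1, 1), datetime.date(2015, 1, 21))  # 3 weeks


def _screened_frame(weekly_counts, origin=ow.SOCIAL_MEDIA, drug="fentanyl"):
    """Hand-built screened frame with given retained counts per week."""
    rows = []
    for wi, count in enumerate(weekly_counts):
        for j in range(count):
            rows.append(
                {
                    "post_id": f"w{wi}p{j}",
                    "parent_id": None,
                    "timestamp": pd.Timestamp("2015-01-01") + pd.Timedelta(days=7 * wi, hours=j),
                    "site_domain": "twitter.com",
                    "country": "US",
                    "language": "en",
                    "text": drug,
                    "origin_class": origin,
                    "excluded": False,
                    "exclusion_reason": None,
                    f"mentions_{drug}": True,
                }
            )
    return pd.DataFrame(rows)


class TestBuildStrata:
    def test_no_folding_needed(self):
        strata = ow.build_strata(_screened_frame([5, 7, 9]), "fentanyl", WINDOW)
        assert [s.N_h for s in strata] == [5, 7, 9]
        assert all((s.end - s.start) == pd.Timedelta(days=7) for s in strata)

    def test_deficient_week_folds_forward(self):
        strata = ow.build_strata(
            _screened_frame([1, 4]), "fentanyl",
            (datetime.date(2015, 1, 1), datetime.date(2015, 1, 14)),
        )
        assert [s.N_h for s in strata] == [5]
        assert strata[0].end - strata[0].start == pd.Timedelta(days=14)

    def test_trailing_deficient_week_folds_backward(self):
        strata = ow.build_strata(
            _screened_frame([3, 1]), "fentanyl",
            (datetime.date(2015, 1, 1), datetime.date(2015, 1, 14)),
        )
        assert [s.N_h for s in strata] == [4]

    def test_absent_drug_gives_empty_strata(self):
        strata = ow.build_strata(_screened_frame([5, 5, 5]), "oxycodone", WINDOW)
        assert strata == []

    def test_origins_fold_independently(self):
        frame = pd.concat(
            [
                _screened_frame([1, 4, 3]),
                _screened_frame([5, 5, 5], origin=ow.BLOGS_FORUMS),
            ],
            ignore_index=True,
        )
        strata = ow.build_strata(frame, "fentanyl", WINDOW)
        by_origin = {}
        for s in strata:
            by_origin.setdefault(s.origin_class, []).append(s.N_h)
        assert by_origin[ow.SOCIAL_MEDIA] == [5, 3]
        assert by_origin[ow.BLOGS_FORUMS] == [5, 5, 5]

    def test_folding_leaves_no_deficient_stratum(self, study):
        for strata in study["designs"].values():
            assert min(s.N_h for s in strata) >= 2


def _oracle_halfwidth(k, n, N, alpha=0.05):
    """Brute-force tail inversion by enumerating every K (scipy tails)."""
    Ks = np.arange(N + 1)
    sf = hypergeom.sf(k - 1, N, Ks, n)
    cdf = hypergeom.cdf(k, N, Ks, n)
    K_lo = Ks[sf > alpha / 2][0]
    K_hi = Ks[cdf > alpha / 2][-1]
    return (K_hi - K_lo) / (2 * N)


class TestHalfwidth:
    def test_census_has_zero_halfwidth(self):
        assert ow.halfwidth(3, 10, 10) == 0.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        cases = [(0, 10, 100)]
        for _ in range(25):
            N = int(rng.integers(2, 500))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, n + 1))
            cases.append((k, n, N))
        for k, n, N in cases:
            assert ow.halfwidth(k, n, N) == pytest.approx(_oracle_halfwidth(k, n, N), abs=0)

    def test_success_failure_relabeling_symmetry(self):
        for k, n, N in [(5, 10, 100), (3, 10, 100), (0, 17, 60)]:
            assert ow.halfwidth(k, n, N) == ow.halfwidth(n - k, n, N)

    @pytest.mark.parametrize("k,n,N", [(5, 4, 100), (5, 10, 8), (-1, 10, 100)])
    def test_invalid_arguments(self, k, n, N):
        with pytest.raises(ValueError):
            ow.halfwidth(k, n, N)


def _oracle_sample_size(N, params):
    """Upward scan with full enumeration over all k, scipy tails."""
    K = int(np.floor(params.p0 * N + 0.5))
    for n in range(1, N + 1):
        if n == N:
            return N
        ks = np.arange(max(0, n - (N - K)), min(n, K) + 1)
        pmf = hypergeom.pmf(ks, N, K, n)
        good = np.array([_oracle_halfwidth(k, n, N, params.alpha) <= params.d for k in ks])
        if float(pmf[good].sum()) >= params.coverage:
            return n
    return N


class TestSampleSize:
    def test_population_of_one(self):
        assert ow.sample_size(1, ow.DesignParams()) == 1

    def test_vacuous_precision(self):
        assert ow.sample_size(500, ow.DesignParams(d=0.49)) == 1

    @pytest.mark.parametrize("N", [1, 2, 5, 17, 40, 60])
    def test_matches_enumeration_oracle_small(self, N):
        params = ow.DesignParams(p0=0.2, d=0.12)
        assert ow.sample_size(N, params) == _oracle_sample_size(N, params)

    def test_solution_is_minimal_and_sufficient(self):
        """The returned n attains the coverage and n-1 does not, checked
        with scipy tail probabilities."""
        params = ow.DesignParams()
        for N in (1000, 2500):
            n = ow.sample_size(N, params)
            K = int(np.floor(params.p0 * N + 0.5))

            def scipy_ok(n_):
                ks = np.arange(max(0, n_ - (N - K)), min(n_, K) + 1)
                pmf = hypergeom.pmf(ks, N, K, n_)
                keep = pmf > 1e-12
                good = np.array(
                    [_oracle_halfwidth(k, n_, N, params.alpha) <= params.d for k in ks[keep]]
                )
                return float(pmf[keep][good].sum()) >= params.coverage

            assert scipy_ok(n)
            assert not scipy_ok(n - 1)

    def test_monotone_in_precision_and_coverage(self):
        N = 300
        sizes_d = [ow.sample_size(N, ow.DesignParams(d=d)) for d in (0.03, 0.06, 0.12, 0.24)]
        assert sizes_d == sorted(sizes_d, reverse=True)
        sizes_cov = [
            ow.sample_size(N, ow.DesignParams(d=0.05, coverage=c)) for c in (0.8, 0.9, 0.95)
        ]
        assert sizes_cov == sorted(sizes_cov)

    def test_attained_coverage_at_solution(self):
        N, params = 2000, ow.DesignParams()
        n = ow.sample_size(N, params)
        K = int(np.floor(params.p0 * N + 0.5))
        assert attained_coverage(n, N, K, params.d, params.alpha) >= params.coverage


class TestAllocate:
    def _strata(self, sizes):
        return [
            ow.StratumSpec(
                drug="fentanyl",
                start=pd.Timestamp("2015-01-01") + pd.Timedelta(days=7 * i),
                end=pd.Timestamp("2015-01-01") + pd.Timedelta(days=7 * (i + 1)),
                origin_class=ow.SOCIAL_MEDIA,
                N_h=size,
            )
            for i, size in enumerate(sizes)
        ]

    def test_symmetric_split(self):
        alloc = ow.allocate(self._strata([100, 100]), 10)
        assert [s.n_h for s in alloc] == [5, 5]

    def test_largest_remainder_with_tie(self):
        alloc = ow.allocate(self._strata([10, 10, 10]), 10)
        assert [s.n_h for s in alloc] == [4, 3, 3]

    def test_census_limit(self):
        alloc = ow.allocate(self._strata([40]), 40)
        assert alloc[0].n_h == 40
        assert alloc[0].weight == 1.0

    def test_overallocation_rejected(self):
        with pytest.raises(ValueError):
            ow.allocate(self._strata([5, 5]), 11)

    @given(
        sizes=st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=12),
        frac=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_allocation_invariants(self, sizes, frac):
        total = sum(sizes)
        n_total = max(len(sizes), min(total, int(round(frac * total))))
        alloc = ow.allocate(self._strata(sizes), n_total)
        ns = [s.n_h for s in alloc]
        assert sum(ns) == n_total
        assert all(1 <= n_h <= s.N_h for n_h, s in zip(ns, alloc))


class TestDrawSample:
    def test_census_returns_population_with_unit_weights(self):
        frame = _screened_frame([4, 5, 6])
        strata = ow.build_strata(frame, "fentanyl", WINDOW)
        strata = ow.allocate(strata, sum(s.N_h for s in strata))
        sample = ow.draw_sample(strata, frame, seed=1)
        assert len(sample) == len(frame)
        assert (sample["weight"] == 1.0).all()

    def test_deterministic_given_seed(self):
        frame = _screened_frame([10, 12, 14])
        strata = ow.allocate(ow.build_strata(frame, "fentanyl", WINDOW), 9)
        first = ow.draw_sample(strata, frame, seed=7)
        second = ow.draw_sample(strata, frame, seed=7)
        pd.testing.assert_frame_equal(first, second)
        third = ow.draw_sample(strata, frame, seed=8)
        assert set(first["post_id"]) != set(third["post_id"])

    def test_weights_expand_to_population_size(self):
        frame = _screened_frame([10, 12, 14])
        strata = ow.allocate(ow.build_strata(frame, "fentanyl", WINDOW), 9)
        sample = ow.draw_sample(strata, frame, seed=3)
        assert sample["weight"].sum() == pytest.approx(sum(s.N_h for s in strata))

    def test_unique_post_ids(self):
        frame = _screened_frame([10, 12, 14])
        strata = ow.allocate(ow.build_strata(frame, "fentanyl", WINDOW), 20)
        sample = ow.draw_sample(strata, frame, seed=3)
        assert sample["post_id"].is_unique

    def test_unfilled_allocation_rejected(self):
        frame = _screened_frame([10, 12, 14])
        strata = ow.build_strata(frame, "fentanyl", WINDOW)
        with pytest.raises(ValueError):
            ow.draw_sample(strata, frame, seed=1)
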