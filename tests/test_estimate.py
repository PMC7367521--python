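import dataclasses
import datetime

import numpy as np
import pandas as pd
import pytest

import opioidwatch as ow
from tests.conftest import make_small_config


def _design(spec_sizes, alloc, origin=ow.SOCIAL_MEDIA):
    strata = []
    for i, (N_h, n_h) in enumerate(zip(spec_sizes, alloc)):
        strata.append(
            ow.StratumSpec(
                drug="fentanyl",
                start=pd.Timestamp("2015-01-01") + pd.Timedelta(days=7 * i),
                end=pd.Timestamp("2015-01-01") + pd.Timedelta(days=7 * (i + 1)),
                origin_class=origin,
                N_h=N_h,
                n_h=n_h,
            )
        )
    return strata


def _sample(strata, positives):
    """Sample frame with `positives[h]` positive indicators per stratum."""
    rows = []
    for h, spec in enumerate(strata):
        for j in range(spec.n_h):
            rows.append(
                {
                    "post_id": f"s{h}p{j}",
                    "stratum": h,
                    "weight": spec.N_h / spec.n_h,
                    "origin_class": spec.origin_class,
                    "y": j < positives[h],
                }
            )
    return pd.DataFrame(rows)


class TestWeightedTotal:
    def test_hand_horvitz_thompson_expansion(self):
        strata = _design([100, 200], [10, 20])
        sample = _sample(strata, [2, 5])
        est = ow.weighted_total(sample, "y", strata)
        assert est.point == pytest.approx(100 * 2 / 10 + 200 * 5 / 20)  # 70

    def test_census_has_zero_variance(self):
        strata = _design([10, 15], [10, 15])
        sample = _sample(strata, [3, 4])
        est = ow.weighted_total(sample, "y", strata)
        assert est.point == 7
        assert est.se == 0.0
        assert (est.ci_lo, est.ci_hi) == (7.0, 7.0)

    def test_degenerate_indicator(self):
        strata = _design([100, 200], [10, 20])
        sample = _sample(strata, [0, 0])
        est = ow.weighted_total(sample, "y", strata)
        assert est.point == 0.0
        assert (est.ci_lo, est.ci_hi) == (0.0, 0.0)

    def test_variance_matches_textbook_formula(self):
        strata = _design([100, 200], [10, 20])
        sample = _sample(strata, [2, 5])
        est = ow.weighted_total(sample, "y", strata)
        expected = 0.0
        for N, n, k in ((100, 10, 2), (200, 20, 5)):
            p = k / n
            s2 = n / (n - 1) * p * (1 - p)
            expected += N**2 * (1 - n / N) * s2 / n
        assert est.se**2 == pytest.approx(expected, rel=1e-12)

    def test_unsampled_stratum_rejected(self):
        strata = _design([100, 200], [10, 0])
        sample = _sample([strata[0]], [2])
        with pytest.raises(ValueError, match="weight undefined"):
            ow.weighted_total(sample, "y", strata)

    def test_singleton_strata_use_collapsed_variance(self):
        strata = _design([50, 60, 70], [1, 1, 4])
        sample = _sample(strata, [1, 0, 2])
        est = ow.weighted_total(sample, "y", strata)
        assert est.se > 0  # collapsed groups still produce a variance

    def test_sum_consistency_for_constant_indicator(self):
        strata = _design([100, 200, 37], [10, 20, 5])
        sample = _sample(strata, [10, 20, 5])
        est = ow.weighted_total(sample, "y", strata)
        assert est.point == pytest.approx(337)
        assert est.se == pytest.approx(0.0, abs=1e-12)


class TestSamplePercentage:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (485, 24837, 1.95),
            (166, 24837, 0.67),
            (584, 24837, 2.35),
            (379, 24837, 1.53),
            (534, 24837, 2.15),
            (0, 10, 0.0),
            (24837, 24837, 100.0),
            (1, 800, 0.13),  # 0.125 rounds half-up
        ],
    )
    def test_rounding(self, num, den, expected):
        assert ow.sample_percentage(num, den) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ow.sample_percentage(1, 0)
        with pytest.raises(ValueError):
            ow.sample_percentage(5, 4)


class TestQuarterlySeries:
    def test_constant_indicator_rate_is_ten_thousand(self):
        strata = _design([40, 40, 40], [4, 4, 4])
        sample = _sample(strata, [4, 4, 4])
        series = ow.quarterly_series(sample, strata, "fentanyl", "y")
        assert (series["rate"] == 10_000.0).all()

    def test_zero_indicator_rate_is_zero(self):
        strata = _design([40, 40, 40], [4, 4, 4])
        sample = _sample(strata, [0, 0, 0])
        series = ow.quarterly_series(sample, strata, "fentanyl", "y")
        assert (series["rate"] == 0.0).all()

    def test_strata_assigned_to_quarter_of_interval_start(self):
        strata = _design([40] * 14, [4] * 14)  # weeks spill into Q2
        sample = _sample(strata, [0] * 14)
        series = ow.quarterly_series(sample, strata, "fentanyl", "y")
        assert list(series["quarter"]) == ["2015Q1", "2015Q2"]

    def test_simulation_recovery_of_quarterly_rate(self):
        """Mean estimated rate over replicates matches the realized
        population rate within Monte-Carlo error."""
        config = make_small_config(
            end_date=datetime.date(2015, 6, 24),
            weekly_volume={"fentanyl": {ow.SOCIAL_MEDIA: 60, ow.BLOGS_FORUMS: 40}},
            prevalence={"fentanyl": {"overdose": 0.02}},
            origin_effect={"fentanyl": {"overdose": 0.0}},
            spam_fraction=0.0,
            misspelling_prob=0.0,
            non_english_fraction=0.0,
            non_us_fraction=0.0,
            secondary_mention_prob=0.0,
            seed=41,
        )
        corpus, truth = ow.generate_corpus(config)
        screened = ow.screen_corpus(corpus, window=(config.start_date, config.end_date))
        coded = ow.code_sample(screened[~screened["excluded"]].reset_index(drop=True))
        strata = ow.allocate(
            ow.build_strata(coded, "fentanyl", (config.start_date, config.end_date)), 600
        )
        sampler = ow.StratifiedSampler(strata, coded)
        per_quarter = {}
        for rep in range(200):
            series = ow.quarterly_series(sampler.draw(1000 + rep), strata, "fentanyl", "overdose")
            for row in series.itertuples(index=False):
                per_quarter.setdefault(row.quarter, []).append(row.rate)
        truth_rates = truth.totals[truth.totals["risk"] == "overdose"].set_index("quarter")["count"]
        pop_by_quarter = truth.stratum_counts.assign(
            quarter=truth.stratum_counts["week_start"].map(lambda t: str(pd.Period(t, freq="Q")))
        ).groupby("quarter")["N"].sum()
        for quarter, rates in per_quarter.items():
            rates = np.array(rates)
            true_rate = 1e4 * truth_rates.get(quarter, 0) / pop_by_quarter[quarter]
            mc_se = rates.std(ddof=1) / np.sqrt(len(rates))
            assert abs(rates.mean() - true_rate) <= 3 * mc_se, (quarter, rates.mean(), true_rate)


class TestOriginShare:
    def _risk_sample(self, strata, blogs, social):
        rows = []
        for h, spec in enumerate(strata):
            w = spec.N_h / spec.n_h
            for j in range(spec.n_h):
                is_blog = j < blogs[h]
                is_social_risk = blogs[h] <= j < blogs[h] + social[h]
                rows.append(
                    {
                        "post_id": f"s{h}p{j}",
                        "stratum": h,
                        "weight": w,
                        "origin_class": ow.BLOGS_FORUMS if is_blog else ow.SOCIAL_MEDIA,
                        "misuse_abuse": "misuse" if (is_blog or is_social_risk) else "none",
                        "addiction": False,
                        "overdose": False,
                        "death": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_all_key_risk_posts_from_blogs(self):
        strata = _design([100], [10])
        sample = self._risk_sample(strata, blogs=[4], social=[0])
        est = ow.origin_share(sample, strata, "fentanyl")
        assert est.point == 1.0

    def test_hand_single_stratum_ratio(self):
        strata = _design([100], [100])
        sample = self._risk_sample(strata, blogs=[30], social=[70])
        est = ow.origin_share(sample, strata, "fentanyl")
        assert est.point == pytest.approx(0.30)

    def test_no_key_risk_posts_rejected(self):
        strata = _design([100], [10])
        sample = self._risk_sample(strata, blogs=[0], social=[0])
        with pytest.raises(ValueError):
            ow.origin_share(sample, strata, "fentanyl")


class TestReplicateRecovery:
    def test_horvitz_thompson_unbiased_over_replicates(self):
        """Weighted totals average to the (screened) population count."""
        config = make_small_config(
            weekly_volume={d: {ow.SOCIAL_MEDIA: 30, ow.BLOGS_FORUMS: 20} for d in ("fentanyl",)},
            misspelling_prob=0.0,
            seed=77,
        )
        corpus, truth = ow.generate_corpus(config)
        screened = ow.screen_corpus(corpus, window=(config.start_date, config.end_date))
        coded = ow.code_sample(screened[~screened["excluded"]].reset_index(drop=True))
        strata = ow.allocate(
            ow.build_strata(coded, "fentanyl", (config.start_date, config.end_date)), 150
        )
        sampler = ow.StratifiedSampler(strata, coded)
        truth_total = truth.population_total("fentanyl", "addiction")
        points = np.array(
            [ow.weighted_total(sampler.draw(500 + r), "addiction", strata).point for r in range(150)]
        )
        mc_se = points.std(ddof=1) / np.sqrt(len(points))
        assert abs(points.mean() - truth_total) <= 3 * mc_se
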