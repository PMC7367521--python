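import dataclasses
import datetime

import pytest
from hypothesis import HealthCheck, settings

import opioidwatch as ow

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_small_config(**overrides):
    """Four drugs, 12 weeks, small volumes; overridable per test."""
    base = ow.default_config(seed=11)
    small = dataclasses.replace(
        base,
        start_date=datetime.date(2015, 1, 1),
        end_date=datetime.date(2015, 3, 25),
        weekly_volume={
            drug: {ow.SOCIAL_MEDIA: 9, ow.BLOGS_FORUMS: 5} for drug in ow.DRUGS
        },
        surge=None,
    )
    return dataclasses.replace(small, **overrides)


@pytest.fixture(scope="session")
def small_config():
    return make_small_config()


@pytest.fixture(scope="session")
def small_corpus(small_config):
    corpus, truth = ow.generate_corpus(small_config)
    return corpus, truth


@pytest.fixture(scope="session")
def small_screened(small_config, small_corpus):
    corpus, _ = small_corpus
    return ow.screen_corpus(
        corpus, window=(small_config.start_date, small_config.end_date)
    )


@pytest.fixture(scope="session")
def clean_corpus():
    """Small corpus with no misspellings (screening recall is exact)."""
    config = make_small_config(misspelling_prob=0.0, seed=23)
    corpus, truth = ow.generate_corpus(config)
    screened = ow.screen_corpus(corpus, window=(config.start_date, config.end_date))
    return config, corpus, truth, screened


@pytest.fixture(scope="session")
def study():
    """Full-scale study conditions: the default four-drug 2015-2018 corpus
    (~180k posts, 2% misuse prevalence) with misspellings disabled so the
    sampling frame coincides with the latent population, plus the solver
    design and reusable samplers per drug."""
    config = dataclasses.replace(ow.default_config(seed=2027), misspelling_prob=0.0)
    corpus, truth = ow.generate_corpus(config)
    screened = ow.screen_corpus(corpus, window=(config.start_date, config.end_date))
    coded = ow.code_sample(screened[~screened["excluded"]].reset_index(drop=True))
    params = ow.DesignParams()
    designs = {}
    for drug in ow.DRUGS:
        strata = ow.build_strata(coded, drug, (config.start_date, config.end_date))
        total = sum(s.N_h for s in strata)
        n = max(ow.sample_size(total, params), len(strata))
        designs[drug] = ow.allocate(strata, n)
    samplers = {drug: ow.StratifiedSampler(designs[drug], coded) for drug in ow.DRUGS}
    return {
        "config": config,
        "corpus": corpus,
        "truth": truth,
        "screened": screened,
        "coded": coded,
        "designs": designs,
        "samplers": samplers,
        "params": params,
    }
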