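"""Seeded synthetic post corpora with known ground truth.

The generator emulates the structural features of a scraped opioid-mention
corpus so every downstream stage is testable without any real data: weekly
post volumes per drug and origin over a multi-year window, a late-2017
fentanyl volume surge, low key-risk prevalence with origin-dependent odds,
misspelled drug mentions, spam/off-topic contaminants, threaded replies,
and non-English / non-US metadata. Latent labels are planted as marker
phrases from the shared phrasebook, so screening and coding can recover
them deterministically. One RNG stream is used per (drug, week) cell so
that changing one cell's volume never perturbs any other cell.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from typing import Optional

import numpy as np
import pandas as pd

from .coding import Phrasebook
from .constants import BLOGS_FORUMS, DRUGS, ORIGINS, RISKS, SOCIAL_MEDIA
from .posts import RAW_COLUMNS

_CELL_STREAM_LABEL = 101  # domain-separation label for per-cell RNG streams
_RATER_STREAM_LABEL = 202

_SOCIAL_DOMAINS = ("twitter.com", "facebook.com", "myspace.com", "instagram.com", "tumblr.com")
_BLOG_DOMAINS = ("reddit.com", "blogger.com", "wordpress.com", "drugs-forum.com", "medhelp.org")

_BASE_TEMPLATES = (
    "took {drug} for my back pain today and it finally eased off",
    "my doctor switched me to {drug} last month",
    "anyone else get drowsy on {drug} after surgery",
    "the pharmacy finally filled my {drug} script",
    "week three on {drug} for the nerve pain",
)
_SPAM_TEMPLATE = "cheap pills online {drug} no prescription needed limited time offer"
_NON_ENGLISH_TEMPLATE = "tome {drug} anoche y todavia me duele la espalda"
_SECONDARY_TEMPLATE = " a buddy takes {drug} for the same thing"

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclasses.dataclass(frozen=True)
class SurgeSpec:
    """A step increase in one drug's weekly volume from an onset date on."""

    drug: str
    onset: datetime.date
    multiplier: float


@dataclasses.dataclass
class CorpusConfig:
    """Study conditions for a synthetic corpus.

    ``weekly_volume`` maps drug -> origin class -> posts/week.
    ``prevalence`` maps drug -> risk -> probability per analyzed
    blogs/forums post; ``origin_effect`` maps drug -> risk -> log-odds
    shift for social-media posts relative to blogs/forums, so an origin
    contrast is planted directly on the latent labels.
    """

    start_date: datetime.date
    end_date: datetime.date
    weekly_volume: dict
    prevalence: dict
    origin_effect: dict
    surge: Optional[SurgeSpec] = None
    spam_fraction: float = 0.08
    misspelling_prob: float = 0.05
    reply_fraction: float = 0.15
    secondary_mention_prob: float = 0.03
    non_english_fraction: float = 0.01
    non_us_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.end_date < self.start_date:
            raise ValueError("end_date must be >= start_date")
        for drug, by_origin in self.weekly_volume.items():
            for origin, vol in by_origin.items():
                if origin not in ORIGINS:
                    raise ValueError(f"unknown origin {origin!r} for {drug}")
                if vol < 0:
                    raise ValueError(f"negative volume for {drug}/{origin}")
        for drug, by_risk in self.prevalence.items():
            for risk, p in by_risk.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence {p} for {drug}/{risk} outside [0,1]")
        if self.surge is not None and self.surge.multiplier < 1:
            raise ValueError("surge multiplier must be >= 1")
        for frac_name in (
            "spam_fraction",
            "misspelling_prob",
            "reply_fraction",
            "secondary_mention_prob",
            "non_english_fraction",
            "non_us_fraction",
        ):
            value = getattr(self, frac_name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{frac_name}={value} outside [0,1]")

    def drugs(self) -> tuple[str, ...]:
        return tuple(self.weekly_volume)


def default_config(seed: int = 0) -> CorpusConfig:
    """The default study conditions: 2015-2018 window, four drugs, a more
    than tenfold fentanyl surge from late 2017, key-risk prevalences in the
    0.5-2.5% band, and origin effects with the pattern seen in this kind
    of surveillance (fentanyl overdose/death skewed to social media,
    abuse/addiction to blogs and forums)."""
    prevalence_row = {
        "misuse": 0.020,
        "abuse": 0.007,
        "addiction": 0.023,
        "overdose": 0.015,
        "death": 0.021,
    }
    origin_effect = {
        "fentanyl": {
            "misuse": 0.0,
            "abuse": math.log(0.10),
            "addiction": math.log(0.24),
            "overdose": math.log(4.32),
            "death": math.log(5.05),
        },
        "hydrocodone": {
            "misuse": math.log(0.7),
            "abuse": math.log(0.8),
            "addiction": math.log(0.35),
            "overdose": math.log(1.5),
            "death": math.log(2.0),
        },
        "oxycodone": {
            "misuse": math.log(0.7),
            "abuse": math.log(0.8),
            "addiction": math.log(0.30),
            "overdose": math.log(1.5),
            "death": math.log(2.0),
        },
        "oxymorphone": {
            "misuse": math.log(0.7),
            "abuse": math.log(0.8),
            "addiction": math.log(0.46),
            "overdose": math.log(1.5),
            "death": math.log(2.0),
        },
    }
    return CorpusConfig(
        start_date=datetime.date(2015, 1, 1),
        end_date=datetime.date(2018, 12, 31),
        weekly_volume={
            "fentanyl": {SOCIAL_MEDIA: 70, BLOGS_FORUMS: 12},
            "hydrocodone": {SOCIAL_MEDIA: 210, BLOGS_FORUMS: 48},
            "oxycodone": {SOCIAL_MEDIA: 190, BLOGS_FORUMS: 40},
            "oxymorphone": {SOCIAL_MEDIA: 40, BLOGS_FORUMS: 36},
        },
        prevalence={drug: dict(prevalence_row) for drug in DRUGS},
        origin_effect=origin_effect,
        surge=SurgeSpec("fentanyl", datetime.date(2017, 10, 1), 10.0),
        seed=seed,
    )


def week_bounds(start: datetime.date, end: datetime.date) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Half-open 7-day blocks [t, t+7d) from ``start``; the final partial
    block is its own week. ``end`` is the inclusive last calendar day."""
    if end < start:
        raise ValueError("empty date range")
    bounds = []
    cursor = pd.Timestamp(start)
    stop = pd.Timestamp(end) + pd.Timedelta(days=1)
    while cursor < stop:
        nxt = min(cursor + pd.Timedelta(days=7), stop)
        bounds.append((cursor, nxt))
        cursor = nxt
    return bounds


@dataclasses.dataclass
class GroundTruth:
    """Latent labels and exact population quantities for a synthetic corpus.

    ``posts`` carries one row per generated post (drug flags, risk flags,
    excludability, origin, week index). ``stratum_counts`` gives the true
    non-excludable population count per (drug, week, origin) cell, and
    ``totals`` the true risk counts per drug x risk x calendar quarter
    (quarters keyed by week start date).
    """

    posts: pd.DataFrame
    stratum_counts: pd.DataFrame
    totals: pd.DataFrame
    weeks: list
    config: CorpusConfig

    def population_total(self, drug: str, risk: str) -> int:
        """True number of non-excludable posts flagged with ``drug`` whose
        latent ``risk`` label is positive."""
        mask = (~self.posts["excludable"]) & self.posts["drugs"].str.contains(drug) & self.posts[risk]
        return int(mask.sum())


def _risk_probability(base: float, effect: float, social: bool) -> float:
    if not social or effect == 0.0 or base in (0.0, 1.0):
        return base
    return _expit(_logit(base) + effect)


def _misspell(word: str, rng: np.random.Generator) -> str:
    """One random substitution; usually lands outside the lexicon."""
    pos = int(rng.integers(0, len(word)))
    repl = _LETTERS[int(rng.integers(0, 26))]
    while repl == word[pos]:
        repl = _LETTERS[int(rng.integers(0, 26))]
    return word[: pos] + repl + word[pos + 1 :]


def generate_corpus(config: CorpusConfig, phrasebook: Optional[Phrasebook] = None):
    """Generate a corpus and its ground truth. Deterministic given config."""
    phrasebook = phrasebook or Phrasebook.load_default()
    weeks = week_bounds(config.start_date, config.end_date)
    drugs = config.drugs()
    rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for di, drug in enumerate(drugs):
        volumes = config.weekly_volume[drug]
        by_risk = config.prevalence.get(drug, {})
        effects = config.origin_effect.get(drug, {})
        for wi, (wstart, wend) in enumerate(weeks):
            mult = 1.0
            if (
                config.surge is not None
                and config.surge.drug == drug
                and wstart >= pd.Timestamp(config.surge.onset)
            ):
                mult = config.surge.multiplier
            rng = np.random.default_rng([config.seed, _CELL_STREAM_LABEL, di, wi])
            week_seconds = int((wend - wstart).total_seconds())
            for origin in ORIGINS:
                n = int(round(volumes.get(origin, 0) * mult))
                if n == 0:
                    continue
                social = origin == SOCIAL_MEDIA
                domains = _SOCIAL_DOMAINS if social else _BLOG_DOMAINS
                offsets = rng.integers(0, week_seconds, size=n)
                spam = rng.random(n) < config.spam_fraction
                non_en = rng.random(n) < config.non_english_fraction
                non_us = rng.random(n) < config.non_us_fraction
                reply = rng.random(n) < config.reply_fraction
                secondary = rng.random(n) < config.secondary_mention_prob
                misspelled = rng.random(n) < config.misspelling_prob
                analyzed = ~(spam | non_en | non_us)

                p_abuse = _risk_probability(by_risk.get("abuse", 0.0), effects.get("abuse", 0.0), social)
                p_misuse = _risk_probability(by_risk.get("misuse", 0.0), effects.get("misuse", 0.0), social)
                abuse = analyzed & (rng.random(n) < p_abuse)
                # conditional draw keeps the misuse marginal exactly at its
                # configured value despite misuse/abuse exclusivity
                p_mis_cond = min(1.0, p_misuse / (1.0 - p_abuse)) if p_abuse < 1.0 else 0.0
                misuse = analyzed & ~abuse & (rng.random(n) < p_mis_cond)
                flags = {"misuse": misuse, "abuse": abuse}
                for risk in ("addiction", "overdose", "death"):
                    p = _risk_probability(by_risk.get(risk, 0.0), effects.get(risk, 0.0), social)
                    flags[risk] = analyzed & (rng.random(n) < p)

                cell_ids = []
                for j in range(n):
                    post_id = f"{drug[:2]}{di}-w{wi:03d}-{'s' if social else 'b'}-{j:05d}"
                    cell_ids.append(post_id)
                    ts = wstart + pd.Timedelta(seconds=int(offsets[j]))
                    domain = domains[int(rng.integers(0, len(domains)))]
                    country = "US"
                    language = "en"
                    parent_id = None
                    if reply[j] and j > 0 and not spam[j]:
                        parent_id = cell_ids[int(rng.integers(0, j))]

                    surface = drug
                    if misspelled[j]:
                        surface = _misspell(drug, rng)

                    if spam[j]:
                        text = _SPAM_TEMPLATE.format(drug=surface)
                        true_reason = "spam"
                    elif non_en[j]:
                        text = _NON_ENGLISH_TEMPLATE.format(drug=surface)
                        language = "es"
                        true_reason = "non_english"
                    elif non_us[j]:
                        template = _BASE_TEMPLATES[int(rng.integers(0, len(_BASE_TEMPLATES)))]
                        text = template.format(drug=surface)
                        country = ("CA", "GB", "AU")[int(rng.integers(0, 3))]
                        true_reason = "non_us"
                    else:
                        template = _BASE_TEMPLATES[int(rng.integers(0, len(_BASE_TEMPLATES)))]
                        text = template.format(drug=surface)
                        true_reason = None
                        for risk in RISKS:
                            if flags[risk][j]:
                                markers = phrasebook.markers[risk]
                                text += ". " + markers[int(rng.integers(0, len(markers)))]

                    post_drugs = [drug]
                    if secondary[j] and len(drugs) > 1 and not spam[j]:
                        other = drugs[int(rng.integers(0, len(drugs)))]
                        if other == drug:
                            other = drugs[(drugs.index(other) + 1) % len(drugs)]
                        text += _SECONDARY_TEMPLATE.format(drug=other)
                        post_drugs.append(other)

                    rows.append((post_id, parent_id, ts, domain, country, language, text))
                    truth_rows.append(
                        (
                            post_id,
                            drug,
                            "|".join(post_drugs),
                            origin,
                            wi,
                            true_reason is not None,
                            true_reason,
                            bool(flags["misuse"][j]),
                            bool(flags["abuse"][j]),
                            bool(flags["addiction"][j]),
                            bool(flags["overdose"][j]),
                            bool(flags["death"][j]),
                            bool(misspelled[j]),
                        )
                    )

    corpus = pd.DataFrame(rows, columns=RAW_COLUMNS)
    truth_posts = pd.DataFrame(
        truth_rows,
        columns=[
            "post_id",
            "primary_drug",
            "drugs",
            "origin_class",
            "week_index",
            "excludable",
            "true_reason",
            "misuse",
            "abuse",
            "addiction",
            "overdose",
            "death",
            "misspelled",
        ],
    )
    stratum_counts, totals = _summarise_truth(truth_posts, weeks, drugs)
    truth = GroundTruth(
        posts=truth_posts,
        stratum_counts=stratum_counts,
        totals=totals,
        weeks=weeks,
        config=config,
    )
    return corpus, truth


def _summarise_truth(truth_posts: pd.DataFrame, weeks, drugs):
    if truth_posts.empty:
        empty_counts = pd.DataFrame(
            columns=["drug", "week_index", "week_start", "week_end", "origin_class", "N"]
        )
        empty_totals = pd.DataFrame(columns=["drug", "risk", "quarter", "count"])
        return empty_counts, empty_totals
    kept = truth_posts[~truth_posts["excludable"]].copy()
    kept["drug_list"] = kept["drugs"].str.split("|")
    exploded = kept.explode("drug_list")
    counts = (
        exploded.groupby(["drug_list", "week_index", "origin_class"], sort=True)
        .size()
        .reset_index(name="N")
        .rename(columns={"drug_list": "drug"})
    )
    counts["week_start"] = counts["week_index"].map(lambda i: weeks[i][0])
    counts["week_end"] = counts["week_index"].map(lambda i: weeks[i][1])
    counts = counts[["drug", "week_index", "week_start", "week_end", "origin_class", "N"]]

    exploded["quarter"] = exploded["week_index"].map(
        lambda i: str(pd.Period(weeks[i][0], freq="Q"))
    )
    total_rows = []
    for risk in RISKS:
        grp = (
            exploded[exploded[risk]]
            .groupby(["drug_list", "quarter"], sort=True)
            .size()
            .reset_index(name="count")
        )
        for row in grp.itertuples(index=False):
            total_rows.append((row.drug_list, risk, row.quarter, int(row.count)))
    totals = pd.DataFrame(total_rows, columns=["drug", "risk", "quarter", "count"])
    return counts, totals


def simulate_raters(truth_labels, error_rates, seed: int = 0) -> np.ndarray:
    """Three simulated coders who each flip the true binary label
    independently with their own error rate. Returns an items x 3 matrix."""
    rates = tuple(error_rates)
    if len(rates) != 3:
        raise ValueError(f"expected exactly 3 error rates, got {len(rates)}")
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"error rate {r} outside [0,1]")
    labels = np.asarray(truth_labels, dtype=bool)
    rng = np.random.default_rng([seed, _RATER_STREAM_LABEL])
    columns = []
    for r in rates:
        flip = rng.random(labels.shape[0]) < r
        columns.append(np.where(flip, ~labels, labels))
    return np.column_stack(columns).astype(int)
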