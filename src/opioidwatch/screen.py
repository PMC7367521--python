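"""Keyword screening, exclusion rules and origin classification.

Posts are flagged per drug by case-insensitive whole-token matching against
a keyword lexicon (canonical names, product names, slang, misspellings).
An ordered two-step exclusion pass then removes uninformative posts:
metadata rules (surveillance window, language, country, source class)
followed by phrase rules that approximate manual screening (off-context,
spam, pharmacy/news/pop-culture, indeterminate). Exclusion does not cascade
down threads: a reply under an excluded originating post is retained when
it carries informative content of its own.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import re
from importlib import resources
from typing import Optional, Sequence

import pandas as pd
import yaml

from .constants import BLOGS_FORUMS, EXCLUSION_CODES, SOCIAL_MEDIA, mention_col

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_HOST_RE = re.compile(
    r"[a-z0-9]([a-z0-9-]*[a-z0-9])?(\.[a-z0-9]([a-z0-9-]*[a-z0-9])?)+"
)

#: Rule codes whose predicate inspects post text rather than metadata.
PHRASE_RULES = ("off_context", "spam", "pharmacy_news_popculture", "indeterminate")


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("opioidwatch").joinpath("data", name).open("r") as handle:
        return yaml.safe_load(handle)


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens; everything else is a separator."""
    return _TOKEN_RE.findall(text.lower())


@dataclasses.dataclass
class Lexicon:
    """Per-drug search terms grouped by category.

    Terms must be lowercase and nonempty, and no term may appear in more
    than one variant list of the same drug.
    """

    version: int
    terms: dict[str, dict[str, list[str]]]

    def __post_init__(self):
        for drug, groups in self.terms.items():
            seen: set[str] = set()
            for category, words in groups.items():
                for word in words:
                    if not word or word != word.lower():
                        raise ValueError(
                            f"lexicon term {word!r} for {drug}/{category} must be nonempty lowercase"
                        )
                    if word in seen:
                        raise ValueError(f"duplicate lexicon term {word!r} for {drug}")
                    seen.add(word)
        self._index = None

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(version=raw.get("version", 1), terms=raw["drugs"])

    @classmethod
    def load_default(cls) -> "Lexicon":
        raw = _load_packaged_yaml("lexicon.yaml")
        return cls(version=raw.get("version", 1), terms=raw["drugs"])

    def drugs(self) -> tuple[str, ...]:
        return tuple(self.terms)

    def variants(self, drug: str) -> list[str]:
        return [w for words in self.terms[drug].values() for w in words]

    def token_index(self):
        """Per drug: (set of single tokens, {length: set of token tuples})."""
        if self._index is None:
            index = {}
            for drug in self.terms:
                unigrams: set[str] = set()
                multi: dict[int, set[tuple[str, ...]]] = {}
                for term in self.variants(drug):
                    toks = tuple(tokenize(term))
                    if not toks:
                        raise ValueError(f"lexicon term {term!r} has no tokens")
                    if len(toks) == 1:
                        unigrams.add(toks[0])
                    else:
                        multi.setdefault(len(toks), set()).add(toks)
                index[drug] = (unigrams, multi)
            self._index = index
        return self._index


def match_drugs(post, lexicon: Lexicon) -> frozenset:
    """Drug flags for one post by whole-token (not substring) matching."""
    if not lexicon.terms:
        raise ValueError("lexicon is empty")
    text = post if isinstance(post, str) else post.text
    return _match_tokens(tokenize(text), lexicon.token_index())


def _match_tokens(tokens: list[str], index) -> frozenset:
    token_set = set(tokens)
    flags = set()
    for drug, (unigrams, multi) in index.items():
        if token_set & unigrams:
            flags.add(drug)
            continue
        for length, seqs in multi.items():
            if any(
                tuple(tokens[i : i + length]) in seqs
                for i in range(len(tokens) - length + 1)
            ):
                flags.add(drug)
                break
    return frozenset(flags)


@dataclasses.dataclass
class DomainRegistry:
    """Hostname -> origin class map with parent-domain fallback."""

    domains: dict[str, str]
    default_class: str = SOCIAL_MEDIA

    @classmethod
    def from_yaml(cls, path) -> "DomainRegistry":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(domains=raw["domains"], default_class=raw.get("default_class", SOCIAL_MEDIA))

    @classmethod
    def load_default(cls) -> "DomainRegistry":
        raw = _load_packaged_yaml("domains.yaml")
        return cls(domains=raw["domains"], default_class=raw.get("default_class", SOCIAL_MEDIA))


def classify_origin(site_domain: str, registry: DomainRegistry) -> str:
    """Origin class by exact then parent-domain lookup.

    Unknown domains fall back to the registry's configurable default class
    (social media by default, since it dominates volume) with a warning.
    """
    if not registry.domains:
        raise ValueError("domain registry is empty")
    host = site_domain.strip().lower()
    if not _HOST_RE.fullmatch(host):
        raise ValueError(f"malformed hostname: {site_domain!r}")
    labels = host.split(".")
    for start in range(len(labels) - 1):
        candidate = ".".join(labels[start:])
        if candidate in registry.domains:
            return registry.domains[candidate]
    logger.warning("unknown domain %r; defaulting to %s", site_domain, registry.default_class)
    return registry.default_class


@dataclasses.dataclass
class ExclusionRules:
    """Ordered exclusion rules plus their metadata and phrase parameters."""

    order: list[str]
    allowed_languages: list[str]
    allowed_countries: list[str]
    phrases: dict[str, list[str]]

    def __post_init__(self):
        for code in self.order:
            if code not in EXCLUSION_CODES:
                raise ValueError(f"unknown exclusion rule code {code!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExclusionRules":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(
            order=raw["order"],
            allowed_languages=raw.get("allowed_languages", ["en"]),
            allowed_countries=raw.get("allowed_countries", ["US"]),
            phrases={k: list(v) for k, v in raw.get("phrases", {}).items()},
        )

    @classmethod
    def load_default(cls) -> "ExclusionRules":
        raw = _load_packaged_yaml("rules.yaml")
        return cls(
            order=raw["order"],
            allowed_languages=raw.get("allowed_languages", ["en"]),
            allowed_countries=raw.get("allowed_countries", ["US"]),
            phrases={k: list(v) for k, v in raw.get("phrases", {}).items()},
        )


def _contains_any(text_lower: pd.Series, phrases: Sequence[str]) -> pd.Series:
    mask = pd.Series(False, index=text_lower.index)
    for phrase in phrases:
        mask |= text_lower.str.contains(phrase, regex=False)
    return mask


def _default_informative_phrases() -> list[str]:
    raw = _load_packaged_yaml("phrasebook.yaml")
    return [p for plist in raw["markers"].values() for p in plist]


def apply_exclusions(
    posts: pd.DataFrame,
    rules: ExclusionRules,
    window: tuple[datetime.date, datetime.date],
    registry: Optional[DomainRegistry] = None,
    informative_phrases: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Apply ordered exclusion rules; first matching rule sets the reason.

    ``window`` is an inclusive pair of calendar dates. Phrase rules spare
    replies (``parent_id`` set) that carry informative content, defined as
    at least one drug flag together with a key-risk marker phrase; this
    realises the convention that only originating posts are removed while
    informative related posts are kept. Idempotent: the output columns are
    recomputed from scratch on every call.
    """
    out = posts.copy()
    mention_cols = [c for c in out.columns if c.startswith("mentions_")]
    if mention_cols:
        has_flag = out[mention_cols].any(axis=1)
    else:
        has_flag = pd.Series(False, index=out.index)
    text_lower = out["text"].str.lower()
    if informative_phrases is None:
        informative_phrases = _default_informative_phrases()
    is_reply = out["parent_id"].notna()
    informative = is_reply & has_flag & _contains_any(text_lower, informative_phrases)

    start = pd.Timestamp(window[0])
    end_exclusive = pd.Timestamp(window[1]) + pd.Timedelta(days=1)
    timestamps = pd.to_datetime(out["timestamp"])

    reason = pd.Series([None] * len(out), index=out.index, dtype=object)
    for code in rules.order:
        if code == "out_of_window":
            fired = (timestamps < start) | (timestamps >= end_exclusive)
        elif code == "non_english":
            fired = ~out["language"].isin(rules.allowed_languages)
        elif code == "non_us":
            fired = ~out["country"].isin(rules.allowed_countries)
        elif code == "bad_source":
            reg = registry if registry is not None else DomainRegistry.load_default()
            classes = out["site_domain"].map(lambda d: classify_origin(d, reg))
            fired = ~classes.isin([SOCIAL_MEDIA, BLOGS_FORUMS])
        elif code in PHRASE_RULES:
            fired = _contains_any(text_lower, rules.phrases.get(code, []))
            fired &= ~informative
        else:  # pragma: no cover - constructor validates codes
            raise ValueError(f"unknown exclusion rule code {code!r}")
        newly = fired & reason.isna()
        reason[newly] = code

    out["exclusion_reason"] = reason
    out["excluded"] = reason.notna()
    return out


def screen_corpus(
    corpus: pd.DataFrame,
    lexicon: Optional[Lexicon] = None,
    rules: Optional[ExclusionRules] = None,
    registry: Optional[DomainRegistry] = None,
    window: Optional[tuple[datetime.date, datetime.date]] = None,
    informative_phrases: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Full screening pass: drug flags, origin class, exclusions.

    Posts left without any drug flag are excluded as ``off_context`` (the
    drug name was never actually referenced), so that every retained post
    carries at least one flag.
    """
    lexicon = lexicon or Lexicon.load_default()
    rules = rules or ExclusionRules.load_default()
    registry = registry or DomainRegistry.load_default()
    if window is None:
        dates = pd.to_datetime(corpus["timestamp"])
        window = (dates.min().date(), dates.max().date())

    out = corpus.copy()
    index = lexicon.token_index()
    flags = [_match_tokens(tokenize(t), index) for t in out["text"]]
    for drug in lexicon.drugs():
        out[mention_col(drug)] = [drug in f for f in flags]

    origin_map = {
        dom: classify_origin(dom, registry) for dom in out["site_domain"].unique()
    }
    out["origin_class"] = out["site_domain"].map(origin_map)

    out = apply_exclusions(out, rules, window, registry, informative_phrases)

    mention_cols = [mention_col(d) for d in lexicon.drugs()]
    no_flag = ~out[mention_cols].any(axis=1) & ~out["excluded"]
    out.loc[no_flag, "exclusion_reason"] = "off_context"
    out.loc[no_flag, "excluded"] = True
    # posts classified into the residual "other" source class are handled by
    # the bad_source rule; anything still unexcluded has a proper origin
    return out


def funnel_counts(screened: pd.DataFrame) -> dict:
    """Stage counts in flowchart form: collected, excluded by reason, retained."""
    counts = {"collected": int(len(screened))}
    by_reason = screened["exclusion_reason"].value_counts(dropna=True)
    counts["excluded"] = {k: int(v) for k, v in by_reason.items()}
    counts["retained"] = int((~screened["excluded"]).sum())
    return counts
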