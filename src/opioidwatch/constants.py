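"""Shared vocabulary: drugs under surveillance, key risks, origin classes."""

DRUGS = ("fentanyl", "hydrocodone", "oxycodone", "oxymorphone")

#: The five boxed-warning key risks. Misuse and abuse are coded jointly into
#: one ternary variable downstream but are tracked separately here so that
#: reports can break them out again.
RISKS = ("misuse", "abuse", "addiction", "overdose", "death")

SOCIAL_MEDIA = "social_media"
BLOGS_FORUMS = "blogs_forums"
ORIGINS = (SOCIAL_MEDIA, BLOGS_FORUMS)

#: Enumerated exclusion-reason codes, in the order rules are applied.
EXCLUSION_CODES = (
    "out_of_window",
    "non_english",
    "non_us",
    "bad_source",
    "off_context",
    "spam",
    "pharmacy_news_popculture",
    "indeterminate",
)

#: Column-name prefix for per-drug mention flags on screened frames.
MENTION_PREFIX = "mentions_"


def mention_col(drug: str) -> str:
    return MENTION_PREFIX + drug
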