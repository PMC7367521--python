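"""American Soundex and bounded-edit phonetic variant generation.

Drug-name keyword lists are expanded with plausible misspellings by
enumerating every string within a small edit distance of a term and keeping
those that share the term's Soundex code. Bounding the edit distance makes
the variant set finite and deterministic.
"""

from __future__ import annotations

import itertools
import string

_CODE_MAP = {}
for _letters, _digit in (
    ("bfpv", "1"),
    ("cgjkqsxz", "2"),
    ("dt", "3"),
    ("l", "4"),
    ("mn", "5"),
    ("r", "6"),
):
    for _ch in _letters:
        _CODE_MAP[_ch] = _digit

_VOWELS = set("aeiouy")
_IGNORED = set("hw")
_ALPHABET = string.ascii_lowercase


def soundex(word: str) -> str:
    """Four-character American Soundex code (letter + three digits).

    Vowels separate duplicate consonant codes; ``h`` and ``w`` do not.
    """
    w = word.lower()
    if not w or not w.isalpha():
        raise ValueError(f"soundex requires a nonempty alphabetic word, got {word!r}")
    first = w[0].upper()
    last = _CODE_MAP.get(w[0], "")
    digits: list[str] = []
    for ch in w[1:]:
        if ch in _IGNORED:
            continue
        if ch in _VOWELS:
            last = ""
            continue
        code = _CODE_MAP[ch]
        if code != last:
            digits.append(code)
        last = code
    return (first + "".join(digits) + "000")[:4]


def _single_edits(word: str):
    """All strings at Levenshtein distance exactly 1 from ``word`` (a-z)."""
    for i in range(len(word)):
        yield word[:i] + word[i + 1 :]  # deletion
        for ch in _ALPHABET:
            if ch != word[i]:
                yield word[:i] + ch + word[i + 1 :]  # substitution
    for i in range(len(word) + 1):
        for ch in _ALPHABET:
            yield word[:i] + ch + word[i:]  # insertion


def phonetic_variants(term: str, candidate_edits: int = 1) -> set[str]:
    """Strings within ``candidate_edits`` edits of ``term`` sharing its Soundex.

    Always includes ``term`` itself. The candidate neighbourhood grows
    roughly as (53·len)^edits, so bounds above 2 are rejected.
    """
    term = term.lower()
    if not term or not term.isalpha():
        raise ValueError(f"term must be nonempty alphabetic, got {term!r}")
    if candidate_edits < 0:
        raise ValueError("candidate_edits must be >= 0")
    if candidate_edits > 2:
        raise ValueError("candidate_edits above 2 is not supported (combinatorial blow-up)")
    frontier = {term}
    neighbourhood = {term}
    for _ in range(candidate_edits):
        nxt = set()
        for w in frontier:
            nxt.update(_single_edits(w))
        nxt -= neighbourhood
        neighbourhood |= nxt
        frontier = nxt
    code = soundex(term)
    variants = {w for w in neighbourhood if w and w.isalpha() and soundex(w) == code}
    variants.add(term)
    return variants
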