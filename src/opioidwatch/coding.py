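"""Key-risk coding of screened posts and three-coder reconciliation.

Real-world coding of this kind is done by trained human coders; here it is
mechanised as deterministic phrase-marker lookup against a versioned
phrasebook so that latent labels planted by the corpus generator are
machine-recoverable. Misuse and abuse are coded into a single ternary
variable (none / misuse / abuse): markers indicating pursuit of a high or
euphoric effect code as abuse, other improper use codes as misuse.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import RISKS

RISK_VARIABLES = ("misuse_abuse", "addiction", "overdose", "death")


@dataclasses.dataclass
class Phrasebook:
    """Versioned marker phrases per key risk.

    No marker may be a substring of another marker (of any risk); this
    keeps phrase lookup unambiguous.
    """

    version: int
    markers: dict[str, list[str]]

    def __post_init__(self):
        missing = [r for r in RISKS if r not in self.markers]
        if missing:
            raise ValueError(f"phrasebook missing risks: {missing}")
        flat = [(r, p) for r, ps in self.markers.items() for p in ps]
        for risk, phrase in flat:
            if not phrase or phrase != phrase.lower():
                raise ValueError(f"marker {phrase!r} must be nonempty lowercase")
            for other_risk, other in flat:
                if phrase != other and phrase in other:
                    raise ValueError(
                        f"marker {phrase!r} ({risk}) is a substring of {other!r} ({other_risk})"
                    )

    @classmethod
    def from_yaml(cls, path) -> "Phrasebook":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(version=raw.get("version", 1), markers=raw["markers"])

    @classmethod
    def load_default(cls) -> "Phrasebook":
        with resources.files("opioidwatch").joinpath("data", "phrasebook.yaml").open("r") as handle:
            raw = yaml.safe_load(handle)
        return cls(version=raw.get("version", 1), markers=raw["markers"])


@dataclasses.dataclass
class CodedPost:
    """A sampled post with its sampling weight and coded key-risk labels."""

    post_id: str
    weight: float
    origin_class: str
    drug_flags: frozenset
    misuse_abuse: str  # "none" | "misuse" | "abuse"
    addiction: bool
    overdose: bool
    death: bool

    def __post_init__(self):
        if self.weight < 1:
            raise ValueError("sampling weight must be >= 1")
        if self.misuse_abuse not in ("none", "misuse", "abuse"):
            raise ValueError(f"bad misuse_abuse value {self.misuse_abuse!r}")


def _code_text(text: str, phrasebook: Phrasebook) -> dict:
    lower = text.lower()
    found = {
        risk: any(p in lower for p in phrasebook.markers[risk]) for risk in RISKS
    }
    if found["abuse"]:
        misuse_abuse = "abuse"
    elif found["misuse"]:
        misuse_abuse = "misuse"
    else:
        misuse_abuse = "none"
    return {
        "misuse_abuse": misuse_abuse,
        "misuse": misuse_abuse == "misuse",
        "abuse": misuse_abuse == "abuse",
        "addiction": found["addiction"],
        "overdose": found["overdose"],
        "death": found["death"],
    }


def auto_code(post, phrasebook: Optional[Phrasebook] = None, weight: float = 1.0) -> CodedPost:
    """Code one screened, non-excluded post by marker lookup.

    ``post`` is a mapping/Series with at least ``post_id``, ``text``,
    ``origin_class`` and ``excluded``; drug flags are read from the
    ``mentions_*`` columns when present.
    """
    phrasebook = phrasebook or Phrasebook.load_default()
    if bool(post["excluded"]):
        raise ValueError(f"cannot code excluded post {post['post_id']}")
    labels = _code_text(post["text"], phrasebook)
    keys = post.keys() if hasattr(post, "keys") else post.index
    flags = frozenset(
        k[len("mentions_"):] for k in keys if k.startswith("mentions_") and post[k]
    )
    return CodedPost(
        post_id=post["post_id"],
        weight=float(weight),
        origin_class=post["origin_class"],
        drug_flags=flags,
        misuse_abuse=labels["misuse_abuse"],
        addiction=labels["addiction"],
        overdose=labels["overdose"],
        death=labels["death"],
    )


def code_sample(sample: pd.DataFrame, phrasebook: Optional[Phrasebook] = None) -> pd.DataFrame:
    """Vectorised coding of a frame of screened posts.

    Adds ``misuse_abuse`` plus boolean columns ``misuse``, ``abuse``,
    ``addiction``, ``overdose`` and ``death``. Raises if any row is excluded.
    """
    phrasebook = phrasebook or Phrasebook.load_default()
    if "excluded" in sample.columns and sample["excluded"].any():
        raise ValueError("sample contains excluded posts; code only analyzed posts")
    out = sample.copy()
    lower = out["text"].str.lower()
    found = {}
    for risk in RISKS:
        mask = pd.Series(False, index=out.index)
        for phrase in phrasebook.markers[risk]:
            mask |= lower.str.contains(phrase, regex=False)
        found[risk] = mask
    misuse_abuse = np.where(found["abuse"], "abuse", np.where(found["misuse"], "misuse", "none"))
    out["misuse_abuse"] = misuse_abuse
    out["misuse"] = misuse_abuse == "misuse"
    out["abuse"] = misuse_abuse == "abuse"
    out["addiction"] = found["addiction"].to_numpy()
    out["overdose"] = found["overdose"].to_numpy()
    out["death"] = found["death"].to_numpy()
    return out


def reconcile(labels: Sequence[int], adjudicator) -> int:
    """Final label from three coder labels plus an adjudicator.

    Unanimity stands; any disagreement is decided by the adjudicator (no
    majority rule). Invariant under permutation of the three labels.
    """
    labels = list(labels)
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 labels, got {len(labels)}")
    if labels[0] == labels[1] == labels[2]:
        return labels[0]
    return adjudicator


def reconcile_matrix(matrix: np.ndarray, adjudicator: np.ndarray) -> np.ndarray:
    """Vectorised :func:`reconcile` over an items x 3 label matrix."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 3:
        raise ValueError("rater matrix must be items x 3")
    adjudicator = np.asarray(adjudicator)
    unanimous = (matrix[:, 0] == matrix[:, 1]) & (matrix[:, 1] == matrix[:, 2])
    return np.where(unanimous, matrix[:, 0], adjudicator)
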