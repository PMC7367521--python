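"""Post records and line-delimited (JSON-lines) corpus I/O.

A corpus is held in memory as a :class:`pandas.DataFrame` with one row per
post. The canonical raw columns are ``post_id``, ``parent_id``,
``timestamp`` (naive UTC), ``site_domain``, ``country``, ``language`` and
``text``; screening and coding append further columns. Serialisation is
deliberately canonical (fixed key order, compact separators, second-level
timestamps) so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from typing import Optional

import numpy as np
import pandas as pd

RAW_COLUMNS = [
    "post_id",
    "parent_id",
    "timestamp",
    "site_domain",
    "country",
    "language",
    "text",
]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


@dataclasses.dataclass(frozen=True)
class RawPost:
    """A single point of communication entered by one individual at one time."""

    post_id: str
    parent_id: Optional[str]
    timestamp: datetime.datetime
    site_domain: str
    country: str
    language: str
    text: str


def _to_jsonable(value):
    if value is None:
        return None
    if isinstance(value, pd.Timestamp):
        return value.strftime(_TS_FORMAT)
    if isinstance(value, datetime.datetime):
        return value.strftime(_TS_FORMAT)
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return None
        return float(value)
    return value


def write_jsonl(frame: pd.DataFrame, path) -> None:
    """Write one JSON object per row, keys in column order, UTF-8."""
    columns = list(frame.columns)
    with open(path, "w", encoding="utf-8") as handle:
        for row in frame.itertuples(index=False):
            record = {c: _to_jsonable(v) for c, v in zip(columns, row)}
            handle.write(json.dumps(record, ensure_ascii=True, separators=(",", ":")))
            handle.write("\n")


def read_jsonl(path) -> pd.DataFrame:
    """Read a JSON-lines corpus, parsing ``timestamp`` back to datetimes."""
    records = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    frame = pd.DataFrame.from_records(records)
    if "timestamp" in frame.columns:
        frame["timestamp"] = pd.to_datetime(frame["timestamp"], format=_TS_FORMAT)
    return frame


def frame_to_posts(frame: pd.DataFrame) -> list[RawPost]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            RawPost(
                post_id=row.post_id,
                parent_id=None if row.parent_id is None or (isinstance(row.parent_id, float) and math.isnan(row.parent_id)) else row.parent_id,
                timestamp=pd.Timestamp(row.timestamp).to_pydatetime(),
                site_domain=row.site_domain,
                country=row.country,
                language=row.language,
                text=row.text,
            )
        )
    return out
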