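"""Respondent-level activity summaries from raw per-sport episode records.

Each raw record reports, for one respondent and one sport over a 28-day
recall window, the number of days played, the per-day average hours, an
out-of-breath/sweaty effort flag and the sport's intensity class (1-3).
The summary collapses these to: participation, aggregate duration ``t``
(hours per 28 days), event multiplicity ``q`` and a vigour class in
{1, 2, 3} (low / moderate / high).  Only the sports attaining the
respondent's maximal individualized vigour contribute to ``t`` and ``q``;
ties at the maximum are all included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "SportEpisodeRecord",
    "ActivitySummary",
    "classify_vigour",
    "summarize_activity",
    "summarize_episodes",
    "read_episodes_csv",
    "write_summaries_csv",
]

logger = logging.getLogger(__name__)

EPISODE_COLUMNS = [
    "respondent_id",
    "sport_id",
    "d_days",
    "a_avg_hours",
    "e_effort",
    "s_intensity",
]


class ValidationError(ValueError):
    """A record violates its stated invariants."""


@dataclass(frozen=True)
class SportEpisodeRecord:
    """One respondent's report for one sport over the 28-day recall."""

    respondent_id: str
    sport_id: str
    d_days: int
    a_avg_hours: float
    e_effort: int
    s_intensity: int

    def __post_init__(self) -> None:
        tag = f"record ({self.respondent_id!r}, {self.sport_id!r})"
        if not 0 <= int(self.d_days) <= 28:
            raise ValidationError(f"{tag}: d_days must be in 0..28, got {self.d_days}")
        if self.a_avg_hours < 0:
            raise ValidationError(f"{tag}: a_avg_hours must be >= 0, got {self.a_avg_hours}")
        if self.e_effort not in (0, 1):
            raise ValidationError(f"{tag}: e_effort must be 0 or 1, got {self.e_effort}")
        if self.s_intensity not in (1, 2, 3):
            raise ValidationError(f"{tag}: s_intensity must be 1, 2 or 3, got {self.s_intensity}")


@dataclass(frozen=True)
class ActivitySummary:
    """Per-respondent participation / duration / multiplicity / vigour."""

    respondent_id: str
    participated: int
    t_hours_28d: float
    q_events_28d: int
    v_vigour: Optional[int]
    zero_duration_flag: bool = False


def classify_vigour(s_intensity: int, e_effort: int) -> tuple[int, int]:
    """Map (sport intensity, effort flag) to (fine, collapsed) vigour.

    The fine 4-level class is ``s + e``; levels 1 and 2 are merged so the
    collapsed class is 1 (low), 2 (moderate) or 3 (high).
    """
    if s_intensity not in (1, 2, 3):
        raise ValidationError(f"s_intensity must be 1, 2 or 3, got {s_intensity}")
    if e_effort not in (0, 1):
        raise ValidationError(f"e_effort must be 0 or 1, got {e_effort}")
    fine = s_intensity + e_effort
    collapsed = 1 if fine <= 2 else fine - 1
    return fine, collapsed


def summarize_activity(
    records: Sequence[SportEpisodeRecord],
    respondent_id: Optional[str] = None,
) -> ActivitySummary:
    """Collapse one respondent's episode records to an :class:`ActivitySummary`.

    Aggregate duration sums ``a * d`` and multiplicity sums ``d`` over
    exactly the sports (with ``d > 0``) whose collapsed vigour attains the
    respondent-level maximum.  An empty collection or all-zero days yields
    a non-participant summary.  A participant whose selected sports all
    report zero average hours gets ``t = 0`` with ``zero_duration_flag``
    set; such rows must be excluded from duration fitting.
    """
    records = list(records)
    if not records:
        if respondent_id is None:
            raise ValidationError("empty record collection with no respondent_id given")
        return ActivitySummary(respondent_id, 0, 0.0, 0, None)
    rid = records[0].respondent_id
    if respondent_id is not None and rid != respondent_id:
        raise ValidationError(
            f"records belong to {rid!r}, not the stated respondent {respondent_id!r}"
        )
    if any(r.respondent_id != rid for r in records):
        ids = sorted({r.respondent_id for r in records})
        raise ValidationError(f"records mix respondent ids: {ids}")
    seen = set()
    for r in records:
        key = (r.respondent_id, r.sport_id)
        if key in seen:
            raise ValidationError(f"duplicate record for {key}")
        seen.add(key)

    active = [r for r in records if r.d_days > 0]
    if not active:
        return ActivitySummary(rid, 0, 0.0, 0, None)

    vig = {r.sport_id: classify_vigour(r.s_intensity, r.e_effort)[1] for r in active}
    v_max = max(vig.values())
    selected = [r for r in active if vig[r.sport_id] == v_max]
    t = float(sum(r.a_avg_hours * r.d_days for r in selected))
    q = int(sum(r.d_days for r in selected))
    return ActivitySummary(rid, 1, t, q, v_max, zero_duration_flag=(t == 0.0))


def summarize_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Summarize a long-format episode table into one row per respondent.

    The input must carry the columns of ``EPISODE_COLUMNS``; the output has
    columns respondent_id, participated, t_hours_28d, q_events_28d,
    v_vigour (empty for non-participants) and zero_duration_flag.
    """
    missing = [c for c in EPISODE_COLUMNS if c not in episodes.columns]
    if missing:
        raise ValidationError(f"episode table is missing columns: {missing}")
    rows = []
    for rid, grp in episodes.groupby("respondent_id", sort=True):
        recs = [
            SportEpisodeRecord(
                respondent_id=str(rid),
                sport_id=str(r.sport_id),
                d_days=int(r.d_days),
                a_avg_hours=float(r.a_avg_hours),
                e_effort=int(r.e_effort),
                s_intensity=int(r.s_intensity),
            )
            for r in grp.itertuples(index=False)
        ]
        rows.append(summarize_activity(recs))
    n_flagged = sum(r.zero_duration_flag for r in rows)
    if n_flagged:
        logger.info("flagged %d participant(s) with zero aggregate duration", n_flagged)
    return pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in rows],
            "participated": [r.participated for r in rows],
            "t_hours_28d": [r.t_hours_28d for r in rows],
            "q_events_28d": [r.q_events_28d for r in rows],
            "v_vigour": [r.v_vigour if r.v_vigour is not None else pd.NA for r in rows],
            "zero_duration_flag": [r.zero_duration_flag for r in rows],
        }
    )


def read_episodes_csv(path) -> pd.DataFrame:
    """Read a long-format episode CSV (header required, UTF-8)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in EPISODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def write_summaries_csv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, index=False)
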