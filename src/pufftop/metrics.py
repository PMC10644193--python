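"""Participant-level topography end points.

Seven end points summarise each participant's use over the evaluation
period: daily puffs, daily sessions, mean session length (s), mean
within-session IPI (s), mean puffs per session, mean puff duration (s)
and mean intersession interval (min).

Aggregation is session-then-participant: each session contributes one
value (its own mean), and sessions are weighted equally in the
participant mean.  A puff-weighted pooling variant is available for
sensitivity analysis via ``weighting="puff"``.  Daily rates use the fixed
evaluation period (default 14 days) as denominator, not days-with-use.
Single-puff sessions count toward session numbers, lengths, durations and
puffs-per-session but contribute no within-session IPI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cleansing import CleansingConfig
from .errors import PuffTopError
from .io import StudyDataset
from .sessionization import SessionizationResult, sessionize

log = logging.getLogger(__name__)

#: the seven comparison end points, in reporting order
ENDPOINTS = [
    "daily_puffs",
    "daily_sessions",
    "session_length_s",
    "within_ipi_s",
    "puffs_per_session",
    "puff_duration_s",
    "isi_min",
]


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    total_puffs: int
    daily_puffs: float
    daily_sessions: float
    session_length_s: float
    within_ipi_s: float
    puffs_per_session: float
    puff_duration_s: float
    isi_min: float
    evaluation_days: int = 14


def summarize_participant(
    result: SessionizationResult,
    evaluation_days: int = 14,
    weighting: Literal["session", "puff"] = "session",
) -> ParticipantSummary:
    """Reduce one participant's sessionization to the seven end points.

    With zero sessions the summary has ``total_puffs == 0`` and NaN for
    every mean; a participant with sessions but no threshold-cause ISI
    gets NaN for ``isi_min`` only.
    """
    if evaluation_days < 1:
        raise PuffTopError("evaluation_days must be >= 1")
    nan = float("nan")
    n_sessions = result.n_sessions
    total = int(result.puff_session.size)
    if n_sessions == 0:
        return ParticipantSummary(
            result.participant_id, 0, 0.0, 0.0, nan, nan, nan, nan, nan, evaluation_days
        )
    counts = result.session_n_puffs
    lengths = result.session_end - result.session_start
    multi = counts >= 2
    if weighting == "session":
        sess_within_mean = result.session_within_ipi_sum[multi] / (counts[multi] - 1)
        within = float(sess_within_mean.mean()) if multi.any() else nan
        duration = float(result.session_mean_duration.mean())
    elif weighting == "puff":
        w_count = int((counts - 1).sum())
        within = float(result.session_within_ipi_sum.sum() / w_count) if w_count else nan
        duration = float((result.session_mean_duration * counts).sum() / total)
    else:
        raise PuffTopError(f"unknown weighting {weighting!r}")
    isi = float(result.isi_lengths.mean() / 60.0) if result.isi_lengths.size else nan
    return ParticipantSummary(
        participant_id=result.participant_id,
        total_puffs=total,
        daily_puffs=total / evaluation_days,
        daily_sessions=n_sessions / evaluation_days,
        session_length_s=float(lengths.mean()),
        within_ipi_s=within,
        puffs_per_session=float(counts.mean()),
        puff_duration_s=duration,
        isi_min=isi,
        evaluation_days=evaluation_days,
    )


def summarize_study(
    dataset: StudyDataset,
    cfg: CleansingConfig | None = None,
    weighting: Literal["session", "puff"] = "session",
    on_error: Literal["warn", "raise"] = "warn",
) -> list[ParticipantSummary]:
    """Per-participant pipeline map; participant order is preserved.

    Per-participant failures are logged and skipped unless
    ``on_error="raise"``.
    """
    cfg = cfg or CleansingConfig()
    out: list[ParticipantSummary] = []
    for stream in dataset:
        try:
            result = sessionize(stream, cfg)
            out.append(
                summarize_participant(result, stream.evaluation_days, weighting)
            )
        except PuffTopError as exc:
            if on_error == "raise":
                raise
            log.warning("participant %s skipped: %s", stream.participant_id, exc)
    return out
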