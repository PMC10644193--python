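"""Adaptive-threshold sessionization of cleansed puff streams.

The operational definition: a participant's *mean IPI* — the arithmetic
mean of their interpuff intervals after prolonged-nonuse gaps are
excluded — is an adaptive per-participant threshold.  Scanning the stream
in time order, an IPI ends the current session iff it strictly exceeds
that threshold or is a flagged nonuse gap.  Threshold-exceeding IPIs that
are not nonuse become intersession intervals (ISIs); nonuse gaps end
sessions but are excluded from ISI statistics, since reported ISI means
(minutes) are far below the overnight 12–16 h breaks.

The threshold is computed once per participant over the whole evaluation
period (single pass, no iterative refinement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .cleansing import (
    WITHIN_CANDIDATE,
    CleansingConfig,
    CleanStream,
    IpiInterval,
    flag_nonuse,
    remove_false_puffs,
)
from .errors import UndefinedThresholdError, ValidationError
from .io import ParticipantStream

CAUSE_THRESHOLD = "threshold"
CAUSE_NONUSE = "nonuse"


@dataclass(frozen=True)
class Session:
    """A maximal run of puffs whose internal IPIs do not exceed the
    participant's mean IPI."""

    participant_id: str
    index: int
    first_puff: int
    last_puff: int
    start: float
    end: float
    n_puffs: int
    session_length_s: float
    within_ipis: np.ndarray
    mean_duration_s: float

    @property
    def puff_indices(self) -> range:
        return range(self.first_puff, self.last_puff + 1)


@dataclass(frozen=True)
class IntersessionInterval:
    participant_id: str
    between_sessions: tuple[int, int]
    length: float
    cause: str  # "threshold" or "nonuse"


@dataclass
class SessionizationResult:
    """Array-backed segmentation of one participant's clean stream.

    Per-session arrays are aligned by session index; ``puff_session``
    gives each surviving puff's 0-based session index.  ``sessions`` and
    ``isis`` materialise object views on demand.
    """

    participant_id: str
    mean_ipi_s: float
    session_first: np.ndarray
    session_last: np.ndarray
    session_start: np.ndarray
    session_end: np.ndarray
    session_n_puffs: np.ndarray
    session_mean_duration: np.ndarray
    session_within_ipi_sum: np.ndarray
    puff_session: np.ndarray
    isi_lengths: np.ndarray  # threshold-cause only
    isi_between: np.ndarray  # session index left of each threshold ISI
    nonuse_break_count: int
    ipi_lengths: np.ndarray
    boundary: np.ndarray

    @property
    def n_sessions(self) -> int:
        return int(self.session_first.size)

    @property
    def sessions(self) -> list[Session]:
        out = []
        for j in range(self.n_sessions):
            f, l = int(self.session_first[j]), int(self.session_last[j])
            within = self.ipi_lengths[f:l] if l > f else np.array([], dtype=float)
            out.append(
                Session(
                    participant_id=self.participant_id,
                    index=j,
                    first_puff=f,
                    last_puff=l,
                    start=float(self.session_start[j]),
                    end=float(self.session_end[j]),
                    n_puffs=int(self.session_n_puffs[j]),
                    session_length_s=float(self.session_end[j] - self.session_start[j]),
                    within_ipis=within,
                    mean_duration_s=float(self.session_mean_duration[j]),
                )
            )
        return out

    @property
    def isis(self) -> list[IntersessionInterval]:
        return [
            IntersessionInterval(
                participant_id=self.participant_id,
                between_sessions=(int(j), int(j) + 1),
                length=float(x),
                cause=CAUSE_THRESHOLD,
            )
            for j, x in zip(self.isi_between, self.isi_lengths)
        ]


def _empty_result(participant_id: str, threshold: float) -> SessionizationResult:
    z = np.array([], dtype=float)
    zi = np.array([], dtype=int)
    return SessionizationResult(
        participant_id, threshold, zi, zi, z, z, zi, z, z, zi, z, zi, 0, z,
        np.array([], dtype=bool),
    )


def mean_ipi(ipis: Union[CleanStream, Sequence[IpiInterval]]) -> float:
    """Arithmetic mean of within-candidate (non-nonuse) IPI lengths.

    Raises :class:`UndefinedThresholdError` when no within-candidate IPI
    exists (participant has fewer than two usable puffs).
    """
    if isinstance(ipis, CleanStream):
        lengths = ipis.ipi_lengths[~ipis.ipi_nonuse]
    else:
        lengths = np.array(
            [iv.length for iv in ipis if iv.klass == WITHIN_CANDIDATE], dtype=float
        )
    if lengths.size == 0:
        raise UndefinedThresholdError(
            "no within-candidate IPIs; the mean-IPI session threshold is undefined"
        )
    return float(lengths.mean())


def segment(clean: CleanStream, threshold: float) -> SessionizationResult:
    """Split a clean stream into sessions at the given IPI threshold.

    An IPI ends the current session iff its length strictly exceeds
    ``threshold`` or it carries a nonuse flag (``clean.ipi_nonuse``).
    Threshold-exceeding non-nonuse IPIs are recorded as ISIs.
    """
    n = clean.n_puffs
    if n == 0:
        return _empty_result(clean.participant_id, threshold)
    if not threshold > 0 and n > 1:
        raise ValidationError(f"session threshold must be positive, got {threshold}")
    lengths = clean.ipi_lengths
    nonuse = clean.ipi_nonuse
    boundary = (lengths > threshold) | nonuse
    firsts = np.concatenate([[0], np.flatnonzero(boundary) + 1]).astype(int)
    lasts = np.concatenate([firsts[1:] - 1, [n - 1]]).astype(int)
    counts = lasts - firsts + 1
    cum_dur = np.concatenate([[0.0], np.cumsum(clean.duration_s)])
    mean_dur = (cum_dur[lasts + 1] - cum_dur[firsts]) / counts
    within = np.where(boundary, 0.0, lengths)
    cum_w = np.concatenate([[0.0], np.cumsum(within)])
    within_sum = cum_w[lasts] - cum_w[firsts]
    isi_pos = np.flatnonzero(boundary & ~nonuse)
    # session index left of each boundary = number of boundaries before it
    all_bounds = np.flatnonzero(boundary)
    isi_between = np.searchsorted(all_bounds, isi_pos)
    puff_session = np.repeat(np.arange(firsts.size), counts)
    return SessionizationResult(
        participant_id=clean.participant_id,
        mean_ipi_s=float(threshold),
        session_first=firsts,
        session_last=lasts,
        session_start=clean.start_s[firsts],
        session_end=clean.start_s[lasts] + clean.duration_s[lasts],
        session_n_puffs=counts,
        session_mean_duration=mean_dur,
        session_within_ipi_sum=within_sum,
        puff_session=puff_session,
        isi_lengths=lengths[isi_pos],
        isi_between=isi_between,
        nonuse_break_count=int((boundary & nonuse).sum()),
        ipi_lengths=lengths,
        boundary=boundary,
    )


def sessionize(
    stream: ParticipantStream, cfg: CleansingConfig | None = None
) -> SessionizationResult:
    """Full per-participant chain: false-puff removal, nonuse flagging,
    mean-IPI threshold, segmentation."""
    cfg = cfg or CleansingConfig()
    clean = remove_false_puffs(stream, cfg)
    clean = flag_nonuse(clean, cfg)
    if clean.n_puffs < 2:
        return segment(clean, threshold=float("nan"))
    threshold = mean_ipi(clean)
    if threshold == 0.0:
        # degenerate: all usable IPIs are zero; no IPI can strictly exceed 0
        threshold = np.finfo(float).tiny
    return segment(clean, threshold)
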