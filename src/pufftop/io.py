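"""Domain types for device puff streams and CSV readers/writers.

Time is stored as float seconds since the study epoch (the start of the
participant's evaluation period); a puff occupies the half-open interval
``[start, start + duration)``.  An optional converter from ISO-8601
timestamp columns is provided, but seconds-since-epoch is canonical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

SECONDS_PER_DAY = 86400.0

#: column order of the canonical puffs.csv dialect
PUFF_COLUMNS = ["participant_id", "start_s", "duration_s", "voltage_v", "current_a"]


@dataclass(frozen=True)
class PuffRecord:
    """One device-logged puff.

    Parameters
    ----------
    start : float
        Puff start, seconds since the study epoch (non-negative).
    duration : float
        Puff duration in seconds (strictly positive; the device defines a
        puff by the activation voltage rising from and returning to zero,
        so zero-length records are rejected).
    voltage : float
        Battery voltage associated with the puff, volts.
    current : float, optional
        Current draw in amperes; not needed by the cleansing rule.
    """

    start: float
    duration: float
    voltage: float
    current: float | None = None

    def __post_init__(self) -> None:
        if not self.start >= 0:
            raise ValidationError(f"puff start must be >= 0, got {self.start}")
        if not self.duration > 0:
            raise ValidationError(f"puff duration must be > 0, got {self.duration}")
        if not self.voltage >= 0:
            raise ValidationError(f"puff voltage must be >= 0, got {self.voltage}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class ParticipantStream:
    """A participant's ordered raw puff series over the evaluation period.

    Internally array-backed for speed; ``puffs`` materialises
    :class:`PuffRecord` objects on demand.
    """

    participant_id: str
    start_s: np.ndarray
    duration_s: np.ndarray
    voltage_v: np.ndarray
    current_a: np.ndarray | None = None
    evaluation_days: int = 14

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        self.voltage_v = np.asarray(self.voltage_v, dtype=float)
        if self.current_a is not None:
            self.current_a = np.asarray(self.current_a, dtype=float)
        if self.evaluation_days < 1:
            raise ValidationError("evaluation_days must be >= 1")
        n = self.start_s.size
        if not (self.duration_s.size == n == self.voltage_v.size):
            raise ValidationError("puff field arrays must have equal length")
        if n == 0:
            return
        if np.any(self.start_s < 0) or np.any(self.duration_s <= 0):
            raise ValidationError("puffs must have start >= 0 and duration > 0")
        horizon = self.evaluation_days * SECONDS_PER_DAY
        if np.any(self.start_s + self.duration_s > horizon):
            raise ValidationError(
                f"puffs must fall within the {self.evaluation_days}-day evaluation period"
            )
        ends = self.start_s[:-1] + self.duration_s[:-1]
        bad = np.flatnonzero(self.start_s[1:] < ends)
        if bad.size:
            raise ValidationError(
                f"puffs out of order or overlapping at indices {bad[:10].tolist()}",
                rows=bad.tolist(),
            )

    @property
    def n_puffs(self) -> int:
        return int(self.start_s.size)

    @property
    def puffs(self) -> list[PuffRecord]:
        cur = self.current_a if self.current_a is not None else [None] * self.n_puffs
        return [
            PuffRecord(s, d, v, c)
            for s, d, v, c in zip(self.start_s, self.duration_s, self.voltage_v, cur)
        ]

    @classmethod
    def from_puffs(
        cls,
        participant_id: str,
        puffs: Sequence[PuffRecord],
        evaluation_days: int = 14,
    ) -> "ParticipantStream":
        cur = None
        if puffs and all(p.current is not None for p in puffs):
            cur = np.array([p.current for p in puffs], dtype=float)
        return cls(
            participant_id=participant_id,
            start_s=np.array([p.start for p in puffs], dtype=float),
            duration_s=np.array([p.duration for p in puffs], dtype=float),
            voltage_v=np.array([p.voltage for p in puffs], dtype=float),
            current_a=cur,
            evaluation_days=evaluation_days,
        )


@dataclass
class StudyDataset:
    """All participant streams of one study plus free-form metadata."""

    streams: list[ParticipantStream]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.streams]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate participant_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.streams)

    def __iter__(self):
        return iter(self.streams)

    def to_frame(self) -> pd.DataFrame:
        """Long-format puff table in the puffs.csv dialect."""
        parts = []
        for s in self.streams:
            cur = s.current_a if s.current_a is not None else np.full(s.n_puffs, np.nan)
            parts.append(
                pd.DataFrame(
                    {
                        "participant_id": s.participant_id,
                        "start_s": s.start_s,
                        "duration_s": s.duration_s,
                        "voltage_v": s.voltage_v,
                        "current_a": cur,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=PUFF_COLUMNS)
        return pd.concat(parts, ignore_index=True)


def read_puff_csv(path: str | Path, evaluation_days: int = 14) -> StudyDataset:
    """Read a puffs.csv file into a :class:`StudyDataset`.

    Required columns: participant_id, start_s, duration_s, voltage_v;
    current_a is optional.  Rows are grouped by participant and sorted by
    start time; ordering/overlap violations raise :class:`ValidationError`
    listing the offending 1-based data rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = ["participant_id", "start_s", "duration_s", "voltage_v"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    numeric_cols = ["start_s", "duration_s", "voltage_v"]
    has_current = "current_a" in df.columns
    if has_current:
        numeric_cols.append("current_a")
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        blank = df[col].isna() if col == "current_a" else pd.Series(False, index=df.index)
        bad = parsed.isna() & ~blank
        if bad.any():
            row = int(bad.idxmax()) + 1  # 1-based data row
            raise ParseError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column {col!r} at row {row}",
                row=row,
            )
        df[col] = parsed
    streams = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("start_s", kind="stable")
        cur = grp["current_a"].to_numpy() if has_current else None
        if cur is not None and np.isnan(cur).all():
            cur = None
        streams.append(
            ParticipantStream(
                participant_id=str(pid),
                start_s=grp["start_s"].to_numpy(),
                duration_s=grp["duration_s"].to_numpy(),
                voltage_v=grp["voltage_v"].to_numpy(),
                current_a=cur,
                evaluation_days=evaluation_days,
            )
        )
    return StudyDataset(streams=streams, metadata={"source": str(path)})


def write_puff_csv(dataset: StudyDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def write_table_csv(
    rows: Iterable[Any],
    path: str | Path,
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write homogeneous records (dataclasses or mappings) as CSV.

    Round-trip contract: ``read_table_csv(write_table_csv(x))`` reproduces
    every field to float precision.  An empty list with ``fieldnames``
    yields a header-only file.
    """
    rows = list(rows)
    dicts: list[dict[str, Any]] = []
    for r in rows:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            dicts.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            dicts.append(r)
        else:
            raise TypeError(f"cannot serialise record of type {type(r).__name__}")
    if dicts:
        fieldnames = fieldnames or list(dicts[0])
        if any(list(d) != list(fieldnames) for d in dicts):
            raise FormatError("records are not homogeneous")
    df = pd.DataFrame(dicts, columns=list(fieldnames) if fieldnames else None)
    df.to_csv(path, index=False, float_format="%.12g")


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def iso_to_seconds(
    timestamps: Iterable[str], epoch: str | pd.Timestamp | None = None
) -> np.ndarray:
    """Convert ISO-8601 timestamps to float seconds since ``epoch``.

    ``epoch`` defaults to the earliest timestamp, which defines the study
    epoch for that participant.
    """
    ts = pd.to_datetime(list(timestamps))
    if len(ts) == 0:
        return np.array([], dtype=float)
    epoch = ts.min() if epoch is None else pd.Timestamp(epoch)
    return ((ts - epoch) / pd.Timedelta(seconds=1)).to_numpy(dtype=float)
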