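"""False-puff removal and prolonged-nonuse flagging.

Two cleansing steps precede sessionization:

1. *False puffs* — sub-0.5 s records whose voltage lies below the device's
   activated output (3.3 V for the product studied) are charger
   connect/disconnect artifacts and are removed.  The rule is a conjunction
   of the two conditions; a disjunctive variant is available for
   sensitivity analysis.
2. *Prolonged nonuse* — interpuff intervals (IPIs) that represent overnight
   or multi-hour breaks are flagged so they do not enter the mean-IPI
   session threshold.  Default: per-participant 95th-percentile rule
   (strictly greater than the quantile); an absolute-threshold mode
   (default 12 h) is also provided.

Nonuse flagging affects only the IPI signal: the puffs on both sides of a
flagged gap are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, overload

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import ParticipantStream, PuffRecord

WITHIN_CANDIDATE = "within-candidate"
NONUSE = "nonuse"


@dataclass(frozen=True)
class CleansingConfig:
    """Thresholds for the two cleansing rules.

    ``false_puff_rule`` is ``"and"`` (remove iff short AND low-voltage,
    the operational definition) or ``"or"`` (sensitivity variant).
    """

    false_puff_max_duration_s: float = 0.5
    device_output_voltage_v: float = 3.3
    nonuse_mode: str = "percentile"  # or "absolute"
    nonuse_quantile: float = 0.95
    nonuse_absolute_s: float = 43200.0  # 12 h
    false_puff_rule: str = "and"

    def __post_init__(self) -> None:
        if self.false_puff_max_duration_s <= 0 or self.device_output_voltage_v <= 0:
            raise ConfigurationError("cleansing thresholds must be positive")
        if not 0 < self.nonuse_quantile < 1:
            raise ConfigurationError("nonuse_quantile must lie in (0, 1)")
        if self.nonuse_absolute_s <= 0:
            raise ConfigurationError("nonuse_absolute_s must be positive")
        if self.nonuse_mode not in ("percentile", "absolute"):
            raise ConfigurationError(f"unknown nonuse_mode {self.nonuse_mode!r}")
        if self.false_puff_rule not in ("and", "or"):
            raise ConfigurationError(f"unknown false_puff_rule {self.false_puff_rule!r}")


@dataclass(frozen=True)
class IpiInterval:
    """The gap between the end of one puff and the start of the next."""

    from_puff: int
    to_puff: int
    length: float
    klass: str = WITHIN_CANDIDATE

    def __post_init__(self) -> None:
        if self.to_puff != self.from_puff + 1:
            raise ValidationError("IPI must connect consecutive puffs")
        if self.length < 0:
            raise ValidationError(f"negative IPI length {self.length}")


@dataclass
class CleanStream:
    """A participant's puff series after false-puff removal.

    ``kept_index`` maps surviving puffs back to positions in the raw
    stream; ``ipi_nonuse`` marks IPIs flagged as prolonged nonuse (all
    False until :func:`flag_nonuse` is applied).
    """

    participant_id: str
    start_s: np.ndarray
    duration_s: np.ndarray
    voltage_v: np.ndarray
    current_a: np.ndarray | None
    kept_index: np.ndarray
    removed_count: int
    evaluation_days: int = 14
    ipi_nonuse: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ipi_nonuse is None:
            self.ipi_nonuse = np.zeros(max(self.n_puffs - 1, 0), dtype=bool)

    @property
    def n_puffs(self) -> int:
        return int(self.start_s.size)

    @property
    def ipi_lengths(self) -> np.ndarray:
        return compute_ipi_lengths(self.start_s, self.duration_s)

    @property
    def ipis(self) -> list[IpiInterval]:
        lengths = self.ipi_lengths
        return [
            IpiInterval(i, i + 1, float(lengths[i]), NONUSE if self.ipi_nonuse[i] else WITHIN_CANDIDATE)
            for i in range(lengths.size)
        ]

    @property
    def puffs(self) -> list[PuffRecord]:
        cur = self.current_a if self.current_a is not None else [None] * self.n_puffs
        return [
            PuffRecord(s, d, v, c)
            for s, d, v, c in zip(self.start_s, self.duration_s, self.voltage_v, cur)
        ]


def false_puff_mask(stream: ParticipantStream, cfg: CleansingConfig) -> np.ndarray:
    """Boolean mask of puffs classified as charger artifacts."""
    short = stream.duration_s < cfg.false_puff_max_duration_s
    low = stream.voltage_v < cfg.device_output_voltage_v
    return (short & low) if cfg.false_puff_rule == "and" else (short | low)


def remove_false_puffs(stream: ParticipantStream, cfg: CleansingConfig | None = None) -> CleanStream:
    """Drop charger artifacts; survivors keep their original timestamps."""
    cfg = cfg or CleansingConfig()
    drop = false_puff_mask(stream, cfg)
    keep = np.flatnonzero(~drop)
    return CleanStream(
        participant_id=stream.participant_id,
        start_s=stream.start_s[keep],
        duration_s=stream.duration_s[keep],
        voltage_v=stream.voltage_v[keep],
        current_a=None if stream.current_a is None else stream.current_a[keep],
        kept_index=keep,
        removed_count=int(drop.sum()),
        evaluation_days=stream.evaluation_days,
    )


def compute_ipi_lengths(start_s: np.ndarray, duration_s: np.ndarray) -> np.ndarray:
    """IPI[i] = start[i+1] - (start[i] + duration[i]), length n-1."""
    if start_s.size < 2:
        return np.array([], dtype=float)
    lengths = start_s[1:] - (start_s[:-1] + duration_s[:-1])
    if np.any(lengths < 0):
        bad = np.flatnonzero(lengths < 0)
        raise ValidationError(f"overlapping puffs at indices {bad[:10].tolist()}", rows=bad.tolist())
    return lengths


def compute_ipis(puffs: Sequence[PuffRecord]) -> list[IpiInterval]:
    """Object-level IPI computation from an ordered puff list."""
    start = np.array([p.start for p in puffs], dtype=float)
    dur = np.array([p.duration for p in puffs], dtype=float)
    lengths = compute_ipi_lengths(start, dur)
    return [IpiInterval(i, i + 1, float(x)) for i, x in enumerate(lengths)]


def nonuse_mask(lengths: np.ndarray, cfg: CleansingConfig) -> np.ndarray:
    """Boolean nonuse flags for an array of IPI lengths.

    Percentile mode flags lengths strictly greater than the participant's
    ``nonuse_quantile`` (linear-interpolation quantile); absolute mode
    flags lengths >= ``nonuse_absolute_s``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        return np.zeros(0, dtype=bool)
    if cfg.nonuse_mode == "percentile":
        cut = np.quantile(lengths, cfg.nonuse_quantile)
        return lengths > cut
    return lengths >= cfg.nonuse_absolute_s


@overload
def flag_nonuse(ipis: CleanStream, cfg: CleansingConfig) -> CleanStream: ...
@overload
def flag_nonuse(ipis: Sequence[IpiInterval], cfg: CleansingConfig) -> list[IpiInterval]: ...


def flag_nonuse(ipis, cfg: CleansingConfig):
    """Classify each IPI as within-candidate or nonuse.

    Accepts either a :class:`CleanStream` (returns a copy with
    ``ipi_nonuse`` set) or a list of :class:`IpiInterval`.
    """
    if isinstance(ipis, CleanStream):
        mask = nonuse_mask(ipis.ipi_lengths, cfg)
        return replace(ipis, ipi_nonuse=mask)
    lengths = np.array([iv.length for iv in ipis], dtype=float)
    mask = nonuse_mask(lengths, cfg)
    return [
        replace(iv, klass=NONUSE if m else WITHIN_CANDIDATE)
        for iv, m in zip(ipis, mask)
    ]
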