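"""Hierarchical generator of multi-day puff streams with ground truth.

The generator emulates the record stream of an in-line puff-logging
device worn by an e-cigarette user over a multi-week ambulatory study:

* each simulated day has a waking window opening at 07:00 whose length is
  24 h minus an overnight nonuse gap drawn uniformly from 12–16 h;
* the number of use sessions per day is Poisson; puffs per session is
  1 + Poisson (so sessions are never empty);
* within-session interpuff intervals (IPIs) and puff durations are drawn
  from truncated lognormals whose *truncated* mean and SD are
  moment-matched to the requested values (positive, right-skewed, in line
  with the large SDs observed in field data);
* intersession gaps are lognormal (CV 0.5) around the requested ISI mean
  with a hard lower truncation, and are compressed proportionally toward
  that floor whenever a day's drawn schedule would overrun the waking
  window — group presets describing very frequent use are therefore
  honoured in session counts and within-session structure, while emergent
  ISI means may fall below the preset;
* genuine puffs log the activated product voltage (3.3 V); charger
  artifacts ("false puffs") are injected into overnight gaps at a Poisson
  daily rate with duration U(0.05, 0.45) s and voltage 0.

Every puff carries a ground-truth session index and every inter-puff gap
a ground-truth class, so downstream segmentation can be scored exactly.
Seeding is hierarchical: a study-level seed spawns one deterministic
substream per participant index, so any participant can be regenerated
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .errors import ConfigurationError
from .groupstats import DEFAULT_PES_MAPPING, PesResponse
from .io import SECONDS_PER_DAY, ParticipantStream, StudyDataset

GENUINE_VOLTAGE_V = 3.3
GENUINE_CURRENT_A = 1.0
WAKE_HOUR = 7.0

INTERVAL_WITHIN = "within-session"
INTERVAL_INTERSESSION = "intersession"
INTERVAL_NONUSE = "nonuse"
INTERVAL_ARTIFACT = "artifact"


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one use group.

    Means/SDs are the *targets of the realised process*: the truncated
    sampling distributions are moment-matched so that, e.g., the expected
    within-session IPI equals ``within_ipi_mean_s`` exactly.
    ``isi_min_s`` optionally sets a hard floor on intersession gaps
    (default: twice the within-IPI upper truncation bound), which lets a
    scenario guarantee that true ISIs dominate true within-IPIs.
    """

    label: str
    sessions_per_day_mean: float
    puffs_per_session_mean: float
    within_ipi_mean_s: float
    within_ipi_sd_s: float
    puff_duration_mean_s: float
    puff_duration_sd_s: float
    isi_mean_min: float
    overnight_gap_hours: tuple[float, float] = (12.0, 16.0)
    false_puff_rate_per_day: float = 2.0
    isi_min_s: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("low", "moderate", "high"):
            raise ConfigurationError(f"unknown group label {self.label!r}")
        positive = {
            "sessions_per_day_mean": self.sessions_per_day_mean,
            "within_ipi_mean_s": self.within_ipi_mean_s,
            "puff_duration_mean_s": self.puff_duration_mean_s,
            "isi_mean_min": self.isi_mean_min,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        if self.puffs_per_session_mean < 1:
            raise ConfigurationError("puffs_per_session_mean must be >= 1")
        if self.within_ipi_sd_s < 0 or self.puff_duration_sd_s < 0:
            raise ConfigurationError("SDs must be >= 0")
        if self.false_puff_rate_per_day < 0:
            raise ConfigurationError("false_puff_rate_per_day must be >= 0")
        lo, hi = self.overnight_gap_hours
        if not 0 < lo <= hi < 24:
            raise ConfigurationError("overnight_gap_hours must satisfy 0 < low <= high < 24")
        if not self.within_ipi_mean_s < self.isi_mean_min * 60.0:
            raise ConfigurationError(
                "within_ipi_mean_s must be below isi_mean_min (sessions must be "
                "separable in expectation)"
            )

    @property
    def within_ipi_hi(self) -> float:
        return self.within_ipi_mean_s + 4.0 * self.within_ipi_sd_s

    @property
    def isi_floor_s(self) -> float:
        return self.isi_min_s if self.isi_min_s is not None else 2.0 * self.within_ipi_hi


@dataclass
class TruthLabel:
    """Ground truth for one generated stream.

    ``session_index`` is per puff (-1 for charger artifacts) and
    non-decreasing along the stream; ``interval_class`` labels the gap
    between consecutive puffs; ``session_day`` maps each true session to
    its simulated day.
    """

    session_index: np.ndarray
    interval_class: np.ndarray
    session_day: np.ndarray
    group_label: str | None = None

    @property
    def n_sessions(self) -> int:
        return int(self.session_day.size)

    @property
    def is_artifact(self) -> np.ndarray:
        return self.session_index < 0


@dataclass
class StudyTruth:
    labels: dict[str, TruthLabel] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# truncated lognormal with moment-matched truncated mean/SD


def _trunc_lognorm_moments(mu: float, sigma: float, lo: float, hi: float):
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    z = special.ndtr(b) - special.ndtr(a)
    if z <= 0:
        return np.nan, np.nan
    m1 = np.exp(mu + sigma**2 / 2) * (special.ndtr(b - sigma) - special.ndtr(a - sigma)) / z
    m2 = (
        np.exp(2 * mu + 2 * sigma**2)
        * (special.ndtr(b - 2 * sigma) - special.ndtr(a - 2 * sigma))
        / z
    )
    var = max(m2 - m1**2, 0.0)
    return m1, np.sqrt(var)


@dataclass(frozen=True)
class TruncatedLognormal:
    """Lognormal restricted to [lo, hi], sampled by rejection."""

    mu: float
    sigma: float
    lo: float
    hi: float

    @property
    def mean(self) -> float:
        if self.sigma == 0.0:
            return float(np.exp(self.mu))
        return float(_trunc_lognorm_moments(self.mu, self.sigma, self.lo, self.hi)[0])

    @property
    def sd(self) -> float:
        if self.sigma == 0.0:
            return 0.0
        return float(_trunc_lognorm_moments(self.mu, self.sigma, self.lo, self.hi)[1])

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if size == 0:
            return np.array([], dtype=float)
        if self.sigma == 0.0:
            return np.full(size, np.exp(self.mu))
        out = np.empty(size)
        filled = 0
        for _ in range(1000):
            need = size - filled
            draw = rng.lognormal(self.mu, self.sigma, size=max(need * 2, 16))
            ok = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(ok.size, need)
            out[filled : filled + take] = ok[:take]
            filled += take
            if filled == size:
                return out
        raise ConfigurationError("truncated lognormal rejection sampling stalled")


def fit_truncated_lognormal(
    mean: float, sd: float, lo: float | None = None, hi: float | None = None
) -> TruncatedLognormal:
    """Lognormal whose [lo, hi]-truncated mean/SD equal the targets.

    Solved by root-finding on (mu, log sigma) with the closed-form
    truncated moments, starting from the untruncated parameterisation.
    With sd == 0 the distribution degenerates to the constant ``mean``.
    """
    if mean <= 0:
        raise ConfigurationError("mean must be positive")
    if sd == 0.0:
        return TruncatedLognormal(float(np.log(mean)), 0.0, mean, mean)
    lo = max(1e-3, mean - 4.0 * sd) if lo is None else lo
    hi = mean + 4.0 * sd if hi is None else hi
    if not 0 < lo < mean < hi:
        raise ConfigurationError(f"truncation [{lo}, {hi}] must bracket the mean {mean}")
    cv2 = (sd / mean) ** 2
    sigma0 = np.sqrt(np.log1p(cv2))
    mu0 = np.log(mean) - sigma0**2 / 2

    def residual(theta):
        mu, logsig = theta
        m, s = _trunc_lognorm_moments(mu, np.exp(logsig), lo, hi)
        if not np.isfinite(m):
            return [1e6, 1e6]
        return [m - mean, s - sd]

    sol = optimize.root(residual, x0=[mu0, np.log(sigma0)], method="hybr")
    if sol.success and np.all(np.abs(sol.fun) < 1e-8 * max(mean, sd)):
        mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    else:  # fall back to untruncated moment matching
        mu, sigma = mu0, sigma0
    return TruncatedLognormal(float(mu), float(sigma), float(lo), float(hi))


class _GroupDists:
    """Per-group sampling distributions, built once per GroupParams."""

    def __init__(self, p: GroupParams):
        self.ipi = fit_truncated_lognormal(
            p.within_ipi_mean_s, p.within_ipi_sd_s, hi=p.within_ipi_hi
        )
        self.dur = fit_truncated_lognormal(p.puff_duration_mean_s, p.puff_duration_sd_s)
        isi_mean = p.isi_mean_min * 60.0
        floor = p.isi_floor_s
        if isi_mean <= floor * 1.05:
            self.isi = TruncatedLognormal(float(np.log(floor)), 0.0, floor, floor)
        else:
            isi_sd = 0.5 * isi_mean  # fixed CV; shape not specified by any preset
            self.isi = fit_truncated_lognormal(
                isi_mean, isi_sd, lo=floor, hi=isi_mean + 6 * isi_sd
            )


_DIST_CACHE: dict[GroupParams, _GroupDists] = {}


def _dists(params: GroupParams) -> _GroupDists:
    if params not in _DIST_CACHE:
        _DIST_CACHE[params] = _GroupDists(params)
    return _DIST_CACHE[params]


# ---------------------------------------------------------------------------
# simulation


def _compress_gaps(gaps: np.ndarray, avail: float, floor: float) -> np.ndarray:
    """Scale intersession gaps toward the floor so the day's schedule fits
    its waking window; the floor is only violated when even floored gaps
    do not fit."""
    if gaps.size == 0 or gaps.sum() <= avail:
        return gaps
    floored = gaps.size * floor
    if avail <= floored:
        return np.full(gaps.size, max(avail / gaps.size, 1.0))
    scale = (avail - floored) / (gaps.sum() - floored)
    return floor + (gaps - floor) * scale


def simulate_participant(
    params: GroupParams,
    days: int = 14,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "P000",
) -> tuple[ParticipantStream, TruthLabel]:
    """Generate one participant's raw stream plus ground truth.

    Deterministic in (params, days, seed).
    """
    if days < 1:
        raise ConfigurationError("days must be >= 1")
    rng = np.random.default_rng(seed)
    dists = _dists(params)
    horizon = days * SECONDS_PER_DAY

    starts: list[np.ndarray] = []
    durs: list[np.ndarray] = []
    sess_of_puff: list[np.ndarray] = []
    session_day: list[int] = []
    fp_starts: list[float] = []
    fp_durs: list[float] = []
    n_sessions = 0
    prev_end = 0.0

    for d in range(days):
        wake = d * SECONDS_PER_DAY + WAKE_HOUR * 3600.0
        gap_h = rng.uniform(*params.overnight_gap_hours)
        window_len = (24.0 - gap_h) * 3600.0
        day_start = max(wake, prev_end + 60.0)
        k = int(rng.poisson(params.sessions_per_day_mean))
        day_last_end = day_start
        if k > 0:
            counts = 1 + rng.poisson(params.puffs_per_session_mean - 1.0, size=k)
            total = int(counts.sum())
            dur = dists.dur.sample(rng, total)
            wipi = dists.ipi.sample(rng, total - k)
            # per-session sums of durations and within-IPIs
            sess_edge = np.concatenate([[0], np.cumsum(counts)])
            cd = np.concatenate([[0.0], np.cumsum(dur)])
            dur_sum = cd[sess_edge[1:]] - cd[sess_edge[:-1]]
            ipi_edge = np.concatenate([[0], np.cumsum(counts - 1)])
            cw = np.concatenate([[0.0], np.cumsum(wipi)])
            wipi_sum = cw[ipi_edge[1:]] - cw[ipi_edge[:-1]]
            sess_len = dur_sum + wipi_sum
            gaps = dists.isi.sample(rng, k - 1)
            offset = rng.uniform(0.0, min(3600.0, 0.1 * window_len))
            avail = window_len - offset - sess_len.sum()
            gaps = _compress_gaps(gaps, avail, dists.isi.lo)
            sess_start = day_start + offset + np.concatenate(
                [[0.0], np.cumsum(sess_len[:-1] + gaps)]
            )
            # puff starts: within each session, cumulative durations + IPIs
            step = np.empty(total)
            step[sess_edge[:-1]] = sess_start  # session first puffs: absolute
            inner = np.ones(total, dtype=bool)
            inner[sess_edge[:-1]] = False
            step[inner] = dur[np.flatnonzero(inner) - 1] + wipi
            grp = np.repeat(np.arange(k), counts)
            # cumulative sum of steps with a reset at each session start
            c = np.cumsum(np.where(inner, step, 0.0))
            abs_start = sess_start[grp] + c - c[sess_edge[:-1]][grp]
            starts.append(abs_start)
            durs.append(dur)
            sess_of_puff.append(n_sessions + grp)
            session_day.extend([d] * k)
            n_sessions += k
            day_last_end = float(abs_start[-1] + dur[-1])
        prev_end = day_last_end
        # charger artifacts inside the overnight gap
        n_fp = int(rng.poisson(params.false_puff_rate_per_day))
        if n_fp > 0:
            next_wake = (d + 1) * SECONDS_PER_DAY + WAKE_HOUR * 3600.0
            gap_lo = max(day_start + window_len, day_last_end) + 60.0
            gap_hi = min(next_wake, horizon) - 60.0
            if gap_hi - gap_lo > 10.0 * n_fp:
                t = np.sort(rng.uniform(gap_lo, gap_hi, size=n_fp))
                dfp = rng.uniform(0.05, 0.45, size=n_fp)
                keep_t, keep_d, last = [], [], -np.inf
                for ti, di in zip(t, dfp):
                    if ti > last + 1.0:
                        keep_t.append(ti)
                        keep_d.append(di)
                        last = ti + di
                fp_starts.extend(keep_t)
                fp_durs.extend(keep_d)

    g_start = np.concatenate(starts) if starts else np.array([], dtype=float)
    g_dur = np.concatenate(durs) if durs else np.array([], dtype=float)
    g_sess = (
        np.concatenate(sess_of_puff).astype(int)
        if sess_of_puff
        else np.array([], dtype=int)
    )
    a_start = np.asarray(fp_starts, dtype=float)
    a_dur = np.asarray(fp_durs, dtype=float)

    start = np.concatenate([g_start, a_start])
    dur_all = np.concatenate([g_dur, a_dur])
    volt = np.concatenate(
        [np.full(g_start.size, GENUINE_VOLTAGE_V), np.zeros(a_start.size)]
    )
    cur = np.concatenate(
        [np.full(g_start.size, GENUINE_CURRENT_A), np.zeros(a_start.size)]
    )
    sess = np.concatenate([g_sess, np.full(a_start.size, -1, dtype=int)])
    order = np.argsort(start, kind="stable")
    start, dur_all, volt, cur, sess = (
        start[order], dur_all[order], volt[order], cur[order], sess[order]
    )
    keep = start + dur_all <= horizon  # defensive clip at the study horizon
    start, dur_all, volt, cur, sess = (
        start[keep], dur_all[keep], volt[keep], cur[keep], sess[keep]
    )
    day_of = np.asarray(session_day, dtype=int)
    interval_class = _interval_classes(sess, day_of)
    stream = ParticipantStream(
        participant_id=participant_id,
        start_s=start,
        duration_s=dur_all,
        voltage_v=volt,
        current_a=cur,
        evaluation_days=days,
    )
    truth = TruthLabel(
        session_index=sess,
        interval_class=interval_class,
        session_day=day_of,
        group_label=params.label,
    )
    return stream, truth


def _interval_classes(sess: np.ndarray, session_day: np.ndarray) -> np.ndarray:
    n = sess.size
    if n < 2:
        return np.array([], dtype=object)
    out = np.empty(n - 1, dtype=object)
    a, b = sess[:-1], sess[1:]
    artifact = (a < 0) | (b < 0)
    same = (a == b) & ~artifact
    out[artifact] = INTERVAL_ARTIFACT
    out[same] = INTERVAL_WITHIN
    cross = ~artifact & ~same
    idx = np.flatnonzero(cross)
    for i in idx:
        out[i] = (
            INTERVAL_INTERSESSION
            if session_day[a[i]] == session_day[b[i]]
            else INTERVAL_NONUSE
        )
    return out


def simulate_study(
    group_params: Sequence[GroupParams],
    n_per_group: Sequence[int],
    days: int = 14,
    seed: int = 0,
) -> tuple[StudyDataset, StudyTruth]:
    """Generate a full study cohort with per-participant substreams.

    Participant i's stream is seeded from SeedSequence([seed, i]), so it
    is reproducible independently of cohort size or ordering.
    """
    if len(group_params) != len(n_per_group):
        raise ConfigurationError("group_params and n_per_group must have equal length")
    if any(n < 0 for n in n_per_group):
        raise ConfigurationError("n_per_group entries must be >= 0")
    streams, truth = [], StudyTruth()
    idx = 0
    for params, n in zip(group_params, n_per_group):
        for _ in range(n):
            pid = f"P{idx:03d}"
            ss = np.random.SeedSequence([int(seed), idx])
            stream, label = simulate_participant(params, days, ss, participant_id=pid)
            streams.append(stream)
            truth.labels[pid] = label
            truth.groups[pid] = params.label
            idx += 1
    dataset = StudyDataset(
        streams=streams,
        metadata={"seed": int(seed), "days": int(days), "generator": "pufftop.synthetic"},
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# presets and scenario files

#: Field-data group presets: generative means/SDs set to the observed
#: per-group topography (within-session IPI, puff duration, sessions/day,
#: puffs/session, ISI) of low/moderate/high users of a closed-system ENDS.
def table2_preset() -> list[GroupParams]:
    return [
        GroupParams(
            label="low", sessions_per_day_mean=7.49, puffs_per_session_mean=4.40,
            within_ipi_mean_s=61.66, within_ipi_sd_s=63.04,
            puff_duration_mean_s=2.10, puff_duration_sd_s=0.62, isi_mean_min=255.20,
        ),
        GroupParams(
            label="moderate", sessions_per_day_mean=30.95, puffs_per_session_mean=3.37,
            within_ipi_mean_s=25.56, within_ipi_sd_s=16.57,
            puff_duration_mean_s=2.18, puff_duration_sd_s=0.71, isi_mean_min=94.09,
        ),
        GroupParams(
            label="high", sessions_per_day_mean=32.26, puffs_per_session_mean=6.71,
            within_ipi_mean_s=32.78, within_ipi_sd_s=22.41,
            puff_duration_mean_s=2.19, puff_duration_sd_s=0.72, isi_mean_min=84.64,
        ),
    ]


def separable_preset() -> list[GroupParams]:
    """A regime in which every true intersession gap is at least ten times
    the largest possible within-session IPI, so the adaptive-threshold
    segmentation must recover ground truth exactly."""
    return [
        GroupParams(
            label="moderate", sessions_per_day_mean=8.0, puffs_per_session_mean=6.0,
            within_ipi_mean_s=20.0, within_ipi_sd_s=5.0,
            puff_duration_mean_s=2.2, puff_duration_sd_s=0.5, isi_mean_min=30.0,
            isi_min_s=400.0,  # 10 x the within-IPI upper truncation bound (40 s)
        )
    ]


PRESETS = {"table2": table2_preset, "separable": separable_preset}

#: Observed split of the analysed cohort across use groups.
TABLE2_N_PER_GROUP = [12, 24, 19]


def dump_scenario(group_params: Sequence[GroupParams], path: str | Path) -> None:
    doc = {
        "groups": [
            {
                "label": p.label,
                "sessions_per_day_mean": p.sessions_per_day_mean,
                "puffs_per_session_mean": p.puffs_per_session_mean,
                "within_ipi_mean_s": p.within_ipi_mean_s,
                "within_ipi_sd_s": p.within_ipi_sd_s,
                "puff_duration_mean_s": p.puff_duration_mean_s,
                "puff_duration_sd_s": p.puff_duration_sd_s,
                "isi_mean_min": p.isi_mean_min,
                "overnight_gap_hours": list(p.overnight_gap_hours),
                "false_puff_rate_per_day": p.false_puff_rate_per_day,
                "isi_min_s": p.isi_min_s,
            }
            for p in group_params
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenario(path: str | Path) -> list[GroupParams]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ConfigurationError(f"scenario file {path} lacks a 'groups' list")
    out = []
    for g in doc["groups"]:
        g = dict(g)
        if "overnight_gap_hours" in g:
            g["overnight_gap_hours"] = tuple(g["overnight_gap_hours"])
        out.append(GroupParams(**g))
    return out


def truth_to_frame(truth: StudyTruth) -> pd.DataFrame:
    """Long-format ground truth (truth.csv dialect): one row per puff with
    its session index and the class of the interval that follows it."""
    rows = []
    for pid in sorted(truth.labels):
        lab = truth.labels[pid]
        n = lab.session_index.size
        following = np.concatenate([lab.interval_class, [""]]) if n else []
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "puff_index": np.arange(n),
                    "session_index": lab.session_index,
                    "interval_class": following,
                }
            )
        )
    cols = ["participant_id", "puff_index", "session_index", "interval_class"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


# Observed PES domain means by use group, as a preset for Likert draws.
TABLE3_PES_PRESET: dict[str, dict[str, float]] = {
    "low": {
        "comfort and ease of use": 4.26, "satisfaction": 3.97,
        "psychological reward": 3.58, "aversion": 2.58, "relief": 4.21,
    },
    "moderate": {
        "comfort and ease of use": 4.38, "satisfaction": 4.78,
        "psychological reward": 3.98, "aversion": 2.22, "relief": 4.45,
    },
    "high": {
        "comfort and ease of use": 5.29, "satisfaction": 5.05,
        "psychological reward": 3.65, "aversion": 1.55, "relief": 4.04,
    },
}


def simulate_pes_responses(
    domain_means: Mapping[str, float],
    n: int,
    sd: float = 1.2,
    seed: int = 0,
    mapping: Mapping[int, str] | None = None,
) -> list[PesResponse]:
    """Draw simple Likert responses: each item is a rounded normal around
    its domain mean, clipped to the 1..7 scale."""
    mapping = mapping or DEFAULT_PES_MAPPING
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        items = np.empty(21, dtype=int)
        for item in range(1, 22):
            mu = domain_means[mapping[item]]
            items[item - 1] = int(np.clip(np.rint(rng.normal(mu, sd)), 1, 7))
        out.append(PesResponse(participant_id=f"S{i:03d}", items=items))
    return out
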