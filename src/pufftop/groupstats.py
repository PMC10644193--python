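"""Use-group stratification and between-group statistics.

Participants are stratified by percentile rank of mean daily puff count:
below-10-puff totals are excluded first, then ranks over the remaining
cohort define low ([10, 40)), moderate ([40, 70)) and high (>= 70) use.
Participants who survive the exclusion but rank below the 10th percentile
are assigned to the low group (the exclusion makes this set empty in a
cohort resembling the original study).

End points are compared with a classical one-way fixed-effects ANOVA and
Bonferroni-adjusted pairwise t tests using the pooled within-group
variance (SPSS-style post hoc).  Product Evaluation Scale (PES) responses
— 21 seven-point Likert items — are aggregated into five domain means and
compared pairwise with two-sided t tests at a Bonferroni-adjusted alpha
(default .016).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .errors import ConfigurationError
from .metrics import ParticipantSummary

GROUP_ORDER = ["low", "moderate", "high"]
EXCLUDED = "excluded"

PES_DOMAINS = [
    "satisfaction",
    "psychological reward",
    "aversion",
    "comfort and ease of use",
    "relief",
]

# Synthetic placeholder mapping of the 21 Likert items to the five domains,
# following the conventional domain sizes of product-evaluation
# questionnaires (3 satisfaction, 5 psychological reward, 4 aversion,
# 7 relief, 2 comfort/ease-of-use items).  The instrument's true item
# assignment is not public; override via a pes_mapping.yaml file.
DEFAULT_PES_MAPPING: dict[int, str] = {
    **{i: "satisfaction" for i in range(1, 4)},
    **{i: "psychological reward" for i in range(4, 9)},
    **{i: "aversion" for i in range(9, 13)},
    **{i: "relief" for i in range(13, 20)},
    **{i: "comfort and ease of use" for i in range(20, 22)},
}


@dataclass(frozen=True)
class UseGroupAssignment:
    participant_id: str
    percentile_rank: float  # NaN for excluded participants
    group: str


@dataclass
class GroupComparison:
    """One end point's ANOVA across use groups plus Bonferroni post hoc."""

    endpoint: str
    group_n: dict[str, int]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    f: float
    p_overall: float
    pairwise_raw: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_adjusted: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class PesResponse:
    """One participant's 21-item PES response (scores 1..7)."""

    participant_id: str
    items: np.ndarray

    def __post_init__(self) -> None:
        items = np.asarray(self.items, dtype=int)
        object.__setattr__(self, "items", items)
        if items.size != 21:
            raise ConfigurationError(f"PES expects 21 items, got {items.size}")
        if np.any((items < 1) | (items > 7)):
            raise ConfigurationError("PES item scores must lie in 1..7")


def percentile_ranks(
    values: np.ndarray, method: Literal["linear", "nearest"] = "linear"
) -> np.ndarray:
    """Percentile rank in [0, 100] of each value within its cohort.

    ``linear`` (default): rank = 100 * (r - 1) / (n - 1) with r the
    average rank of ties, so the minimum scores 0 and the maximum 100.
    ``nearest``: nearest-rank estimator, 100 * r / n with r the maximal
    rank of ties.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return np.array([], dtype=float)
    if n == 1:
        return np.zeros(1)
    if method == "linear":
        r = stats.rankdata(values, method="average")
        return (r - 1.0) / (n - 1.0) * 100.0
    if method == "nearest":
        r = stats.rankdata(values, method="max")
        return r / n * 100.0
    raise ConfigurationError(f"unknown percentile method {method!r}")


def assign_groups(
    summaries: Sequence[ParticipantSummary],
    bins: tuple[float, float, float] = (10.0, 40.0, 70.0),
    min_total_puffs: int = 10,
    method: Literal["linear", "nearest"] = "linear",
) -> list[UseGroupAssignment]:
    """Exclude near-zero users, then bin the rest by daily-puff percentile.

    Bin edges are left-closed/right-open: low [bins[0], bins[1]),
    moderate [bins[1], bins[2]), high >= bins[2]; ranks below bins[0]
    fall to low.
    """
    if not summaries:
        raise ConfigurationError("assign_groups needs at least one summary")
    lo_edge, mid_edge, hi_edge = bins
    if not (0 <= lo_edge < mid_edge < hi_edge <= 100):
        raise ConfigurationError(f"bin edges must increase within [0, 100]: {bins}")
    included = [s for s in summaries if s.total_puffs >= min_total_puffs]
    ranks = percentile_ranks(
        np.array([s.daily_puffs for s in included]), method=method
    )
    rank_of = {s.participant_id: float(r) for s, r in zip(included, ranks)}
    out = []
    for s in summaries:
        if s.participant_id not in rank_of:
            out.append(UseGroupAssignment(s.participant_id, float("nan"), EXCLUDED))
            continue
        r = rank_of[s.participant_id]
        group = "high" if r >= hi_edge else "moderate" if r >= mid_edge else "low"
        out.append(UseGroupAssignment(s.participant_id, r, group))
    return out


def _pooled_pairwise(
    groups: dict[str, np.ndarray], n_comparisons: int
) -> tuple[dict, dict]:
    """Two-sided t tests on the pooled within-group variance, df = N - k."""
    ns = {g: v.size for g, v in groups.items()}
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df = sum(ns.values()) - len(groups)
    mse = ssw / df if df > 0 else float("nan")
    raw, adj = {}, {}
    for a, b in itertools.combinations(groups, 2):
        if ns[a] < 2 or ns[b] < 2 or not mse > 0:
            raw[(a, b)] = adj[(a, b)] = float("nan")
            continue
        se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        t = (groups[a].mean() - groups[b].mean()) / se
        p = 2.0 * stats.t.sf(abs(t), df)
        raw[(a, b)] = float(p)
        adj[(a, b)] = float(min(1.0, p * n_comparisons))
    return raw, adj


def compare_groups(
    assignments: Sequence[UseGroupAssignment],
    summaries: Sequence[ParticipantSummary],
    endpoint: str,
) -> GroupComparison:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t tests for one
    end point across the non-excluded use groups.

    Participants with an undefined (NaN) value for the end point are
    dropped from this comparison.
    """
    by_id = {s.participant_id: s for s in summaries}
    groups: dict[str, np.ndarray] = {}
    for g in GROUP_ORDER:
        vals = np.array(
            [
                getattr(by_id[a.participant_id], endpoint)
                for a in assignments
                if a.group == g and a.participant_id in by_id
            ],
            dtype=float,
        )
        vals = vals[~np.isnan(vals)]
        if vals.size:
            groups[g] = vals
    if len(groups) < 2:
        raise ConfigurationError(
            f"endpoint {endpoint!r}: need >= 2 non-empty groups, got {len(groups)}"
        )
    if all(np.ptp(v) == 0 for v in groups.values()) and len(
        {v[0] for v in groups.values()}
    ) == 1:
        f, p = 0.0, 1.0  # zero between- and within-group variance
    else:
        f, p = stats.f_oneway(*groups.values())
    n_pairs = len(list(itertools.combinations(groups, 2)))
    raw, adj = _pooled_pairwise(groups, n_pairs)
    return GroupComparison(
        endpoint=endpoint,
        group_n={g: int(v.size) for g, v in groups.items()},
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sds={g: float(v.std(ddof=1)) if v.size > 1 else float("nan") for g, v in groups.items()},
        f=float(f),
        p_overall=float(p),
        pairwise_raw=raw,
        pairwise_adjusted=adj,
    )


def load_pes_mapping(path: str | Path) -> dict[int, str]:
    """Read an item->domain mapping from YAML ({item_number: domain})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mapping = {int(k): str(v) for k, v in raw.items()}
    bad = sorted(set(mapping.values()) - set(PES_DOMAINS))
    if bad:
        raise ConfigurationError(f"unknown PES domains in mapping: {bad}")
    return mapping


def pes_domain_scores(
    response: PesResponse, mapping: Mapping[int, str] | None = None
) -> dict[str, float]:
    """Arithmetic mean of each domain's item scores."""
    mapping = mapping or DEFAULT_PES_MAPPING
    missing = [i for i in range(1, 22) if i not in mapping]
    if missing:
        raise ConfigurationError(f"PES items without a domain mapping: {missing}")
    scores: dict[str, list[int]] = {}
    for item, domain in mapping.items():
        scores.setdefault(domain, []).append(int(response.items[item - 1]))
    return {d: float(np.mean(v)) for d, v in scores.items()}


@dataclass(frozen=True)
class PesTestRow:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    p: float
    significant: bool


def pes_group_tests(
    scores_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.016,
    welch: bool = False,
) -> list[PesTestRow]:
    """Pairwise two-sided t tests of a PES domain score across groups.

    Pooled-variance Student t by default; ``welch=True`` drops the
    equal-variance assumption.  Significance is strict: p < alpha.
    """
    if len(scores_by_group) < 2:
        raise ConfigurationError("pes_group_tests needs >= 2 groups")
    rows = []
    for a, b in itertools.combinations(scores_by_group, 2):
        xa = np.asarray(scores_by_group[a], dtype=float)
        xb = np.asarray(scores_by_group[b], dtype=float)
        if xa.size < 2 or xb.size < 2:
            t = p = float("nan")
        elif np.ptp(np.concatenate([xa, xb])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
        rows.append(
            PesTestRow(
                a, b, xa.size, xb.size, float(xa.mean()) if xa.size else float("nan"),
                float(xb.mean()) if xb.size else float("nan"),
                float(t), float(p), bool(p < alpha),
            )
        )
    return rows


def format_p_value(p: float) -> str:
    """Display convention: three decimals, floored at '<.001'."""
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")
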