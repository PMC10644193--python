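"""End-to-end pipeline: cleanse -> sessionize -> summarise -> compare.

`run_pipeline` maps the per-participant chain over a study dataset,
assigns use groups, runs the between-group comparisons and keeps a
stage-count ledger (puffs in, false puffs removed, nonuse gaps flagged,
sessions formed, participants excluded) whose conservation is testable:
at every stage, records in = records kept + records removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleansing import flag_nonuse, remove_false_puffs
from .config import PipelineConfig
from .errors import ConfigurationError, PuffTopError
from .groupstats import GroupComparison, UseGroupAssignment, assign_groups, compare_groups
from .io import StudyDataset
from .metrics import ENDPOINTS, ParticipantSummary, summarize_participant
from .sessionization import SessionizationResult, mean_ipi, segment

log = logging.getLogger("pufftop")


@dataclass
class PipelineResult:
    summaries: list[ParticipantSummary]
    assignments: list[UseGroupAssignment]
    comparisons: list[GroupComparison]
    sessionizations: dict[str, SessionizationResult]
    counts: dict[str, int] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        group_of = {a.participant_id: a.group for a in self.assignments}
        rows = []
        for s in self.summaries:
            row = {
                "participant_id": s.participant_id,
                "total_puffs": s.total_puffs,
                **{e: getattr(s, e) for e in ENDPOINTS},
                "use_group": group_of.get(s.participant_id, ""),
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def sessions_frame(self) -> pd.DataFrame:
        rows = []
        for pid, res in self.sessionizations.items():
            n = res.n_sessions
            if n == 0:
                continue
            counts = res.session_n_puffs
            multi = counts > 1
            mean_within = np.full(n, np.nan)
            mean_within[multi] = res.session_within_ipi_sum[multi] / (counts[multi] - 1)
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "session_index": np.arange(n),
                        "start_s": res.session_start,
                        "end_s": res.session_end,
                        "n_puffs": counts,
                        "session_length_s": res.session_end - res.session_start,
                        "mean_within_ipi_s": mean_within,
                        "mean_duration_s": res.session_mean_duration,
                    }
                )
            )
        cols = [
            "participant_id", "session_index", "start_s", "end_s", "n_puffs",
            "session_length_s", "mean_within_ipi_s", "mean_duration_s",
        ]
        if not rows:
            return pd.DataFrame(columns=cols)
        return pd.concat(rows, ignore_index=True)

    def comparison_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            row: dict = {"endpoint": c.endpoint, "F": c.f, "p_overall": c.p_overall}
            for g, m in c.group_means.items():
                row[f"mean_{g}"] = m
                row[f"sd_{g}"] = c.group_sds[g]
                row[f"n_{g}"] = c.group_n[g]
            for (a, b), p in c.pairwise_raw.items():
                row[f"p_raw_{a}_vs_{b}"] = p
            for (a, b), p in c.pairwise_adjusted.items():
                row[f"p_adj_{a}_vs_{b}"] = p
            rows.append(row)
        return pd.DataFrame(rows)


def run_pipeline(dataset: StudyDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis chain on a study dataset.

    Deterministic given (dataset, config).  Participants whose stream
    cannot be sessionized (fewer than two usable puffs leave the session
    threshold undefined only when every IPI is a nonuse gap) are logged
    and carried with zero-session summaries where possible.
    """
    config = config or PipelineConfig()
    cfg = config.cleansing
    counts = {
        "participants_in": len(dataset),
        "puffs_in": 0,
        "false_puffs_removed": 0,
        "puffs_kept": 0,
        "nonuse_gaps_flagged": 0,
        "sessions_formed": 0,
        "participants_summarised": 0,
        "participants_excluded": 0,
    }
    summaries: list[ParticipantSummary] = []
    sessionizations: dict[str, SessionizationResult] = {}
    for stream in dataset:
        counts["puffs_in"] += stream.n_puffs
        clean = remove_false_puffs(stream, cfg)
        clean = flag_nonuse(clean, cfg)
        counts["false_puffs_removed"] += clean.removed_count
        counts["puffs_kept"] += clean.n_puffs
        counts["nonuse_gaps_flagged"] += int(clean.ipi_nonuse.sum())
        try:
            thr = mean_ipi(clean) if clean.n_puffs >= 2 else float("nan")
        except PuffTopError as exc:
            log.warning("participant %s: %s", stream.participant_id, exc)
            continue
        result = segment(clean, thr if thr > 0 else np.finfo(float).tiny)
        sessionizations[stream.participant_id] = result
        counts["sessions_formed"] += result.n_sessions
        summaries.append(
            summarize_participant(result, config.evaluation_days, config.weighting)
        )
        counts["participants_summarised"] += 1
        log.info(
            "participant %s: %d puffs in, %d false puffs removed, %d nonuse gaps, "
            "mean IPI %.1f s, %d sessions",
            stream.participant_id, stream.n_puffs, clean.removed_count,
            int(clean.ipi_nonuse.sum()), result.mean_ipi_s, result.n_sessions,
        )
    if not summaries:
        log.warning("empty input: no participants could be summarised")
        return PipelineResult([], [], [], {}, counts)
    assignments = assign_groups(
        summaries,
        bins=config.group_bins,
        min_total_puffs=config.min_total_puffs,
        method=config.percentile_method,  # type: ignore[arg-type]
    )
    counts["participants_excluded"] = sum(a.group == "excluded" for a in assignments)
    log.info(
        "groups: %s (%d excluded with < %d total puffs)",
        {g: sum(a.group == g for a in assignments) for g in ("low", "moderate", "high")},
        counts["participants_excluded"], config.min_total_puffs,
    )
    comparisons = []
    for endpoint in ENDPOINTS:
        try:
            comparisons.append(compare_groups(assignments, summaries, endpoint))
        except ConfigurationError as exc:
            log.warning("endpoint %s not compared: %s", endpoint, exc)
    return PipelineResult(summaries, assignments, comparisons, sessionizations, counts)
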