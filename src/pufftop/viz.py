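"""Minimal session-timeline figure helper."""

from __future__ import annotations

from .sessionization import SessionizationResult


def plot_session_timeline(result: SessionizationResult, ax=None, day_seconds: float = 86400.0):
    """Broken-bar timeline of one participant's sessions, one row per day.

    Returns the matplotlib Axes.  Sessions are drawn as horizontal bars
    at their within-day offset; useful for eyeballing segmentation
    against the overnight gaps.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for start, end in zip(result.session_start, result.session_end):
        day = int(start // day_seconds)
        x0 = start - day * day_seconds
        ax.broken_barh([(x0 / 3600.0, max((end - start) / 3600.0, 0.02))], (day - 0.4, 0.8))
    ax.set_xlabel("hour of day")
    ax.set_ylabel("study day")
    ax.set_xlim(0, 24)
    ax.invert_yaxis()
    ax.set_title(f"{result.participant_id}: {result.n_sessions} sessions")
    return ax
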