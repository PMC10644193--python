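"""Independent brute-force recomputations used as test oracles.

Everything here is deliberately naive (pure-Python loops, textbook
formulas) and shares no code with the package implementation.
"""

import math


def brute_segment(ipi_lengths, nonuse_flags, threshold):
    """Sessions as lists of puff indices: scan IPIs left to right, close
    the session when an IPI strictly exceeds the threshold or is nonuse."""
    n = len(ipi_lengths) + 1
    sessions, current = [], [0]
    for i, (length, nonuse) in enumerate(zip(ipi_lengths, nonuse_flags)):
        if length > threshold or nonuse:
            sessions.append(current)
            current = [i + 1]
        else:
            current.append(i + 1)
    sessions.append(current)
    assert sum(len(s) for s in sessions) == n
    return sessions


def brute_quantile(values, q):
    """Linear-interpolation quantile, computed from scratch."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = q * (n - 1)
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def brute_nonuse_flags(values, q):
    cut = brute_quantile(values, q)
    return [v > cut for v in values]


def brute_anova_f(groups):
    """One-way fixed-effects ANOVA F from explicit sums of squares."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ssb / df_b) / (ssw / df_w)


def brute_percentile_ranks(values):
    """Rank in [0, 100]: average rank of ties, rescaled so min -> 0 and
    max -> 100."""
    n = len(values)
    out = []
    for x in values:
        less = sum(1 for y in values if y < x)
        equal = sum(1 for y in values if y == x)
        avg_rank = less + (equal + 1) / 2.0
        out.append((avg_rank - 1.0) / (n - 1.0) * 100.0)
    return out


def brute_mean_unflagged(lengths, flags):
    vals = [x for x, f in zip(lengths, flags) if not f]
    return sum(vals) / len(vals)
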