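"""CI-precision (tolerance-probability) sample size and attrition inflation.

For a normal mean with unknown SD, the two-sided 100·confidence% CI from a
sample of n observations has half-width t_{1-a/2, n-1} · S / sqrt(n), where
S is the sample SD.  Because S is random, the half-width meets a target h
only with some probability; with true SD sigma,

    P(half-width <= h) = P( (n-1) S^2 / sigma^2 <= (n-1) (h sqrt(n) / (t sigma))^2 )

which is a chi-square(n-1) CDF.  The precision sample size is the smallest
n for which this probability reaches the requested level (default 0.9).
Coverage and width are treated as independent events, so the "overall"
probability of a covering, sufficiently narrow interval is reported as
confidence × width_probability; the exact joint probability differs
slightly, but the product rule is the reporting convention adopted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError


@dataclass(frozen=True)
class PrecisionSpec:
    """Inputs to the CI-precision calculation.

    assumed_sd and target_halfwidth are in the units of the end point
    (seconds for puff duration); confidence is the CI level and
    width_probability the required chance of meeting the width target.
    """

    assumed_sd: float
    target_halfwidth: float
    confidence: float = 0.95
    width_probability: float = 0.9

    def __post_init__(self) -> None:
        if self.assumed_sd <= 0 or self.target_halfwidth <= 0:
            raise ConfigurationError("assumed_sd and target_halfwidth must be positive")
        if not 0 < self.confidence < 1 or not 0 < self.width_probability < 1:
            raise ConfigurationError("confidence and width_probability must lie in (0, 1)")


def halfwidth_probability(n: int, spec: PrecisionSpec) -> float:
    """P(the n-sample CI half-width is at most the target)."""
    if n < 2:
        raise ConfigurationError(f"need n >= 2 observations, got {n}")
    t_crit = stats.t.ppf(1.0 - (1.0 - spec.confidence) / 2.0, n - 1)
    ratio = spec.target_halfwidth * math.sqrt(n) / (t_crit * spec.assumed_sd)
    return float(stats.chi2.cdf((n - 1) * ratio**2, n - 1))


def precision_sample_size(spec: PrecisionSpec, n_max: int = 10_000_000) -> int:
    """Smallest n >= 2 with halfwidth_probability(n) >= width_probability.

    The probability can dip at very small n (the t critical value shrinks
    faster than S/sqrt(n) concentrates) before increasing to 1, so a
    plain upward scan is used: it returns the true minimum regardless of
    local non-monotonicity, and certifies that n - 1 fails.
    """
    n = 2
    while halfwidth_probability(n, spec) < spec.width_probability:
        n += 1
        if n > n_max:
            raise ConfigurationError("sample size search exceeded n_max")
    return n


def overall_probability(spec: PrecisionSpec) -> float:
    """Joint probability of coverage and meeting the width target, under
    the independence (product-rule) convention."""
    return spec.confidence * spec.width_probability


def recruitment_for_attrition(completers_required: int, attrition_rate: float) -> int:
    """Smallest recruitment r with expected completers r(1-a) >= target."""
    if completers_required < 1:
        raise ConfigurationError("completers_required must be positive")
    if not 0 <= attrition_rate < 1:
        raise ConfigurationError("attrition_rate must lie in [0, 1)")
    retain = 1.0 - attrition_rate
    r = max(completers_required, int(math.floor(completers_required / retain)))
    while r * retain < completers_required:
        r += 1
    return r


def simulate_halfwidth_probability(
    n: int, spec: PrecisionSpec, n_sim: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo check of halfwidth_probability by direct simulation of
    n-sample CIs; used as an independent oracle in tests."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, spec.assumed_sd, size=(n_sim, n))
    s = x.std(axis=1, ddof=1)
    t_crit = stats.t.ppf(1.0 - (1.0 - spec.confidence) / 2.0, n - 1)
    hw = t_crit * s / math.sqrt(n)
    return float((hw <= spec.target_halfwidth).mean())
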