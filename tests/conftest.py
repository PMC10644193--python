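import numpy as np
import pytest

from pufftop import CleansingConfig, ParticipantStream


@pytest.fixture
def cfg() -> CleansingConfig:
    return CleansingConfig()


def make_stream(
    starts,
    durations,
    voltages=None,
    participant_id="P000",
    evaluation_days=14,
) -> ParticipantStream:
    """Build a stream from plain lists; voltage defaults to the activated
    product voltage so no puff is a false puff."""
    starts = np.asarray(starts, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if voltages is None:
        voltages = np.full(starts.size, 3.3)
    return ParticipantStream(
        participant_id=participant_id,
        start_s=starts,
        duration_s=durations,
        voltage_v=np.asarray(voltages, dtype=float),
        evaluation_days=evaluation_days,
    )


def random_stream(rng, n, max_ipi=200.0, evaluation_days=14):
    """Random valid stream: positive durations, non-negative IPIs."""
    durations = rng.uniform(0.1, 4.0, size=n)
    ipis = rng.uniform(0.0, max_ipi, size=max(n - 1, 0))
    starts = np.zeros(n)
    if n > 1:
        starts[1:] = np.cumsum(durations[:-1] + ipis)
    return make_stream(starts, durations, evaluation_days=evaluation_days)
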