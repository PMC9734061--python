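import numpy as np
import pytest

from tcsleep import Hypnogram, SimParams


def make_hypnogram(spec: list[tuple[str, int]], epoch_s: float = 1.0) -> Hypnogram:
    """Build a hypnogram from (state, n_epochs) pairs."""
    labels: list[str] = []
    for state, n in spec:
        labels.extend([state] * n)
    return Hypnogram(labels=np.array(labels, dtype=object), epoch_s=epoch_s)


@pytest.fixture
def all_nrem_hyp():
    return make_hypnogram([("NREM", 600)])


@pytest.fixture
def short_params():
    """Small, fast simulation: 10 minutes at 200 Hz."""
    return SimParams(duration_s=600.0, seed=11)


@pytest.fixture
def sim_recording(short_params):
    from tcsleep import simulate_hypnogram, simulate_recording

    hyp = simulate_hypnogram(short_params)
    rec, gt = simulate_recording(hyp, short_params)
    return hyp, rec, gt
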