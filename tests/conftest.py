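import numpy as np
import pytest

from fraximm.model_core import DEFAULT_PARAMS, standard_arms


@pytest.fixture
def params():
    return DEFAULT_PARAMS


@pytest.fixture
def arms():
    return standard_arms()


@pytest.fixture
def logrank_oracle():
    """Brute-force two-group log-rank statistic from explicit risk tables."""

    def compute(times_a, events_a, times_b, events_b):
        times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
        events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
        event_times = np.unique(
            np.concatenate([times_a[events_a == 1], times_b[events_b == 1]])
        )
        observed_minus_expected = 0.0
        variance = 0.0
        for t in event_times:
            n_a = np.sum(times_a >= t)
            n_b = np.sum(times_b >= t)
            n = n_a + n_b
            d_a = np.sum((times_a == t) & (events_a == 1))
            d_b = np.sum((times_b == t) & (events_b == 1))
            d = d_a + d_b
            if n_a == 0 or n_b == 0 or n <= 1:
                continue  # a single at-risk group contributes nothing
            expected_a = d * n_a / n
            observed_minus_expected += d_a - expected_a
            variance += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        return observed_minus_expected**2 / variance

    return compute
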