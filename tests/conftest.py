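import numpy as np
import pytest

import stripsurvey as ss


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180712)


def make_distance_events(rng, n_druses, p0, sigma, w=1.0, tid="d01"):
    """Draw distance-survey detection events directly from the model:
    druses uniform in perpendicular distance, two independent observers
    with a shared half-normal curve."""
    y = rng.uniform(0.0, w, n_druses)
    g = p0 * np.exp(-(y**2) / (2.0 * sigma**2))
    u1, u2 = rng.uniform(size=2 * n_druses).reshape(2, -1)
    first = u1 < g
    detected = first | (u2 < g)
    return [
        ss.DetectionEvent(
            tid,
            ss.History.FIRST_OBSERVER if f else ss.History.SECOND_OBSERVER_ONLY,
            1,
            float(d),
        )
        for d, f, det in zip(y, first, detected)
        if det
    ]


def removal_events(n1, n2, tid="r01"):
    return [ss.DetectionEvent(tid, ss.History.FIRST_OBSERVER, 1)] * n1 + [
        ss.DetectionEvent(tid, ss.History.SECOND_OBSERVER_ONLY, 1)
    ] * n2
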