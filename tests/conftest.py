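import numpy as np
import pytest

from swaymetrics.session import DEFAULT_SCHEDULE
from swaymetrics.synthetic import SynthParams


@pytest.fixture(scope="session")
def mini_schedule():
    """Schedule shrunk 8x (phases 5 s) for fast end-to-end tests."""
    return DEFAULT_SCHEDULE.scaled(1.0 / 8.0)


@pytest.fixture(scope="session")
def tiny_schedule():
    """A 5 s miniature of the protocol for I/O round-trip tests."""
    return DEFAULT_SCHEDULE.scaled(1.0 / 64.0)


@pytest.fixture(scope="session")
def small_params():
    return SynthParams(n_healthy=3, n_pd=2, seed=7)


def brute_sampen(x, m, r):
    """Direct-count sample entropy oracle: enumerate every template pair.

    Independent of the package implementation (plain Python loops).
    Returns NaN when either count is zero.
    """
    x = [float(v) for v in np.asarray(x).ravel()]
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    import math

    return -math.log(a / b)


def brute_cliffs_delta(a, b):
    """Cliff's delta by explicit double loop (oracle)."""
    a = list(np.asarray(a).ravel())
    b = list(np.asarray(b).ravel())
    more = sum(1 for x in a for y in b if x > y)
    less = sum(1 for x in a for y in b if x < y)
    return (more - less) / (len(a) * len(b))
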