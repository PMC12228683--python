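import numpy as np
import pytest

from tubulekit.core import EndTrace


def piecewise_trace(slopes_um_min, durations_s, x0=5.0, dt=2.0, end="plus", noise=0.0, seed=0):
    """Noiseless (or lightly noisy) sampled trace from slope/duration specs."""
    ts, xs = [0.0], [x0]
    for sl, d in zip(slopes_um_min, durations_s):
        ts.append(ts[-1] + d)
        xs.append(xs[-1] + sl / 60.0 * d)
    t = np.arange(0.0, ts[-1] + dt / 2, dt)
    x = np.interp(t, ts, xs)
    if noise > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise, x.shape)
    if x.min() < 0:
        raise ValueError("test trace dips below the seed; adjust x0")
    return EndTrace(times=t, positions=x, end=end)


@pytest.fixture
def make_trace():
    return piecewise_trace
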