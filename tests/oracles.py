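"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own smoothing/derivative code paths:
slopes come from raw central differences, searches are exhaustive, and window
statistics are computed by direct indexing.
"""

import numpy as np


def t_zero_exhaustive(maneuver):
    """Test the tangent line at every sample (raw finite-difference slope)
    and report the zero-volume crossing of the max-slope sample."""
    t, v = maneuver.time, maneuver.volume
    slopes = np.gradient(v, t)
    k = int(np.argmax(slopes))
    return float(t[k] - v[k] / slopes[k])


def bev_linear(maneuver, t_zero):
    """Volume at t_zero by direct linear interpolation, clipped at zero."""
    return max(0.0, float(np.interp(t_zero, maneuver.time, maneuver.volume)))


def eotv_direct(maneuver, window=1.0):
    """Max-minus-min volume over the trailing window by direct indexing."""
    mask = maneuver.time >= maneuver.time[-1] - window
    tail = maneuver.volume[mask]
    return float(tail.max() - tail.min())


def fet100_direct(maneuver, t_zero):
    """Time from t_zero to the first sample attaining the maximum volume."""
    k = int(np.argmax(maneuver.volume))
    return float(maneuver.time[k] - t_zero)


def dense_cumulative_volume(flow_fn, t_end, rate=1000.0):
    """Cumulative volume of an analytic flow on a dense grid (Riemann sum)."""
    dt = 1.0 / rate
    t = np.arange(0.0, t_end + dt / 2, dt)
    f = flow_fn(t)
    v = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * dt)])
    return t, v
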