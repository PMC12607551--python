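"""Modified Akima (makima) piecewise-cubic Hermite interpolation.

Akima's method sets the derivative at each node from a weighted mean of the
neighbouring secant slopes; the *modified* weights

    w1 = |d[i+1] - d[i]|   + |d[i+1] + d[i]| / 2
    w2 = |d[i-1] - d[i-2]| + |d[i-1] + d[i-2]| / 2
    t[i] = (w1 * d[i-1] + w2 * d[i]) / (w1 + w2)

(d = secant slopes, extended past each end by the usual quadratic rule
d[-1] = 2 d[0] - d[1], d[-2] = 2 d[-1] - d[0]) avoid the flat segments the
original weights produce around equal slopes, and damp overshoot near
near-constant data.  Evaluation outside the support span extrapolates the
end cubic segments.  With only two support points the scheme degenerates to
the linear interpolant.
"""

from __future__ import annotations

import numpy as np


def makima_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Node derivatives of the modified-Akima interpolant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("makima needs at least 2 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    d = np.diff(y) / np.diff(x)
    if n == 2:
        return np.array([d[0], d[0]])
    # extend secant slopes two past each end: d[-1] = 2 d[0] - d[1], etc.
    ext = np.empty(n + 3)
    ext[2:n + 1] = d
    ext[1] = 2.0 * d[0] - d[1]
    ext[0] = 2.0 * ext[1] - d[0]
    ext[n + 1] = 2.0 * d[-1] - d[-2]
    ext[n + 2] = 2.0 * ext[n + 1] - d[-1]

    w1 = np.abs(ext[3:] - ext[2:-1]) + np.abs(ext[3:] + ext[2:-1]) / 2.0
    w2 = np.abs(ext[1:-2] - ext[:-3]) + np.abs(ext[1:-2] + ext[:-3]) / 2.0
    denom = w1 + w2
    t = np.zeros(n)
    nz = denom > 0
    t[nz] = (w1[nz] * ext[1:-2][nz] + w2[nz] * ext[2:-1][nz]) / denom[nz]
    return t


def makima_interpolate(x: np.ndarray, y: np.ndarray,
                       xq: np.ndarray) -> np.ndarray:
    """Evaluate the modified-Akima interpolant of (x, y) at xq.

    Queries beyond [x[0], x[-1]] are extrapolated with the end cubics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xq = np.asarray(xq, dtype=float)
    t = makima_slopes(x, y)
    # cubic Hermite segment evaluation; clamp to end segments to extrapolate
    idx = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, x.size - 2)
    h = x[idx + 1] - x[idx]
    s = (xq - x[idx]) / h
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s ** 2 * (3 - 2 * s)
    h11 = s ** 2 * (s - 1)
    return (h00 * y[idx] + h10 * h * t[idx]
            + h01 * y[idx + 1] + h11 * h * t[idx + 1])
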