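"""Numba kernels for the spatially-discretized first-crossing velocity scans.

The scans are O(T * span) with tiny constants; they dominate the pipeline
cost at simulation scale, hence the jit. Scans never bridge an invalid
sample: a validity break before the R-crossing leaves the velocity
unattained.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def first_crossing_forward(x, y, valid, R, use_path):
    """Index of the first sample at displacement (or path length) >= R.

    Returns an int64 array ``out`` with out[i] = smallest j > i such that the
    straight-line displacement from i to j (use_path False) or the cumulative
    path length over i..j (use_path True) is >= R, scanning only over
    contiguous valid samples; -1 where no crossing is attained.
    """
    n = x.shape[0]
    out = np.full(n, -1, dtype=np.int64)
    R2 = R * R
    for i in range(n):
        if not valid[i]:
            continue
        xi = x[i]
        yi = y[i]
        acc = 0.0
        for j in range(i + 1, n):
            if not valid[j]:
                break
            if use_path:
                ddx = x[j] - x[j - 1]
                ddy = y[j] - y[j - 1]
                acc += np.sqrt(ddx * ddx + ddy * ddy)
                if acc >= R:
                    out[i] = j
                    break
            else:
                dx = x[j] - xi
                dy = y[j] - yi
                if dx * dx + dy * dy >= R2:
                    out[i] = j
                    break
    return out


@njit(cache=True)
def first_crossing_backward(x, y, valid, R, use_path):
    """Mirror of :func:`first_crossing_forward`, scanning toward the past."""
    n = x.shape[0]
    out = np.full(n, -1, dtype=np.int64)
    R2 = R * R
    for i in range(n):
        if not valid[i]:
            continue
        xi = x[i]
        yi = y[i]
        acc = 0.0
        for j in range(i - 1, -1, -1):
            if not valid[j]:
                break
            if use_path:
                ddx = x[j] - x[j + 1]
                ddy = y[j] - y[j + 1]
                acc += np.sqrt(ddx * ddx + ddy * ddy)
                if acc >= R:
                    out[i] = j
                    break
            else:
                dx = x[j] - xi
                dy = y[j] - yi
                if dx * dx + dy * dy >= R2:
                    out[i] = j
                    break
    return out
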