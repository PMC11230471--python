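"""Exact sliding-window percentile.

Maintains a sorted buffer of the current window and slides it one sample at
a time, so the result at every sample equals the percentile (linear
interpolation between order statistics, numpy's default rule) of the
centered window clipped to the trace bounds. Compiled with numba when
available; a plain-numpy loop is kept as a fallback and as a readable
statement of the algorithm.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _sliding_percentile_core(x: np.ndarray, half_width: int, q: float) -> np.ndarray:
    n = x.size
    out = np.empty(n, dtype=np.float64)
    cap = min(n, 2 * half_width + 1)
    buf = np.empty(cap, dtype=np.float64)

    # initial window for sample 0: indices [0, half_width]
    end = min(n, half_width + 1)
    m = end
    buf[:m] = np.sort(x[:end])
    start = 0

    for i in range(n):
        if i > 0:
            new_end = min(n, i + half_width + 1)
            if new_end > end:
                v = x[new_end - 1]
                j = np.searchsorted(buf[:m], v)
                for k in range(m, j, -1):
                    buf[k] = buf[k - 1]
                buf[j] = v
                m += 1
                end = new_end
            new_start = i - half_width
            if new_start > start:
                v = x[start]
                j = np.searchsorted(buf[:m], v)  # first occurrence of v
                for k in range(j, m - 1):
                    buf[k] = buf[k + 1]
                m -= 1
                start = new_start
        # linear interpolation between order statistics (numpy's rule)
        h = q / 100.0 * (m - 1)
        lo = int(np.floor(h))
        g = h - lo
        hi = lo + 1 if lo + 1 < m else lo
        a = buf[lo]
        b = buf[hi]
        d = b - a
        if g >= 0.5:
            out[i] = b - d * (1.0 - g)
        else:
            out[i] = a + g * d
    return out


def sliding_percentile(x: np.ndarray, half_width: int, q: float) -> np.ndarray:
    """Percentile of ``x`` over centered windows of ``2*half_width+1`` samples.

    Windows are clipped (shrink) at the edges; no padding is fabricated.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if _HAVE_NUMBA:
        return _sliding_percentile_core(x, int(half_width), float(q))
    # fallback: brute force per window
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_width)
        hi = min(n, i + half_width + 1)
        out[i] = np.percentile(x[lo:hi], q)
    return out
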