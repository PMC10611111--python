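"""Classical dynamic time warping with absolute-difference local cost.

Unnormalized accumulated cost, steps {match, insert, delete}, no window.
A numba-compiled kernel is used when available; the pure-numpy fallback is
identical in output.
"""

from __future__ import annotations

import numpy as np


def _dtw_py(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    prev[:] = np.inf
    prev[0] = 0.0
    for i in range(n):
        cur[0] = np.inf
        for j in range(m):
            c = abs(a[i] - b[j])
            best = prev[j]
            if prev[j + 1] < best:
                best = prev[j + 1]
            if cur[j] < best:
                best = cur[j]
            cur[j + 1] = c + best
        prev, cur = cur, prev
    return float(prev[m])


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _dtw_fast = njit("f8(f8[::1], f8[::1])", cache=True)(_dtw_py)
except Exception:  # pragma: no cover
    _dtw_fast = None


def dtw_distance(a, b) -> float:
    """DTW distance between two 1-D sequences (symmetric, >= 0)."""
    a = np.ascontiguousarray(a, dtype=float).ravel()
    b = np.ascontiguousarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty sequences")
    if _dtw_fast is not None:
        return float(_dtw_fast(a, b))
    return _dtw_py(a, b)
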