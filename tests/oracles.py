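"""Independent brute-force oracles used only by the test suite.

Deliberately naive (explicit Python loops, sorting) so they share no code
path with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np


def feature_oracle(x, dt) -> list[float]:
    """Seven features of one channel, computed with plain loops."""
    x = list(map(float, x))
    n = len(x)
    f1 = sum(x) / n
    m2 = sum((v - f1) ** 2 for v in x) / n
    m3 = sum((v - f1) ** 3 for v in x) / n
    m4 = sum((v - f1) ** 4 for v in x) / n
    f2 = m2
    f3 = math.sqrt(sum(v * v for v in x) / n)
    f4 = m3 / m2**1.5 if m2 > 0 else 0.0
    f5 = m4 / m2**2 - 3.0 if m2 > 0 else 0.0
    f6 = sum(v * v for v in x)
    f8 = sum(abs(v) for v in x) * dt
    return [f1, f2, f3, f4, f5, f6, f8]


def rolling_median_oracle(values, w) -> list[float]:
    """Centered rolling median with truncated edge windows, by sorting."""
    values = list(map(float, values))
    n = len(values)
    half = w // 2
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        window = sorted(values[lo:hi])
        m = len(window)
        mid = window[m // 2] if m % 2 else 0.5 * (window[m // 2 - 1] + window[m // 2])
        out.append(mid)
    return out


def quantile_oracle(values, p) -> float:
    """Type-7 quantile: linear interpolation between order statistics."""
    xs = sorted(map(float, values))
    n = len(xs)
    h = (n - 1) * p
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def confusion_oracle(y_true, y_pred):
    """Per-class TP/FN/FP via an explicit confusion matrix."""
    classes = sorted(set(y_true) | set(y_pred))
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    out = {}
    for c in classes:
        i = idx[c]
        out[c] = {
            "tp": int(M[i, i]),
            "fn": int(M[i, :].sum() - M[i, i]),
            "fp": int(M[:, i].sum() - M[i, i]),
        }
    return out
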