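"""Independent brute-force references used as oracles by the test suite.

These deliberately share no code with the package's optimized kernels: the
sample-entropy reference enumerates template pairs with NumPy broadcasting,
one anchor row at a time.
"""

import numpy as np


def naive_sampen_counts(x, m, r, metric="chebyshev"):
    """O(n^2) pair enumeration of sample-entropy match counts (A, B).

    Uses the n - m templates common to lengths m and m+1, excludes
    self-matches, counts unordered pairs with distance <= r.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m
    tpl = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    A = 0
    B = 0
    for i in range(nt - 1):
        diff = tpl[i + 1:] - tpl[i]
        if metric == "chebyshev":
            dm = np.abs(diff[:, :m]).max(axis=1)
            dm1 = np.maximum(dm, np.abs(diff[:, m]))
            B += int((dm <= r).sum())
            A += int((dm1 <= r).sum())
        elif metric == "euclidean":
            dm = np.sqrt((diff[:, :m] ** 2).sum(axis=1))
            dm1 = np.sqrt((diff ** 2).sum(axis=1))
            B += int((dm <= r).sum())
            A += int((dm1 <= r).sum())
        else:
            raise ValueError(metric)
    return A, B


def naive_sample_entropy(x, m, r, metric="chebyshev"):
    """-ln(A/B) from the brute-force counts; NaN when degenerate."""
    A, B = naive_sampen_counts(x, m, r, metric=metric)
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))
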