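"""Independent reference implementations used only by the test suite.

Each oracle is deliberately written in the most direct style possible
(explicit loops, textbook formulas) and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def df_loop(xa, ya, xb, yb) -> float:
    """Elementwise-loop dissimilarity factor: mean of 200 squared diffs."""
    total = 0.0
    for i in range(100):
        total += (xa[i] - xb[i]) ** 2
        total += (ya[i] - yb[i]) ** 2
    return total / 200.0


def dlt_homography(src, dst) -> np.ndarray:
    """Direct-linear-transform homography via SVD of the 8x9 system."""
    rows = []
    for (x, y), (xp, yp) in zip(src, dst):
        rows.append([-x, -y, -1, 0, 0, 0, xp * x, xp * y, xp])
        rows.append([0, 0, 0, -x, -y, -1, yp * x, yp * y, yp])
    _, _, vt = np.linalg.svd(np.asarray(rows, dtype=float))
    H = vt[-1].reshape(3, 3)
    return H / H[2, 2]


def project(H, point) -> np.ndarray:
    x, y = point
    xp, yp, w = H @ np.array([x, y, 1.0])
    return np.array([xp / w, yp / w])


def average_ranks(values) -> np.ndarray:
    """Mid-ranks (1-based, ties averaged) without scipy."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_H(groups) -> float:
    """Tie-corrected Kruskal–Wallis H from the rank-sum closed form."""
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups])
    N = len(pooled)
    ranks = average_ranks(pooled)
    H = 0.0
    start = 0
    for v in groups:
        n = len(v)
        R = ranks[start : start + n].sum()
        H += R * R / n
        start += n
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = float((counts**3 - counts).sum())
    correction = 1.0 - ties / (N**3 - N)
    return H / correction


def ks_sup_distance(values) -> float:
    """Sup distance between the ECDF and a normal CDF with sample mean/SD.

    Evaluated at the sample points from both sides of each jump, by an
    explicit loop over the sorted sample.
    """
    from math import erf, sqrt

    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    mu = x.mean()
    sd = x.std(ddof=1)
    sup = 0.0
    for i in range(n):
        cdf = 0.5 * (1.0 + erf((x[i] - mu) / (sd * sqrt(2.0))))
        sup = max(sup, abs((i + 1) / n - cdf), abs(i / n - cdf))
    return sup
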