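"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the DTW oracle is an
exhaustive recursion over every monotone full-boundary alignment (no dynamic
programming table, no memoization), and the dipole oracle is the
infinite-medium closed form.
"""

from __future__ import annotations

import sys

import numpy as np


def dtw_bruteforce(s, t) -> float:
    """Minimal alignment cost by exhaustive enumeration of monotone paths."""
    s = list(map(float, s))
    t = list(map(float, t))
    sys.setrecursionlimit(100000)

    def go(i: int, j: int) -> float:
        c = abs(s[i] - t[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0 and j > 0:
            best = min(best, go(i - 1, j - 1))
        if i > 0:
            best = min(best, go(i - 1, j))
        if j > 0:
            best = min(best, go(i, j - 1))
        return c + best

    return go(len(s) - 1, len(t) - 1)


def dipole_potential_infinite_medium(points_mm, dipole_moment_A_m, sigma_S_per_m):
    """phi = p cos(theta) / (4 pi sigma r^2) for a z-directed dipole at the origin."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) / 1000.0
    r = np.linalg.norm(pts, axis=1)
    cos = pts[:, 2] / r
    return dipole_moment_A_m * cos / (4.0 * np.pi * sigma_S_per_m * r**2)
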