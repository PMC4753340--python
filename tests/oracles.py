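"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: flood fill is
recursive instead of scan-based, the natural-spline solve builds and solves
the full tridiagonal system by hand, and Otsu is a plain Python loop over
all 256 candidate thresholds.
"""

from __future__ import annotations

import math
import sys

import numpy as np


def flood_fill_partition(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components as a set of pixel-coordinate frozensets."""
    sys.setrecursionlimit(100_000)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []

    def fill(y, x, acc):
        if y < 0 or y >= h or x < 0 or x >= w or seen[y, x] or not mask[y, x]:
            return
        seen[y, x] = True
        acc.append((x, y))
        for dy, dx in nbrs:
            fill(y + dy, x + dx, acc)

    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                acc: list = []
                fill(y, x, acc)
                comps.append(frozenset(acc))
    return comps


def natural_spline_coeffs(x: np.ndarray, y: np.ndarray):
    """Per-segment (a, b, c, d) of the natural cubic spline, by direct
    tridiagonal solve for the knot second derivatives M_i (M_0 = M_n = 0).

    Segment i on [x_i, x_{i+1}]:
    S_i(t) = a_i + b_i (t-x_i) + c_i (t-x_i)^2 + d_i (t-x_i)^3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    h = np.diff(x)
    if n == 2:
        m = np.zeros(2)
    else:
        # interior equations: h[i-1] M[i-1] + 2(h[i-1]+h[i]) M[i] + h[i] M[i+1]
        #                     = 6 ((y[i+1]-y[i])/h[i] - (y[i]-y[i-1])/h[i-1])
        a_mat = np.zeros((n - 2, n - 2))
        rhs = np.zeros(n - 2)
        for i in range(1, n - 1):
            r = i - 1
            a_mat[r, r] = 2.0 * (h[i - 1] + h[i])
            if r > 0:
                a_mat[r, r - 1] = h[i - 1]
            if r < n - 3:
                a_mat[r, r + 1] = h[i]
            rhs[r] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
        m = np.zeros(n)
        m[1:-1] = np.linalg.solve(a_mat, rhs)
    a = y[:-1].copy()
    b = (y[1:] - y[:-1]) / h - h * (2.0 * m[:-1] + m[1:]) / 6.0
    c = m[:-1] / 2.0
    d = (m[1:] - m[:-1]) / (6.0 * h)
    return a, b, c, d


def natural_spline_eval(x: np.ndarray, y: np.ndarray, xq: float) -> float:
    a, b, c, d = natural_spline_coeffs(x, y)
    i = int(np.clip(np.searchsorted(x, xq, side="right") - 1, 0, x.size - 2))
    dx = xq - x[i]
    return float(a[i] + b[i] * dx + c[i] * dx**2 + d[i] * dx**3)


def otsu_bruteforce(pixels: np.ndarray) -> int:
    """Exhaustive search over all 256 thresholds, plain Python arithmetic."""
    flat = pixels.ravel().tolist()
    n = len(flat)
    best_t, best_var = 0, -1.0
    for t in range(255):
        c0 = [v for v in flat if v <= t]
        c1 = [v for v in flat if v > t]
        if not c0 or not c1:
            var = 0.0
        else:
            w0, w1 = len(c0) / n, len(c1) / n
            var = w0 * w1 * (sum(c0) / len(c0) - sum(c1) / len(c1)) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def boundary_set_bruteforce(mask: np.ndarray) -> set:
    """Foreground pixels with a background 4-neighbor or on the image border."""
    h, w = mask.shape
    out = set()
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            on_border = x == 0 or y == 0 or x == w - 1 or y == h - 1
            bg4 = any(
                0 <= y + dy < h and 0 <= x + dx < w and not mask[y + dy, x + dx]
                for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1))
            )
            if on_border or bg4:
                out.add((x, y))
    return out


def round_half_up_scalar(v: float) -> int:
    return math.floor(v + 0.5)
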