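"""Boundary curves, natural cubic-spline reconnection, and DDA line filling.

A boundary curve is a single-valued-in-x polyline: at most one row per
column, strictly increasing columns.  Fascia and bone boundaries broken by
thresholding are reconnected by interpolating the surviving points with a
natural cubic spline (second derivative zero at both end knots) and, between
neighbouring objects, by Digital Differential Analyzer (DDA) rasterization of
the straight segment, ``y = round(m (x - x1) + y1)`` with
``m = (y2 - y1) / (x2 - x1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from ._util import round_half_up

__all__ = [
    "BoundaryCurve",
    "SplineModel",
    "fit_natural_spline",
    "eval_spline",
    "reconnect_boundary",
    "dda_fill",
]


@dataclass
class BoundaryCurve:
    """Ordered (x, y) pixel samples with strictly increasing x."""

    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=np.int64)
        self.ys = np.asarray(self.ys)
        if self.xs.ndim != 1 or self.xs.shape != self.ys.shape:
            raise ValueError("xs and ys must be 1-D arrays of equal length")
        if self.xs.size >= 2 and not np.all(np.diff(self.xs) > 0):
            raise ValueError("xs must be strictly increasing")

    def __len__(self) -> int:
        return int(self.xs.size)

    @property
    def x_first(self) -> int:
        return int(self.xs[0])

    @property
    def x_last(self) -> int:
        return int(self.xs[-1])

    def y_at(self, x: int) -> float:
        """Exact stored row at column x (raises KeyError for unknown columns)."""
        i = np.searchsorted(self.xs, x)
        if i >= self.xs.size or self.xs[i] != x:
            raise KeyError(f"column {x} not on curve")
        return float(self.ys[i])

    def covers(self, x: int) -> bool:
        i = np.searchsorted(self.xs, x)
        return i < self.xs.size and self.xs[i] == x


@dataclass
class SplineModel:
    """Per-segment cubic coefficients: S_i(x) = a_i + b_i dx + c_i dx^2 + d_i dx^3
    with dx = x - x_i on segment [x_i, x_{i+1}]."""

    knots: BoundaryCurve
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray


def fit_natural_spline(knots: BoundaryCurve) -> SplineModel:
    """Interpolating cubic spline through *knots* with natural end conditions.

    The spline reproduces every knot exactly, is C2-continuous at interior
    knots, and has zero second derivative at both ends; with only two knots
    it degenerates to the straight segment between them.  Knot spacing may be
    non-uniform.
    """
    if len(knots) < 2:
        raise ValueError("need at least 2 knots to fit a spline")
    x = knots.xs.astype(np.float64)
    y = knots.ys.astype(np.float64)
    cs = CubicSpline(x, y, bc_type="natural")
    # scipy stores c[k, i] as the coefficient of (x - x_i)**(3 - k)
    return SplineModel(knots, a=cs.c[3], b=cs.c[2], c=cs.c[1], d=cs.c[0])


def eval_spline(model: SplineModel, x) -> float | np.ndarray:
    """Evaluate the spline at column(s) x inside the knot domain (no extrapolation)."""
    xs = model.knots.xs.astype(np.float64)
    xq = np.asarray(x, dtype=np.float64)
    if np.any(xq < xs[0]) or np.any(xq > xs[-1]):
        raise ValueError(
            f"query outside spline domain [{xs[0]:g}, {xs[-1]:g}]"
        )
    seg = np.clip(np.searchsorted(xs, xq, side="right") - 1, 0, xs.size - 2)
    dx = xq - xs[seg]
    val = model.a[seg] + model.b[seg] * dx + model.c[seg] * dx**2 + model.d[seg] * dx**3
    if np.ndim(x) == 0:
        return float(val)
    return val


def reconnect_boundary(
    curve: BoundaryCurve,
    full_domain: tuple[int, int],
    *,
    image_height: int | None = None,
    extend_flat: bool = False,
) -> BoundaryCurve:
    """Fill missing columns of *curve* across ``full_domain = (x0, x1)`` inclusive.

    Known points are preserved exactly; missing columns take the fitted
    natural spline's value, rounded half-up and clamped to the image when
    ``image_height`` is given.  The spline never extrapolates: if the domain
    extends beyond the known columns, ``extend_flat=True`` anchors the ends
    by repeating the first/last known row at the domain edges (the convention
    used for full-width anatomical boundaries); otherwise it is an error.
    """
    if len(curve) < 2:
        raise ValueError("need at least 2 known columns to reconnect a boundary")
    x0, x1 = int(full_domain[0]), int(full_domain[1])
    if x0 > x1:
        raise ValueError("empty domain")
    xs, ys = curve.xs, np.asarray(curve.ys, dtype=np.float64)
    if x0 < xs[0] or x1 > xs[-1]:
        if not extend_flat:
            raise ValueError(
                "full_domain exceeds known columns; pass extend_flat=True to anchor ends"
            )
        if x0 < xs[0]:
            xs = np.concatenate(([x0], xs))
            ys = np.concatenate(([ys[0]], ys))
        if x1 > xs[-1]:
            xs = np.concatenate((xs, [x1]))
            ys = np.concatenate((ys, [ys[-1]]))
        curve = BoundaryCurve(xs, ys)
    model = fit_natural_spline(curve)
    all_x = np.arange(x0, x1 + 1)
    out_y = np.empty(all_x.size, dtype=np.int64)
    known = np.isin(all_x, curve.xs)
    if known.any():
        idx = np.searchsorted(curve.xs, all_x[known])
        out_y[known] = round_half_up(np.asarray(curve.ys, dtype=np.float64)[idx])
    if (~known).any():
        out_y[~known] = round_half_up(eval_spline(model, all_x[~known]))
    if image_height is not None:
        out_y = np.clip(out_y, 0, image_height - 1)
    return BoundaryCurve(all_x, out_y)


def dda_fill(p1: tuple[int, int], p2: tuple[int, int]) -> list[tuple[int, int]]:
    """Rasterize the straight segment p1 -> p2 by DDA.

    For every integer column x from x1 to x2 (inclusive, stepping toward x2)
    the pixel ``(x, round_half_up(m (x - x1) + y1))`` is emitted.  A vertical
    segment (x1 == x2) falls outside the slope formula and is handled by
    emitting every integer row between y1 and y2.
    """
    x1, y1 = p1
    x2, y2 = p2
    if x1 == x2:
        step = 1 if y2 >= y1 else -1
        return [(x1, y) for y in range(y1, y2 + step, step)]
    m = (y2 - y1) / (x2 - x1)
    step = 1 if x2 > x1 else -1
    return [
        (x, round_half_up(m * (x - x1) + y1))
        for x in range(x1, x2 + step, step)
    ]
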