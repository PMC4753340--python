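"""Thresholding schemes: average, Otsu, and fuzzy sigma binarization.

Binary images are uint8 arrays containing only {0, 255}, in the same
coordinate convention as :class:`~dcfseg.imgio.GrayImage`.

The fuzzy sigma binarizer is the workhorse for the low-contrast neighborhood
of the deep cervical flexor, where vertebral echoes, muscle and fascia have
similar brightness.  It derives a sigma-shaped membership function from the
image's own min/mid/max intensities:

Step 1.  ``P_min_f = P_mid - P_min``,  ``P_max_f = P_max - P_mid``
Step 2.  if ``P_mid > P_min + 0.75 (P_max - P_min)`` then ``P_mid_f = 255 - P_mid``
         else ``P_mid_f = P_mid``   (compensates overly bright acquisitions)
Step 3.  a nested conditional picks the half-width ``beta`` (see
         :func:`fuzzy_sigma_params`; it reduces to a min-selection, which a
         unit test documents)
Step 4.  ``P_min_new = P_mid - beta``,  ``P_max_new = P_mid + beta``

The membership of intensity P is 0 at or below ``P_min_new``, rises linearly
to 1 at ``P_mid``, and stays 1 above.  A pixel is foreground when its
membership reaches the alpha-cut (default 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imgio import GrayImage

log = logging.getLogger(__name__)

__all__ = [
    "FuzzyParams",
    "average_binarize",
    "otsu_binarize",
    "otsu_threshold",
    "fuzzy_sigma_params",
    "fuzzy_membership",
    "fuzzy_sigma_binarize",
]


def _as_pixels(img: GrayImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img)


def average_binarize(img: GrayImage) -> np.ndarray:
    """Threshold at the mean intensity: pixel >= mean -> 255, else 0."""
    g = _as_pixels(img)
    t = g.mean()
    return np.where(g >= t, 255, 0).astype(np.uint8)


def otsu_threshold(img: GrayImage) -> int:
    """The threshold t in [0, 254] maximizing between-class variance.

    Classes are {intensity <= t} and {intensity > t} over the 256-bin
    histogram; ties resolve to the smallest t.
    """
    g = _as_pixels(img)
    hist = np.bincount(g.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("otsu_binarize requires at least two distinct intensities")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]            # pixels <= t, t = 0..254
    w1 = n - w0
    s0 = np.cumsum(hist * levels)[:-1]   # intensity mass <= t
    s1 = hist @ levels - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, s0 / w0, 0.0)
        mu1 = np.where(w1 > 0, s1 / w1, 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(sigma_b))


def otsu_binarize(img: GrayImage) -> np.ndarray:
    """Otsu's method: foreground is pixel > threshold."""
    t = otsu_threshold(img)
    g = _as_pixels(img)
    return np.where(g > t, 255, 0).astype(np.uint8)


@dataclass(frozen=True)
class FuzzyParams:
    """Derived quantities of the fuzzy sigma binarizer (Steps 1-4)."""

    p_min: float
    p_max: float
    p_mid: float
    p_min_f: float
    p_max_f: float
    p_mid_f: float
    beta: float
    p_min_new: float
    p_max_new: float
    alpha_cut: float = 0.5

    def __post_init__(self) -> None:
        if not (self.p_min <= self.p_mid <= self.p_max):
            raise ValueError("require p_min <= p_mid <= p_max")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not (0.0 <= self.alpha_cut <= 1.0):
            raise ValueError("alpha_cut must lie in [0, 1]")


def fuzzy_sigma_params(img: GrayImage | np.ndarray, alpha_cut: float = 0.5) -> FuzzyParams:
    """Compute the fuzzy membership support from the image's own intensities.

    ``p_min``/``p_max`` are the image minimum and maximum; ``p_mid`` is their
    average, kept at full precision (it may be a half-integer).  A constant
    image yields ``beta = 0`` and the membership degenerates to a step at
    ``p_mid``.
    """
    if not (0.0 <= alpha_cut <= 1.0):
        raise ValueError(f"alpha_cut must lie in [0, 1], got {alpha_cut}")
    g = _as_pixels(img)
    p_min = float(g.min())
    p_max = float(g.max())
    p_mid = (p_min + p_max) / 2.0

    # Step 1
    p_min_f = p_mid - p_min
    p_max_f = p_max - p_mid
    # Step 2: brightness compensation at the upper three-quarters point
    if p_mid > p_min + 0.75 * (p_max - p_min):
        p_mid_f = 255.0 - p_mid
    else:
        p_mid_f = p_mid
    # Step 3: printed verbatim as the nested conditional
    if p_mid_f > p_max_f:
        if p_min_f > p_mid_f:
            beta = p_mid_f
        else:
            beta = p_min_f
    else:
        if p_max_f > p_mid_f:
            beta = p_mid_f
        else:
            beta = p_max_f
    # Step 4
    p_min_new = p_mid - beta
    p_max_new = p_mid + beta
    return FuzzyParams(
        p_min=p_min, p_max=p_max, p_mid=p_mid,
        p_min_f=p_min_f, p_max_f=p_max_f, p_mid_f=p_mid_f,
        beta=beta, p_min_new=p_min_new, p_max_new=p_max_new,
        alpha_cut=alpha_cut,
    )


def fuzzy_membership(p, params: FuzzyParams):
    """Membership degree u(P) in [0, 1]; accepts scalars or arrays.

    u = 0 for P <= p_min_new, rises linearly to 1 at p_mid, and is 1 for
    P >= p_mid.  With beta = 0 the function degenerates to a step at p_mid.
    """
    arr = np.asarray(p, dtype=np.float64)
    if params.beta == 0.0 or params.p_mid == params.p_min_new:
        u = np.where(arr >= params.p_mid, 1.0, 0.0)
    else:
        u = (arr - params.p_min_new) / (params.p_mid - params.p_min_new)
        u = np.clip(u, 0.0, 1.0)
    if np.ndim(p) == 0:
        return float(u)
    return u


def fuzzy_sigma_binarize(img: GrayImage | np.ndarray, alpha_cut: float = 0.5) -> np.ndarray:
    """Binarize by cutting the fuzzy membership at *alpha_cut*.

    A pixel becomes foreground (255) iff its membership is >= alpha_cut.
    With alpha_cut = 0 every pixel is foreground (u >= 0 always); with
    alpha_cut = 1 the foreground is exactly {P >= p_mid}.
    """
    params = fuzzy_sigma_params(img, alpha_cut)
    u = fuzzy_membership(_as_pixels(img), params)
    return np.where(u >= alpha_cut, 255, 0).astype(np.uint8)
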