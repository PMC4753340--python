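"""Contrast normalization by ends-in search stretching.

Ends-in search stretching is a min-max linear remap with clamping at both
ends: intensities at or below ``Min`` go to 0, at or above ``Max`` go to 255,
and everything in between is scaled linearly,

    P(x, y) = 255 * (G(x, y) - Min) / (Max - Min).

It preserves the ordering of intensities (and hence the relative shape of the
histogram), which is why it is preferred here over speckle filtering: bright
fascia and bone echoes keep their contrast against the dark muscle without
smearing thin structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._util import round_half_up
from .imgio import GrayImage

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StretchParams:
    """Input window for the stretch: intensities clamped outside [min_in, max_in]."""

    min_in: int
    max_in: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_in <= self.max_in <= 255):
            raise ValueError(f"invalid stretch window {self}")


def histogram(img: GrayImage) -> np.ndarray:
    """256-bin intensity histogram; bin i counts pixels of intensity exactly i."""
    return np.bincount(img.pixels.ravel(), minlength=256)


def ends_in_stretch(img: GrayImage, params: StretchParams | None = None) -> GrayImage:
    """Stretch *img* so that [min_in, max_in] maps onto [0, 255].

    In auto mode (``params=None``) the window is the image's own min and max.
    A constant image is returned unchanged with a logged warning, since the
    linear map is undefined there.
    """
    g = img.pixels
    if params is None:
        params = StretchParams(int(g.min()), int(g.max()))
    mn, mx = params.min_in, params.max_in
    if mn == mx:
        log.warning("ends_in_stretch: degenerate window (min == max == %d); no-op", mn)
        return GrayImage(g.copy(), img.spacing_cm)
    gf = g.astype(np.float64)
    out = round_half_up(255.0 * (gf - mn) / (mx - mn))
    out = np.clip(out, 0, 255)
    out[g <= mn] = 0
    out[g >= mx] = 255
    return GrayImage(out.astype(np.uint8), img.spacing_cm)
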