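"""Result visualization: boundaries, key point and measuring chords on the image."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .imgio import GrayImage
from .pipeline import ExtractionResult

__all__ = ["draw_overlay"]

_UPPER = (255, 80, 80)
_LOWER = (80, 220, 80)
_CHORD = (80, 160, 255)
_KEY = (255, 255, 0)


def draw_overlay(image: GrayImage, result: ExtractionResult, path: str | Path) -> None:
    """Write an RGB PNG of *image* with the extraction result drawn on top.

    Coordinates in *result* are ROI-local; the ROI offset is applied here.
    Failed extractions are drawn as far as their stages got.
    """
    rgb = Image.fromarray(image.pixels, mode="L").convert("RGB")
    draw = ImageDraw.Draw(rgb)
    roi = result.roi
    ox, oy = (roi.x0, roi.y0) if roi is not None else (0, 0)
    if roi is not None:
        draw.rectangle([roi.x0, roi.y0, roi.x1 - 1, roi.y1 - 1], outline=(120, 120, 120))
    for curve, color in ((result.dcf_upper, _UPPER), (result.dcf_lower, _LOWER)):
        if curve is None:
            continue
        pts = [(int(x) + ox, int(y) + oy)
               for x, y in zip(curve.xs, np.asarray(curve.ys))]
        draw.line(pts, fill=color, width=2)
    if result.chords:
        for c in result.chords:
            x = c["x"] + ox
            draw.line([(x, int(c["y_top"]) + oy), (x, int(c["y_bottom"]) + oy)],
                      fill=_CHORD, width=2)
    if result.key_point is not None:
        kx, ky = result.key_point[0] + ox, result.key_point[1] + oy
        r = 5
        draw.line([(kx - r, ky), (kx + r, ky)], fill=_KEY, width=2)
        draw.line([(kx, ky - r), (kx, ky + r)], fill=_KEY, width=2)
    rgb.save(path)
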