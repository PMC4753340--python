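"""Connected components, object-level noise removal, hole filling,
gap bridging, expansion, and 4-directional contour tracing.

The object-level noise rule removes a connected component O from a W x H
region of interest when

    S(O) < 0.085 * S(ROI)
    OR ( O.left < 0.1 * W  AND  Width(O) < 0.5 * W )

with S(ROI) = W * H: small blobs are speckle, and narrow objects hugging the
left edge are acquisition artifacts rather than the long curved fascia/bone
echoes.  All three comparisons are strict, and the constants are exposed so
callers can re-tune them for other probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

log = logging.getLogger(__name__)

__all__ = [
    "ObjectStats",
    "LabeledObjects",
    "blob_label",
    "remove_noise_objects",
    "fill_between_boundaries",
    "bridge_neighbor_gaps",
    "expand",
    "contour_trace_4dir",
    "boundary_pixel_set",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ObjectStats:
    """Per-object geometry: size and inclusive bounding box."""

    label: int
    size: int
    x_left: int
    y_top: int
    x_right: int
    y_bottom: int

    @property
    def width(self) -> int:
        return self.x_right - self.x_left + 1

    @property
    def height(self) -> int:
        return self.y_bottom - self.y_top + 1

    @property
    def centroid_x(self) -> float:
        return (self.x_left + self.x_right) / 2.0


@dataclass
class LabeledObjects:
    """A label map (0 = background) plus per-object stats.

    Labels are assigned in raster-scan first-encounter order, 1..n.
    """

    label_map: np.ndarray
    objects: list[ObjectStats] = field(default_factory=list)

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def width(self) -> int:
        return self.label_map.shape[1]

    @property
    def height(self) -> int:
        return self.label_map.shape[0]

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one object, or of all foreground when label is None."""
        if label is None:
            return self.label_map > 0
        return self.label_map == label


def _as_bool(binary: np.ndarray) -> np.ndarray:
    arr = np.asarray(binary)
    return arr.astype(bool) if arr.dtype != bool else arr


def blob_label(binary: np.ndarray, connectivity: int = 8) -> LabeledObjects:
    """Label connected foreground components ("Blob" analysis).

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    Components are relabeled into raster-scan first-encounter order so the
    output is independent of the underlying labeling library.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = _as_bool(binary)
    struct = _STRUCT4 if connectivity == 4 else _STRUCT8
    raw, n = ndi.label(mask, structure=struct)
    if n == 0:
        return LabeledObjects(raw.astype(np.int32), [])
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat, np.arange(flat.size))
    order = np.argsort(first[1:], kind="stable")  # old labels in raster order
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1)
    label_map = remap[raw]
    objects = _compute_stats(label_map, n)
    return LabeledObjects(label_map, objects)


def _compute_stats(label_map: np.ndarray, n: int) -> list[ObjectStats]:
    sizes = np.bincount(label_map.ravel(), minlength=n + 1)
    slices = ndi.find_objects(label_map, max_label=n)
    out: list[ObjectStats] = []
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        if sl is None:
            continue
        ys, xs = sl
        out.append(
            ObjectStats(
                label=lab,
                size=int(sizes[lab]),
                x_left=int(xs.start),
                y_top=int(ys.start),
                x_right=int(xs.stop - 1),
                y_bottom=int(ys.stop - 1),
            )
        )
    return out


def remove_noise_objects(
    objs: LabeledObjects,
    roi_width: int,
    roi_height: int,
    *,
    size_frac: float = 0.085,
    left_margin_frac: float = 0.1,
    min_width_frac: float = 0.5,
) -> LabeledObjects:
    """Drop objects matching the noise criteria (strict inequalities).

    An object O is removed iff ``S(O) < size_frac * W * H`` or
    (``O.left < left_margin_frac * W`` and ``Width(O) < min_width_frac * W``).
    Survivors keep their pixels and are relabeled 1..k preserving order.
    """
    s_roi = roi_width * roi_height
    keep: list[ObjectStats] = []
    removed = 0
    for o in objs.objects:
        small = o.size < size_frac * s_roi
        left_skewed = (
            o.x_left < left_margin_frac * roi_width
            and o.width < min_width_frac * roi_width
        )
        if small or left_skewed:
            removed += 1
        else:
            keep.append(o)
    log.debug("remove_noise_objects: removed %d of %d objects", removed, objs.n_objects)
    remap = np.zeros(objs.n_objects + 1, dtype=np.int32)
    new_objs: list[ObjectStats] = []
    for new_lab, o in enumerate(keep, start=1):
        remap[o.label] = new_lab
        new_objs.append(
            ObjectStats(new_lab, o.size, o.x_left, o.y_top, o.x_right, o.y_bottom)
        )
    return LabeledObjects(remap[objs.label_map], new_objs)


def fill_between_boundaries(binary: np.ndarray) -> np.ndarray:
    """Fill each column between its topmost and bottommost foreground pixels.

    For every column x with any foreground, all rows between the first
    foreground row from the top and the first from the bottom are set to 255.
    Columns with no foreground are left unchanged.  Idempotent.
    """
    mask = _as_bool(binary)
    h, w = mask.shape
    any_fg = mask.any(axis=0)
    top = mask.argmax(axis=0)
    bottom = h - 1 - mask[::-1, :].argmax(axis=0)
    rows = np.arange(h)[:, None]
    filled = (rows >= top[None, :]) & (rows <= bottom[None, :]) & any_fg[None, :]
    return np.where(filled, 255, 0).astype(np.uint8)


def bridge_neighbor_gaps(binary: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Set background pixels 8-adjacent to foreground to 255, *iterations* times.

    Equivalent to dilation with a 3x3 structuring element; reconnects boundary
    lines broken by thresholding.  Foreground never shrinks.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    mask = _as_bool(binary)
    out = ndi.binary_dilation(mask, structure=_STRUCT8, iterations=iterations)
    return np.where(out, 255, 0).astype(np.uint8)


def expand(binary: np.ndarray, kernel_radius: int = 1) -> np.ndarray:
    """Morphological dilation with a square element of side ``2*radius + 1``."""
    if kernel_radius < 1:
        raise ValueError(f"kernel_radius must be >= 1, got {kernel_radius}")
    mask = _as_bool(binary)
    size = 2 * kernel_radius + 1
    out = ndi.binary_dilation(mask, structure=np.ones((size, size), dtype=bool))
    return np.where(out, 255, 0).astype(np.uint8)


def boundary_pixel_set(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of foreground pixels with a background 4-neighbor or on the border."""
    m = _as_bool(mask)
    interior = ndi.binary_erosion(m, structure=_STRUCT4, border_value=0)
    return m & ~interior


def contour_trace_4dir(binary: np.ndarray, connectivity: int = 8):
    """Trace ordered boundary loops of every object.

    Returns a list of ``(label, loops)`` pairs in label order, where *loops*
    is a list of closed pixel sequences (arrays of (x, y)); the first loop of
    an object starts at its top-leftmost pixel, and objects with holes get one
    additional loop per hole.  Boundary pixels are foreground pixels
    4-adjacent to background (or on the image border); consecutive pixels in
    a loop are 8-adjacent and the loop closes back on its start.

    The walk follows the cracks between foreground and background with a
    fixed turning rule (foreground kept on the right), so each loop visits
    exactly the boundary pixels of its contour, each at least once.
    """
    objs = blob_label(binary, connectivity=connectivity)
    results = []
    for o in objs.objects:
        mask = objs.mask(o.label)
        loops = _trace_object(mask)
        results.append((o.label, loops))
    return results


# Crack directions: E, S, W, N as (dx, dy) on the corner grid.
_DELTA = ((1, 0), (0, 1), (-1, 0), (0, -1))


def _trace_object(mask: np.ndarray) -> list[np.ndarray]:
    h, w = mask.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and mask[y, x]

    # Canonical horizontal boundary cracks: E-edges (bg above fg) start outer
    # loops; W-edges (fg above bg) start hole loops not reached otherwise.
    starts: list[tuple[int, int, int]] = []
    above = np.zeros_like(mask)
    above[1:, :] = mask[:-1, :]
    below = np.zeros_like(mask)
    below[:-1, :] = mask[1:, :]
    for y, x in zip(*np.nonzero(mask & ~above)):
        starts.append((int(x), int(y), 0))          # corner (x, y), heading E
    for y, x in zip(*np.nonzero(mask & ~below)):
        starts.append((int(x) + 1, int(y) + 1, 2))  # corner (x+1, y+1), heading W

    visited: set[tuple[int, int, int]] = set()
    loops: list[np.ndarray] = []
    for start in starts:
        if start in visited:
            continue
        loops.append(_walk_loop(start, fg, visited))
    return loops


def _right_pixel(cx: int, cy: int, d: int) -> tuple[int, int]:
    """Foreground pixel on the right of the directed crack edge from (cx, cy)."""
    if d == 0:
        return cx, cy
    if d == 1:
        return cx - 1, cy
    if d == 2:
        return cx - 1, cy - 1
    return cx, cy - 1


def _walk_loop(start, fg, visited) -> np.ndarray:
    pixels: list[tuple[int, int]] = []
    edge = start
    while True:
        visited.add(edge)
        cx, cy, d = edge
        px = _right_pixel(cx, cy, d)
        if not pixels or pixels[-1] != px:
            pixels.append(px)
        # advance to the next corner and turn
        dx, dy = _DELTA[d]
        nx, ny = cx + dx, cy + dy
        if d == 0:
            pl, pr = (nx, ny - 1), (nx, ny)
        elif d == 1:
            pl, pr = (nx, ny), (nx - 1, ny)
        elif d == 2:
            pl, pr = (nx - 1, ny), (nx - 1, ny - 1)
        else:
            pl, pr = (nx - 1, ny - 1), (nx, ny - 1)
        if fg(*pl):
            nd = (d - 1) % 4  # turn left
        elif fg(*pr):
            nd = d            # straight on
        else:
            nd = (d + 1) % 4  # turn right
        edge = (nx, ny, nd)
        if edge == start:
            break
    if len(pixels) > 1 and pixels[0] == pixels[-1]:
        pixels.pop()
    return np.array(pixels, dtype=np.int64)
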