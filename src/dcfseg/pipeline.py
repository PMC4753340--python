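"""End-to-end extraction and thickness measurement of the deep cervical flexor.

The pipeline mirrors the two-stage design of the method:

1.  *DCF candidate*: contrast-stretch the ROI, average-binarize, label blobs,
    drop noise objects, fill each column between the surviving upper and
    lower boundary objects, bridge one-pixel gaps, trace contours and
    spline-reconnect the top/bottom boundary curves.  The top of this filled
    band (the superficial fascial echo) is the upper measurement boundary.
2.  *Vertebrae*: fuzzy-sigma-binarize the stretched ROI (the vertebral
    echoes are barely brighter than muscle, which defeats a plain average
    threshold), label, drop noise, dilate, remove fat false positives lying
    above the candidate band's lower line, and - when the leftmost detected
    vertebra sits in the right half of the ROI, a sign that the true leftmost
    echo was lost - boost the grayscale with a distance-weighted restoration
    and re-threshold once with average binarization.  The completed upper
    boundary of the vertebral echoes is the lower measurement boundary.

The measuring key point is the rightmost pixel of the leftmost vertebral
object; thickness is the mean of the three vertical chords between the two
boundaries at the key column and 1 cm to either side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import round_half_up
from .binarize import average_binarize, fuzzy_sigma_binarize
from .curves import BoundaryCurve, dda_fill, reconnect_boundary
from .enhance import ends_in_stretch
from .errors import UnitsError
from .imgio import GrayImage, ROISpec, crop_roi
from .morph import (
    LabeledObjects,
    ObjectStats,
    blob_label,
    bridge_neighbor_gaps,
    contour_trace_4dir,
    expand,
    fill_between_boundaries,
    remove_noise_objects,
)

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ExtractionResult",
    "extract_dcf_candidate",
    "extract_vertebrae",
    "weighted_restore",
    "remove_fat_false_positives",
    "locate_key_point",
    "measure_thickness",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the extraction pipeline (defaults are the method's values)."""

    roi: ROISpec | None = None
    alpha_cut: float = 0.5
    connectivity: int = 8
    noise_size_frac: float = 0.085
    left_margin_frac: float = 0.1
    min_width_frac: float = 0.5
    bridge_iterations: int = 1
    expand_radius: int = 1
    restore_center: tuple[int, int] | None = None   # defaults to the ROI center
    restore_divisor: float = 1000.0
    pixel_spacing: tuple[float, float] | None = None  # cm/px override (sx, sy)
    offset_cm: float = 1.0       # lateral offset of the side measuring columns
    offset_px: int = 100         # fallback offset when no calibration exists
    vertebra_max_width_frac: float = 0.9  # wider objects are boundary lines, not vertebrae
    mirror: bool = False         # right-dominant anatomy: flip, run, flip back

    def __post_init__(self) -> None:
        if self.restore_divisor <= 0:
            raise ValueError("restore_divisor must be positive")
        if not (0.0 <= self.alpha_cut <= 1.0):
            raise ValueError("alpha_cut must lie in [0, 1]")


@dataclass
class StageRecord:
    stage: str
    info: dict


@dataclass
class CandidateResult:
    success: bool
    mask: np.ndarray | None = None
    upper: BoundaryCurve | None = None
    lower: BoundaryCurve | None = None
    stretched: GrayImage | None = None
    stage_log: list[StageRecord] = field(default_factory=list)
    failed_stage: str | None = None


@dataclass
class VertebraResult:
    success: bool
    objects: LabeledObjects | None = None
    upper_boundary: BoundaryCurve | None = None
    restore_invoked: bool = False
    stage_log: list[StageRecord] = field(default_factory=list)
    failed_stage: str | None = None


@dataclass
class ExtractionResult:
    """Everything the pipeline found for one image."""

    success: bool
    failed_stage: str | None = None
    reason: str | None = None
    roi: ROISpec | None = None
    dcf_mask: np.ndarray | None = None          # final band, ROI coordinates
    candidate_mask: np.ndarray | None = None
    dcf_upper: BoundaryCurve | None = None
    dcf_lower: BoundaryCurve | None = None
    vertebrae: LabeledObjects | None = None
    key_point: tuple[int, int] | None = None    # ROI coordinates
    measure_xs: tuple[int, int, int] | None = None
    chords: list[dict] | None = None
    thickness_cm: float | None = None
    thickness_px: float | None = None
    units: str = "cm"
    stage_log: list[StageRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-ready summary (raster fields omitted)."""
        return {
            "success": self.success,
            "failed_stage": self.failed_stage,
            "reason": self.reason,
            "roi": [self.roi.x0, self.roi.y0, self.roi.x1, self.roi.y1] if self.roi else None,
            "key_point": list(self.key_point) if self.key_point else None,
            "measure_xs": list(self.measure_xs) if self.measure_xs else None,
            "chords": self.chords,
            "thickness_cm": self.thickness_cm,
            "thickness_px": self.thickness_px,
            "units": self.units,
            "n_vertebrae": self.vertebrae.n_objects if self.vertebrae else 0,
            "stages": [{"stage": s.stage, **s.info} for s in self.stage_log],
        }


def _mask_boundaries(mask: np.ndarray) -> tuple[BoundaryCurve, BoundaryCurve]:
    """Per-column top and bottom rows of the foreground."""
    m = mask.astype(bool)
    h = m.shape[0]
    cols = np.nonzero(m.any(axis=0))[0]
    top = m.argmax(axis=0)[cols]
    bottom = (h - 1 - m[::-1, :].argmax(axis=0))[cols]
    return BoundaryCurve(cols, top), BoundaryCurve(cols, bottom)


def extract_dcf_candidate(roi_img: GrayImage, cfg: PipelineConfig) -> CandidateResult:
    """Stage 1: the bright-boundary band that contains the DCF.

    Returns the filled candidate mask together with its spline-completed
    upper and lower boundary curves (anchored flat to the ROI edges).  The
    stage log records object counts after each step.
    """
    w, h = roi_img.width, roi_img.height
    log_: list[StageRecord] = []
    if roi_img.pixels.min() == roi_img.pixels.max():
        # A constant ROI carries no anatomy; every threshold degenerates.
        return CandidateResult(False, mask=np.zeros((h, w), dtype=np.uint8),
                               stretched=roi_img, failed_stage="degenerate_roi")
    stretched = ends_in_stretch(roi_img)
    binary = average_binarize(stretched)
    objs = blob_label(binary, cfg.connectivity)
    log_.append(StageRecord("average_binarize", {"n_objects": objs.n_objects}))
    objs = remove_noise_objects(
        objs, w, h,
        size_frac=cfg.noise_size_frac,
        left_margin_frac=cfg.left_margin_frac,
        min_width_frac=cfg.min_width_frac,
    )
    log_.append(StageRecord("remove_noise_objects", {"n_objects": objs.n_objects}))
    if objs.n_objects == 0:
        return CandidateResult(False, stretched=stretched, stage_log=log_,
                               failed_stage="remove_noise_objects")
    filled = fill_between_boundaries(np.where(objs.mask(), 255, 0).astype(np.uint8))
    bridged = bridge_neighbor_gaps(filled, cfg.bridge_iterations)
    contours = contour_trace_4dir(bridged, cfg.connectivity)
    log_.append(StageRecord("fill_and_bridge",
                            {"n_contours": sum(len(l) for _, l in contours)}))
    upper_raw, lower_raw = _mask_boundaries(bridged)
    upper = reconnect_boundary(upper_raw, (0, w - 1), image_height=h, extend_flat=True)
    lower = reconnect_boundary(lower_raw, (0, w - 1), image_height=h, extend_flat=True)
    return CandidateResult(True, mask=bridged, upper=upper, lower=lower,
                           stretched=stretched, stage_log=log_)


def weighted_restore(img: GrayImage | np.ndarray,
                     center: tuple[int, int],
                     divisor: float = 1000.0) -> np.ndarray:
    """Distance-weighted intensity boost, clamped at 255.

    Every pixel is multiplied by ``alpha = 1 + ((x - x1)^2 + (y - y1)^2) / divisor``
    where (x1, y1) is *center*: pixels far from the center - in particular the
    far-left region where a dim vertebral echo may have been thresholded away -
    are boosted the most.
    """
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    h, w = pixels.shape
    x1, y1 = center
    yy, xx = np.mgrid[0:h, 0:w]
    alpha = 1.0 + ((xx - x1) ** 2 + (yy - y1) ** 2) / divisor
    boosted = round_half_up(pixels.astype(np.float64) * alpha)
    return np.clip(boosted, 0, 255).astype(np.uint8)


def remove_fat_false_positives(objs: LabeledObjects,
                               dcf_lower: BoundaryCurve) -> LabeledObjects:
    """Drop candidate vertebrae lying strictly above the DCF band's lower line.

    Bright subcutaneous fat sits inside or above the muscle band; a true
    vertebral echo reaches down to the band's lower boundary.  An object is
    removed iff its bottommost row is strictly above the boundary at the
    object's centroid column (objects straddling the line are kept).
    """
    keep: list[ObjectStats] = []
    for o in objs.objects:
        col = int(np.clip(round_half_up(o.centroid_x), dcf_lower.x_first, dcf_lower.x_last))
        boundary_y = dcf_lower.y_at(col)
        if o.y_bottom < boundary_y:
            continue
        keep.append(o)
    remap = np.zeros(objs.n_objects + 1, dtype=np.int32)
    new_objs = []
    for new_lab, o in enumerate(keep, start=1):
        remap[o.label] = new_lab
        new_objs.append(ObjectStats(new_lab, o.size, o.x_left, o.y_top,
                                    o.x_right, o.y_bottom))
    return LabeledObjects(remap[objs.label_map], new_objs)


def _vertebra_chain(binary: np.ndarray, dcf_lower: BoundaryCurve,
                    cfg: PipelineConfig, w: int, h: int) -> LabeledObjects:
    objs = blob_label(binary, cfg.connectivity)
    objs = remove_noise_objects(
        objs, w, h,
        size_frac=cfg.noise_size_frac,
        left_margin_frac=cfg.left_margin_frac,
        min_width_frac=cfg.min_width_frac,
    )
    if objs.n_objects == 0:
        return objs
    grown = expand(np.where(objs.mask(), 255, 0).astype(np.uint8), cfg.expand_radius)
    objs = blob_label(grown, cfg.connectivity)
    # Objects spanning (almost) the full ROI width are boundary lines - the
    # long curved fascia/bone echoes the noise rule deliberately keeps for
    # boundary reconstruction - not vertebral bodies.
    objs = _drop_full_width_objects(objs, cfg.vertebra_max_width_frac * w)
    return remove_fat_false_positives(objs, dcf_lower)


def _drop_full_width_objects(objs: LabeledObjects, max_width: float) -> LabeledObjects:
    keep = [o for o in objs.objects if o.width < max_width]
    remap = np.zeros(objs.n_objects + 1, dtype=np.int32)
    new_objs = []
    for new_lab, o in enumerate(keep, start=1):
        remap[o.label] = new_lab
        new_objs.append(ObjectStats(new_lab, o.size, o.x_left, o.y_top,
                                    o.x_right, o.y_bottom))
    return LabeledObjects(remap[objs.label_map], new_objs)


def extract_vertebrae(stretched: GrayImage, dcf_lower: BoundaryCurve,
                      cfg: PipelineConfig) -> VertebraResult:
    """Stage 2: vertebral echo objects and their completed upper boundary.

    Runs fuzzy sigma binarization, the object-level cleaning chain and fat
    removal; if the leftmost surviving object starts in the right half of the
    ROI the distance-weighted restoration retry is invoked once.  The
    returned boundary (vertebral echo tops, DDA-connected across the
    inter-vertebral gaps, spline-completed and anchored to the ROI edges) is
    the DCF band's final lower boundary.
    """
    w, h = stretched.width, stretched.height
    log_: list[StageRecord] = []
    binary = fuzzy_sigma_binarize(stretched, cfg.alpha_cut)
    objs = _vertebra_chain(binary, dcf_lower, cfg, w, h)
    log_.append(StageRecord("fuzzy_sigma_binarize", {"n_objects": objs.n_objects}))
    restore_invoked = False
    if objs.n_objects == 0:
        return VertebraResult(False, stage_log=log_, failed_stage="vertebra_candidates")
    leftmost = min(objs.objects, key=lambda o: (o.x_left, o.y_top))
    if leftmost.x_left >= w / 2:
        # The true leftmost vertebra was probably lost during thresholding:
        # boost the grayscale away from the center and re-threshold once.
        restore_invoked = True
        center = cfg.restore_center or (w // 2, h // 2)
        boosted = weighted_restore(stretched, center, cfg.restore_divisor)
        retry = _vertebra_chain(average_binarize(boosted), dcf_lower, cfg, w, h)
        log_.append(StageRecord("weighted_restore", {"n_objects": retry.n_objects}))
        if retry.n_objects > 0:
            objs = retry
    objs = _sort_left_to_right(objs)
    boundary = _vertebra_upper_boundary(objs, w, h)
    if boundary is None:
        return VertebraResult(False, objects=objs, restore_invoked=restore_invoked,
                              stage_log=log_, failed_stage="vertebra_boundary")
    return VertebraResult(True, objects=objs, upper_boundary=boundary,
                          restore_invoked=restore_invoked, stage_log=log_)


def _sort_left_to_right(objs: LabeledObjects) -> LabeledObjects:
    order = sorted(objs.objects, key=lambda o: (o.x_left, o.y_top))
    remap = np.zeros(objs.n_objects + 1, dtype=np.int32)
    new_objs = []
    for new_lab, o in enumerate(order, start=1):
        remap[o.label] = new_lab
        new_objs.append(ObjectStats(new_lab, o.size, o.x_left, o.y_top,
                                    o.x_right, o.y_bottom))
    return LabeledObjects(remap[objs.label_map], new_objs)


def _vertebra_upper_boundary(objs: LabeledObjects, w: int, h: int) -> BoundaryCurve | None:
    mask = objs.mask()
    cols = np.nonzero(mask.any(axis=0))[0]
    if cols.size < 2:
        return None
    tops = mask.argmax(axis=0)[cols]
    xs = list(cols)
    ys = list(tops)
    # DDA-connect the gaps between neighbouring vertebral echoes
    gaps = np.nonzero(np.diff(cols) > 1)[0]
    for gi in gaps:
        seg = dda_fill((int(cols[gi]), int(tops[gi])),
                       (int(cols[gi + 1]), int(tops[gi + 1])))
        for x, y in seg[1:-1]:
            xs.append(x)
            ys.append(y)
    order = np.argsort(xs)
    curve = BoundaryCurve(np.asarray(xs)[order], np.asarray(ys)[order])
    return reconnect_boundary(curve, (0, w - 1), image_height=h, extend_flat=True)


def locate_key_point(vertebrae: LabeledObjects) -> tuple[int, int]:
    """Rightmost pixel of the leftmost vertebral object.

    The leftmost object has the minimal bounding-box left edge (ties by
    smaller top edge); within it, the pixel with maximal x wins, ties by
    smallest y.
    """
    if vertebrae.n_objects == 0:
        raise ValueError("no vertebral objects")
    leftmost = min(vertebrae.objects, key=lambda o: (o.x_left, o.y_top))
    ys, xs = np.nonzero(vertebrae.label_map == leftmost.label)
    xmax = xs.max()
    ymin = ys[xs == xmax].min()
    return int(xmax), int(ymin)


@dataclass
class MeasureResult:
    success: bool
    reason: str | None = None
    measure_xs: tuple[int, int, int] | None = None
    chords: list[dict] | None = None
    thickness: float | None = None


def measure_thickness(dcf_upper: BoundaryCurve, dcf_lower: BoundaryCurve,
                      key_point: tuple[int, int],
                      spacing_cm: tuple[float, float] | None,
                      offset_cm: float = 1.0,
                      offset_px: int | None = None) -> MeasureResult:
    """Three vertical chords through the DCF at the key column and +-1 cm.

    Chord length at column x is ``(y_lower - y_upper) * sy``.  Without
    calibration (``spacing_cm=None``) an explicit pixel offset must be
    given and lengths are returned in pixels.
    """
    kx = key_point[0]
    if spacing_cm is None:
        if offset_px is None:
            raise UnitsError(
                "pixel spacing unknown: supply --pixel-spacing for cm output"
            )
        d = int(offset_px)
        sy = 1.0
    else:
        d = round_half_up(offset_cm / spacing_cm[0])
        sy = spacing_cm[1]
    xs = (kx - d, kx, kx + d)
    chords = []
    for x in xs:
        if not (dcf_upper.covers(x) and dcf_lower.covers(x)):
            return MeasureResult(False, reason=f"measuring column {x} outside boundary domain",
                                 measure_xs=xs)
        y_up = dcf_upper.y_at(x)
        y_lo = dcf_lower.y_at(x)
        if not y_up < y_lo:
            return MeasureResult(False, reason=f"inverted boundaries at column {x}",
                                 measure_xs=xs)
        chords.append({"x": int(x), "y_top": float(y_up), "y_bottom": float(y_lo),
                       "length": (y_lo - y_up) * sy})
    thickness = float(np.mean([c["length"] for c in chords]))
    return MeasureResult(True, measure_xs=xs, chords=chords, thickness=thickness)


def run_pipeline(image: GrayImage, cfg: PipelineConfig | None = None) -> ExtractionResult:
    """Crop, extract, locate the key point and measure; never raises on valid images.

    The result is deterministic: identical inputs and configuration yield
    bit-identical outputs (there is no randomness anywhere in the pipeline).
    With ``cfg.mirror=True`` the image is flipped horizontally on input and
    all reported coordinates are flipped back, for right-dominant anatomy.
    """
    cfg = cfg or PipelineConfig()
    if cfg.mirror:
        flipped = GrayImage(np.fliplr(image.pixels).copy(), image.spacing_cm)
        m_roi = None
        if cfg.roi is not None:
            m_roi = ROISpec(image.width - cfg.roi.x1, cfg.roi.y0,
                            image.width - cfg.roi.x0, cfg.roi.y1)
        res = run_pipeline(flipped, replace(cfg, mirror=False, roi=m_roi))
        return _mirror_result(res, cfg.roi)

    roi = cfg.roi or ROISpec(0, 0, image.width, image.height)
    roi.validate_for(image)
    roi_img = crop_roi(image, roi)
    spacing = cfg.pixel_spacing or image.spacing_cm
    if spacing is None:
        log.warning("no pixel spacing available: measuring in pixel units "
                    "with a %d px lateral offset", cfg.offset_px)

    cand = extract_dcf_candidate(roi_img, cfg)
    if not cand.success:
        reason = ("constant region of interest" if cand.failed_stage == "degenerate_roi"
                  else "no object survived noise removal")
        return ExtractionResult(False, failed_stage=cand.failed_stage or "dcf_candidate",
                                reason=reason, roi=roi,
                                dcf_mask=np.zeros((roi_img.height, roi_img.width), dtype=np.uint8),
                                stage_log=cand.stage_log)
    vert = extract_vertebrae(cand.stretched, cand.lower, cfg)
    stage_log = cand.stage_log + vert.stage_log
    if not vert.success:
        return ExtractionResult(False, failed_stage=vert.failed_stage or "vertebrae",
                                reason="no vertebral object found",
                                roi=roi, candidate_mask=cand.mask,
                                dcf_upper=cand.upper, stage_log=stage_log)
    key = locate_key_point(vert.objects)
    dcf_upper, dcf_lower = cand.upper, vert.upper_boundary
    units = "cm" if spacing is not None else "px"
    meas = measure_thickness(dcf_upper, dcf_lower, key, spacing,
                             offset_cm=cfg.offset_cm, offset_px=cfg.offset_px)
    final_mask = _band_mask(dcf_upper, dcf_lower, roi_img.height, roi_img.width)
    if not meas.success:
        return ExtractionResult(False, failed_stage="measure_thickness",
                                reason=meas.reason, roi=roi,
                                dcf_mask=final_mask, candidate_mask=cand.mask,
                                dcf_upper=dcf_upper, dcf_lower=dcf_lower,
                                vertebrae=vert.objects, key_point=key,
                                measure_xs=meas.measure_xs, units=units,
                                stage_log=stage_log)
    stage_log = stage_log + [StageRecord("measure_thickness",
                                         {"thickness": meas.thickness, "units": units})]
    return ExtractionResult(
        True, roi=roi, dcf_mask=final_mask, candidate_mask=cand.mask,
        dcf_upper=dcf_upper, dcf_lower=dcf_lower, vertebrae=vert.objects,
        key_point=key, measure_xs=meas.measure_xs, chords=meas.chords,
        thickness_cm=meas.thickness if units == "cm" else None,
        thickness_px=meas.thickness if units == "px" else None,
        units=units, stage_log=stage_log,
    )


def _band_mask(upper: BoundaryCurve, lower: BoundaryCurve, h: int, w: int) -> np.ndarray:
    """The final DCF band: rows from the upper boundary down to (excl.) the lower."""
    mask = np.zeros((h, w), dtype=np.uint8)
    rows = np.arange(h)[:, None]
    uy = np.full(w, h, dtype=np.int64)
    ly = np.full(w, -1, dtype=np.int64)
    uy[upper.xs] = np.asarray(upper.ys, dtype=np.int64)
    ly[lower.xs] = np.asarray(lower.ys, dtype=np.int64)
    band = (rows >= uy[None, :]) & (rows < ly[None, :])
    mask[band] = 255
    return mask


def _mirror_result(res: ExtractionResult, orig_roi: ROISpec | None) -> ExtractionResult:
    """Map a result computed on the flipped image back to original coordinates."""
    if res.roi is None:
        return res
    w = res.roi.width

    def flip_x(x: int) -> int:
        return w - 1 - x

    def flip_curve(c: BoundaryCurve | None) -> BoundaryCurve | None:
        if c is None:
            return None
        return BoundaryCurve(w - 1 - c.xs[::-1], np.asarray(c.ys)[::-1])

    def flip_mask(m: np.ndarray | None) -> np.ndarray | None:
        return None if m is None else np.fliplr(m).copy()

    res.roi = orig_roi
    res.dcf_mask = flip_mask(res.dcf_mask)
    res.candidate_mask = flip_mask(res.candidate_mask)
    res.dcf_upper = flip_curve(res.dcf_upper)
    res.dcf_lower = flip_curve(res.dcf_lower)
    if res.key_point is not None:
        res.key_point = (flip_x(res.key_point[0]), res.key_point[1])
    if res.measure_xs is not None:
        res.measure_xs = tuple(sorted(flip_x(x) for x in res.measure_xs))
    if res.chords is not None:
        for c in res.chords:
            c["x"] = flip_x(c["x"])
        res.chords = sorted(res.chords, key=lambda c: c["x"])
    if res.vertebrae is not None:
        res.vertebrae = None  # label map not re-mapped; object stats would be stale
    return res
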