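"""Synthetic craniocervical sonogram phantoms with full ground truth.

The phantom emulates the B-mode scene the extraction pipeline is built for:
a bright skin echo, the dark sternocleidomastoid (SCM) band bounded by bright
fascia, a dark blood vessel, the bright superficial fascia of the deep
cervical flexor (DCF), the dark DCF muscle band, and three bright vertebral
echo caps with an acoustic shadow beneath.  Multiplicative unit-mean gamma
speckle followed by a Gaussian blur approximates ultrasound texture, and the
resulting intensity histogram is skewed toward zero as in real craniocervical
sonograms.

Ground truth (masks, boundary curves, key point, thickness) is recorded
before noise is applied, so every pipeline stage can be scored exactly.

Thickness convention: the phantom's "DCF thickness" is the vertical distance
from the top of the superficial fascial echo to the top of the vertebral
echo, i.e. the band a mask-top measurement sees.  See docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from ._util import round_half_up
from .curves import BoundaryCurve
from .imgio import GrayImage, ROISpec, write_image, read_image

__all__ = ["PhantomParams", "PhantomTruth", "generate_phantom", "generate_batch",
           "write_truth", "read_truth"]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, echogenicity and noise settings of the synthetic sonogram.

    Lengths are in pixels unless suffixed ``_cm``.  Intensity means are the
    noiseless tissue levels; fascia and vertebral echoes must be brighter
    than muscle.  ``dcf_thickness_cm=None`` draws the thickness uniformly
    from ``thickness_range_cm`` using the phantom's own seed.
    """

    width: int = 800
    height: int = 600
    roi: ROISpec = field(default_factory=lambda: ROISpec(150, 180, 650, 430))
    spacing_cm: tuple[float, float] = (0.01, 0.01)

    # layers above the ROI (full-image realism only)
    skin_y: int = 55
    skin_thickness: int = 8
    scm_top: int = 75
    scm_bottom: int = 150
    scm_fascia_thickness: int = 6
    vessel_center: tuple[int, int] = (400, 166)
    vessel_axes: tuple[int, int] = (55, 13)

    # DCF band geometry (relative to the ROI)
    fascia_offset: int = 8            # rows below ROI top where the fascia starts
    fascia_amp: float = 5.0           # gentle curvature of the fascia line
    fascia_thickness: int = 22
    dcf_thickness_cm: float | None = None
    thickness_range_cm: tuple[float, float] = (0.6, 1.4)

    # vertebral echo caps
    vertebra_count: int = 3
    vertebra_width: int = 138
    vertebra_gap: int = 14
    vertebra_height: int = 90
    vertebra_left_margin: int = 52    # >= 10% of ROI width, clear of the left-skew rule
    vertebra_taper: int = 12          # rounded lower corners

    # echogenicity (mean intensities)
    tissue_mean: float = 50.0
    skin_mean: float = 190.0
    scm_mean: float = 40.0
    vessel_mean: float = 15.0
    fascia_mean: float = 215.0
    muscle_mean: float = 35.0
    vertebra_mean: float = 185.0
    vertebra_fade: float = 90.0   # brightness drop from echo top to cap bottom
    shadow_mean: float = 15.0

    # noise model
    speckle_var: float = 0.15         # relative variance of the multiplicative speckle
    blur_sigma: float = 1.0
    shift_right: bool = False         # push the vertebrae into the right half
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fascia_mean > self.muscle_mean and self.vertebra_mean > self.muscle_mean):
            raise ValueError("fascia and vertebra means must exceed the muscle mean")
        if self.thickness_range_cm[0] <= 0:
            raise ValueError("thickness range must be positive")
        if self.speckle_var < 0:
            raise ValueError("speckle_var must be non-negative")


@dataclass
class PhantomTruth:
    """Noiseless ground truth of one phantom (full-image coordinates)."""

    dcf_mask: np.ndarray
    scm_mask: np.ndarray
    vertebra_masks: list[np.ndarray]
    key_point: tuple[int, int]
    thickness_cm: float
    thickness_px: int
    upper_boundary: BoundaryCurve
    lower_boundary: BoundaryCurve
    roi: ROISpec
    spacing_cm: tuple[float, float]

    def dcf_mask_roi(self) -> np.ndarray:
        r = self.roi
        return self.dcf_mask[r.y0 : r.y1, r.x0 : r.x1]

    def vertebra_mask_roi(self) -> np.ndarray:
        r = self.roi
        out = np.zeros((r.height, r.width), dtype=bool)
        for m in self.vertebra_masks:
            out |= m[r.y0 : r.y1, r.x0 : r.x1]
        return out

    def key_point_roi(self) -> tuple[int, int]:
        return (self.key_point[0] - self.roi.x0, self.key_point[1] - self.roi.y0)


def _fascia_top_rows(p: PhantomParams) -> np.ndarray:
    """Absolute row of the fascia top per ROI column (gentle sine arch)."""
    w = p.roi.width
    u = np.arange(w) / max(w - 1, 1)
    f0 = p.roi.y0 + p.fascia_offset + p.fascia_amp * np.sin(np.pi * u)
    return round_half_up(f0)


def _cap_spans(p: PhantomParams) -> list[tuple[int, int]]:
    """Absolute (x_start, x_end_exclusive) of each vertebral cap, clipped to the ROI."""
    margin = p.vertebra_left_margin
    if p.shift_right:
        margin = p.roi.width // 2 + 10
    spans = []
    x = p.roi.x0 + margin
    for _ in range(p.vertebra_count):
        x0, x1 = x, min(x + p.vertebra_width, p.roi.x1)
        if x1 - x0 >= p.vertebra_taper * 2:
            spans.append((x0, x1))
        x += p.vertebra_width + p.vertebra_gap
    if not spans:
        raise ValueError("no vertebral cap fits the ROI with these parameters")
    return spans


def generate_phantom(params: PhantomParams | None = None) -> tuple[GrayImage, PhantomTruth]:
    """Draw one phantom and its ground truth; same seed, same bits."""
    p = params or PhantomParams()
    rng = np.random.default_rng(p.seed)

    t_cm = p.dcf_thickness_cm
    if t_cm is None:
        t_cm = float(rng.uniform(*p.thickness_range_cm))
    t_px = round_half_up(t_cm / p.spacing_cm[1])
    if t_px <= p.fascia_thickness:
        raise ValueError("DCF thickness must exceed the fascia thickness")
    f_top = _fascia_top_rows(p)
    if int(f_top.max()) + t_px + p.vertebra_height > p.roi.y1:
        raise ValueError("DCF band and vertebrae do not fit inside the ROI")

    h, w = p.height, p.width
    base = np.full((h, w), p.tissue_mean, dtype=np.float64)

    # superficial anatomy above the ROI
    base[p.skin_y : p.skin_y + p.skin_thickness, :] = p.skin_mean
    ft = p.scm_fascia_thickness
    base[p.scm_top : p.scm_top + ft, :] = p.fascia_mean - 25
    base[p.scm_top + ft : p.scm_bottom - ft, :] = p.scm_mean
    base[p.scm_bottom - ft : p.scm_bottom, :] = p.fascia_mean - 25
    cx, cy = p.vessel_center
    ax, ay = p.vessel_axes
    yy, xx = np.mgrid[0:h, 0:w]
    base[((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0] = p.vessel_mean

    # DCF band: fascia, muscle, vertebral caps, shadow (per ROI column)
    cols = np.arange(p.roi.x0, p.roi.x1)
    rows = np.arange(h)[:, None]
    ftop = f_top[None, :]
    in_roi_cols = np.zeros(w, dtype=bool)
    in_roi_cols[cols] = True

    sub = base[:, cols]
    sub[(rows >= ftop) & (rows < ftop + p.fascia_thickness)] = p.fascia_mean
    sub[(rows >= ftop + p.fascia_thickness) & (rows < ftop + t_px)] = p.muscle_mean
    sub[rows >= ftop + t_px] = p.shadow_mean
    base[:, cols] = sub

    spans = _cap_spans(p)
    cap_masks: list[np.ndarray] = []
    for (x0, x1) in spans:
        mask = np.zeros((h, w), dtype=bool)
        for x in range(x0, x1):
            edge = min(x - x0, x1 - 1 - x)
            if edge >= p.vertebra_taper:
                depth = p.vertebra_height
            else:
                depth = round_half_up(p.vertebra_height * (0.3 + 0.7 * edge / p.vertebra_taper))
            top = int(f_top[x - p.roi.x0]) + t_px
            mask[top : top + depth, x] = True
            # bright surface echo fading toward the cap bottom: the deep part
            # of the bone echo is barely brighter than muscle, which is the
            # low-contrast condition the fuzzy binarizer is designed for
            depths = np.arange(depth) / max(p.vertebra_height - 1, 1)
            base[top : top + depth, x] = p.vertebra_mean - p.vertebra_fade * depths
        cap_masks.append(mask)

    # speckle + blur
    img = base
    if p.speckle_var > 0:
        k = 1.0 / p.speckle_var
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    if p.blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=p.blur_sigma)
    pixels = np.clip(round_half_up(img), 0, 255).astype(np.uint8)

    # ground truth
    dcf_mask = np.zeros((h, w), dtype=bool)
    sub = dcf_mask[:, cols]
    sub[(rows >= ftop) & (rows < ftop + t_px)] = True
    dcf_mask[:, cols] = sub
    scm_mask = np.zeros((h, w), dtype=bool)
    scm_mask[p.scm_top + ft : p.scm_bottom - ft, cols] = True

    kx = spans[0][1] - 1
    ky = int(f_top[kx - p.roi.x0]) + t_px
    truth = PhantomTruth(
        dcf_mask=dcf_mask,
        scm_mask=scm_mask,
        vertebra_masks=cap_masks,
        key_point=(kx, ky),
        thickness_cm=t_px * p.spacing_cm[1],
        thickness_px=t_px,
        upper_boundary=BoundaryCurve(cols, f_top),
        lower_boundary=BoundaryCurve(cols, f_top + t_px),
        roi=p.roi,
        spacing_cm=p.spacing_cm,
    )
    return GrayImage(pixels, p.spacing_cm), truth


def generate_batch(
    n: int, params: PhantomParams | None = None, base_seed: int = 1
) -> list[tuple[GrayImage, PhantomTruth]]:
    """Phantoms for seeds ``base_seed .. base_seed + n - 1``.

    Each phantom draws its own DCF thickness from ``thickness_range_cm``
    (unless pinned in *params*), so a batch spans the configured range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params or PhantomParams()
    return [generate_phantom(replace(p, seed=base_seed + i)) for i in range(n)]


def write_truth(truth: PhantomTruth, path: str | Path) -> None:
    """Write masks as binary PNGs and scalars/curves as JSON under *path*/ ."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_mask(truth.dcf_mask, path / "dcf_mask.png")
    _write_mask(truth.scm_mask, path / "scm_mask.png")
    for i, m in enumerate(truth.vertebra_masks):
        _write_mask(m, path / f"vertebra_mask_{i}.png")
    meta = {
        "key_point": list(truth.key_point),
        "thickness_cm": round(float(truth.thickness_cm), 6),
        "thickness_px": int(truth.thickness_px),
        "upper_boundary": {"x": truth.upper_boundary.xs.tolist(),
                           "y": np.asarray(truth.upper_boundary.ys).tolist()},
        "lower_boundary": {"x": truth.lower_boundary.xs.tolist(),
                           "y": np.asarray(truth.lower_boundary.ys).tolist()},
        "roi": [truth.roi.x0, truth.roi.y0, truth.roi.x1, truth.roi.y1],
        "spacing_cm": list(truth.spacing_cm),
        "n_vertebrae": len(truth.vertebra_masks),
    }
    (path / "truth.json").write_text(json.dumps(meta, indent=1))


def _write_mask(mask: np.ndarray, path: Path) -> None:
    write_image(GrayImage(np.where(mask, 255, 0).astype(np.uint8)), path)


def read_truth(path: str | Path) -> PhantomTruth:
    """Inverse of :func:`write_truth`."""
    path = Path(path)
    meta = json.loads((path / "truth.json").read_text())
    dcf = read_image(path / "dcf_mask.png").pixels > 0
    scm = read_image(path / "scm_mask.png").pixels > 0
    verts = [
        read_image(path / f"vertebra_mask_{i}.png").pixels > 0
        for i in range(meta["n_vertebrae"])
    ]
    return PhantomTruth(
        dcf_mask=dcf,
        scm_mask=scm,
        vertebra_masks=verts,
        key_point=tuple(meta["key_point"]),
        thickness_cm=float(meta["thickness_cm"]),
        thickness_px=int(meta["thickness_px"]),
        upper_boundary=BoundaryCurve(np.array(meta["upper_boundary"]["x"]),
                                     np.array(meta["upper_boundary"]["y"])),
        lower_boundary=BoundaryCurve(np.array(meta["lower_boundary"]["x"]),
                                     np.array(meta["lower_boundary"]["y"])),
        roi=ROISpec(*meta["roi"]),
        spacing_cm=tuple(meta["spacing_cm"]),
    )
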