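"""Per-image analysis: distortion correction, fiducial registration,
HSV green segmentation and per-well area measurement.

The processing chain mirrors the acquisition platform's software: each
top-view plate image is first corrected for radial lens distortion, then
registered to the plate template using the blue boundary marks on the tray.
Because mark detection can pick up spurious blobs, several candidate
registrations are scored and tried in order of decreasing plausibility;
a candidate is accepted only if, after cropping to the plate and
thresholding in HSV space, no green area is found outside the wells.  The
green-pixel count of each well disc, in column-wise well order, is the
measurement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage import color, measure, morphology, transform

from .optics import correct_fisheye
from .plates import PlateLayout, mark_template

__all__ = [
    "PlateImage",
    "Registration",
    "SegmentationConfig",
    "WellMap",
    "PlateMeasurement",
    "MarkDetectionError",
    "RegistrationError",
    "load_plate_image",
    "segment_green",
    "detect_blue_marks",
    "propose_registrations",
    "apply_registration",
    "validate_registration",
    "count_well_areas",
    "measure_plate",
    "nominal_px_per_mm",
]


class MarkDetectionError(RuntimeError):
    """Raised when fewer fiducial marks are found than registration needs."""

    def __init__(self, n_found: int, n_required: int = 2):
        self.n_found = n_found
        super().__init__(f"found {n_found} blue marks, need at least {n_required}")


class RegistrationError(RuntimeError):
    pass


@dataclass
class PlateImage:
    """An 8-bit RGB plate image plus the metadata encoded in its filename."""

    pixels: np.ndarray
    filename: str = ""
    acquisition_time: datetime | None = None
    camera_xy: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a (H, W, 3) RGB array")
        if px.dtype != np.uint8:
            # convert other bit depths on read
            px = np.clip(px.astype(float) * (255.0 / px.max() if px.max() > 255 else 1.0),
                         0, 255).astype(np.uint8)
        self.pixels = px


def load_plate_image(path) -> PlateImage:
    """Read a PNG and parse acquisition time / camera (x, y) from its name."""
    from .store import parse_filename

    path = Path(path)
    try:
        px = iio.imread(path)
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[..., :3]
    t, xy = parse_filename(path.name)
    return PlateImage(pixels=px, filename=path.name, acquisition_time=t, camera_xy=xy)


@dataclass(frozen=True)
class Registration:
    """A candidate similarity transform (plate mm -> image px) with its
    plausibility score (normalised inverse residual) and rank."""

    transform: transform.SimilarityTransform
    score: float
    rank: int = 0

    @property
    def scale(self) -> float:
        return float(self.transform.scale)

    @property
    def rotation(self) -> float:
        return float(self.transform.rotation)

    @property
    def translation(self) -> tuple[float, float]:
        return tuple(self.transform.translation)


@dataclass
class SegmentationConfig:
    """Thresholds and camera parameters for one imaging setup.

    Hue cut-offs use the 0-179 convention (half-degrees), saturation and
    value 0-255, as is customary for 8-bit HSV thresholding.  Plant pixels
    must satisfy all three band tests simultaneously (logical AND); the only
    post-processing is removal of connected components below
    ``min_component_size`` pixels, guarding against single-pixel sensor
    noise.  ``outside_tolerance`` is the number of (post-filter) green pixels
    allowed outside the well discs before a registration is rejected.
    """

    h_low: float = 35.0
    h_high: float = 90.0
    s_low: float = 60.0
    v_low: float = 40.0
    v_high: float = 255.0
    blue_h_low: float = 100.0
    blue_h_high: float = 140.0
    blue_s_low: float = 80.0
    min_component_size: int = 5
    min_mark_size: int = 40
    distortion_k: float = 0.0
    distortion_center: tuple[float, float] | None = None
    outside_tolerance: int = 0
    crop_px_per_mm: float | None = None
    max_candidates: int = 10
    mark_margin_mm: float = 6.0

    @classmethod
    def from_yaml(cls, path) -> "SegmentationConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {k: v for k, v in cfg.items() if k in cls.__dataclass_fields__}
        if "distortion_center" in known and known["distortion_center"] is not None:
            known["distortion_center"] = tuple(known["distortion_center"])
        return cls(**known)


@dataclass
class WellMap:
    """Well geometry in the pixel frame of a cropped plate image."""

    centers: np.ndarray  # (n, 2) px, column-wise well order
    radius: float        # px
    shape: tuple[int, int]  # (H, W) of the cropped raster

    def _window(self, cx: float, cy: float, r: float):
        h, w = self.shape
        x0, x1 = max(0, int(cx - r) - 2), min(w, int(cx + r) + 3)
        y0, y1 = max(0, int(cy - r) - 2), min(h, int(cy + r) + 3)
        wy, wx = np.mgrid[y0:y1, x0:x1]
        return (slice(y0, y1), slice(x0, x1)), wx, wy

    def disc_mask(self) -> np.ndarray:
        """Boolean raster: union of all well discs."""
        inside = np.zeros(self.shape, dtype=bool)
        for cx, cy in self.centers:
            win, wx, wy = self._window(cx, cy, self.radius)
            inside[win] |= (wx - cx) ** 2 + (wy - cy) ** 2 <= self.radius**2
        return inside


@dataclass
class PlateMeasurement:
    """Per-well green areas (pixels, column-wise order) for one image."""

    areas: list[int]
    registration_used: Registration | None
    valid: bool
    preview_path: str | None = None
    filename: str = ""
    acquisition_time: datetime | None = None
    camera_xy: tuple[int, int] | None = None


def nominal_px_per_mm(image_shape: tuple[int, int], layout: PlateLayout,
                      margin_mm: float = 12.0) -> float:
    """Scale at which a plate plus fiducial margin nominally fills the raster.

    The same convention is used by the synthetic renderer and as the default
    crop resolution, so measured pixel areas are directly comparable to
    generated ground truth.
    """
    h, w = image_shape[:2]
    return min(w / (layout.plate_width + 2 * margin_mm),
               h / (layout.plate_height + 2 * margin_mm))


def _hsv(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hsv = color.rgb2hsv(image)
    # H in [0,1] -> 0-179 half-degree units; S, V -> 0-255
    return hsv[..., 0] * 180.0, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0


def segment_green(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Binary plant mask: fixed cut-off in each HSV channel, combined by AND.

    A purely per-pixel classification followed by an optional
    minimum-component-size filter; no other morphology is applied.
    """
    config = config or SegmentationConfig()
    h, s, v = _hsv(np.asarray(image))
    mask = ((h >= config.h_low) & (h <= config.h_high)
            & (s >= config.s_low)
            & (v >= config.v_low) & (v <= config.v_high))
    if config.min_component_size > 1:
        mask = morphology.remove_small_objects(mask, max_size=config.min_component_size - 1)
    return mask


def detect_blue_marks(image: np.ndarray,
                      config: SegmentationConfig | None = None) -> np.ndarray:
    """Centroids (x, y) of the blue tray fiducials, ordered by angle about
    their common centroid.

    Blue is thresholded in HSV like the plant mask; connected components
    below ``min_mark_size`` pixels are discarded.  Raises
    :class:`MarkDetectionError` when fewer than two marks survive.
    """
    config = config or SegmentationConfig()
    h, s, v = _hsv(np.asarray(image))
    mask = ((h >= config.blue_h_low) & (h <= config.blue_h_high)
            & (s >= config.blue_s_low) & (v >= config.v_low))
    lab = measure.label(mask)
    props = [p for p in measure.regionprops(lab) if p.area >= config.min_mark_size]
    if len(props) < 2:
        raise MarkDetectionError(len(props))
    props.sort(key=lambda p: p.area, reverse=True)
    props = props[:8]  # cap the correspondence search
    pts = np.array([(p.centroid[1], p.centroid[0]) for p in props], dtype=float)
    ang = np.arctan2(pts[:, 1] - pts[:, 1].mean(), pts[:, 0] - pts[:, 0].mean())
    return pts[np.argsort(ang)]


def propose_registrations(marks: np.ndarray, layout: PlateLayout,
                          template: np.ndarray | None = None,
                          mark_margin_mm: float = 6.0) -> list[Registration]:
    """Ranked candidate similarity transforms from mark/template
    correspondences.

    Every assignment of ``m = min(len(marks), 4)`` detected marks to m
    template positions is fitted by least squares; candidates are scored by
    normalised inverse RMS residual and returned sorted by decreasing score.
    Grossly implausible scales are discarded.
    """
    marks = np.asarray(marks, dtype=float)
    if len(marks) < 2:
        raise RegistrationError(f"need at least 2 marks, got {len(marks)}")
    if template is None:
        template = mark_template(layout, margin=mark_margin_mm)
    m = min(len(marks), len(template))
    candidates: list[tuple[float, transform.SimilarityTransform]] = []
    for dst_idx in itertools.combinations(range(len(marks)), m):
        dst_sub = marks[list(dst_idx)]
        for src_idx in itertools.permutations(range(len(template)), m):
            src = template[list(src_idx)]
            tf = transform.SimilarityTransform.from_estimate(src, dst_sub)
            if not tf:
                continue
            if not (tf.scale > 0 and np.isfinite(tf.scale)):
                continue
            resid = tf(src) - dst_sub
            rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
            candidates.append((rms, tf))
    if not candidates:
        raise RegistrationError("no geometrically consistent mark correspondence")
    candidates.sort(key=lambda c: c[0])
    # drop near-duplicate transforms (same params within 1 px / 1e-3 rad)
    out: list[Registration] = []
    seen: list[np.ndarray] = []
    inv_scores = [1.0 / (1.0 + rms) for rms, _ in candidates]
    total = sum(inv_scores)
    for (rms, tf), s in zip(candidates, inv_scores):
        key = np.array([tf.scale, tf.rotation, *tf.translation])
        if any(np.allclose(key, k, atol=1.0) for k in seen):
            continue
        seen.append(key)
        out.append(Registration(transform=tf, score=s / total, rank=len(out)))
    return out


def apply_registration(image: np.ndarray, registration: Registration,
                       layout: PlateLayout, px_per_mm: float | None = None
                       ) -> tuple[np.ndarray, WellMap]:
    """Crop the image to the plate rectangle and map wells to pixel space.

    The output raster covers exactly the plate rectangle at ``px_per_mm``
    (default: the nominal scale for this image size), so well geometry in
    the crop is the layout scaled by that factor.  Raises
    :class:`RegistrationError` if the transform would sample outside the
    image.
    """
    image = np.asarray(image)
    if px_per_mm is None:
        px_per_mm = nominal_px_per_mm(image.shape, layout)
    out_w = int(round(layout.plate_width * px_per_mm))
    out_h = int(round(layout.plate_height * px_per_mm))
    # inverse map: crop px -> plate mm -> image px
    scale_tf = transform.SimilarityTransform(scale=1.0 / px_per_mm)
    inv = transform.SimilarityTransform(
        matrix=registration.transform.params @ scale_tf.params)
    corners = inv(np.array([(0, 0), (out_w, 0), (out_w, out_h), (0, out_h)], float))
    h, w = image.shape[:2]
    pad = 2.0
    if (corners[:, 0].min() < -pad or corners[:, 1].min() < -pad
            or corners[:, 0].max() > w - 1 + pad or corners[:, 1].max() > h - 1 + pad):
        raise RegistrationError("registration maps the plate partially outside the image")
    crop = transform.warp(image, inverse_map=inv, output_shape=(out_h, out_w),
                          order=1, preserve_range=True).astype(image.dtype)
    centers = layout.well_centers() * px_per_mm
    well_map = WellMap(centers=centers, radius=layout.well_radius * px_per_mm,
                       shape=(out_h, out_w))
    return crop, well_map


def validate_registration(mask: np.ndarray, well_map: WellMap,
                          outside_tolerance: int = 0) -> bool:
    """True iff at most ``outside_tolerance`` plant pixels fall outside all
    well discs — the platform's self-check that registration succeeded."""
    outside = mask & ~well_map.disc_mask()
    return int(outside.sum()) <= outside_tolerance


def count_well_areas(mask: np.ndarray, well_map: WellMap) -> list[int]:
    """Green-pixel count inside each well disc, column-wise well order."""
    areas = []
    for cx, cy in well_map.centers:
        win, wx, wy = well_map._window(cx, cy, well_map.radius)
        disc = (wx - cx) ** 2 + (wy - cy) ** 2 <= well_map.radius**2
        areas.append(int((mask[win] & disc).sum()))
    return areas


def _write_preview(crop: np.ndarray, mask: np.ndarray, well_map: WellMap,
                   path: Path) -> None:
    """Overlay: segmented pixels tinted magenta, well perimeters drawn blue."""
    overlay = crop.copy()
    overlay[mask] = (0.5 * overlay[mask] + 0.5 * np.array([255, 0, 255])).astype(np.uint8)
    for cx, cy in well_map.centers:
        win, wx, wy = well_map._window(cx, cy, well_map.radius + 2)
        d2 = (wx - cx) ** 2 + (wy - cy) ** 2
        ring = (d2 <= (well_map.radius + 1) ** 2) & (d2 >= (well_map.radius - 1) ** 2)
        overlay[win][ring] = (40, 40, 255)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, overlay)


def measure_plate(image: PlateImage | np.ndarray, layout: PlateLayout,
                  config: SegmentationConfig | None = None,
                  preview_dir=None) -> PlateMeasurement:
    """Full per-image measurement with the registration retry loop.

    Candidates are tried in rank order: distortion-correct, register, crop,
    segment, validate.  The first candidate with no green outside the wells
    is accepted; its per-well counts (column-wise) are returned with
    ``valid=True`` and, if requested, a preview overlay is written.  If every
    candidate fails validation the best-scoring croppable candidate is
    returned flagged ``valid=False`` for manual review; if registration is
    impossible altogether the measurement carries zero areas and no
    registration.
    """
    config = config or SegmentationConfig()
    if isinstance(image, np.ndarray):
        image = PlateImage(pixels=image)
    px = correct_fisheye(image.pixels, config.distortion_k, config.distortion_center)
    ppm = config.crop_px_per_mm or nominal_px_per_mm(px.shape, layout)

    def _finish(areas, reg, valid, crop=None, mask=None, wmap=None):
        preview = None
        if preview_dir is not None and crop is not None:
            preview = Path(preview_dir) / f"{Path(image.filename or 'plate').stem}_preview.png"
            _write_preview(crop, mask, wmap, preview)
        return PlateMeasurement(
            areas=areas, registration_used=reg, valid=valid,
            preview_path=str(preview) if preview else None,
            filename=image.filename, acquisition_time=image.acquisition_time,
            camera_xy=image.camera_xy)

    try:
        marks = detect_blue_marks(px, config)
        cands = propose_registrations(marks, layout,
                                      mark_margin_mm=config.mark_margin_mm)
    except (MarkDetectionError, RegistrationError):
        return _finish([0] * layout.wells_per_plate, None, False)

    fallback = None
    for reg in cands[: config.max_candidates]:
        try:
            crop, wmap = apply_registration(px, reg, layout, px_per_mm=ppm)
        except RegistrationError:
            continue
        mask = segment_green(crop, config)
        areas = count_well_areas(mask, wmap)
        if validate_registration(mask, wmap, config.outside_tolerance):
            return _finish(areas, reg, True, crop, mask, wmap)
        if fallback is None:
            fallback = (areas, reg, crop, mask, wmap)
    if fallback is not None:
        areas, reg, crop, mask, wmap = fallback
        return _finish(areas, reg, False, crop, mask, wmap)
    return _finish([0] * layout.wells_per_plate, None, False)
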