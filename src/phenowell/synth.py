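"""Ground-truthed synthetic inputs: rendered plate images and simulated
growth/stress experiments.

The renderer emulates what the acquisition platform photographs: a
white-background multi-well plate with green rosette blobs in a well grid
and blue boundary fiducials on the tray, viewed through a camera with an
unknown similarity pose and mild radial lens distortion.  Because every
nuisance (pose, distortion, noise) is applied on top of an ideal raster
whose per-well green pixel counts are controlled *exactly*, the whole
analysis pipeline can be scored against known truth.

The growth simulator produces per-plant exponential area series
``A(t) = A0 * exp(r_eff * t) * noise`` with treatment-dependent RGR
reduction and per-day mortality (a dead plant's area is zero from its death
day onward), emulating a salt-stress dose-response assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import color

from .growth import GrowthSeries
from .optics import undistort_points
from .pipeline import nominal_px_per_mm
from .plates import ExperimentDesign, PlateLayout, mark_template, standard_layout
from .store import format_filename

__all__ = [
    "GroundTruthPlate",
    "GrowthModel",
    "GenerationError",
    "make_transform",
    "random_plate",
    "render_plate",
    "simulate_growth",
    "generate_experiment",
    "FULL_RESOLUTION",
]

# Native raster of the platform camera, (height, width).
FULL_RESOLUTION: tuple[int, int] = (2000, 2500)

_MARK_RADIUS_MM = 2.5


class GenerationError(ValueError):
    pass


@dataclass
class GroundTruthPlate:
    """Everything needed to render one plate image and score its analysis.

    ``areas`` are exact green pixel counts per well (column-wise order) in
    the undistorted, untransformed plate raster at the nominal scale for
    ``image_size``.  ``transform_params`` is the applied similarity
    (scale s relative to nominal, rotation rad, translation px) mapping
    plate coordinates into the camera frame; ``distortion_k`` the radial
    division-model coefficient (px^-2) applied on top.
    """

    layout: PlateLayout
    areas: list[int]
    rng_seed: int = 0
    image_size: tuple[int, int] = FULL_RESOLUTION
    transform_params: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    distortion_k: float = 0.0
    noise_sd: float = 0.0
    mark_margin_mm: float = 6.0

    def __post_init__(self) -> None:
        if len(self.areas) != self.layout.wells_per_plate:
            raise GenerationError("one area per well required (column-wise)")
        if any(a < 0 for a in self.areas):
            raise GenerationError("areas must be non-negative")

    @property
    def px_per_mm(self) -> float:
        return nominal_px_per_mm(self.image_size, self.layout)

    def mark_positions_mm(self) -> np.ndarray:
        return mark_template(self.layout, margin=self.mark_margin_mm)

    def plate_to_image(self, pts_mm: np.ndarray) -> np.ndarray:
        """Map plate mm through the applied similarity + distortion into
        camera pixel coordinates."""
        s, rot, tx, ty = self.transform_params
        ppm = self.px_per_mm * s
        c, sn = math.cos(rot), math.sin(rot)
        pts = np.asarray(pts_mm, dtype=float)
        # similarity about the plate centre, then recentre on the image
        ctr = np.array([self.layout.plate_width / 2, self.layout.plate_height / 2])
        d = (pts - ctr) * ppm
        rotated = np.stack([c * d[..., 0] - sn * d[..., 1],
                            sn * d[..., 0] + c * d[..., 1]], axis=-1)
        h, w = self.image_size
        img_ctr = np.array([(w - 1) / 2 + tx, (h - 1) / 2 + ty])
        undist = rotated + img_ctr
        if self.distortion_k == 0:
            return undist
        from .optics import distort_points
        return distort_points(undist, self.distortion_k,
                              ((w - 1) / 2, (h - 1) / 2))


def _blob_pixels(n: int, radius_px: float, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Offsets (dx, dy) of exactly n pixels forming a rosette-like blob.

    The blob is defined by a star-shaped radius profile (a disc modulated by
    4-8 angular lobes); pixels are admitted in order of increasing
    normalised radius, which makes the pixel count exact and monotone in n.
    """
    r = int(math.ceil(radius_px)) + 1
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    rad = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    n_lobes = int(rng.integers(4, 9))
    phase = rng.uniform(0, 2 * math.pi)
    amp = rng.uniform(0.1, 0.25)
    profile = 1.0 + amp * np.cos(n_lobes * theta + phase)
    f = rad / profile
    ok = rad <= radius_px
    if n > int(ok.sum()):
        raise GenerationError(
            f"area {n} px does not fit in a well of radius {radius_px:.1f} px")
    order = np.argsort(f[ok], kind="stable")[:n]
    return dx[ok][order], dy[ok][order]


def _hsv_to_rgb8(h_frac, s_frac, v_frac) -> np.ndarray:
    rgb = color.hsv2rgb(np.stack(np.broadcast_arrays(h_frac, s_frac, v_frac), axis=-1))
    return np.clip(rgb * 255, 0, 255).astype(np.uint8)


def render_plate(truth: GroundTruthPlate) -> np.ndarray:
    """Render a plate image (8-bit RGB, ``truth.image_size``).

    An ideal plate raster is built first — near-white background, blue
    fiducial discs, per-well green blobs whose pixel counts equal
    ``truth.areas`` exactly — then resampled once (nearest-neighbour)
    through the applied similarity transform and radial distortion, and
    finally perturbed with Gaussian sensor noise.  Deterministic per seed.
    """
    rng = np.random.default_rng(truth.rng_seed)
    lay = truth.layout
    ppm = truth.px_per_mm
    m = truth.mark_margin_mm * 2  # ideal raster margin around the plate, mm
    iw = int(round((lay.plate_width + 2 * m) * ppm))
    ih = int(round((lay.plate_height + 2 * m) * ppm))
    origin = np.array([m, m])  # plate origin inside ideal raster, mm

    # near-white background with a hint of texture
    ideal = np.full((ih, iw, 3), 245, dtype=np.uint8)
    ideal += rng.integers(0, 8, size=(ih, iw, 1), dtype=np.uint8)

    def _window(cx, cy, r):
        """Local raster window around (cx, cy): slices plus coordinate grids."""
        x0, x1 = max(0, int(cx - r) - 2), min(iw, int(cx + r) + 3)
        y0, y1 = max(0, int(cy - r) - 2), min(ih, int(cy + r) + 3)
        wy, wx = np.mgrid[y0:y1, x0:x1]
        return (slice(y0, y1), slice(x0, x1)), wx, wy

    # blue fiducials (hue ~240 deg)
    marks_px = (truth.mark_positions_mm() + origin) * ppm
    for mx, my in marks_px:
        win, wx, wy = _window(mx, my, _MARK_RADIUS_MM * ppm)
        disc = (wx - mx) ** 2 + (wy - my) ** 2 <= (_MARK_RADIUS_MM * ppm) ** 2
        hue = rng.normal(240, 4, size=int(disc.sum())) / 360.0
        ideal[win][disc] = _hsv_to_rgb8(hue, 0.85, 0.75)

    # faint well rims so the raster looks like a plate (grey, never green)
    for cx, cy in lay.well_centers():
        px, py = (np.array([cx, cy]) + origin) * ppm
        win, wx, wy = _window(px, py, lay.well_radius * ppm + 2)
        d2 = (wx - px) ** 2 + (wy - py) ** 2
        rim = (d2 <= (lay.well_radius * ppm + 1.5) ** 2) & (d2 >= (lay.well_radius * ppm - 1.5) ** 2)
        ideal[win][rim] = 210

    # green rosette blobs with exact pixel counts
    for (cx, cy), n in zip(lay.well_centers(), truth.areas):
        if n == 0:
            continue
        px, py = (np.array([cx, cy]) + origin) * ppm
        dx, dy = _blob_pixels(int(n), lay.well_radius * ppm - 2.0, rng)
        bx = np.clip(np.round(px + dx).astype(int), 0, iw - 1)
        by = np.clip(np.round(py + dy).astype(int), 0, ih - 1)
        hue = rng.normal(120, 8, size=len(bx)) / 360.0  # ~100-140 deg
        sat = rng.uniform(0.55, 0.8, size=len(bx))
        val = rng.uniform(0.4, 0.65, size=len(bx))
        ideal[by, bx] = _hsv_to_rgb8(hue, sat, val)

    # single inverse-mapped resampling: camera px -> undistort -> inverse
    # similarity -> ideal raster px (nearest neighbour keeps colours crisp)
    h, w = truth.image_size
    s, rot, tx, ty = truth.transform_params
    gy, gx = np.mgrid[0:h, 0:w]
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
    if truth.distortion_k != 0:
        pts = undistort_points(pts, truth.distortion_k, ((w - 1) / 2, (h - 1) / 2))
    img_ctr = np.array([(w - 1) / 2 + tx, (h - 1) / 2 + ty])
    d = pts - img_ctr
    c_, s_ = math.cos(-rot), math.sin(-rot)
    d = np.stack([c_ * d[:, 0] - s_ * d[:, 1], s_ * d[:, 0] + c_ * d[:, 1]], axis=1)
    plate_mm = d / (ppm * s) + np.array([lay.plate_width / 2, lay.plate_height / 2])
    ideal_px = (plate_mm + origin) * ppm
    ix = np.round(ideal_px[:, 0]).astype(int)
    iy = np.round(ideal_px[:, 1]).astype(int)
    inside = (ix >= 0) & (ix < iw) & (iy >= 0) & (iy < ih)
    out = np.full((h * w, 3), 245, dtype=np.uint8)
    out[inside] = ideal[iy[inside], ix[inside]]
    out = out.reshape(h, w, 3)

    # verify the fiducials landed on the raster
    cam_marks = truth.plate_to_image(truth.mark_positions_mm())
    pad = _MARK_RADIUS_MM * ppm * s
    if (cam_marks[:, 0].min() < pad or cam_marks[:, 1].min() < pad
            or cam_marks[:, 0].max() > w - 1 - pad or cam_marks[:, 1].max() > h - 1 - pad):
        raise GenerationError("applied transform pushes a fiducial off the image")

    if truth.noise_sd > 0:
        noise = rng.normal(0, truth.noise_sd, size=out.shape)
        out = np.clip(out.astype(float) + noise, 0, 255).astype(np.uint8)
    return out


def make_transform(rng: np.random.Generator, image_size: tuple[int, int],
                   scale_range=(0.88, 0.97), max_rotation_deg: float = 3.0,
                   max_translation_frac: float = 0.01
                   ) -> tuple[float, float, float, float]:
    """Draw a random camera pose (scale, rotation, translation) that keeps
    the plate and its fiducials comfortably inside the raster."""
    h, w = image_size
    jitter = max_translation_frac * min(h, w)
    return (float(rng.uniform(*scale_range)),
            float(np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))),
            float(rng.uniform(-jitter, jitter)),
            float(rng.uniform(-jitter, jitter)))


def random_plate(layout: PlateLayout | str = "24-well",
                 image_size: tuple[int, int] = FULL_RESOLUTION,
                 seed: int = 0,
                 area_range: tuple[int, int] | None = None,
                 distortion: bool = True,
                 noise_sd: float = 3.0) -> GroundTruthPlate:
    """A randomly posed, distorted, noisy plate with random per-well areas —
    the workhorse fixture for end-to-end accuracy checks."""
    if isinstance(layout, str):
        layout = standard_layout(layout)
    rng = np.random.default_rng(seed)
    ppm = nominal_px_per_mm(image_size, layout)
    max_fit = math.pi * (layout.well_radius * ppm - 2.0) ** 2
    if area_range is None:
        area_range = (int(0.05 * max_fit), int(0.4 * max_fit))
    areas = rng.integers(area_range[0], area_range[1] + 1,
                         size=layout.wells_per_plate).tolist()
    h, w = image_size
    r_max2 = ((w - 1) / 2) ** 2 + ((h - 1) / 2) ** 2
    k = float(rng.uniform(0, 0.03) / r_max2) if distortion else 0.0
    return GroundTruthPlate(
        layout=layout, areas=areas, rng_seed=seed, image_size=image_size,
        transform_params=make_transform(rng, image_size),
        distortion_k=k, noise_sd=noise_sd)


def render_plate_with_spurious_marks(truth: GroundTruthPlate,
                                     shift_pitch_frac: float = 0.45
                                     ) -> np.ndarray:
    """Render a plate whose fiducials are degraded and shadowed by a
    spurious replica — the registration failure case.

    The true marks are eroded on four different sides (their centroids move
    ~1 px in mutually inconsistent directions, so the true correspondence
    fits imperfectly) while a pixel-perfect replica of the mark pattern is
    painted shifted by ``shift_pitch_frac`` of the well pitch.  A
    least-squares candidate ranking will therefore prefer the replica, whose
    registration puts green areas outside the wells and must be rejected by
    the validation step; the analysis should recover via a lower-ranked
    candidate.
    """
    img = render_plate(truth).copy()
    rng = np.random.default_rng(truth.rng_seed + 1)
    true_marks = truth.plate_to_image(truth.mark_positions_mm())
    ppm = truth.px_per_mm * truth.transform_params[0]
    r_px = _MARK_RADIUS_MM * ppm
    h, w = img.shape[:2]
    for (mx, my), (dx, dy) in zip(true_marks, [(1, 0), (-1, 0), (0, 1), (0, -1)]):
        wy, wx = np.mgrid[max(0, int(my - r_px) - 1):min(h, int(my + r_px) + 2),
                          max(0, int(mx - r_px) - 1):min(w, int(mx + r_px) + 2)]
        cap = (((wx - mx) ** 2 + (wy - my) ** 2 <= r_px**2)
               & ((wx - mx) * dx + (wy - my) * dy > r_px * 0.3))
        img[wy[cap], wx[cap]] = 248
    shift = np.array([0.0, shift_pitch_frac * truth.layout.pitch * ppm])
    for mx, my in true_marks + shift:
        wy, wx = np.mgrid[max(0, int(my - r_px) - 1):min(h, int(my + r_px) + 2),
                          max(0, int(mx - r_px) - 1):min(w, int(mx + r_px) + 2)]
        disc = (wx - mx) ** 2 + (wy - my) ** 2 <= r_px**2
        hue = rng.normal(240, 4, size=int(disc.sum())) / 360.0
        img[wy[disc], wx[disc]] = _hsv_to_rgb8(hue, 0.85, 0.75)
    return img


@dataclass
class GrowthModel:
    """Stochastic exponential growth with treatment effects and mortality.

    Initial areas are drawn from N(a0_mean, a0_sd) truncated at a0_min
    (pixels at the platform's native resolution).  Each treatment scales the
    baseline RGR by a factor in [0, 1] and contributes a per-day death
    probability; observation noise is multiplicative log-normal.  Defaults
    emulate a salt dose-response: strong RGR suppression and appreciable
    mortality only at the highest dose.
    """

    a0_mean: float = 300.0
    a0_sd: float = 60.0
    a0_min: float = 50.0
    baseline_rgr: float = 0.40
    treatment_effects: dict = field(default_factory=lambda: {
        "Control": 1.0, "NaCl50": 0.85, "NaCl75": 0.70,
        "NaCl100": 0.44, "NaCl150": 0.16})
    mortality_hazard: dict = field(default_factory=lambda: {
        "Control": 0.0, "NaCl50": 0.0, "NaCl75": 0.0,
        "NaCl100": 0.01, "NaCl150": 0.07})
    noise_sd: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.a0_mean <= 0 or self.a0_min <= 0:
            raise ValueError("initial area must be positive")
        for t, f in self.treatment_effects.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"RGR factor for {t!r} outside [0, 1]")
        for t, hz in self.mortality_hazard.items():
            if not 0.0 <= hz <= 1.0:
                raise ValueError(f"hazard for {t!r} outside [0, 1]")

    def effective_rgr(self, treatment: str) -> float:
        return self.baseline_rgr * self.treatment_effects.get(treatment, 1.0)


def simulate_growth(model: GrowthModel, n_plants: int, treatment: str,
                    days: int, rng: np.random.Generator | None = None
                    ) -> list[GrowthSeries]:
    """Simulate ``n_plants`` area series observed daily on days 0..days-1.

    ``A(t) = A0 * exp(r_eff t) * exp(eps_t)`` with eps ~ N(0, noise_sd)
    per observation; each night the plant dies with the treatment's hazard
    probability, after which its area is zero for all later days (death is
    absorbing).  Deterministic given the model seed.
    """
    if days < 1 or n_plants < 1:
        raise ValueError("need days >= 1 and n_plants >= 1")
    if rng is None:
        rng = np.random.default_rng(model.rng_seed)
    r_eff = model.effective_rgr(treatment)
    hz = model.mortality_hazard.get(treatment, 0.0)
    t = np.arange(days, dtype=float)
    out = []
    for i in range(n_plants):
        a0 = max(model.a0_min, rng.normal(model.a0_mean, model.a0_sd))
        noise = (np.exp(rng.normal(0, model.noise_sd, size=days))
                 if model.noise_sd > 0 else np.ones(days))
        areas = a0 * np.exp(r_eff * t) * noise
        if hz > 0:
            deaths = rng.random(days - 1) < hz  # one hazard draw per night
            if deaths.any():
                d = int(np.argmax(deaths)) + 1
                areas[d:] = 0.0
        out.append(GrowthSeries(plant_id=f"{treatment}_{i + 1}",
                                treatment=treatment, times=t, areas=areas))
    return out


def generate_experiment(design: ExperimentDesign, model: GrowthModel,
                        imaging_times: list[float], outdir,
                        image_size: tuple[int, int] = FULL_RESOLUTION,
                        start: datetime | None = None,
                        seed: int | None = None,
                        distortion: bool = True,
                        noise_sd: float = 3.0) -> pd.DataFrame:
    """Render one image per plate per imaging time plus a ground-truth table.

    ``imaging_times`` are day offsets from the experiment start.  Each plate
    keeps a fixed camera pose across time-points (plates do not move on the
    table); areas simulated at the platform's native resolution are rescaled
    to the rendering resolution so the generated ground truth matches what
    the pipeline should measure.  Returns the ground-truth DataFrame, also
    written to ``outdir/ground_truth.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if start is None:
        start = datetime(2017, 6, 15, 12, 0, 0)
    rng = np.random.default_rng(model.rng_seed if seed is None else seed)
    layout = design.layout
    ppm_full = nominal_px_per_mm(FULL_RESOLUTION, layout)
    ppm_here = nominal_px_per_mm(image_size, layout)
    area_scale = (ppm_here / ppm_full) ** 2
    days = int(math.floor(max(imaging_times))) + 1
    rows = []
    for pid, (treatment, pos) in sorted(design.plate_assignments.items()):
        series = simulate_growth(model, layout.wells_per_plate, treatment,
                                 days, rng=rng)
        pose = make_transform(rng, image_size)
        h, w = image_size
        r_max2 = ((w - 1) / 2) ** 2 + ((h - 1) / 2) ** 2
        k = float(rng.uniform(0, 0.03) / r_max2) if distortion else 0.0
        for day in imaging_times:
            t_acq = start + timedelta(days=day)
            areas = [int(round(np.interp(day, s.times, s.areas) * area_scale))
                     for s in series]
            truth = GroundTruthPlate(
                layout=layout, areas=areas,
                rng_seed=int(rng.integers(2**31)),
                image_size=image_size, transform_params=pose,
                distortion_k=k, noise_sd=noise_sd)
            name = format_filename(t_acq, pos)
            iio.imwrite(outdir / name, render_plate(truth))
            rows.append(dict(filename=name, plate_id=pid, treatment=treatment,
                             day=day, x=pos[0], y=pos[1],
                             **{f"area_{i + 1}": a for i, a in enumerate(areas)}))
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "ground_truth.csv", index=False)
    return table
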