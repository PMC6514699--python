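"""Synthetic scene rendering with exact ground truth.

Replaces the physical clamp device and phone camera: scenes contain a
light calibration plate bearing a black rectangular frame (outer size
``plate_width_mm x plate_height_mm``), 1-mm tick marks just inside the
frame's upper and left borders, and a dark silhouette (test shape or leaf
template) centred in the frame interior.

The camera is a planar pinhole model parameterised by distance (scale)
and a single tilt angle about the plate's horizontal centreline — the
geometry of the distance/angle bench tests.  The induced plate-to-image
homography is exact and returned as ground truth.  Rendering evaluates
the scene analytically at a supersampled grid (default 4x) and
block-averages down, giving sub-pixel edge fidelity without a mesh.

Silhouettes are star-convex radial curves or exact polygons, so the true
area/perimeter attached to each scene is analytic (regular shapes) or
computed from a dense (>= 2^14-vertex) polygonal approximation (leaf
templates).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig, PlateConfig
from .errors import InvalidSpecError, LeafGeomError

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "Silhouette",
    "make_silhouette",
    "render",
    "render_regions",
    "config_for_scene",
    "run_experiment",
    "summarize_experiment",
]

# scene colours (RGB): chosen so plate/background both binarise to
# background while frame, ticks and silhouette binarise to foreground
BACKGROUND = np.array([205.0, 208.0, 212.0])
PLATE = np.array([235.0, 233.0, 228.0])
INK = np.array([28.0, 26.0, 25.0])
SHAPE = np.array([40.0, 40.0, 42.0])
LEAF = np.array([35.0, 60.0, 30.0])
SHADOW_ALPHA = 0.65  # ink fraction in the leaf-edge shadow band

_DENSE_N = 2 ** 14


@dataclass
class SceneSpec:
    """Full description of one synthetic scene.

    Camera distance emulates the 230-260 mm bench sweep; tilt the 0-45
    degree angle sweep.  ``image_width_px`` emulates phone resolution
    (default 1600 for desk-scale speed; the tick-dilation kernel in the
    measurement module rescales accordingly).
    """

    # plate geometry (frame outer dimensions)
    plate_width_mm: float = 160.0
    plate_height_mm: float = 120.0
    frame_thickness_mm: float = 3.0
    tick_spacing_mm: float = 1.0
    tick_len_mm: float = 2.5
    tick_width_mm: float = 0.3
    tick_gap_mm: float = 0.4  # gap between frame inner edge and tick start
    margin_mm: float = 12.0  # plate material beyond the frame

    # measured object
    shape: str = "square"  # square | rectangle | circle | triangle | leaf
    side_mm: float = 50.0  # square
    length_mm: float = 60.0  # rectangle
    width_mm: float = 40.0  # rectangle
    diameter_mm: float = 60.0  # circle
    base_mm: float = 60.0  # triangle (isosceles)
    height_mm: float = 60.0  # triangle
    leaf_template: str = "oval"  # heart | oval | serrated | slender
    leaf_area_cm2: float = 25.0
    serration_amp: float = 0.04

    # camera
    camera_distance_mm: float = 240.0
    tilt_deg: float = 0.0
    image_width_px: int = 1600
    supersample: int = 4

    # degradations
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0
    edge_shadow_px: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "plate_width_mm plate_height_mm frame_thickness_mm tick_spacing_mm "
            "tick_len_mm tick_width_mm margin_mm side_mm length_mm width_mm "
            "diameter_mm base_mm height_mm leaf_area_cm2 camera_distance_mm"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0")
        if not (0 <= self.tilt_deg < 60):
            raise InvalidSpecError(f"tilt_deg must be in [0, 60), got {self.tilt_deg}")
        if self.shape not in ("square", "rectangle", "circle", "triangle", "leaf"):
            raise InvalidSpecError(f"unknown shape {self.shape!r}")
        if self.leaf_template not in ("heart", "oval", "serrated", "slender"):
            raise InvalidSpecError(f"unknown leaf template {self.leaf_template!r}")
        if self.image_width_px < 64 or self.supersample < 1:
            raise InvalidSpecError("image_width_px >= 64 and supersample >= 1 required")

    @property
    def image_height_px(self) -> int:
        return int(round(self.image_width_px * 3 / 4))

    @property
    def inner_clearance_mm(self) -> float:
        """Margin the silhouette must keep from the frame inner edge so it
        never coincides with the tick marks."""
        return self.tick_gap_mm + self.tick_len_mm + 2.0


@dataclass(frozen=True)
class GroundTruth:
    """Exact scene parameters the measurement pipeline tries to recover."""

    true_length_mm: float
    true_width_mm: float
    true_area_cm2: float
    true_perimeter_cm: float
    true_corner_px: np.ndarray  # (4, 2) frame outer corners TL,TR,BR,BL
    applied_homography: np.ndarray  # 3x3 plate-mm -> image-px

    def to_dict(self) -> dict:
        return {
            "true_length_mm": self.true_length_mm,
            "true_width_mm": self.true_width_mm,
            "true_area_cm2": self.true_area_cm2,
            "true_perimeter_cm": self.true_perimeter_cm,
            "true_corner_px": np.asarray(self.true_corner_px).tolist(),
            "applied_homography": np.asarray(self.applied_homography).tolist(),
        }


@dataclass
class Silhouette:
    """A silhouette in plate-mm coordinates with analytic membership test."""

    polygon: np.ndarray  # (N, 2) dense closed boundary, mm
    inside: Callable[[np.ndarray, np.ndarray, float], np.ndarray]  # (x, y, grow_mm)
    true_length_mm: float
    true_width_mm: float
    true_area_mm2: float
    true_perimeter_mm: float


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _polygon_perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _radial_template(spec: SceneSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Unit-scale star-convex radius function r(phi) for a leaf template."""
    t = spec.leaf_template
    rng = np.random.default_rng(spec.seed)
    if t == "heart":
        # cardioid pointing along +x (leaf tip right, cusp left)
        return lambda phi: 0.5 * (1.0 + np.cos(phi)) + 0.12
    if t == "oval":
        k = 1.4
        return lambda phi: 1.0 / np.sqrt((np.cos(phi) / k) ** 2 + np.sin(phi) ** 2)
    if t == "slender":
        k = 7.0
        return lambda phi: 1.0 / np.sqrt((np.cos(phi) / k) ** 2 + np.sin(phi) ** 2)
    # serrated: lobed oval with sawtooth edge; seeded low-order lobes
    k = 1.25
    n_teeth = 36
    coeffs = rng.uniform(0.0, 0.03, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    amp = spec.serration_amp

    def r(phi: np.ndarray) -> np.ndarray:
        base = 1.0 / np.sqrt((np.cos(phi) / k) ** 2 + np.sin(phi) ** 2)
        lobes = sum(c * np.cos((j + 2) * phi + p) for j, (c, p) in enumerate(zip(coeffs, phases)))
        teeth = amp * (0.5 + 0.5 * np.cos(n_teeth * phi))
        return base * (1.0 + lobes + teeth)

    return r


def make_silhouette(spec: SceneSpec) -> Silhouette:
    """Construct the measured object's silhouette, centred in the frame.

    Regular shapes carry analytic truth; leaf templates attach truth from
    a dense (2^14-vertex) polygonal boundary.  Raises
    :class:`InvalidSpecError` if the shape cannot fit inside the frame
    interior with clearance from the tick marks.
    """
    cx, cy = spec.plate_width_mm / 2.0, spec.plate_height_mm / 2.0
    if spec.shape == "square":
        a = spec.side_mm / 2.0
        half = (a, a)

        def inside(x, y, grow=0.0):
            return (np.abs(x - cx) <= a + grow) & (np.abs(y - cy) <= a + grow)

        poly = np.array([[cx - a, cy - a], [cx + a, cy - a], [cx + a, cy + a], [cx - a, cy + a]])
        truth = (2 * a, 2 * a, 4 * a * a, 8 * a)
    elif spec.shape == "rectangle":
        a, b = spec.length_mm / 2.0, spec.width_mm / 2.0
        half = (a, b)

        def inside(x, y, grow=0.0):
            return (np.abs(x - cx) <= a + grow) & (np.abs(y - cy) <= b + grow)

        poly = np.array([[cx - a, cy - b], [cx + a, cy - b], [cx + a, cy + b], [cx - a, cy + b]])
        truth = (2 * a, 2 * b, 4 * a * b, 4 * (a + b))
    elif spec.shape == "circle":
        r = spec.diameter_mm / 2.0
        half = (r, r)

        def inside(x, y, grow=0.0):
            return (x - cx) ** 2 + (y - cy) ** 2 <= (r + grow) ** 2

        phi = np.linspace(0, 2 * np.pi, _DENSE_N, endpoint=False)
        poly = np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])
        truth = (2 * r, 2 * r, np.pi * r * r, 2 * np.pi * r)
    elif spec.shape == "triangle":
        # isosceles: base parallel to x at the bottom, apex above
        b2, h = spec.base_mm / 2.0, spec.height_mm
        half = (b2, h / 2.0)
        yb, yt = cy + h / 2.0, cy - h / 2.0  # base at bottom (y down)
        slant = np.hypot(b2, h)

        def inside(x, y, grow=0.0):
            dx = np.abs(x - cx)
            # half-planes offset outward by grow (corner rounding ignored)
            below_base = y <= yb + grow
            # edge from apex (cx, yt) to (cx±b2, yb): normal distance
            nx, ny = h, b2  # unnormalised normal of the right edge
            norm = np.hypot(nx, ny)
            inside_slant = (nx * dx + ny * (y - yt)) / norm <= (b2 * h) / norm + grow
            return below_base & inside_slant & (y >= yt - grow)

        poly = np.array([[cx, yt], [cx + b2, yb], [cx - b2, yb]])
        truth = (2 * b2, h, b2 * h, 2 * b2 + 2 * slant)
    else:  # leaf template
        r_fn = _radial_template(spec)
        phi = np.linspace(0, 2 * np.pi, _DENSE_N, endpoint=False)
        r_unit = r_fn(phi)
        unit = np.column_stack([r_unit * np.cos(phi), r_unit * np.sin(phi)])
        scale = np.sqrt(spec.leaf_area_cm2 * 100.0 / _polygon_area(unit))
        scaled = unit * scale
        bbox_min, bbox_max = scaled.min(axis=0), scaled.max(axis=0)
        centre_off = (bbox_min + bbox_max) / 2.0
        shift = np.array([cx, cy]) - centre_off
        poly = scaled + shift

        def inside(x, y, grow=0.0, _shift=shift, _scale=scale, _r=r_fn):
            px = np.asarray(x) - _shift[0]
            py = np.asarray(y) - _shift[1]
            rho = np.hypot(px, py)
            ang = np.arctan2(py, px)
            return rho <= _scale * _r(ang) + grow

        ext = bbox_max - bbox_min
        half = (ext[0] / 2.0, ext[1] / 2.0)
        truth = (ext[0], ext[1], _polygon_area(poly), _polygon_perimeter(poly))

    # fit check: silhouette must stay clear of frame border and ticks
    clear = spec.frame_thickness_mm + spec.inner_clearance_mm
    if (half[0] > spec.plate_width_mm / 2.0 - clear) or (half[1] > spec.plate_height_mm / 2.0 - clear):
        raise InvalidSpecError(
            f"shape extent {2 * half[0]:.1f} x {2 * half[1]:.1f} mm does not fit the "
            f"frame interior with {clear:.1f} mm clearance"
        )
    L, W, A, P = truth
    return Silhouette(
        polygon=poly,
        inside=inside,
        true_length_mm=float(L),
        true_width_mm=float(W),
        true_area_mm2=float(A),
        true_perimeter_mm=float(P),
    )


# ---------------------------------------------------------------------------
# camera and rasterisation
# ---------------------------------------------------------------------------

def camera_homography(spec: SceneSpec) -> np.ndarray:
    """Plate-mm -> image-px homography for the spec's distance and tilt.

    Pinhole camera with fixed focal length (set so the plate fills the
    frame at the closest bench distance), tilted by ``tilt_deg`` about the
    plate's horizontal centreline; the lower plate half is nearer the
    camera.  Normalised so ``M[2, 2] == 1``.
    """
    W, Hh = spec.plate_width_mm, spec.plate_height_mm
    scene_w = W + 2 * spec.margin_mm
    f = 0.72 * spec.image_width_px * 230.0 / scene_w
    cx, cy = W / 2.0, Hh / 2.0
    th = np.deg2rad(spec.tilt_deg)
    d = spec.camera_distance_mm
    P = np.array(
        [
            [f, 0.0, -f * cx],
            [0.0, f * np.cos(th), -f * np.cos(th) * cy],
            [0.0, -np.sin(th), d + cy * np.sin(th)],
        ]
    )
    u0, v0 = spec.image_width_px / 2.0, spec.image_height_px / 2.0
    P[0] += u0 * P[2]
    P[1] += v0 * P[2]
    return P / P[2, 2]


def _paint(
    X: np.ndarray, Y: np.ndarray, spec: SceneSpec, sil: Silhouette, shadow_mm: float
) -> np.ndarray:
    """Evaluate scene colour at plate-mm points; returns (..., 3) float."""
    W, Hh, t = spec.plate_width_mm, spec.plate_height_mm, spec.frame_thickness_mm
    m = spec.margin_mm
    out = np.empty(X.shape + (3,), dtype=np.float32)
    out[:] = BACKGROUND
    on_plate = (X >= -m) & (X <= W + m) & (Y >= -m) & (Y <= Hh + m)
    out[on_plate] = PLATE
    in_outer = (X >= 0) & (X <= W) & (Y >= 0) & (Y <= Hh)
    in_inner = (X >= t) & (X <= W - t) & (Y >= t) & (Y <= Hh - t)
    out[in_outer & ~in_inner] = INK
    # tick marks: 1-mm graduations just inside the upper and left borders
    sp, tw = spec.tick_spacing_mm, spec.tick_width_mm
    band_top = in_inner & (Y >= t + spec.tick_gap_mm) & (Y <= t + spec.tick_gap_mm + spec.tick_len_mm)
    fx = (X - t) % sp
    on_tick_x = (fx <= tw / 2) | (fx >= sp - tw / 2)
    out[band_top & on_tick_x & (X >= t - tw) & (X <= W - t + tw)] = INK
    band_left = in_inner & (X >= t + spec.tick_gap_mm) & (X <= t + spec.tick_gap_mm + spec.tick_len_mm)
    fy = (Y - t) % sp
    on_tick_y = (fy <= tw / 2) | (fy >= sp - tw / 2)
    out[band_left & on_tick_y & (Y >= t - tw) & (Y <= Hh - t + tw)] = INK
    # silhouette with optional edge shadow
    colour = LEAF if spec.shape == "leaf" else SHAPE
    in_leaf = sil.inside(X, Y, 0.0)
    if shadow_mm > 0:
        in_shadow = sil.inside(X, Y, shadow_mm) & ~in_leaf
        out[in_shadow] = SHADOW_ALPHA * INK + (1 - SHADOW_ALPHA) * PLATE
    out[in_leaf] = colour
    return out


def render(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene to an RGB uint8 image with exact ground truth.

    The scene is evaluated analytically at ``supersample``x resolution via
    the inverse camera homography and block-averaged, then optionally
    blurred (camera blur grows below 235 mm distance, emulating close-up
    defocus), noised and shadowed.  Deterministic under ``spec.seed``.
    """
    sil = make_silhouette(spec)
    M = camera_homography(spec)
    Minv = np.linalg.inv(M)
    s = spec.supersample
    Wpx, Hpx = spec.image_width_px, spec.image_height_px
    # local mm per px at plate centre, for shadow width conversion
    mm_per_px = spec.camera_distance_mm * (spec.plate_width_mm + 2 * spec.margin_mm) / (
        0.72 * 230.0 * spec.image_width_px
    )
    shadow_mm = spec.edge_shadow_px * mm_per_px if spec.edge_shadow_px > 0 else 0.0

    img = np.empty((Hpx, Wpx, 3), dtype=np.float32)
    xs = (np.arange(Wpx * s) + 0.5) / s - 0.5
    block = max(1, 256 // s)  # output rows per block
    for y0 in range(0, Hpx, block):
        y1 = min(Hpx, y0 + block)
        ys = (np.arange(y0 * s, y1 * s) + 0.5) / s - 0.5
        U, V = np.meshgrid(xs, ys)
        den = Minv[2, 0] * U + Minv[2, 1] * V + Minv[2, 2]
        X = (Minv[0, 0] * U + Minv[0, 1] * V + Minv[0, 2]) / den
        Y = (Minv[1, 0] * U + Minv[1, 1] * V + Minv[1, 2]) / den
        colours = _paint(X, Y, spec, sil, shadow_mm)
        h = y1 - y0
        img[y0:y1] = colours.reshape(h, s, Wpx, s, 3).mean(axis=(1, 3))

    d = spec.camera_distance_mm
    extra_blur = 0.8 if d < 232.5 else (0.5 if d < 235.0 else 0.0)
    total_blur = float(np.hypot(spec.blur_sigma_px, extra_blur))
    if total_blur > 0:
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], total_blur, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    corners_mm = np.array(
        [
            [0.0, 0.0],
            [spec.plate_width_mm, 0.0],
            [spec.plate_width_mm, spec.plate_height_mm],
            [0.0, spec.plate_height_mm],
        ]
    )
    hom = np.column_stack([corners_mm, np.ones(4)]) @ M.T
    corners_px = hom[:, :2] / hom[:, 2:3]
    truth = GroundTruth(
        true_length_mm=sil.true_length_mm,
        true_width_mm=sil.true_width_mm,
        true_area_cm2=sil.true_area_mm2 / 100.0,
        true_perimeter_cm=sil.true_perimeter_mm / 10.0,
        true_corner_px=corners_px,
        applied_homography=M,
    )
    return image, truth


def render_regions(spec: SceneSpec) -> np.ndarray:
    """Region-id map sampled at pixel centres (no antialiasing).

    Ids: 0 background, 1 plate, 2 frame, 3 tick, 4 silhouette.  Useful for
    pixel-exact comparisons against the preprocessing mask on noiseless,
    unsupersampled renders.
    """
    sil = make_silhouette(spec)
    Minv = np.linalg.inv(camera_homography(spec))
    U, V = np.meshgrid(
        np.arange(spec.image_width_px, dtype=float), np.arange(spec.image_height_px, dtype=float)
    )
    den = Minv[2, 0] * U + Minv[2, 1] * V + Minv[2, 2]
    X = (Minv[0, 0] * U + Minv[0, 1] * V + Minv[0, 2]) / den
    Y = (Minv[1, 0] * U + Minv[1, 1] * V + Minv[1, 2]) / den
    W, Hh, t, m = spec.plate_width_mm, spec.plate_height_mm, spec.frame_thickness_mm, spec.margin_mm
    ids = np.zeros(X.shape, np.uint8)
    ids[(X >= -m) & (X <= W + m) & (Y >= -m) & (Y <= Hh + m)] = 1
    in_outer = (X >= 0) & (X <= W) & (Y >= 0) & (Y <= Hh)
    in_inner = (X >= t) & (X <= W - t) & (Y >= t) & (Y <= Hh - t)
    ids[in_outer & ~in_inner] = 2
    sp, tw = spec.tick_spacing_mm, spec.tick_width_mm
    fx, fy = (X - t) % sp, (Y - t) % sp
    band_top = in_inner & (Y >= t + spec.tick_gap_mm) & (Y <= t + spec.tick_gap_mm + spec.tick_len_mm)
    ids[band_top & ((fx <= tw / 2) | (fx >= sp - tw / 2)) & (X >= t - tw) & (X <= W - t + tw)] = 3
    band_left = in_inner & (X >= t + spec.tick_gap_mm) & (X <= t + spec.tick_gap_mm + spec.tick_len_mm)
    ids[band_left & ((fy <= tw / 2) | (fy >= sp - tw / 2)) & (Y >= t - tw) & (Y <= Hh - t + tw)] = 3
    ids[sil.inside(X, Y, 0.0)] = 4
    return ids


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

def config_for_scene(spec: SceneSpec, px_per_mm: float = 10.0) -> PipelineConfig:
    """Pipeline configuration consistent with a scene's plate geometry."""
    return PipelineConfig(
        plate=PlateConfig(
            width_mm=spec.plate_width_mm,
            height_mm=spec.plate_height_mm,
            thickness_mm=spec.frame_thickness_mm,
            tick_spacing_mm=spec.tick_spacing_mm,
            px_per_mm=px_per_mm,
        )
    )


def _subseed(base: int, *parts: int) -> int:
    ss = np.random.SeedSequence([int(base)] + [int(p) for p in parts])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_experiment(
    specs: list[SceneSpec],
    repeats: int = 1,
    base_seed: int = 0,
    px_per_mm: float = 10.0,
) -> pd.DataFrame:
    """Render and measure a grid of scenes; return per-run relative errors.

    Each spec is rendered ``repeats`` times with distinct sub-seeds
    (repeat-to-repeat variation comes from the noise realisation).
    Failures are recorded per row (column ``error``) without aborting the
    grid.  Relative errors are fractions (0.01 == 1%).
    """
    from . import measurement  # deferred: avoid import cycle

    rows = []
    for i, spec in enumerate(specs):
        for r in range(repeats):
            sp = dataclasses.replace(spec, seed=_subseed(base_seed, spec.seed, i, r))
            row: dict = {
                "scene": i,
                "repeat": r,
                "shape": sp.shape if sp.shape != "leaf" else f"leaf:{sp.leaf_template}",
                "tilt_deg": sp.tilt_deg,
                "distance_mm": sp.camera_distance_mm,
                "seed": sp.seed,
            }
            try:
                image, truth = render(sp)
                m = measurement.measure(image, config_for_scene(sp, px_per_mm))
                row.update(
                    measured_area_cm2=m.area_cm2,
                    measured_perimeter_cm=m.perimeter_cm,
                    measured_length_mm=m.length_mm,
                    measured_width_mm=m.width_mm,
                    true_area_cm2=truth.true_area_cm2,
                    true_perimeter_cm=truth.true_perimeter_cm,
                    true_length_mm=truth.true_length_mm,
                    true_width_mm=truth.true_width_mm,
                    rel_err_area=(m.area_cm2 - truth.true_area_cm2) / truth.true_area_cm2,
                    rel_err_perimeter=(m.perimeter_cm - truth.true_perimeter_cm) / truth.true_perimeter_cm,
                    rel_err_length=(m.length_mm - truth.true_length_mm) / truth.true_length_mm,
                    rel_err_width=(m.width_mm - truth.true_width_mm) / truth.true_width_mm,
                    corner_reproj_px=m.diagnostics["corner_reproj_px"],
                    error="",
                )
            except LeafGeomError as e:
                row.update(error=str(e))
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_experiment(df: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Mean and min/max range of relative errors, grouped by scene factors."""
    by = by or ["shape"]
    ok = df[df["error"] == ""] if "error" in df else df
    cols = [c for c in ok.columns if c.startswith("rel_err_")]
    return ok.groupby(by)[cols].agg(["mean", "min", "max"])
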