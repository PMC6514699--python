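"""Leaf measurement via the positive circumscribed rectangle.

The method uses the leaf's own axis-aligned bounding rectangle (its
"positive circumscribed rectangle") as a dynamic reference object: the
rectangle's physical size is read off the millimetre tick marks engraved
on the plate frame, and the leaf's area and perimeter follow from pixel
ratios between leaf and rectangle:

    Height = Ymax - Ymin          Length = Xmax - Xmin
    S = Sr * Pt / Prt             Sr = Lr * Wr
    C = Cr * Pc / Pct             Cr = 2 (Lr + Wr)

where Pt / Prt count interior pixels of leaf and rectangle, and Pc / Pct
measure their boundaries in pixel units.  Because leaf and reference share
the image, per-pixel physical weight cancels; a rectangular object is its
own reference and is measured essentially exactly.

Boundary measure: Pc is the length of the leaf's sub-pixel outer contour
after Douglas-Peucker simplification (tolerance 1.2 px), which removes the
rasterisation staircase and is accurate to ~0.1% for both straight and
smoothly curved boundaries; a raw border-pixel count would understate
curved boundaries by ~10% relative to the axis-aligned rectangle.  The raw
8-connected border-pixel count is still exposed on :class:`Contour`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from . import calibration, imgproc
from .calibration import HomographyParams, PlateQuad, VirtualPlate
from .config import PipelineConfig, TickConfig
from .errors import (
    InvalidInputError,
    InvalidStatsError,
    LeafGeomError,
    OutOfRangeError,
    ScaleUnreadableError,
    SceneInvalidError,
    tag_stage,
)

log = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "AxisRect",
    "TickScale",
    "ContourStats",
    "LeafMeasurement",
    "extract_leaf_and_frame",
    "bounding_rect",
    "read_tick_scale",
    "length_width_from_ticks",
    "pixel_counts",
    "area_perimeter",
    "measure",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], int)
_EIGHT = np.ones((3, 3), int)

#: Douglas-Peucker tolerance (px) for the sub-pixel boundary-length measure
BOUNDARY_DP_TOL = 1.2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """A connected region's outer boundary and pixel counts.

    ``filled`` is the hole-filled region mask (wormholes and lesions
    removed, so interior counts reflect the outermost contour only).
    """

    points: np.ndarray  # (N, 2) sub-pixel x, y along the outer boundary
    filled: np.ndarray  # hole-filled boolean mask, full image size
    component: np.ndarray  # raw component pixels (no hole filling)
    pixel_count_interior: int
    pixel_count_boundary: int  # raw 8-connected border pixel count

    @property
    def boundary_length_px(self) -> float:
        """Sub-pixel boundary length (staircase-free), in pixel units."""
        pts = self.points[:, ::-1]  # rows, cols for approximate_polygon
        simplified = skmeasure.approximate_polygon(pts, tolerance=BOUNDARY_DP_TOL)
        d = np.diff(simplified, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class AxisRect:
    """Positive circumscribed rectangle: extreme pixel coordinates.

    Corner A is ``(x_min, y_min)``, corner B is ``(x_max, y_max)``.  The
    pixel extents ``length_px``/``height_px`` are ``max - min``; interior
    pixel counts use ``max - min + 1`` (pixel-area semantics).
    """

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise InvalidInputError("AxisRect requires x_max >= x_min and y_max >= y_min")

    @property
    def length_px(self) -> int:
        return self.x_max - self.x_min

    @property
    def height_px(self) -> int:
        return self.y_max - self.y_min


@dataclass
class TickScale:
    """Recovered ruler geometry: tick positions and derived pixel scales."""

    top_tick_xs: np.ndarray  # sorted x positions (px) of upper-border ticks
    left_tick_ys: np.ndarray  # sorted y positions (px) of left-border ticks
    mm_per_tick: float = 1.0
    # whether the raw recovery had no dropouts; a complete ruler that does
    # not cover a requested span is a hard error, an incomplete one falls
    # back to pixel-scale conversion for the uncovered part
    top_complete: bool = True
    left_complete: bool = True
    px_per_mm_x: float = field(init=False)
    px_per_mm_y: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("top_tick_xs", "left_tick_ys"):
            arr = np.sort(np.asarray(getattr(self, name), dtype=np.float64))
            setattr(self, name, arr)
            if len(arr) < 3:
                raise ScaleUnreadableError(f"{name}: need >= 3 ticks, got {len(arr)}")
        self.px_per_mm_x = _spacing(self.top_tick_xs, "top") / self.mm_per_tick
        self.px_per_mm_y = _spacing(self.left_tick_ys, "left") / self.mm_per_tick


def _spacing(positions: np.ndarray, which: str) -> float:
    diffs = np.diff(positions)
    med = float(np.median(diffs))
    if med <= 0:
        raise ScaleUnreadableError(f"{which} ticks are not strictly increasing")
    ok = diffs[diffs < 1.5 * med]  # gaps from missed ticks excluded
    consistent = np.abs(ok - np.median(ok)) <= 0.2 * np.median(ok)
    # the ruler is trusted when the clear majority of adjacent spacings
    # agree; isolated centroid wobbles (merged fragments) are tolerated
    if consistent.mean() < 0.8:
        raise ScaleUnreadableError(f"{which} tick spacing inconsistent beyond 20%")
    return float(np.median(ok[consistent]))


@dataclass(frozen=True)
class ContourStats:
    """Pixel statistics feeding the area and perimeter ratios.

    Pt/Prt are interior pixel counts of leaf and rectangle; Pc/Pct are
    boundary measures in pixel units (see module docstring).
    """

    Pt: int
    Pc: float
    Prt: int
    Pct: float

    def __post_init__(self) -> None:
        if min(self.Pt, self.Pc, self.Prt, self.Pct) <= 0:
            raise InvalidStatsError("all pixel counts must be positive")
        if self.Prt < self.Pt:
            raise InvalidStatsError("rectangle interior cannot be smaller than leaf interior")


@dataclass
class LeafMeasurement:
    """Complete measurement result with the pixel counts that produced it."""

    length_mm: float  # Lr: x-extent of the circumscribed rectangle
    width_mm: float  # Wr: y-extent
    area_cm2: float  # S
    perimeter_cm: float  # C
    rect_area_cm2: float  # Sr
    rect_perimeter_cm: float  # Cr
    stats: ContourStats
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "length_mm": self.length_mm,
            "width_mm": self.width_mm,
            "area_cm2": self.area_cm2,
            "perimeter_cm": self.perimeter_cm,
            "rect_area_cm2": self.rect_area_cm2,
            "rect_perimeter_cm": self.rect_perimeter_cm,
            "Pt": self.stats.Pt,
            "Pc": self.stats.Pc,
            "Prt": self.stats.Prt,
            "Pct": self.stats.Pct,
            "diagnostics": dict(self.diagnostics),
        }


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

def _component_contour(labels: np.ndarray, idx: int, slc: tuple[slice, slice]) -> Contour:
    comp = labels[slc] == idx
    filled_local = ndimage.binary_fill_holes(comp)
    contours = skmeasure.find_contours(np.pad(filled_local, 1).astype(float), 0.5)
    pts = max(contours, key=len) - 1.0  # rows, cols in local frame
    offset = np.array([slc[0].start, slc[1].start], float)
    pts = (pts + offset)[:, ::-1]  # -> global x, y
    border = filled_local & ~ndimage.binary_erosion(filled_local, _CROSS)
    filled = np.zeros(labels.shape, bool)
    filled[slc] = filled_local
    component = np.zeros(labels.shape, bool)
    component[slc] = comp
    return Contour(
        points=pts,
        filled=filled,
        component=component,
        pixel_count_interior=int(filled_local.sum()),
        pixel_count_boundary=int(border.sum()),
    )


def extract_leaf_and_frame(mask: np.ndarray) -> tuple[Contour, Contour]:
    """Keep the two dominant connected regions: the frame and the leaf.

    Components are ranked by *enclosed* (hole-filled) area so that the thin
    black frame, which encloses the whole plate interior, outranks even a
    large serrated leaf; tick marks and noise blobs rank far below.
    Returns ``(leaf, frame)``.
    """
    mask = np.asarray(mask) > 0
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n < 2:
        raise SceneInvalidError(f"expected >= 2 foreground components, found {n}")
    slices = ndimage.find_objects(labels)
    bbox_area = [(s[0].stop - s[0].start) * (s[1].stop - s[1].start) for s in slices]
    candidates = np.argsort(bbox_area)[::-1][: min(n, 8)]
    enclosed = []
    for i in candidates:
        slc = slices[i]
        enclosed.append(int(ndimage.binary_fill_holes(labels[slc] == i + 1).sum()))
    top2 = [candidates[j] for j in np.argsort(enclosed)[::-1][:2]]
    frame = _component_contour(labels, top2[0] + 1, slices[top2[0]])
    leaf = _component_contour(labels, top2[1] + 1, slices[top2[1]])
    # the leaf must lie strictly inside the frame's outer boundary
    fr, lr = bounding_rect(frame), bounding_rect(leaf)
    if not (fr.x_min < lr.x_min and lr.x_max < fr.x_max and fr.y_min < lr.y_min and lr.y_max < fr.y_max):
        raise SceneInvalidError("second-largest region does not lie inside the frame")
    return leaf, frame


def bounding_rect(contour: Contour) -> AxisRect:
    """Positive circumscribed rectangle of a contour (extreme pixel coords)."""
    if contour.filled is None or not contour.filled.any():
        raise InvalidInputError("empty contour has no bounding rectangle")
    ys, xs = np.nonzero(contour.filled)
    return AxisRect(int(xs.min()), int(xs.max()), int(ys.min()), int(ys.max()))


# ---------------------------------------------------------------------------
# tick-mark ruler reading
# ---------------------------------------------------------------------------

def _frame_thickness(component: np.ndarray, rect: AxisRect, axis: str) -> int:
    """Median run length of the frame band scanned inward from one border."""
    if axis == "top":
        cols = slice(rect.x_min + (rect.x_max - rect.x_min) // 4, rect.x_max - (rect.x_max - rect.x_min) // 4)
        band = component[rect.y_min : rect.y_min + max(2, (rect.y_max - rect.y_min) // 4), cols]
        runs = band.argmin(axis=0)  # first non-frame row per column
    else:
        rows = slice(rect.y_min + (rect.y_max - rect.y_min) // 4, rect.y_max - (rect.y_max - rect.y_min) // 4)
        band = component[rows, rect.x_min : rect.x_min + max(2, (rect.x_max - rect.x_min) // 4)]
        runs = band.argmin(axis=1)
    runs = runs[runs > 0]
    if len(runs) == 0:
        raise ScaleUnreadableError("cannot estimate frame border thickness")
    return int(np.median(runs))


def _tick_positions(
    band: np.ndarray, kernel_len: int, orient: str, origin: float, min_px: int
) -> np.ndarray:
    """Centroid positions of tick components in a border band.

    ``orient`` is the tick long axis: 'vertical' ticks (upper ruler) are
    dilated along y with a (k, 1) element, 'horizontal' ticks (left ruler)
    along x with (1, k), reconnecting fragments without merging neighbours.
    """
    if orient == "vertical":
        structure = np.ones((kernel_len, 1), int)
    else:
        structure = np.ones((1, kernel_len), int)
    dilated = ndimage.binary_dilation(band, structure=structure)
    labels, n = ndimage.label(dilated, structure=_EIGHT)
    if n == 0:
        return np.array([])
    positions = []
    band_h, band_w = band.shape
    for slc in ndimage.find_objects(labels):
        comp_h = slc[0].stop - slc[0].start
        comp_w = slc[1].stop - slc[1].start
        if orient == "vertical":
            # reject blobs wider than a few tick widths or spanning the band
            if comp_w > max(6, band_w // 8) or comp_h >= band_h:
                continue
            if comp_w * comp_h < min_px:
                continue
            positions.append(origin + (slc[1].start + slc[1].stop - 1) / 2.0)
        else:
            if comp_h > max(6, band_h // 8) or comp_w >= band_w:
                continue
            if comp_w * comp_h < min_px:
                continue
            positions.append(origin + (slc[0].start + slc[0].stop - 1) / 2.0)
    return np.sort(np.array(positions))


def _band_refine(
    band_mask: np.ndarray, band_gray: np.ndarray | None, orient: str
) -> np.ndarray:
    """Recover ticks too faint for the global threshold.

    At low capture resolution or strong foreshortening the ~0.3 mm tick
    lines antialias to shallow intensity dips that a global threshold
    misses although the ruler contrast is locally ample.  Pixels are added
    back per tick lane (per column for the upper ruler's vertical ticks,
    per row for the left ruler's horizontal ones) wherever the lane shows
    real contrast; the margin nearest the frame border is skipped because
    border blur smear would bridge adjacent ticks.
    """
    if band_gray is None or band_gray.size == 0:
        return band_mask
    g = np.asarray(band_gray, dtype=np.float64)
    axis = 0 if orient == "vertical" else 1  # stats along each tick lane
    trim = max(2, int(round(0.15 * g.shape[axis])))
    sl = (slice(trim, None), slice(None)) if axis == 0 else (slice(None), slice(trim, None))
    g = g[sl]
    light = np.percentile(g, 90, axis=axis, keepdims=True)
    dark = g.min(axis=axis, keepdims=True)
    contrast = light - dark
    thresh = np.where(contrast > 40, light - 0.45 * contrast, -np.inf)
    refined = g < thresh
    out = band_mask.copy()
    out[sl] |= refined
    return out


def _fit_tick_grid(positions: np.ndarray, which: str) -> np.ndarray:
    """Sub-tick refinement: snap noisy centroids to a fitted regular grid.

    The engraved ruler is strictly periodic, so the recovered centroids
    are modelled as ``phase + k * pitch``: pitch from the robust median
    spacing, phase from the circular mean of the centroid residuals
    modulo the pitch.  This averages per-tick centroid noise (blur,
    fragment merging) over the whole ruler and fills dropped ticks inside
    the covered range.
    """
    if len(positions) < 3:
        return positions
    pitch = _spacing(positions, which)
    ang = 2 * np.pi * (positions % pitch) / pitch
    phase = (pitch / (2 * np.pi)) * np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) % pitch
    k_min = int(np.ceil((positions[0] - pitch / 2 - phase) / pitch))
    k_max = int(np.floor((positions[-1] + pitch / 2 - phase) / pitch))
    return phase + pitch * np.arange(k_min, k_max + 1)


def read_tick_scale(
    mask: np.ndarray,
    frame: Contour,
    ticks: TickConfig | None = None,
    mm_per_tick: float = 1.0,
    gray: np.ndarray | None = None,
) -> TickScale:
    """Recover the millimetre ruler from the frame's upper and left borders.

    Tick marks sit just inside the frame; fragments broken by binarisation
    are reconnected by dilating along each ruler's tick direction (element
    length scaled from the reference 49 px at 3264 px image width).  If the
    greyscale image is supplied, faint ticks are recovered with a
    band-local threshold before dilation.
    """
    ticks = ticks or TickConfig()
    mask = np.asarray(mask) > 0
    rect = bounding_rect(frame)
    klen = ticks.kernel_len(mask.shape[1])
    t_top = _frame_thickness(frame.component, rect, "top")
    t_left = _frame_thickness(frame.component, rect, "left")
    # band just inside the upper border, clear of the frame's own pixels
    non_frame = mask & ~frame.component
    y0 = rect.y_min + t_top
    y1 = min(rect.y_max, y0 + max(3, int(2.2 * t_top)))
    x0 = rect.x_min + 2 * t_left
    x1 = rect.x_max - 2 * t_left
    top_band = _band_refine(
        non_frame[y0:y1, x0:x1], None if gray is None else gray[y0:y1, x0:x1], "vertical"
    )
    top_xs = _tick_positions(top_band, klen, "vertical", origin=float(x0), min_px=2)
    # left border band
    xx0 = rect.x_min + t_left
    xx1 = min(rect.x_max, xx0 + max(3, int(2.2 * t_left)))
    yy0 = rect.y_min + 2 * t_top
    yy1 = rect.y_max - 2 * t_top
    left_band = _band_refine(
        non_frame[yy0:yy1, xx0:xx1], None if gray is None else gray[yy0:yy1, xx0:xx1], "horizontal"
    )
    left_ys = _tick_positions(left_band, klen, "horizontal", origin=float(yy0), min_px=2)
    if len(top_xs) < ticks.min_ticks or len(left_ys) < ticks.min_ticks:
        raise ScaleUnreadableError(
            f"recovered only {len(top_xs)} top / {len(left_ys)} left ticks (need {ticks.min_ticks})"
        )
    def _complete(raw: np.ndarray) -> bool:
        d = np.diff(raw)
        return bool(np.max(d) < 1.5 * np.median(d))

    top_ok, left_ok = _complete(top_xs), _complete(left_ys)
    top_xs = _fit_tick_grid(top_xs, "top")
    left_ys = _fit_tick_grid(left_ys, "left")
    return TickScale(
        top_tick_xs=top_xs,
        left_tick_ys=left_ys,
        mm_per_tick=mm_per_tick,
        top_complete=top_ok,
        left_complete=left_ok,
    )


def _span_from_ticks(
    lo: float,
    hi: float,
    tick_pos: np.ndarray,
    px_per_mm: float,
    mm_per_tick: float,
    complete: bool = True,
) -> float:
    """Physical span of [lo, hi] read against one ruler.

    The ticks strictly inside the span contribute whole tick spacings
    (n - 1 of them for n ticks); the fractional end segments from each
    edge to its nearest inner tick are converted through the pixel scale.
    An edge within 0.5 px of a tick centre counts that tick with zero
    fraction.  The whole-spacing count is taken as the first-to-last inner
    tick distance snapped to the tick pitch, which equals (n - 1) on a
    complete ruler but stays correct when interior ticks are lost to
    blur or resampling.
    """
    spacing_px = px_per_mm * mm_per_tick
    # a complete ruler (no dropouts) that still fails to cover the span
    # means the object lies outside the ruled region; an incomplete ruler
    # instead falls back to pixel-scale conversion for the uncovered part,
    # which is exact in rectified (uniform-scale) coordinates
    if complete and (lo < tick_pos[0] - spacing_px or hi > tick_pos[-1] + spacing_px):
        raise OutOfRangeError("rectangle extends beyond the tick-covered span")
    tie = 0.5
    inner = tick_pos[(tick_pos >= lo - tie) & (tick_pos <= hi + tie)]
    if len(inner) == 0:
        return (hi - lo) / px_per_mm
    whole = round((inner[-1] - inner[0]) / (px_per_mm * mm_per_tick)) * mm_per_tick
    frac_lo = max(0.0, inner[0] - lo) / px_per_mm
    frac_hi = max(0.0, hi - inner[-1]) / px_per_mm
    if abs(inner[0] - lo) <= tie:
        frac_lo = 0.0
    if abs(hi - inner[-1]) <= tie:
        frac_hi = 0.0
    return whole + frac_lo + frac_hi


def length_width_from_ticks(rect: AxisRect, scale: TickScale) -> tuple[float, float]:
    """Physical length (x-extent) and width (y-extent) of the rectangle.

    The rectangle's side extensions are read against the upper ruler (for
    Lr) and the left ruler (for Wr).  Under pixel-area semantics the
    rectangle's physical sides lie half a pixel outside the extreme pixel
    centres, so the end-segment gaps are measured from ``min - 0.5`` and
    ``max + 0.5``; this keeps Lr/Wr consistent with the ``max - min + 1``
    interior counts.
    """
    Lr = _span_from_ticks(
        rect.x_min - 0.5,
        rect.x_max + 0.5,
        scale.top_tick_xs,
        scale.px_per_mm_x,
        scale.mm_per_tick,
        scale.top_complete,
    )
    Wr = _span_from_ticks(
        rect.y_min - 0.5,
        rect.y_max + 0.5,
        scale.left_tick_ys,
        scale.px_per_mm_y,
        scale.mm_per_tick,
        scale.left_complete,
    )
    return Lr, Wr


# ---------------------------------------------------------------------------
# pixel counts and physical parameters
# ---------------------------------------------------------------------------

def pixel_counts(leaf: Contour, rect: AxisRect) -> ContourStats:
    """Pixel statistics of the leaf and its circumscribed rectangle.

    Pt counts pixels enclosed by the leaf's outermost contour (interior
    holes filled); Prt is the rectangle's pixel area (max-min+1 semantics);
    Pct is the rectangle's border pixel count 2(dx+1) + 2(dy+1) - 4; Pc is
    the leaf's sub-pixel boundary length (see module docstring).
    """
    br = bounding_rect(leaf)
    if not (rect.x_min <= br.x_min and br.x_max <= rect.x_max and rect.y_min <= br.y_min and br.y_max <= rect.y_max):
        raise InvalidInputError("leaf contour does not lie inside the given rectangle")
    dx, dy = rect.length_px, rect.height_px
    return ContourStats(
        Pt=leaf.pixel_count_interior,
        Pc=leaf.boundary_length_px,
        Prt=(dx + 1) * (dy + 1),
        Pct=float(2 * (dx + 1) + 2 * (dy + 1) - 4),
    )


def area_perimeter(stats: ContourStats, Lr: float, Wr: float) -> tuple[float, float]:
    """Leaf area (cm^2) and perimeter (cm) from the pixel ratios.

    ``S = Sr * Pt / Prt`` with ``Sr = Lr * Wr``;
    ``C = Cr * Pc / Pct`` with ``Cr = 2 (Lr + Wr)``; Lr, Wr in mm.
    """
    if Lr <= 0 or Wr <= 0:
        raise InvalidStatsError("rectangle physical dimensions must be positive")
    if stats.Prt == 0 or stats.Pct == 0:
        raise InvalidStatsError("zero rectangle pixel counts")
    Sr_mm2 = Lr * Wr
    Cr_mm = 2.0 * (Lr + Wr)
    S_cm2 = Sr_mm2 * stats.Pt / stats.Prt / 100.0
    C_cm = Cr_mm * stats.Pc / stats.Pct / 10.0
    return S_cm2, C_cm


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def measure(image: np.ndarray, config: PipelineConfig | None = None) -> LeafMeasurement:
    """Run the complete pipeline on one scene image.

    preprocess -> plate corner detection -> homography rectification ->
    contour extraction -> tick-scale reading -> rectangle + pixel ratios.
    Raises stage-tagged errors on failure; diagnostics include the corner
    reprojection error and recovered tick counts.
    """
    config = config or PipelineConfig()
    image = np.asarray(image)
    try:
        gray = imgproc.to_grayscale(image, config.preprocess) if image.ndim == 3 else image
        smoothed = imgproc.smooth(gray, config.preprocess.gauss_sigma)
        mask = imgproc.binarize(smoothed, config.preprocess)
    except LeafGeomError as e:
        raise tag_stage(e, "preprocess")
    try:
        quad = calibration.detect_plate_quad(mask, config.detection)
    except LeafGeomError as e:
        raise tag_stage(e, "plate-detection")
    virtual = VirtualPlate(config.plate.width_mm, config.plate.height_mm, config.plate.px_per_mm)
    try:
        H = calibration.estimate_homography(quad, virtual)
        rect_gray = calibration.rectify(gray, H, virtual)
    except LeafGeomError as e:
        raise tag_stage(e, "calibration")
    reproj = float(np.max(np.linalg.norm(H.apply(quad.corners) - virtual.corners, axis=1)))
    try:
        rect_mask = imgproc.binarize(rect_gray, config.preprocess)
        leaf, frame = extract_leaf_and_frame(rect_mask)
    except LeafGeomError as e:
        raise tag_stage(e, "contour-extraction")
    try:
        scale = read_tick_scale(
            rect_mask, frame, config.ticks, config.plate.tick_spacing_mm, gray=rect_gray
        )
    except LeafGeomError as e:
        raise tag_stage(e, "tick-scale")
    try:
        rect = bounding_rect(leaf)
        Lr, Wr = length_width_from_ticks(rect, scale)
        stats = pixel_counts(leaf, rect)
        S, C = area_perimeter(stats, Lr, Wr)
    except LeafGeomError as e:
        raise tag_stage(e, "measurement")
    log.debug("measured Lr=%.2f mm Wr=%.2f mm S=%.2f cm2 C=%.2f cm", Lr, Wr, S, C)
    return LeafMeasurement(
        length_mm=Lr,
        width_mm=Wr,
        area_cm2=S,
        perimeter_cm=C,
        rect_area_cm2=Lr * Wr / 100.0,
        rect_perimeter_cm=2.0 * (Lr + Wr) / 10.0,
        stats=stats,
        diagnostics={
            "corner_reproj_px": reproj,
            "n_ticks_top": int(len(scale.top_tick_xs)),
            "n_ticks_left": int(len(scale.left_tick_ys)),
            "px_per_mm_x": scale.px_per_mm_x,
            "px_per_mm_y": scale.px_per_mm_y,
            "homography": H.to_dict(),
        },
    )
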