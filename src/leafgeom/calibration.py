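"""Plate detection and projective distortion correction.

The calibration plate carries a black rectangular frame.  Its four outer
corners, detected in the (possibly tilted) photograph, are matched to the
corners of a *virtual* frontal plate and the 8-parameter projective
transformation

    u = (A x + B y + C) / (G x + H y + 1)
    v = (D x + E y + F) / (G x + H y + 1)

is solved exactly from the four point pairs (8 equations, 8 unknowns).
Rectification inverse-maps every output pixel through the transform with
bilinear interpolation, so no output pixel is left unfilled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.transform import hough_line, hough_line_peaks

from .config import DetectionConfig
from .errors import PlateNotFoundError, SingularSystemError

__all__ = [
    "PlateQuad",
    "VirtualPlate",
    "HomographyParams",
    "detect_plate_quad",
    "estimate_homography",
    "rectify",
]


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class PlateQuad:
    """Four detected plate corners, ordered TL, TR, BR, BL (image pixels).

    Under the y-down image convention this ordering has positive signed
    area; the quadrilateral must be convex with distinct corners.
    """

    corners: np.ndarray  # (4, 2) float, columns x, y

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=np.float64).reshape(4, 2)
        object.__setattr__(self, "corners", c)
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        if np.any(d[np.triu_indices(4, 1)] < 1e-9):
            raise PlateNotFoundError("degenerate quad: duplicate corners")
        if _signed_area(c) <= 0:
            raise PlateNotFoundError("corner ordering is not TL,TR,BR,BL (signed area <= 0)")
        # convexity: all cross products of consecutive edges share one sign
        e = np.roll(c, -1, axis=0) - c
        cross = e[:, 0] * np.roll(e, -1, axis=0)[:, 1] - e[:, 1] * np.roll(e, -1, axis=0)[:, 0]
        if not (np.all(cross > 0) or np.all(cross < 0)):
            raise PlateNotFoundError("detected quadrilateral is not convex")


@dataclass(frozen=True)
class VirtualPlate:
    """The ideal frontal plate that rectification maps onto.

    The frame's outer corners map onto the corners of a rectified image of
    ``width_mm * px_per_mm`` by ``height_mm * px_per_mm`` pixels.
    """

    width_mm: float
    height_mm: float
    px_per_mm: float = 10.0

    def __post_init__(self) -> None:
        if min(self.width_mm, self.height_mm, self.px_per_mm) <= 0:
            raise SingularSystemError("VirtualPlate dimensions must be > 0")

    @property
    def shape_px(self) -> tuple[int, int]:
        """Rectified image shape as (height, width) in pixels."""
        return (int(round(self.height_mm * self.px_per_mm)), int(round(self.width_mm * self.px_per_mm)))

    @property
    def corners(self) -> np.ndarray:
        """Virtual calibration points TL, TR, BR, BL in rectified pixels."""
        h, w = self.shape_px
        return np.array([[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]])


@dataclass(frozen=True)
class HomographyParams:
    """Entries A-H of the projective transformation matrix (scale fixed at 1)."""

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float
    lam: float = field(default=1.0)

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.A, self.B, self.C], [self.D, self.E, self.F], [self.G, self.H, 1.0]]
        ) * self.lam

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "HomographyParams":
        M = np.asarray(M, dtype=np.float64)
        if abs(M[2, 2]) < 1e-15:
            raise SingularSystemError("matrix cannot be normalised: M[2,2] == 0")
        M = M / M[2, 2]
        p = cls(*(float(v) for v in M.ravel()[:8]))
        if abs(np.linalg.det(p.matrix)) <= 1e-12:
            raise SingularSystemError("transformation matrix is singular")
        return p

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise SingularSystemError("transformation matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) source points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        hom = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    def inverse(self) -> "HomographyParams":
        return HomographyParams.from_matrix(np.linalg.inv(self.matrix))

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in "ABCDEFGH"} | {"lambda": self.lam}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "HomographyParams":
        return cls(*(float(d[k]) for k in "ABCDEFGH"), lam=float(d.get("lambda", 1.0)))


# ---------------------------------------------------------------------------
# corner detection
# ---------------------------------------------------------------------------

def _largest_enclosed_component(mask: np.ndarray) -> np.ndarray:
    """Filled mask of the component with the largest *enclosed* area.

    Ranking by enclosed (hole-filled) area rather than raw pixel count is
    what lets the thin frame outrank a big solid leaf.
    """
    labels, n = ndimage.label(np.asarray(mask) > 0, structure=np.ones((3, 3), int))
    if n == 0:
        raise PlateNotFoundError("blank mask: no foreground components")
    slices = ndimage.find_objects(labels)
    # cheap pre-ranking by bounding-box area, then fill the top candidates
    order = np.argsort([-(s[0].stop - s[0].start) * (s[1].stop - s[1].start) for s in slices])
    best_area, best_filled, best_slc = -1, None, None
    for idx in order[:8]:
        slc = slices[idx]
        comp = labels[slc] == idx + 1
        filled = ndimage.binary_fill_holes(comp)
        area = int(filled.sum())
        if area > best_area:
            best_area, best_filled, best_slc = area, filled, slc
    out = np.zeros(mask.shape, bool)
    out[best_slc] = best_filled
    return out


def _outer_contour(filled: np.ndarray) -> np.ndarray:
    """Longest sub-pixel contour of a filled component, as (N, 2) x,y points."""
    contours = measure.find_contours(np.pad(filled, 1).astype(float), 0.5)
    if not contours:
        raise PlateNotFoundError("component has no traceable contour")
    c = max(contours, key=len) - 1.0  # undo padding; rows, cols
    return c[:, ::-1]  # -> x, y


def _order_corners(pts: np.ndarray) -> np.ndarray:
    centroid = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    # TL (-135 deg), TR (-45), BR (45), BL (135) under y-down
    return pts[np.argsort(ang)]


def _refine_corners(contour: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Sharpen DP corners by intersecting lines fitted to the quad sides.

    Blur and antialiasing round the rasterised corners, pulling the
    Douglas-Peucker vertices inward; fitting each side on its central
    portion (trimming 12% at both ends) and intersecting adjacent side
    lines recovers the true corner to sub-pixel accuracy.
    """
    idx = [int(np.argmin(np.sum((contour - c) ** 2, axis=1))) for c in corners]
    n = len(contour)
    lines = []
    for k in range(4):
        i0, i1 = idx[k], idx[(k + 1) % 4]
        seg = contour[i0:i1] if i1 > i0 else np.vstack([contour[i0:], contour[:i1]])
        if len(seg) < 8:
            return corners  # side too short to fit; keep DP vertices
        trim = max(2, int(0.12 * len(seg)))
        seg = seg[trim:-trim]
        centre = seg.mean(axis=0)
        # total least squares direction via principal component
        _, _, vt = np.linalg.svd(seg - centre, full_matrices=False)
        d = vt[0]
        lines.append((centre, d))
    refined = []
    for k in range(4):
        (p1, d1), (p2, d2) = lines[k - 1], lines[k]
        A = np.array([[d1[0], -d2[0]], [d1[1], -d2[1]]])
        if abs(np.linalg.det(A)) < 1e-9:
            return corners
        t = np.linalg.solve(A, p2 - p1)
        refined.append(p1 + t[0] * d1)
    return np.array(refined)


def _detect_contour(mask: np.ndarray, det: DetectionConfig) -> PlateQuad:
    filled = _largest_enclosed_component(mask)
    contour = _outer_contour(filled)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    # anchor the closed contour at its farthest-from-centroid point (a
    # corner): Douglas-Peucker always keeps its endpoints
    centroid = contour.mean(axis=0)
    start = int(np.argmax(np.sum((contour - centroid) ** 2, axis=1)))
    contour = np.vstack([np.roll(contour, -start, axis=0), contour[start]])
    perimeter = float(np.hypot(*np.diff(contour, axis=0).T).sum())
    tol = det.dp_tol_start * perimeter
    while tol <= det.dp_tol_max * perimeter + 1e-9:
        approx = measure.approximate_polygon(contour[:, ::-1], tolerance=tol)[:, ::-1]
        if len(approx) >= 2 and np.allclose(approx[0], approx[-1]):
            approx = approx[:-1]
        if len(approx) == 4:
            try:
                return PlateQuad(_order_corners(_refine_corners(contour[:-1], approx)))
            except PlateNotFoundError:
                pass
        if len(approx) < 4:
            break
        tol *= det.dp_tol_factor
    raise PlateNotFoundError("no contour simplifiable to 4 convex corners within tolerance schedule")


def _detect_hough(mask: np.ndarray, det: DetectionConfig) -> PlateQuad:
    """Alternative detector: fit the frame's edge lines by Hough transform.

    Finds the two strongest near-horizontal and near-vertical line pairs on
    the outer boundary of the dominant component and intersects them.
    """
    filled = _largest_enclosed_component(mask)
    border = filled & ~ndimage.binary_erosion(filled)
    angles = np.linspace(-np.pi / 2, np.pi / 2, 360, endpoint=False)
    h, theta, d = hough_line(border, theta=angles)
    _, angs, dists = hough_line_peaks(h, theta, d, num_peaks=8, min_distance=9, min_angle=9)
    lines = list(zip(angs, dists))
    # hough normal angle ~0 -> vertical line; ~+-pi/2 -> horizontal
    vert = [(a, r) for a, r in lines if abs(a) < np.pi / 4]
    horiz = [(a, r) for a, r in lines if abs(a) >= np.pi / 4]
    if len(vert) < 2 or len(horiz) < 2:
        raise PlateNotFoundError("Hough detector found fewer than 2+2 frame edge lines")
    vert = sorted(vert[:2], key=lambda ar: ar[1] * np.cos(ar[0]))
    horiz = sorted(horiz[:2], key=lambda ar: ar[1] * np.sin(ar[0]))

    def intersect(l1, l2):
        (a1, r1), (a2, r2) = l1, l2
        A = np.array([[np.cos(a1), np.sin(a1)], [np.cos(a2), np.sin(a2)]])
        if abs(np.linalg.det(A)) < 1e-12:
            raise PlateNotFoundError("parallel Hough lines cannot intersect")
        return np.linalg.solve(A, np.array([r1, r2]))

    corners = np.array(
        [
            intersect(vert[0], horiz[0]),  # TL
            intersect(vert[1], horiz[0]),  # TR
            intersect(vert[1], horiz[1]),  # BR
            intersect(vert[0], horiz[1]),  # BL
        ]
    )
    return PlateQuad(_order_corners(corners))


def detect_plate_quad(mask: np.ndarray, detection: DetectionConfig | None = None) -> PlateQuad:
    """Locate the four outer corners of the black frame in a binary mask.

    The dominant component (largest enclosed area) is traced and its outer
    contour simplified to a quadrilateral by Douglas-Peucker approximation
    with an increasing tolerance schedule; corners are returned in
    canonical TL, TR, BR, BL order.
    """
    detection = detection or DetectionConfig()
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise PlateNotFoundError(f"mask must be 2D, got shape {mask.shape}")
    if detection.method == "hough":
        return _detect_hough(mask, detection)
    return _detect_contour(mask, detection)


# ---------------------------------------------------------------------------
# homography estimation and rectification
# ---------------------------------------------------------------------------

def estimate_homography(quad: PlateQuad, virtual: VirtualPlate | np.ndarray) -> HomographyParams:
    """Solve the transformation parameters A-H from the 4 corner pairs.

    Maps detected (distorted) corners ``(x, y)`` onto the virtual frontal
    corners ``(u, v)``; the 8x8 linear system is solved exactly.
    """
    src = quad.corners
    dst = virtual.corners if isinstance(virtual, VirtualPlate) else np.asarray(virtual, float)
    M = np.zeros((8, 8))
    rhs = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        M[2 * i] = [x, y, 1, 0, 0, 0, -x * u, -y * u]
        M[2 * i + 1] = [0, 0, 0, x, y, 1, -x * v, -y * v]
        rhs[2 * i] = u
        rhs[2 * i + 1] = v
    if abs(np.linalg.det(M)) < 1e-9:
        raise SingularSystemError("corner configuration is degenerate (collinear corners?)")
    p = np.linalg.solve(M, rhs)
    return HomographyParams(*p)


def rectify(image: np.ndarray, H: HomographyParams, virtual: VirtualPlate) -> np.ndarray:
    """Warp the distorted image onto the virtual frontal plate.

    Every output pixel is inverse-mapped through ``H`` and sampled from the
    source with bilinear interpolation, so the rectified image has no
    unfilled pixels (forward mapping would leave holes).
    """
    Hinv = np.linalg.inv(H.matrix)
    h, w = virtual.shape_px
    uu, vv = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    pts = np.stack([uu.ravel(), vv.ravel(), np.ones(uu.size)])
    src = Hinv @ pts
    xs = (src[0] / src[2]).reshape(h, w)
    ys = (src[1] / src[2]).reshape(h, w)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
    chans = [ndimage.map_coordinates(img[..., c], [ys, xs], order=1, mode="nearest") for c in range(img.shape[2])]
    return np.stack(chans, axis=-1)
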