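"""Circumscribed-rectangle measurement: contours, ticks, pixel ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafgeom import (
    AxisRect,
    SceneSpec,
    TickScale,
    area_perimeter,
    bounding_rect,
    config_for_scene,
    extract_leaf_and_frame,
    length_width_from_ticks,
    measure,
    pixel_counts,
    read_tick_scale,
    render,
)
from leafgeom.config import TickConfig
from leafgeom.errors import (
    InvalidStatsError,
    OutOfRangeError,
    PlateNotFoundError,
    SceneInvalidError,
)
from leafgeom.measurement import Contour, ContourStats, _component_contour

from conftest import SMALL, SMALL_PPM


# ---------------------------------------------------------------------------
# helpers / oracles
# ---------------------------------------------------------------------------

def _contour_from_mask(mask: np.ndarray) -> Contour:
    from scipy import ndimage

    labels, n = ndimage.label(mask > 0, structure=np.ones((3, 3), int))
    assert n >= 1
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    idx = int(np.argmax(sizes)) + 1
    return _component_contour(labels, idx, ndimage.find_objects(labels)[idx - 1])


def _flood_fill_interior_oracle(mask: np.ndarray) -> int:
    """Pixels enclosed by the outermost boundary: complement pixels NOT
    reachable from the border (4-connected BFS on the background)."""
    from collections import deque

    h, w = mask.shape
    bg = mask == 0
    seen = np.zeros_like(bg)
    dq = deque()
    for y in range(h):
        for x in (0, w - 1):
            if bg[y, x] and not seen[y, x]:
                seen[y, x] = True
                dq.append((y, x))
    for x in range(w):
        for y in (0, h - 1):
            if bg[y, x] and not seen[y, x]:
                seen[y, x] = True
                dq.append((y, x))
    while dq:
        y, x = dq.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and bg[ny, nx] and not seen[ny, nx]:
                seen[ny, nx] = True
                dq.append((ny, nx))
    return int(mask.size - seen.sum() - 0)  # foreground + enclosed holes


def _blob_mask(rng, size=48) -> np.ndarray:
    """A random connected blob: a chain of overlapping discs."""
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), bool)
    cx, cy = size / 2, size / 2
    r = rng.uniform(5, size / 5)
    for _ in range(rng.integers(1, 5)):
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        step = rng.uniform(0, 0.9 * r, size=2)  # next centre inside the disc
        cx = np.clip(cx + rng.choice([-1, 1]) * step[0], r + 1, size - r - 2)
        cy = np.clip(cy + rng.choice([-1, 1]) * step[1], r + 1, size - r - 2)
        r = rng.uniform(4, size / 5)
    return mask.astype(np.uint8)


def _ruler_scale(top_positions, left_positions):
    return TickScale(
        top_tick_xs=np.asarray(top_positions, float),
        left_tick_ys=np.asarray(left_positions, float),
        mm_per_tick=1.0,
    )


# ---------------------------------------------------------------------------
# bounding rectangle
# ---------------------------------------------------------------------------

class TestBoundingRect:
    def test_rectangle_is_its_own_bounding_box(self):
        mask = np.zeros((40, 40), np.uint8)
        mask[7:27, 5:15] = 1  # 10 x 20 px at (5, 7)
        rect = bounding_rect(_contour_from_mask(mask))
        assert (rect.x_min, rect.x_max, rect.y_min, rect.y_max) == (5, 14, 7, 26)
        assert rect.length_px == 9 and rect.height_px == 19

    def test_single_pixel_degenerate(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[3, 3] = 1
        rect = bounding_rect(_contour_from_mask(mask))
        assert (rect.x_min, rect.x_max, rect.y_min, rect.y_max) == (3, 3, 3, 3)
        assert rect.length_px == 0 and rect.height_px == 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_min_max_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = _blob_mask(rng)
        rect = bounding_rect(_contour_from_mask(mask))
        ys, xs = np.nonzero(mask)
        assert (rect.x_min, rect.x_max) == (xs.min(), xs.max())
        assert (rect.y_min, rect.y_max) == (ys.min(), ys.max())


# ---------------------------------------------------------------------------
# component extraction
# ---------------------------------------------------------------------------

def _frame_and_blob_mask(with_ticks=False):
    mask = np.zeros((300, 400), np.uint8)
    mask[20:280, 20:380] = 1
    mask[26:274, 26:374] = 0  # frame ring
    mask[100:180, 150:250] = 1  # blob (leaf)
    if with_ticks:
        for k in range(40, 360, 10):
            mask[28:33, k] = 1  # 100-odd small tick components
    return mask


class TestExtractLeafAndFrame:
    def test_two_component_scene(self):
        leaf, frame = extract_leaf_and_frame(_frame_and_blob_mask())
        assert frame.pixel_count_interior > leaf.pixel_count_interior
        r = bounding_rect(leaf)
        assert (r.x_min, r.x_max, r.y_min, r.y_max) == (150, 249, 100, 179)

    def test_tick_components_are_ignored(self):
        leaf_a, _ = extract_leaf_and_frame(_frame_and_blob_mask(False))
        leaf_b, _ = extract_leaf_and_frame(_frame_and_blob_mask(True))
        assert np.array_equal(leaf_a.filled, leaf_b.filled)

    def test_frame_outranks_larger_raw_pixel_leaf(self):
        """Ranking is by enclosed area: the thin ring wins although the
        blob has more raw foreground pixels."""
        mask = _frame_and_blob_mask()
        ring_px = int(mask[20:280, 20:380].sum() - mask[100:180, 150:250].sum())
        blob_px = 80 * 100
        assert blob_px > ring_px  # precondition for the scenario
        leaf, frame = extract_leaf_and_frame(mask)
        assert frame.pixel_count_interior == 260 * 360

    def test_empty_mask_raises(self):
        with pytest.raises(SceneInvalidError):
            extract_leaf_and_frame(np.zeros((50, 50), np.uint8))

    def test_leaf_outside_frame_raises(self):
        mask = np.zeros((300, 400), np.uint8)
        mask[20:100, 20:180] = 1
        mask[26:94, 26:174] = 0
        mask[150:250, 250:350] = 1  # blob outside the frame
        with pytest.raises(SceneInvalidError):
            extract_leaf_and_frame(mask)


# ---------------------------------------------------------------------------
# tick-mark ruler
# ---------------------------------------------------------------------------

def _ruler_mask(pitch=10, tick_w=2, broken=False, scale=1):
    """Frame + top/left mm rulers drawn directly (no camera)."""
    p, w = pitch * scale, tick_w * scale
    H, W = 60 * p, 80 * p
    t = 3 * p  # frame thickness ~ 3 mm
    mask = np.zeros((H, W), np.uint8)
    mask[:] = 0
    mask[0:H, 0:W] = 0
    mask[0:t, :] = 1
    mask[-t:, :] = 1
    mask[:, 0:t] = 1
    mask[:, -t:] = 1
    gap = max(2, scale)
    tick_len = 2 * p
    for k in range(t, W - t + 1, p):
        mask[t + gap : t + gap + tick_len, k : k + w] = 1
        if broken:
            mask[t + gap + tick_len // 2, k : k + w] = 0
    for k in range(t, H - t + 1, p):
        mask[k : k + w, t + gap : t + gap + tick_len] = 1
        if broken:
            mask[k : k + w, t + gap + tick_len // 2] = 0
    # a dummy leaf so the mask is a valid two-component scene
    mask[H // 2 : H // 2 + 10 * p, W // 2 : W // 2 + 10 * p] = 1
    return mask


class TestReadTickScale:
    def test_ideal_ruler_pitch_recovered(self):
        mask = _ruler_mask()
        _, frame = extract_leaf_and_frame(mask)
        scale = read_tick_scale(mask, frame, TickConfig())
        assert scale.px_per_mm_x == pytest.approx(10.0, abs=0.01)
        assert scale.px_per_mm_y == pytest.approx(10.0, abs=0.01)
        assert np.allclose(np.diff(scale.top_tick_xs), 10.0, atol=0.01)

    def test_broken_ticks_reconnected_by_directional_dilation(self):
        whole = _ruler_mask(broken=False)
        broken = _ruler_mask(broken=True)
        _, frame_w = extract_leaf_and_frame(whole)
        _, frame_b = extract_leaf_and_frame(broken)
        s_w = read_tick_scale(whole, frame_w, TickConfig())
        s_b = read_tick_scale(broken, frame_b, TickConfig())
        assert len(s_w.top_tick_xs) == len(s_b.top_tick_xs)
        assert np.allclose(s_w.top_tick_xs, s_b.top_tick_xs, atol=0.51)

    def test_double_resolution_doubles_scale(self):
        mask = _ruler_mask(scale=2)
        _, frame = extract_leaf_and_frame(mask)
        scale = read_tick_scale(mask, frame, TickConfig())
        assert scale.px_per_mm_x == pytest.approx(20.0, abs=0.02)
        assert scale.px_per_mm_y == pytest.approx(20.0, abs=0.02)


class TestLengthWidthFromTicks:
    def test_edges_on_ticks_give_whole_millimetres(self):
        ticks = np.arange(100.0, 1000.0, 10.0)
        scale = _ruler_scale(ticks, ticks)
        # AxisRect edges sit at min-0.5 / max+0.5; place them on ticks
        # 10 and 40 of the 1-mm ruler (positions 200.0 and 500.0)
        Lr, Wr = length_width_from_ticks(
            AxisRect(x_min=200, x_max=500, y_min=200, y_max=500), scale
        )
        assert Lr == pytest.approx(30.0, abs=0.06)
        assert Wr == pytest.approx(30.0, abs=0.06)

    def test_fractional_end_segments(self):
        """Edges half a spacing beyond the nearest inner ticks:
        (n-1) spacings + 0.5 mm + 0.5 mm."""
        ticks = np.arange(100.0, 400.1, 10.0)
        scale = _ruler_scale(ticks, ticks)
        # inner ticks 100..380 over [95, 385]: 28 spacings + 2 x 0.5 mm
        rect = AxisRect(x_min=96, x_max=384, y_min=96, y_max=384)
        Lr, Wr = length_width_from_ticks(rect, scale)
        expected = 28.0 + 0.45 + 0.45  # gaps are 4.5 px at 10 px/mm
        assert Lr == pytest.approx(expected, abs=1e-9)
        assert Wr == pytest.approx(expected, abs=1e-9)

    def test_sub_spacing_rect_is_fraction_only(self):
        ticks = np.arange(100.0, 400.1, 10.0)
        scale = _ruler_scale(ticks, ticks)
        rect = AxisRect(x_min=203, x_max=207, y_min=203, y_max=207)
        Lr, Wr = length_width_from_ticks(rect, scale)
        assert 0.0 < Lr < 1.0

    def test_out_of_range_on_complete_ruler(self):
        ticks = np.arange(100.0, 200.1, 10.0)
        scale = _ruler_scale(ticks, ticks)
        with pytest.raises(OutOfRangeError):
            length_width_from_ticks(AxisRect(x_min=150, x_max=400, y_min=150, y_max=180), scale)


# ---------------------------------------------------------------------------
# pixel counts and the area/perimeter ratios
# ---------------------------------------------------------------------------

class TestPixelCounts:
    def test_square_leaf_counts(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[10:20, 10:20] = 1
        leaf = _contour_from_mask(mask)
        stats = pixel_counts(leaf, bounding_rect(leaf))
        assert stats.Pt == 100
        assert stats.Prt == 100
        assert stats.Pct == 36
        assert leaf.pixel_count_boundary == 36

    def test_interior_hole_is_filled(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[10:20, 10:20] = 1
        mask[14:16, 14:16] = 0  # 2x2 wormhole
        leaf = _contour_from_mask(mask)
        stats = pixel_counts(leaf, bounding_rect(leaf))
        assert stats.Pt == 100  # outermost contour only

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_interior_count_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = _blob_mask(rng, size=48)
        # punch a few random holes
        for _ in range(3):
            y, x = rng.integers(5, 43, 2)
            mask[y : y + 2, x : x + 2] = 0
        leaf = _contour_from_mask(mask)
        stats = pixel_counts(leaf, bounding_rect(leaf))
        assert stats.Pt == _flood_fill_interior_oracle(leaf.component.astype(np.uint8))

    def test_invalid_when_leaf_outside_rect(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[10:20, 10:20] = 1
        leaf = _contour_from_mask(mask)
        from leafgeom.errors import InvalidInputError

        with pytest.raises(InvalidInputError):
            pixel_counts(leaf, AxisRect(x_min=0, x_max=5, y_min=0, y_max=5))


class TestAreaPerimeter:
    def test_full_rectangle_leaf(self):
        stats = ContourStats(Pt=10000, Pc=400.0, Prt=10000, Pct=400.0)
        S, C = area_perimeter(stats, 50.0, 50.0)
        assert S == pytest.approx(25.0)
        assert C == pytest.approx(20.0)

    def test_direct_substitution(self):
        stats = ContourStats(Pt=5000, Pc=300.0, Prt=10000, Pct=400.0)
        S, _ = area_perimeter(stats, 60.0, 40.0)  # Sr = 24 cm^2
        assert S == pytest.approx(12.0)

    def test_invalid_dimensions_rejected(self):
        stats = ContourStats(Pt=100, Pc=30.0, Prt=200, Pct=40.0)
        with pytest.raises(InvalidStatsError):
            area_perimeter(stats, 0.0, 10.0)


# ---------------------------------------------------------------------------
# full pipeline invariants
# ---------------------------------------------------------------------------

class TestMeasurePipeline:
    def test_no_plate_raises(self):
        image = np.full((200, 300, 3), 210, dtype=np.uint8)
        image[80:120, 100:200] = 30  # a blob but no frame
        with pytest.raises((PlateNotFoundError, SceneInvalidError)):
            measure(image)

    def test_square_end_to_end_small(self, small_square_scene, small_config):
        spec, image, truth = small_square_scene
        m = measure(image, small_config)
        assert m.area_cm2 == pytest.approx(truth.true_area_cm2, rel=0.01)
        assert m.perimeter_cm == pytest.approx(truth.true_perimeter_cm, rel=0.01)
        assert m.rect_area_cm2 == pytest.approx(m.length_mm * m.width_mm / 100.0)
        assert m.stats.Pt <= m.stats.Prt

    def test_rectangle_self_reference_error_below_half_percent(self):
        """An axis-aligned rectangle is its own reference object: Pt/Prt -> 1
        and the measured area matches the true area almost exactly."""
        spec = SceneSpec(shape="rectangle", length_mm=60, width_mm=40, image_width_px=1200, supersample=2)
        image, truth = render(spec)
        m = measure(image, config_for_scene(spec, px_per_mm=8))
        assert m.stats.Pt / m.stats.Prt > 0.995
        assert abs(m.area_cm2 / truth.true_area_cm2 - 1) < 0.005

    def test_disc_area_monotone_in_radius(self):
        areas = []
        for d in (30.0, 45.0, 60.0):
            spec = SceneSpec(shape="circle", diameter_mm=d, **SMALL)
            image, _ = render(spec)
            areas.append(measure(image, config_for_scene(spec, SMALL_PPM)).area_cm2)
        assert areas[0] < areas[1] < areas[2]

    def test_resolution_robustness_below_half_percent(self):
        """The same scene at 1x and 2x capture resolution yields areas
        within 0.5% of each other."""
        results = []
        for width in (1200, 2400):
            spec = SceneSpec(shape="circle", image_width_px=width, supersample=2)
            image, _ = render(spec)
            results.append(measure(image, config_for_scene(spec, px_per_mm=8)).area_cm2)
        assert abs(results[1] / results[0] - 1) < 0.005

    def test_hole_insensitivity_below_two_permille(self):
        """Interior holes up to ~10% of the area leave the measured area
        almost unchanged (outermost-contour fill)."""
        base = SceneSpec(shape="leaf", leaf_template="oval", leaf_area_cm2=30, **SMALL)
        image, _ = render(base)
        m0 = measure(image, config_for_scene(base, SMALL_PPM))
        # punch holes into the rendered silhouette directly
        img = image.copy()
        h, w = img.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        for cx, cy, r in ((w // 2 - 30, h // 2, 12), (w // 2 + 25, h // 2 + 8, 10)):
            hole = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            img[hole] = (235, 233, 228)
        m1 = measure(img, config_for_scene(base, SMALL_PPM))
        assert abs(m1.area_cm2 / m0.area_cm2 - 1) < 0.002
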