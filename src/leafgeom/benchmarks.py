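"""Reference benchmark panels for validating the measurement pipeline.

These reproduce the bench-test protocol at desk scale: the four regular
test shapes (square 5x5 cm, rectangle 6x4 cm, circle diameter 6 cm,
isosceles triangle base 6 cm / height 6 cm), a tilt sweep over 0-45
degrees at fixed distance, and a panel of 20 seeded leaf silhouettes
(5 per template) under mixed distances and angles.

Panels are rendered at the generator's default study conditions
(1600 px captures).  Leaf areas are drawn per template from the ranges
that physically fit the default 160 x 120 mm frame: the slender (rice)
template at aspect ~7 cannot exceed ~14 cm^2 inside the frame, while the
broad templates range up to 80 cm^2.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .measurement import measure
from .synthetic import SceneSpec, config_for_scene, render

#: true parameters of the four regular test shapes (cm / cm^2)
TABLE_SHAPES: dict[str, dict] = {
    "square": dict(length_cm=5.00, width_cm=5.00, area_cm2=25.00, perimeter_cm=20.00),
    "rectangle": dict(length_cm=6.00, width_cm=4.00, area_cm2=24.00, perimeter_cm=20.00),
    "circle": dict(length_cm=6.00, width_cm=6.00, area_cm2=28.27, perimeter_cm=18.85),
    "triangle": dict(length_cm=6.00, width_cm=6.00, area_cm2=18.00, perimeter_cm=19.42),
}

ANGLE_SWEEP_DEG = (0.0, 15.0, 30.0, 45.0)
DISTANCE_SWEEP_MM = (235.0, 240.0, 250.0, 260.0)

#: per-template leaf areas (cm^2) spanning what fits the default frame
LEAF_PANEL_AREAS: dict[str, tuple[float, ...]] = {
    "heart": (20.0, 35.0, 50.0, 60.0, 72.0),
    "oval": (20.0, 35.0, 50.0, 65.0, 80.0),
    "serrated": (18.0, 30.0, 45.0, 60.0, 75.0),
    "slender": (8.0, 9.5, 11.0, 12.5, 14.0),
}


def table2_spec(shape: str, **overrides) -> SceneSpec:
    """Frontal noiseless scene of one regular test shape."""
    return SceneSpec(shape=shape, **overrides)


def angle_sweep_specs(blur_sigma_px: float = 1.0, noise_sd: float = 2.0) -> list[SceneSpec]:
    """All four shapes at tilts 0/15/30/45 deg, distance 240 mm."""
    return [
        SceneSpec(
            shape=shape,
            tilt_deg=tilt,
            camera_distance_mm=240.0,
            blur_sigma_px=blur_sigma_px,
            noise_sd=noise_sd,
        )
        for shape in TABLE_SHAPES
        for tilt in ANGLE_SWEEP_DEG
    ]


def leaf_panel_specs(blur_sigma_px: float = 1.0, noise_sd: float = 3.0) -> list[SceneSpec]:
    """20 seeded leaf scenes (5 per template) under mixed conditions."""
    specs = []
    i = 0
    for template, areas in LEAF_PANEL_AREAS.items():
        for area in areas:
            specs.append(
                SceneSpec(
                    shape="leaf",
                    leaf_template=template,
                    leaf_area_cm2=area,
                    tilt_deg=ANGLE_SWEEP_DEG[i % 4],
                    camera_distance_mm=DISTANCE_SWEEP_MM[(i // 4) % 4],
                    blur_sigma_px=blur_sigma_px,
                    noise_sd=noise_sd,
                    seed=i,
                )
            )
            i += 1
    return specs


def measure_scene(spec: SceneSpec, seed: int | None = None) -> tuple[dict, dict]:
    """Render one scene (optionally reseeded) and measure it.

    Returns (measured, truth) dictionaries with area/perimeter/length/
    width in the reporting units (cm^2, cm, mm, mm).
    """
    if seed is not None:
        spec = dataclasses.replace(spec, seed=int(seed) & 0x7FFFFFFF)
    image, truth = render(spec)
    m = measure(image, config_for_scene(spec))
    measured = {
        "area_cm2": m.area_cm2,
        "perimeter_cm": m.perimeter_cm,
        "length_mm": m.length_mm,
        "width_mm": m.width_mm,
    }
    true = {
        "area_cm2": truth.true_area_cm2,
        "perimeter_cm": truth.true_perimeter_cm,
        "length_mm": truth.true_length_mm,
        "width_mm": truth.true_width_mm,
    }
    return measured, true


def max_abs_rel_area_error(specs: list[SceneSpec], seeds: list[int]) -> tuple[float, int]:
    """Worst |relative area error| in percent over specs x seeds.

    Each (spec, seed) pair renders an independent noise realisation.
    Returns (percent, number of scenes measured).
    """
    worst = 0.0
    n = 0
    for spec in specs:
        for s in seeds:
            reseeded = dataclasses.replace(spec, seed=int(np.uint32(spec.seed * 1009 + s)) & 0x7FFFFFFF)
            measured, true = measure_scene(reseeded)
            worst = max(worst, abs(measured["area_cm2"] / true["area_cm2"] - 1.0) * 100.0)
            n += 1
    return worst, n
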