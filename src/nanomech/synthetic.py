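"""Synthetic-data generators with known ground truth.

Every pipeline input can be generated here: single force curves and force
volumes per sample class, spatial lesion scenes (soft pigmented lesion
versus stiff healthy skin), thermal-noise cantilever traces, populations of
elliptical cells, and two-group numeric samples.  Each generator is a
deterministic function of its spec and seed, and embeds enough metadata in
its output to recompute the ground truth.

Force curves are generated by exact inversion of the forward contact model:
for each piezo position past contact the cantilever deflection d solves

    k * d = E * g((z - z0) - d)

with g the Sneddon/Hertz geometry term; the root is found by the same
Newton solver the fitting pipeline uses for its forward model, to machine
precision, so a noiseless curve round-trips through the pipeline to the
generating modulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .calibration import FIRST_MODE_CORRECTION, ThermalTrace
from .contact import geometry_term, solve_deflection
from .curves import (
    BOLTZMANN_J_PER_K,
    CantileverCalibration,
    DeflectionUnit,
    Direction,
    ForceVolume,
    RawForceCurve,
    SampleClass,
    SampleClassSettings,
    TipGeometry,
    TipKind,
)

__all__ = [
    "SceneSpec",
    "CellPopulationSpec",
    "simulate_curve",
    "simulate_volume",
    "simulate_thermal_trace",
    "simulate_cell_image",
    "simulate_two_groups",
    "paper_moduli",
    "default_tip",
    "default_calibration",
    "uniform_scene",
    "two_region_scene",
]

#: default pyramidal half-angle (deg) for the soft-lever probe family
DEFAULT_HALF_ANGLE_DEG = 18.0


def paper_moduli() -> dict:
    """Packaged fixture of reported stiffness values by condition (kPa)."""
    text = resources.files("nanomech").joinpath("data/paper_moduli.yaml").read_text()
    return yaml.safe_load(text)


def default_tip(sample_class: SampleClass) -> TipGeometry:
    """Conventional tip for a sample class: pyramid for cells/cryosections,
    500 nm sphere for whole skin reconstructs."""
    sample_class = SampleClass(sample_class)
    if sample_class is SampleClass.HSR_WHOLE:
        return TipGeometry(
            kind=TipKind.SPHERICAL, radius_m=500e-9, nominal_apex_radius_m=500e-9
        )
    return TipGeometry(
        kind=TipKind.PYRAMIDAL,
        half_angle_deg=DEFAULT_HALF_ANGLE_DEG,
        nominal_apex_radius_m=10e-9,
    )


def default_calibration(sample_class: SampleClass) -> CantileverCalibration:
    """Conventional lever: 0.4 N/m (soft, thermally tuned) for cells and
    cryosections, 40 N/m (stiff, pre-calibrated) for whole reconstructs."""
    sample_class = SampleClass(sample_class)
    if sample_class is SampleClass.HSR_WHOLE:
        return CantileverCalibration(
            spring_constant_n_per_m=40.0, method="precalibrated"
        )
    return CantileverCalibration(spring_constant_n_per_m=0.4, method="thermal_tune")


def simulate_curve(
    true_modulus_pa: float,
    settings: SampleClassSettings,
    tip: Optional[TipGeometry] = None,
    calibration: Optional[CantileverCalibration] = None,
    noise_force_frac: float = 0.0,
    baseline_slope_n_per_m: float = 0.0,
    contact_index: Optional[int] = None,
    n_samples: int = 2048,
    seed: Optional[int] = None,
    depth_overshoot: float = 1.1,
    labels: Optional[dict] = None,
) -> RawForceCurve:
    """Generate one approach force curve with known modulus.

    The ramp is uniform in z, contact falls exactly on sample
    ``contact_index``, and the deepest point reaches
    ``depth_overshoot * settings.max_indentation_m`` of true indentation.
    Gaussian force noise with standard deviation ``noise_force_frac`` times
    the peak noiseless force is added to the whole trace, as is an optional
    linear force baseline of ``baseline_slope_n_per_m`` (slope in N per m of
    z, zero-crossing at contact).  Ground truth is recorded in the curve's
    labels.
    """
    if noise_force_frac < 0:
        raise ValueError("noise_force_frac must be non-negative")
    if contact_index is None:
        contact_index = n_samples // 3
    if not 0 < contact_index < n_samples - 16:
        raise ValueError("contact_index must leave room on both sides")
    if true_modulus_pa <= 0:
        raise ValueError("true modulus must be positive")
    if tip is None:
        tip = default_tip(settings.sample_class)
    if calibration is None:
        calibration = default_calibration(settings.sample_class)
    k = calibration.spring_constant_n_per_m

    delta_max = depth_overshoot * settings.max_indentation_m
    d_max = true_modulus_pa * float(geometry_term(delta_max, tip, settings)) / k
    post_span = delta_max + d_max
    dz = post_span / (n_samples - 1 - contact_index)
    z = np.arange(n_samples) * dz
    z0 = z[contact_index]

    d = np.zeros(n_samples)
    d[contact_index:] = solve_deflection(
        z[contact_index:] - z0, true_modulus_pa, tip, settings, k
    )
    force_peak = k * d[-1]

    rng = np.random.default_rng(seed)
    noise_force = (
        rng.normal(0.0, noise_force_frac * force_peak, n_samples)
        if noise_force_frac > 0
        else 0.0
    )
    baseline_force = baseline_slope_n_per_m * (z - z0)
    deflection = d + (noise_force + baseline_force) / k

    truth = {
        "true_modulus_pa": float(true_modulus_pa),
        "true_contact_index": int(contact_index),
        "noise_force_frac": float(noise_force_frac),
        "baseline_slope_n_per_m": float(baseline_slope_n_per_m),
        "seed": seed,
    }
    if labels:
        truth.update(labels)
    return RawForceCurve(
        z_m=z,
        deflection=deflection,
        deflection_unit=DeflectionUnit.METERS,
        direction=Direction.APPROACH,
        tip=tip,
        calibration=calibration,
        labels=truth,
    )


@dataclass
class SceneSpec:
    """Spatial scene for a force volume: regions of known modulus.

    ``regions`` is a list of ``(mask, true_modulus_pa, label)`` triples whose
    boolean masks must partition the grid.  Emulates a soft pigmented lesion
    embedded in stiffer healthy tissue.
    """

    rows: int
    cols: int
    regions: list
    noise_force_frac: float = 0.02
    baseline_slope_n_per_m: float = 0.0
    contact_jitter_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        cover = np.zeros((self.rows, self.cols), dtype=int)
        for mask, modulus, _label in self.regions:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.rows, self.cols):
                raise ValueError("region mask shape does not match grid")
            if modulus <= 0:
                raise ValueError("region moduli must be positive")
            cover += mask.astype(int)
        if not np.all(cover == 1):
            raise ValueError("region masks must partition the grid exactly")

    def truth_map_pa(self) -> np.ndarray:
        truth = np.zeros((self.rows, self.cols))
        for mask, modulus, _label in self.regions:
            truth[np.asarray(mask, dtype=bool)] = modulus
        return truth


def uniform_scene(
    rows: int, cols: int, modulus_pa: float, label: str = "sample", **kwargs
) -> SceneSpec:
    """Single-region homogeneous scene."""
    mask = np.ones((rows, cols), dtype=bool)
    return SceneSpec(rows=rows, cols=cols, regions=[(mask, modulus_pa, label)], **kwargs)


def two_region_scene(
    rows: int,
    cols: int,
    lesion_modulus_pa: float,
    healthy_modulus_pa: float,
    **kwargs,
) -> SceneSpec:
    """Left half soft lesion, right half stiff healthy tissue."""
    lesion = np.zeros((rows, cols), dtype=bool)
    lesion[:, : cols // 2] = True
    return SceneSpec(
        rows=rows,
        cols=cols,
        regions=[
            (lesion, lesion_modulus_pa, "lesion"),
            (~lesion, healthy_modulus_pa, "healthy"),
        ],
        **kwargs,
    )


def simulate_volume(
    scene: SceneSpec,
    settings: SampleClassSettings,
    tip: Optional[TipGeometry] = None,
    calibration: Optional[CantileverCalibration] = None,
    n_samples: int = 2048,
    contact_index: Optional[int] = None,
    pixel_pitch_m: float = 625e-9,
) -> ForceVolume:
    """One simulated curve per scene pixel; truth map stored in the labels.

    The default pixel pitch reproduces a 16x16 grid over a 100 um^2 scan
    area (10 um / 16 pixels).
    """
    if tip is None:
        tip = default_tip(settings.sample_class)
    if calibration is None:
        calibration = default_calibration(settings.sample_class)
    if contact_index is None:
        contact_index = n_samples // 3
    truth = scene.truth_map_pa()
    label_map = np.empty((scene.rows, scene.cols), dtype=object)
    for mask, _m, label in scene.regions:
        label_map[np.asarray(mask, dtype=bool)] = label

    ss = np.random.SeedSequence(scene.seed)
    child_seeds = ss.generate_state(scene.rows * scene.cols * 2).reshape(
        scene.rows, scene.cols, 2
    )
    grid: list[list[RawForceCurve]] = []
    for r in range(scene.rows):
        row = []
        for c in range(scene.cols):
            jitter_rng = np.random.default_rng(int(child_seeds[r, c, 0] % (2**31)))
            ci = contact_index
            if scene.contact_jitter_samples:
                ci += int(
                    jitter_rng.integers(
                        -scene.contact_jitter_samples,
                        scene.contact_jitter_samples + 1,
                    )
                )
            curve = simulate_curve(
                float(truth[r, c]),
                settings,
                tip=tip,
                calibration=calibration,
                noise_force_frac=scene.noise_force_frac,
                baseline_slope_n_per_m=scene.baseline_slope_n_per_m,
                contact_index=ci,
                n_samples=n_samples,
                seed=int(child_seeds[r, c, 1] % (2**31)),
                labels={"region": str(label_map[r, c]), "row": r, "col": c},
            )
            row.append(curve)
        grid.append(row)
    return ForceVolume(
        grid=grid,
        pixel_pitch_m=pixel_pitch_m,
        labels={
            "truth_map_pa": truth.tolist(),
            "scene_seed": scene.seed,
            "noise_force_frac": scene.noise_force_frac,
        },
    )


def simulate_thermal_trace(
    spring_constant_n_per_m: float,
    temperature_k: float = 298.0,
    n_samples: int = 65536,
    seed: Optional[int] = None,
    sample_rate_hz: float = 100e3,
) -> ThermalTrace:
    """Gaussian thermal deflection trace consistent with the thermal tune.

    The variance is beta * k_B * T / k, so the beta-corrected equipartition
    estimator recovers the generating spring constant in expectation.
    """
    if spring_constant_n_per_m <= 0 or temperature_k <= 0:
        raise ValueError("spring constant and temperature must be positive")
    var = (
        FIRST_MODE_CORRECTION
        * BOLTZMANN_J_PER_K
        * temperature_k
        / spring_constant_n_per_m
    )
    rng = np.random.default_rng(seed)
    d = rng.normal(0.0, np.sqrt(var), n_samples)
    return ThermalTrace(
        deflection_m=d, sample_rate_hz=sample_rate_hz, temperature_k=temperature_k
    )


@dataclass
class CellPopulationSpec:
    """Population of elliptical cells for morphometrics fixtures."""

    n_cells: int = 20
    aspect_ratio_dist: tuple = (1.5, 0.3)
    size_dist_um2: tuple = (400.0, 80.0)
    boundary_roughness: float = 0.0
    image_size_px: tuple = (512, 512)
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.boundary_roughness <= 1.0:
            raise ValueError("boundary_roughness must lie in [0, 1]")


def _rough_ellipse_polygon(
    center,
    semi_major_px: float,
    semi_minor_px: float,
    orientation_rad: float,
    roughness: float,
    rng: np.random.Generator,
    n_vertices: int = 256,
):
    """Polygon vertices of an ellipse with optional radial boundary noise."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r_mod = np.ones_like(theta)
    if roughness > 0:
        # a few smooth Fourier modes perturbing the radius
        for mode in (3, 5, 7, 11):
            amp = roughness * 0.12 * rng.uniform(0.3, 1.0)
            phase = rng.uniform(0, 2 * np.pi)
            r_mod += amp * np.cos(mode * theta + phase)
        r_mod = np.clip(r_mod, 0.3, None)
    x = semi_major_px * r_mod * np.cos(theta)
    y = semi_minor_px * r_mod * np.sin(theta)
    ct, st = np.cos(orientation_rad), np.sin(orientation_rad)
    rows = center[0] + (x * st + y * ct)
    cols = center[1] + (x * ct - y * st)
    return rows, cols


def simulate_cell_image(spec: CellPopulationSpec):
    """Render non-overlapping cells on a noisy background.

    Returns ``(image, truth)`` where ``image`` is a float grayscale array
    and ``truth`` a pandas DataFrame listing each cell's area (um^2), aspect
    ratio, center and orientation.  Raises if the requested population
    cannot be placed without overlap after bounded retries.
    """
    import pandas as pd
    from skimage.draw import polygon as draw_polygon
    from skimage.morphology import dilation, disk

    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    occupied = np.zeros((h, w), dtype=bool)
    image = rng.normal(0.1, 0.02, (h, w))
    records = []
    max_tries = 200 * spec.n_cells
    tries = 0
    placed = 0
    margin = disk(2)
    while placed < spec.n_cells:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in a "
                f"{h}x{w} image after {max_tries} tries; use a larger image"
            )
        tries += 1
        ar = max(1.0, rng.normal(*spec.aspect_ratio_dist))
        area_um2 = max(
            9.0 * spec.pixel_size_um**2, rng.normal(*spec.size_dist_um2)
        )
        area_px = area_um2 / spec.pixel_size_um**2
        b = np.sqrt(area_px / (np.pi * ar))
        a = ar * b
        orient = rng.uniform(0, np.pi)
        pad = int(np.ceil(a)) + 4
        if 2 * pad >= min(h, w):
            raise RuntimeError("cells too large for the image; use a larger image")
        center = (rng.uniform(pad, h - pad), rng.uniform(pad, w - pad))
        rr_poly, cc_poly = _rough_ellipse_polygon(
            center, a, b, orient, spec.boundary_roughness, rng
        )
        rr, cc = draw_polygon(rr_poly, cc_poly, shape=(h, w))
        if rr.size == 0:
            continue
        cand = np.zeros((h, w), dtype=bool)
        cand[rr, cc] = True
        if np.any(dilation(cand, margin) & occupied):
            continue
        occupied |= cand
        image[cand] = rng.normal(0.9, 0.02, int(cand.sum()))
        placed += 1
        records.append(
            {
                "cell": placed,
                "area_um2": float(cand.sum()) * spec.pixel_size_um**2,
                "target_area_um2": area_um2,
                "aspect_ratio": ar,
                "center_row": center[0],
                "center_col": center[1],
                "orientation_rad": orient,
            }
        )
    return image, pd.DataFrame.from_records(records)


_DISTRIBUTIONS = ("normal", "lognormal", "exponential")


def simulate_two_groups(
    dist_a: tuple,
    dist_b: tuple,
    n_a: int,
    n_b: int,
    seed: Optional[int] = None,
):
    """Draw two reproducible samples for exercising the test-selection logic.

    Each distribution is ``(name, params)`` with name in normal / lognormal
    / exponential: normal(mu, sd), lognormal(mu, sigma) of the underlying
    normal, exponential(scale).
    """
    if n_a < 3 or n_b < 3:
        raise ValueError("each group needs at least 3 observations")
    rng = np.random.default_rng(seed)

    def draw(dist, n):
        name, params = dist[0], tuple(dist[1:]) if len(dist) > 1 else ()
        if isinstance(dist[1], (tuple, list)):
            params = tuple(dist[1])
        if name == "normal":
            return rng.normal(params[0], params[1], n)
        if name == "lognormal":
            return rng.lognormal(params[0], params[1], n)
        if name == "exponential":
            return rng.exponential(params[0], n)
        raise ValueError(f"unknown distribution '{name}'; use one of {_DISTRIBUTIONS}")

    return draw(dist_a, n_a), draw(dist_b, n_b)
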