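"""Synthetic uncaging time-lapse generator with known ground truth.

Renders a cell as an elliptical plasma-membrane (PM) ring plus bright
intracellular vesicle discs on a dark background, then applies a single
photoactivation event between the last pre-frame and the first post-frame.
Post-activation brightness per compartment is the still-fluorescent fraction
from the closed-form competing-fates model (:mod:`.photochemistry`): the PM
keeps only the still-caged pool (the released alcohol diffuses away), while
vesicles keep caged + retained alcohol.  Gaussian PSF blur, Poisson shot
noise and Gaussian read noise complete a standard fluorescence camera model;
every noise source can be switched off for exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .photochemistry import CompartmentFractions, PhotoreactionParams, photochemistry_closed_form

__all__ = [
    "SceneParams",
    "ImageStack",
    "CompartmentMasks",
    "render_stack",
    "simulate_titration",
]


@dataclass(frozen=True)
class ImageStack:
    """Time-lapse stack (frame, row, col) with acquisition metadata.

    ``uncaging_frame`` is the 0-based index of the first post-activation
    frame; at least one pre-frame is required.
    """

    pixels: np.ndarray
    frame_interval_s: float = 1.0
    uncaging_frame: int = 1
    laser_level: float = 0.0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a 3-D (frame, row, col) array")
        if self.uncaging_frame < 1:
            raise ValueError("uncaging_frame must be >= 1 (need a pre-frame)")
        if self.uncaging_frame > self.pixels.shape[0]:
            raise ValueError("uncaging_frame beyond stack length")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixels must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class CompartmentMasks:
    """Boolean masks of PM, vesicle and cell-free background pixels."""

    pm: np.ndarray
    vesicles: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        if not (self.pm.shape == self.vesicles.shape == self.background.shape):
            raise ValueError("masks must share one shape")
        if (self.pm & self.vesicles).any() or (self.pm & self.background).any() or (
            self.vesicles & self.background
        ).any():
            raise ValueError("masks must be pairwise disjoint")


@dataclass(frozen=True)
class SceneParams:
    """Geometry, brightness and noise configuration of the synthetic cell.

    Brightness values are expected photons/pixel/frame before PSF blur.
    Defaults draw a single HeLa-like cell: an elliptical PM ring a few
    pixels wide with a handful of endocytic vesicles strictly interior to
    it, over a low uniform background.
    """

    shape: tuple[int, int] = (128, 128)
    cell_center: tuple[float, float] = (64.0, 64.0)
    cell_semiaxes: tuple[float, float] = (48.0, 38.0)
    ring_width_px: float = 3.0
    n_vesicles: int = 8
    vesicle_radius_px: tuple[float, float] = (2.0, 4.0)
    vesicle_margin_px: float = 6.0
    pm_brightness: float = 1000.0
    vesicle_brightness: float = 1000.0
    background_level: float = 20.0
    #: ratio of released-alcohol to caged-ester brightness (the coumarin
    #: esters and the alcohol have near-identical photophysics, hence 1.0)
    alcohol_brightness_ratio: float = 1.0
    psf_sigma_px: float = 1.0
    shot_noise: bool = True
    read_noise_sigma: float = 2.0
    camera_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("image too small")
        a, b = self.cell_semiaxes
        if a <= 0 or b <= 0 or self.ring_width_px <= 0:
            raise ValueError("cell geometry must be positive")
        if self.ring_width_px >= min(a, b):
            raise ValueError("degenerate geometry: ring width >= cell semiaxis")
        lo, hi = self.vesicle_radius_px
        if not (0 < lo <= hi):
            raise ValueError("vesicle radius range must be positive and ordered")
        if self.n_vesicles < 0 or self.vesicle_margin_px < 0:
            raise ValueError("vesicle count and margin must be >= 0")
        if self.pm_brightness <= 0 or self.vesicle_brightness <= 0:
            raise ValueError("brightness must be positive")
        if self.background_level < 0 or self.read_noise_sigma < 0 or self.camera_offset < 0:
            raise ValueError("background, read noise and offset must be >= 0")


def _ellipse_radius(shape: tuple[int, int], center, semiaxes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    a, b = semiaxes
    return np.sqrt(((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2)


def _build_masks(scene: SceneParams, rng: np.random.Generator) -> tuple[CompartmentMasks, np.ndarray]:
    """Return masks plus the per-vesicle footprint image (vesicle weight map)."""
    a, b = scene.cell_semiaxes
    r_outer = _ellipse_radius(scene.shape, scene.cell_center, (a, b))
    r_inner = _ellipse_radius(
        scene.shape,
        scene.cell_center,
        (a - scene.ring_width_px, b - scene.ring_width_px),
    )
    pm = (r_outer <= 1.0) & (r_inner > 1.0)
    interior = r_inner <= 1.0
    # background excludes a 3-sigma PSF halo around the cell
    halo = scene.psf_sigma_px * 3.0
    r_halo = _ellipse_radius(scene.shape, scene.cell_center, (a + halo, b + halo))
    background = r_halo > 1.0

    # place vesicles strictly interior, clear of the ring and of each other
    rr, cc = np.mgrid[0 : scene.shape[0], 0 : scene.shape[1]]
    vesicles = np.zeros(scene.shape, dtype=bool)
    placed: list[tuple[float, float, float]] = []
    margin = scene.vesicle_margin_px
    attempts = 0
    while len(placed) < scene.n_vesicles and attempts < 1000 * max(scene.n_vesicles, 1):
        attempts += 1
        y = rng.uniform(0, scene.shape[0])
        x = rng.uniform(0, scene.shape[1])
        radius = rng.uniform(*scene.vesicle_radius_px)
        r_here = _ellipse_radius(
            scene.shape,
            scene.cell_center,
            (a - scene.ring_width_px - margin - radius, b - scene.ring_width_px - margin - radius),
        )[int(y) % scene.shape[0], int(x) % scene.shape[1]]
        if r_here > 1.0:
            continue
        if any((y - py) ** 2 + (x - px) ** 2 < (radius + pr + 2.0) ** 2 for py, px, pr in placed):
            continue
        placed.append((y, x, radius))
        vesicles |= (rr - y) ** 2 + (cc - x) ** 2 <= radius**2
    if len(placed) < scene.n_vesicles:
        raise ValueError("could not place all vesicles; enlarge cell or reduce count")
    vesicles &= interior
    return CompartmentMasks(pm=pm, vesicles=vesicles, background=background), vesicles.astype(float)


def _frame_expected(
    scene: SceneParams,
    masks: CompartmentMasks,
    vesicle_map: np.ndarray,
    pm_scale: float,
    ves_scale: float,
) -> np.ndarray:
    ideal = np.full(scene.shape, float(scene.background_level))
    ideal += scene.pm_brightness * pm_scale * masks.pm
    ideal += scene.vesicle_brightness * ves_scale * vesicle_map
    if scene.psf_sigma_px > 0:
        ideal = gaussian_filter(ideal, scene.psf_sigma_px, mode="nearest")
    return ideal


def render_stack(
    scene: SceneParams,
    reaction: PhotoreactionParams,
    n_pre: int = 5,
    n_post: int = 10,
    laser_level: float = 0.0,
    frame_interval_s: float = 1.0,
) -> tuple[ImageStack, CompartmentMasks, dict[str, CompartmentFractions]]:
    """Render a photoactivation time-lapse with ground truth.

    Pre-frames carry full label brightness; every post-frame is scaled per
    compartment by its still-fluorescent fraction (uncaging is treated as
    instantaneous between the last pre- and first post-frame).  The same
    seed always yields bit-identical pixels.

    Returns
    -------
    (ImageStack, CompartmentMasks, ground_truth)
        ``ground_truth`` maps ``"pm"`` / ``"vesicle"`` to their closed-form
        :class:`~uncagekit.photochemistry.CompartmentFractions`.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("need at least one pre- and one post-frame")

    rng = np.random.default_rng(scene.seed)
    masks, vesicle_map = _build_masks(scene, rng)

    truth = {
        "pm": photochemistry_closed_form(reaction, "pm"),
        "vesicle": photochemistry_closed_form(reaction, "vesicle"),
    }
    ratio = scene.alcohol_brightness_ratio
    pm_post = truth["pm"].caged + ratio * truth["pm"].alcohol_retained
    ves_post = truth["vesicle"].caged + ratio * truth["vesicle"].alcohol_retained

    frames = []
    pre_expected = _frame_expected(scene, masks, vesicle_map, 1.0, 1.0)
    post_expected = _frame_expected(scene, masks, vesicle_map, pm_post, ves_post)
    for i in range(n_pre + n_post):
        expected = pre_expected if i < n_pre else post_expected
        frame = rng.poisson(expected).astype(float) if scene.shot_noise else expected.copy()
        if scene.read_noise_sigma > 0:
            frame = frame + rng.normal(0.0, scene.read_noise_sigma, scene.shape)
        frame = frame + scene.camera_offset
        frames.append(np.clip(frame, 0.0, None))

    stack = ImageStack(
        pixels=np.stack(frames),
        frame_interval_s=frame_interval_s,
        uncaging_frame=n_pre,
        laser_level=laser_level,
    )
    return stack, masks, truth


def simulate_titration(
    scene: SceneParams,
    base_rates: PhotoreactionParams,
    laser_levels: list[float],
    dose_per_percent: float,
    n_scans: int = 1,
    n_pre: int = 5,
    n_post: int = 10,
    seed: int | None = None,
) -> list[tuple[ImageStack, CompartmentMasks, dict[str, CompartmentFractions]]]:
    """Render one stack per laser level with dose = dose_per_percent × level × n_scans.

    Laser levels must be strictly increasing.  Each stack gets an
    independent random sub-stream derived from the top-level seed, so the
    whole series is reproducible from one integer.
    """
    if not laser_levels:
        raise ValueError("laser_levels must be non-empty")
    if any(b <= a for a, b in zip(laser_levels, laser_levels[1:])):
        raise ValueError("laser_levels must be strictly increasing")
    if dose_per_percent <= 0:
        raise ValueError("dose_per_percent must be positive")
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")

    master = scene.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).spawn(len(laser_levels))
    out = []
    for level, child in zip(laser_levels, child_seeds):
        reaction = base_rates.with_dose(dose_per_percent * level * n_scans)
        level_scene = replace(scene, seed=int(child.generate_state(1)[0] % (2**31)))
        out.append(
            render_stack(
                level_scene, reaction, n_pre=n_pre, n_post=n_post, laser_level=level
            )
        )
    return out
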