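"""Synthetic 3-chamber cine phantom with a known ground-truth Ao:LV ratio.

Renders a 2D+time image stack containing an elliptical left-ventricular
blood pool (contracting sinusoidally so end-systole sits at a chosen frame),
a myocardial ring, and an ascending-aorta band whose lumen signal is the LV
blood signal attenuated by the ground-truth ratio — a phenomenological
stand-in for the turbulence-induced flow void of aortic stenosis, not a
physics simulation of intravoxel dephasing.  Magnitude-image noise is
Rician, which coincides with Gaussian noise at high SNR.

Coordinate convention: (row, col), 0-based, physical mm = index x spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PhantomSpec",
    "CineSeries",
    "LandmarkSet",
    "RenderError",
    "render_phantom",
]

AORTA_BAND_LENGTH_MM = 40.0  # band length along the aorta axis; >= 3 cm so
                             # the "1 cm above the leaflets" ROI always fits


class RenderError(ValueError):
    """Raised when phantom geometry cannot be rendered (e.g. aorta off-image)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of a synthetic 3-chamber cine.

    Distances are mm in (row, col) order; intensities are arbitrary units.
    ``true_ratio`` is the ground-truth Ao:LV blood-signal ratio painted into
    the aortic lumen.
    """

    image_shape: tuple[int, int] = (192, 192)
    pixel_spacing: tuple[float, float] = (1.46, 1.46)  # mm (row, col)
    n_frames: int = 30
    end_systolic_frame: int = 10
    lv_center: tuple[float, float] = (190.0, 120.0)  # mm
    lv_semi_axes_diastole: tuple[float, float] = (42.0, 28.0)  # mm
    lv_contraction_fraction: float = 0.35
    myocardial_thickness: float = 9.0  # mm
    valve_point: tuple[float, float] = (130.0, 150.0)  # mm
    aorta_direction: tuple[float, float] = (-1.0, 0.0)  # unit vector
    aorta_diameter: float = 30.0  # mm
    blood_signal: float = 186.2
    myocardium_signal: float = 70.0
    true_ratio: float = 1.0
    noise_sigma: float = 0.0
    frame_interval_ms: float = 35.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.pixel_spacing) <= 0:
            raise RenderError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.n_frames < 2:
            raise RenderError(f"n_frames must be >= 2, got {self.n_frames}")
        if not 0 <= self.end_systolic_frame < self.n_frames:
            raise RenderError(
                f"end_systolic_frame {self.end_systolic_frame} outside "
                f"[0, {self.n_frames})"
            )
        if self.true_ratio <= 0:
            raise RenderError(f"true_ratio must be > 0, got {self.true_ratio}")
        if not 0.0 < self.lv_contraction_fraction < 1.0:
            raise RenderError("lv_contraction_fraction must lie in (0, 1)")
        norm = float(np.hypot(*self.aorta_direction))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise RenderError(
                f"aorta_direction must have unit norm, got |d| = {norm:.6f}"
            )
        if self.noise_sigma < 0:
            raise RenderError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class CineSeries:
    """Multi-frame intensity image with spatial/temporal metadata."""

    intensities: np.ndarray  # (frames, rows, cols), non-negative
    pixel_spacing: tuple[float, float]  # mm (row, col)
    frame_times: np.ndarray  # ms
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise ValueError("intensities must be (frames >= 2, rows, cols)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(
            self, "frame_times", np.asarray(self.frame_times, dtype=float)
        )

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]


@dataclass(frozen=True)
class LandmarkSet:
    """Geometric anchors for ROI placement plus per-frame LV cavity masks."""

    valve_point: tuple[float, float]  # mm
    aorta_direction: tuple[float, float]  # unit vector
    lv_center: tuple[float, float]  # mm
    lv_masks: np.ndarray  # (frames, rows, cols) bool

    def __post_init__(self):
        object.__setattr__(self, "lv_masks", np.asarray(self.lv_masks, dtype=bool))


def _pixel_center_grid(shape: tuple[int, int], spacing: tuple[float, float]):
    rows = np.arange(shape[0])[:, None] * spacing[0]
    cols = np.arange(shape[1])[None, :] * spacing[1]
    return rows, cols


def _lv_mask(spec: PhantomSpec, frame: int) -> np.ndarray:
    """LV cavity ellipse at one frame; pixel centers inside the ellipse."""
    scale = _contraction_scale(spec, frame)
    a = spec.lv_semi_axes_diastole[0] * scale
    b = spec.lv_semi_axes_diastole[1] * scale
    rows, cols = _pixel_center_grid(spec.image_shape, spec.pixel_spacing)
    return ((rows - spec.lv_center[0]) / a) ** 2 + (
        (cols - spec.lv_center[1]) / b
    ) ** 2 < 1.0


def _contraction_scale(spec: PhantomSpec, frame: int) -> float:
    # Sinusoidal contraction with its unique maximum (smallest cavity)
    # exactly at the end-systolic frame.
    phase = 2.0 * np.pi * (frame - spec.end_systolic_frame) / spec.n_frames
    w = 0.5 * (1.0 + np.cos(phase))
    return 1.0 - spec.lv_contraction_fraction * w


def _aorta_mask(spec: PhantomSpec) -> np.ndarray:
    """Constant-width band from the valve point along the aorta direction."""
    d = np.asarray(spec.aorta_direction, dtype=float)
    p0 = np.asarray(spec.valve_point, dtype=float)
    rows, cols = _pixel_center_grid(spec.image_shape, spec.pixel_spacing)
    dr = rows - p0[0]
    dc = cols - p0[1]
    along = dr * d[0] + dc * d[1]
    across = dr * (-d[1]) + dc * d[0]
    return (
        (along >= 0.0)
        & (along <= AORTA_BAND_LENGTH_MM)
        & (np.abs(across) <= spec.aorta_diameter / 2.0)
    )


def _check_aorta_in_image(spec: PhantomSpec) -> None:
    extent = (
        (spec.image_shape[0] - 1) * spec.pixel_spacing[0],
        (spec.image_shape[1] - 1) * spec.pixel_spacing[1],
    )
    d = np.asarray(spec.aorta_direction, dtype=float)
    p0 = np.asarray(spec.valve_point, dtype=float)
    for s in (0.0, AORTA_BAND_LENGTH_MM):
        p = p0 + s * d
        if not (0.0 <= p[0] <= extent[0] and 0.0 <= p[1] <= extent[1]):
            raise RenderError(
                f"aorta (valve_point={spec.valve_point}, "
                f"direction={spec.aorta_direction}) leaves the image at {tuple(p)} mm"
            )


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex signal with i.i.d. Gaussian noise on each channel."""
    if sigma == 0.0:
        return clean
    re = clean + rng.normal(0.0, sigma, clean.shape)
    im = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(re, im)


def render_phantom(spec: PhantomSpec) -> tuple[CineSeries, LandmarkSet, float]:
    """Render the phantom cine; returns (series, landmarks, ground-truth ratio).

    The LV blood pool is painted at ``blood_signal``, the aortic lumen at
    ``blood_signal * true_ratio`` (the flow-void model), the myocardial ring
    at ``myocardium_signal``; Rician noise of scale ``noise_sigma`` is then
    applied frame-wise.
    """
    spec.validate()
    _check_aorta_in_image(spec)
    rng = np.random.default_rng(spec.seed)

    rows, cols = _pixel_center_grid(spec.image_shape, spec.pixel_spacing)
    aorta = _aorta_mask(spec)

    frames = []
    masks = []
    for t in range(spec.n_frames):
        scale = _contraction_scale(spec, t)
        a = spec.lv_semi_axes_diastole[0] * scale
        b = spec.lv_semi_axes_diastole[1] * scale
        ellipse = ((rows - spec.lv_center[0]) / a) ** 2 + (
            (cols - spec.lv_center[1]) / b
        ) ** 2
        cavity = ellipse < 1.0
        a_out = a + spec.myocardial_thickness
        b_out = b + spec.myocardial_thickness
        ring = (
            ((rows - spec.lv_center[0]) / a_out) ** 2
            + ((cols - spec.lv_center[1]) / b_out) ** 2
            < 1.0
        ) & ~cavity

        img = np.zeros(spec.image_shape, dtype=float)
        img[ring] = spec.myocardium_signal
        img[cavity] = spec.blood_signal
        img[aorta & ~cavity & ~ring] = spec.blood_signal * spec.true_ratio

        frames.append(_rician(img, spec.noise_sigma, rng))
        masks.append(cavity)

    series = CineSeries(
        intensities=np.stack(frames),
        pixel_spacing=spec.pixel_spacing,
        frame_times=np.arange(spec.n_frames) * spec.frame_interval_ms,
        metadata={"source": "aolvratio.phantom", "true_ratio": spec.true_ratio,
                  "seed": spec.seed},
    )
    landmarks = LandmarkSet(
        valve_point=spec.valve_point,
        aorta_direction=spec.aorta_direction,
        lv_center=spec.lv_center,
        lv_masks=np.stack(masks),
    )
    return series, landmarks, spec.true_ratio
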