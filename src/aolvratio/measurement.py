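"""Rule-based Ao:LV ratio measurement on a 3-chamber cine.

Protocol: select the end-systolic frame (smallest LV cavity), place a
~1 cm^2 circular ROI in the ascending aorta 10 mm above the valve leaflets
along the aortic axis and a second ROI at the LV cavity centre, average the
blood signal inside each, and report the aorta/LV ratio.  Severity calls use
two ratio cut-offs: below ``any_as_cutoff`` suggests aortic stenosis of any
severity, below ``severe_cutoff`` suggests severe stenosis; boundary values
go to the less-diseased class ("<" operator).

A pixel belongs to an ROI iff its center lies strictly inside the disc.
Coordinates are (row, col), 0-based, physical mm = index x spacing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .phantom import CineSeries, LandmarkSet

__all__ = [
    "RoiSpec",
    "RatioMeasurement",
    "CutoffScheme",
    "SeverityCall",
    "MeasurementError",
    "PlacementError",
    "ROI_AREA_CM2",
    "AORTA_ROI_OFFSET_MM",
    "select_end_systolic_frame",
    "place_rois",
    "roi_pixel_mask",
    "mean_roi_signal",
    "compute_ratio",
    "classify_severity",
    "measure_series",
]

ROI_AREA_CM2 = 1.0
AORTA_ROI_OFFSET_MM = 10.0  # "approximately 1 cm above the leaflets"
ROI_AREA_TOLERANCE = 0.10   # realised pixel area within 10% of target


class MeasurementError(ValueError):
    """Raised when a signal measurement cannot be made."""


class PlacementError(MeasurementError):
    """Raised when an ROI cannot be placed per the protocol rules."""


class SeverityCall(enum.Enum):
    """Three-way severity call from the ratio cut-offs."""

    NO_AS = "no_AS"
    NON_SEVERE_AS = "non_severe_AS"
    SEVERE_AS = "severe_AS"


@dataclass(frozen=True)
class CutoffScheme:
    """Ratio cut-offs: < any_as_cutoff flags any AS, < severe_cutoff severe AS."""

    any_as_cutoff: float = 0.86
    severe_cutoff: float = 0.58

    def __post_init__(self):
        if not 0.0 < self.severe_cutoff < self.any_as_cutoff:
            raise ValueError(
                f"require 0 < severe_cutoff < any_as_cutoff, got "
                f"{self.severe_cutoff} / {self.any_as_cutoff}"
            )


@dataclass(frozen=True)
class RoiSpec:
    """A circular ROI: center in mm (row, col), target area in cm^2, frame index."""

    center: tuple[float, float]
    area_cm2: float = ROI_AREA_CM2
    frame_index: int = 0

    @property
    def radius_mm(self) -> float:
        return float(np.sqrt(self.area_cm2 * 100.0 / np.pi))


@dataclass(frozen=True)
class RatioMeasurement:
    """One Ao:LV ratio measurement with its provenance."""

    aorta_mean: float
    lv_mean: float
    ratio: float
    frame_index: int
    aorta_roi: RoiSpec
    lv_roi: RoiSpec

    @property
    def ratio_display(self) -> float:
        """The ratio rounded to 2 decimals, as reported clinically."""
        return round(self.ratio, 2)


def select_end_systolic_frame(cine: CineSeries, landmarks: LandmarkSet) -> int:
    """Index of the frame with the smallest LV cavity area; ties -> earliest.

    Cavity area is mask pixel count x pixel area (mm^2).  This
    operationalises the visual "smallest LV cavity" rule from masks.
    """
    masks = np.asarray(landmarks.lv_masks, dtype=bool)
    if masks.shape[0] != cine.n_frames:
        raise MeasurementError(
            f"landmarks carry {masks.shape[0]} LV masks for {cine.n_frames} frames"
        )
    counts = masks.reshape(masks.shape[0], -1).sum(axis=1)
    if np.any(counts == 0):
        empty = int(np.argmax(counts == 0))
        raise MeasurementError(f"empty LV mask at frame {empty}")
    # pixel area is a common positive factor; argmin of counts suffices,
    # and numpy argmin already returns the earliest minimiser
    return int(np.argmin(counts))


def roi_pixel_mask(
    roi: RoiSpec, shape: tuple[int, int], spacing: tuple[float, float]
) -> np.ndarray:
    """Boolean mask of pixels whose centers lie strictly inside the ROI disc."""
    rows = np.arange(shape[0])[:, None] * spacing[0]
    cols = np.arange(shape[1])[None, :] * spacing[1]
    return (rows - roi.center[0]) ** 2 + (cols - roi.center[1]) ** 2 < roi.radius_mm**2


def _check_roi_in_image(
    roi: RoiSpec, shape: tuple[int, int], spacing: tuple[float, float], name: str
) -> None:
    r = roi.radius_mm
    extent = ((shape[0] - 1) * spacing[0], (shape[1] - 1) * spacing[1])
    for axis in (0, 1):
        if roi.center[axis] - r < 0 or roi.center[axis] + r > extent[axis]:
            raise PlacementError(
                f"{name} ROI at {roi.center} mm (radius {r:.2f} mm) extends "
                f"beyond the image (extent {extent} mm)"
            )


def place_rois(
    landmarks: LandmarkSet,
    spacing: tuple[float, float],
    frame: int,
    image_shape: tuple[int, int] | None = None,
) -> tuple[RoiSpec, RoiSpec]:
    """Place the aortic and LV ROIs per protocol on the given frame.

    The aortic ROI centre sits ``AORTA_ROI_OFFSET_MM`` above the valve point
    along the aortic direction; the LV ROI centre is the LV cavity centre.
    Both are 1 cm^2 discs.  Raises :class:`PlacementError` if an ROI leaves
    the image or the LV ROI leaves the LV cavity mask.
    """
    if min(spacing) <= 0:
        raise PlacementError(f"pixel spacing must be > 0, got {spacing}")
    d = np.asarray(landmarks.aorta_direction, dtype=float)
    ao_center = tuple(np.asarray(landmarks.valve_point, dtype=float) + AORTA_ROI_OFFSET_MM * d)
    aorta = RoiSpec(center=ao_center, frame_index=frame)
    lv = RoiSpec(center=tuple(landmarks.lv_center), frame_index=frame)

    shape = image_shape
    if shape is None:
        shape = np.asarray(landmarks.lv_masks).shape[1:]
    _check_roi_in_image(aorta, shape, spacing, "aorta")
    _check_roi_in_image(lv, shape, spacing, "LV")

    lv_pixels = roi_pixel_mask(lv, shape, spacing)
    frame_mask = np.asarray(landmarks.lv_masks, dtype=bool)[frame]
    if np.any(lv_pixels & ~frame_mask):
        raise PlacementError(
            f"LV ROI at {lv.center} mm extends outside the LV cavity mask on "
            f"frame {frame}"
        )
    for roi, name in ((aorta, "aorta"), (lv, "LV")):
        n_px = int(roi_pixel_mask(roi, shape, spacing).sum())
        realised = n_px * spacing[0] * spacing[1] / 100.0  # cm^2
        if abs(realised - roi.area_cm2) > ROI_AREA_TOLERANCE * roi.area_cm2:
            raise PlacementError(
                f"{name} ROI realises {realised:.3f} cm^2 on this pixel grid "
                f"(target {roi.area_cm2} cm^2 +/- {ROI_AREA_TOLERANCE:.0%})"
            )
    return aorta, lv


def mean_roi_signal(
    frame_image: np.ndarray, roi: RoiSpec, spacing: tuple[float, float]
) -> float:
    """Arithmetic mean intensity over pixels whose centers fall in the ROI disc."""
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise MeasurementError("frame_image must be 2-D")
    _check_roi_in_image(roi, img.shape, spacing, "requested")
    mask = roi_pixel_mask(roi, img.shape, spacing)
    if not mask.any():
        raise MeasurementError(f"ROI at {roi.center} mm selects zero pixels")
    return float(img[mask].mean())


def compute_ratio(
    aorta_mean: float,
    lv_mean: float,
    frame_index: int = 0,
    aorta_roi: RoiSpec | None = None,
    lv_roi: RoiSpec | None = None,
) -> RatioMeasurement:
    """Ao:LV ratio = mean aortic blood signal / mean LV blood signal."""
    if lv_mean <= 0:
        raise MeasurementError(f"LV mean signal must be > 0, got {lv_mean}")
    ratio = aorta_mean / lv_mean
    placeholder = RoiSpec(center=(np.nan, np.nan), frame_index=frame_index)
    return RatioMeasurement(
        aorta_mean=float(aorta_mean),
        lv_mean=float(lv_mean),
        ratio=float(ratio),
        frame_index=frame_index,
        aorta_roi=aorta_roi if aorta_roi is not None else placeholder,
        lv_roi=lv_roi if lv_roi is not None else placeholder,
    )


def classify_severity(ratio: float, scheme: CutoffScheme | None = None) -> SeverityCall:
    """Three-way severity call; boundary values go to the less-diseased class."""
    scheme = scheme if scheme is not None else CutoffScheme()
    if ratio <= 0:
        raise MeasurementError(f"ratio must be > 0, got {ratio}")
    if ratio < scheme.severe_cutoff:
        return SeverityCall.SEVERE_AS
    if ratio < scheme.any_as_cutoff:
        return SeverityCall.NON_SEVERE_AS
    return SeverityCall.NO_AS


def measure_series(
    cine: CineSeries,
    landmarks: LandmarkSet,
    scheme: CutoffScheme | None = None,
) -> tuple[RatioMeasurement, SeverityCall]:
    """Full protocol: frame selection, ROI placement, means, ratio, call."""
    frame = select_end_systolic_frame(cine, landmarks)
    aorta_roi, lv_roi = place_rois(
        landmarks, cine.pixel_spacing, frame, image_shape=cine.image_shape
    )
    img = cine.intensities[frame]
    aorta_mean = mean_roi_signal(img, aorta_roi, cine.pixel_spacing)
    lv_mean = mean_roi_signal(img, lv_roi, cine.pixel_spacing)
    meas = compute_ratio(aorta_mean, lv_mean, frame, aorta_roi, lv_roi)
    return meas, classify_severity(meas.ratio, scheme)
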