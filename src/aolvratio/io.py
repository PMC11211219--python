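"""Readers and writers for cine stacks and landmark annotations.

Cine stacks travel either as a NIfTI volume (frames on the 4th axis) or as
a minimal single-frame-per-file DICOM series (PixelSpacing and
InstanceNumber populated).  Landmarks travel as JSON.

Landmark JSON schema (all coordinates mm, (row, col) order, 0-based pixel
indexing; masks are nested 0/1 lists, frames x rows x cols)::

    {
      "schema": "aolv-landmarks-1",
      "valve_point_mm": [r, c],
      "aorta_direction": [dr, dc],      # unit vector
      "lv_center_mm": [r, c],
      "lv_masks": [[[0, 1, ...], ...], ...]
    }
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .phantom import CineSeries, LandmarkSet

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_dicom_series",
    "read_dicom_series",
    "write_landmarks_json",
    "read_landmarks_json",
    "load_cine",
]

LANDMARK_SCHEMA = "aolv-landmarks-1"


# --- NIfTI ----------------------------------------------------------------

def write_nifti(series: CineSeries, path) -> None:
    """Write a cine as NIfTI with frames on the 4th axis.

    The array is stored (rows, cols, 1, frames); pixel spacing goes into the
    affine / pixdim, the frame interval into pixdim[4] (ms).
    """
    import nibabel as nib

    arr = np.transpose(series.intensities, (1, 2, 0))[:, :, None, :]
    affine = np.diag([series.pixel_spacing[0], series.pixel_spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(arr.astype(np.float32), affine)
    dt = float(np.diff(series.frame_times).mean()) if series.n_frames > 1 else 0.0
    img.header["pixdim"][4] = dt
    nib.save(img, str(path))


def read_nifti(path) -> CineSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D cine NIfTI, got shape {data.shape}")
    frames = np.transpose(data[:, :, 0, :], (2, 0, 1))
    zooms = img.header.get_zooms()
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return CineSeries(
        intensities=frames,
        pixel_spacing=(float(zooms[0]), float(zooms[1])),
        frame_times=np.arange(frames.shape[0]) * dt,
        metadata={"source": str(path)},
    )


# --- DICOM ----------------------------------------------------------------

def write_dicom_series(series: CineSeries, directory) -> list[Path]:
    """Write one DICOM file per frame into ``directory``.

    Intensities are linearly rescaled to uint16 with RescaleSlope/Intercept
    recording the inverse map; InstanceNumber is the 1-based frame index.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    peak = float(series.intensities.max())
    slope = peak / 65535.0 if peak > 0 else 1.0

    paths = []
    for i, frame in enumerate(series.intensities):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.TriggerTime = float(series.frame_times[i])
        ds.Rows, ds.Columns = frame.shape
        ds.PixelSpacing = [f"{series.pixel_spacing[0]:.6f}",
                           f"{series.pixel_spacing[1]:.6f}"]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{slope:.10g}"
        ds.RescaleIntercept = "0"
        ds.PixelData = np.round(frame / slope).astype(np.uint16).tobytes()

        path = directory / f"frame_{i + 1:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(directory) -> CineSeries:
    """Read a single-frame-per-file DICOM series, ordered by InstanceNumber."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise ValueError(f"no .dcm files found in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: int(d.InstanceNumber))
    frames = []
    times = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(ds.pixel_array.astype(float) * slope + intercept)
        times.append(float(getattr(ds, "TriggerTime", len(times))))
    spacing = tuple(float(v) for v in datasets[0].PixelSpacing)
    return CineSeries(
        intensities=np.stack(frames),
        pixel_spacing=spacing,  # type: ignore[arg-type]
        frame_times=np.asarray(times),
        metadata={"source": str(directory), "n_files": len(files)},
    )


# --- landmarks ------------------------------------------------------------

def write_landmarks_json(landmarks: LandmarkSet, path) -> None:
    doc = {
        "schema": LANDMARK_SCHEMA,
        "valve_point_mm": [float(v) for v in landmarks.valve_point],
        "aorta_direction": [float(v) for v in landmarks.aorta_direction],
        "lv_center_mm": [float(v) for v in landmarks.lv_center],
        "lv_masks": np.asarray(landmarks.lv_masks, dtype=int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_landmarks_json(path) -> LandmarkSet:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != LANDMARK_SCHEMA:
        raise ValueError(f"unrecognised landmark schema: {doc.get('schema')!r}")
    return LandmarkSet(
        valve_point=tuple(doc["valve_point_mm"]),
        aorta_direction=tuple(doc["aorta_direction"]),
        lv_center=tuple(doc["lv_center_mm"]),
        lv_masks=np.asarray(doc["lv_masks"], dtype=bool),
    )


def load_cine(path) -> CineSeries:
    """Load a cine from a NIfTI file or a DICOM series directory."""
    p = Path(path)
    if p.is_dir():
        return read_dicom_series(p)
    return read_nifti(p)
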