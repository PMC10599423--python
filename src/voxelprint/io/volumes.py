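"""Scalar-volume input: DICOM series and NIfTI-1.

Intensities are min-max normalized to [0, 1] on read; geometry (spacing,
origin) comes from the file metadata.  DICOM series must share one
axis-aligned orientation and have uniform slice spacing (gantry-tilted
series are rejected).  A minimal DICOM series writer is provided for
round-trip verification and synthetic fixtures; it is not a clinical
exporter.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from ..grid import GridSpec
from ..volume import ScalarVolume

__all__ = ["read_scalar_volume", "write_nifti", "write_dicom_series"]

_INT_DEPTH = {np.uint8: 8, np.int8: 8, np.uint16: 16, np.int16: 16}


def _normalize(raw: np.ndarray) -> np.ndarray:
    raw = raw.astype(np.float64)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def _bit_depth(dtype: np.dtype) -> int:
    for t, d in _INT_DEPTH.items():
        if dtype == np.dtype(t):
            return d
    if np.issubdtype(dtype, np.floating):
        # float data (e.g. our own NIfTI writer) is treated as 16-bit class
        return 16
    raise ValueError(f"unsupported source bit depth / dtype: {dtype}")


def read_scalar_volume(path: str | Path, format: str | None = None) -> ScalarVolume:
    """Read a scalar volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom_series"``; if omitted it is
    inferred from the path (directory -> DICOM series, file -> NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown volume format {format!r}")


def _read_nifti(path: Path) -> ScalarVolume:
    img = nib.load(str(path))
    raw = np.asanyarray(img.dataobj)
    if raw.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {raw.shape}")
    depth = _bit_depth(raw.dtype)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    grid = GridSpec(dims=raw.shape, spacing=tuple(float(z) for z in zooms), origin=origin)
    return ScalarVolume(grid, _normalize(raw), depth)


def _read_dicom_series(path: Path) -> ScalarVolume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ""))
    files = [p for p in files if p.is_file()]
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    slices = [pydicom.dcmread(str(p)) for p in files]

    orientations = {tuple(np.round(s.ImageOrientationPatient, 6)) for s in slices}
    if len(orientations) != 1:
        raise ValueError("DICOM series has mixed image orientations")
    orient = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row, col = orient[:3], orient[3:]
    normal = np.cross(row, col)
    if not (
        np.allclose(np.abs(row), [1, 0, 0]) and np.allclose(np.abs(col), [0, 1, 0])
    ):
        raise ValueError(
            "only axis-aligned (non-tilted) DICOM series are supported"
        )

    slices.sort(key=lambda s: float(np.dot(s.ImagePositionPatient, normal)))
    zpos = np.array(
        [float(np.dot(s.ImagePositionPatient, normal)) for s in slices]
    )
    if len(zpos) > 1:
        deltas = np.diff(zpos)
        if deltas.min() <= 0 or not np.allclose(deltas, deltas[0], atol=1e-4):
            raise ValueError("nonuniform or degenerate DICOM slice spacing")
        dz = float(deltas[0])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    stack = np.stack([s.pixel_array for s in slices])  # (nz, rows, cols)
    depth = _bit_depth(stack.dtype)
    ps = slices[0].PixelSpacing  # (row spacing, col spacing)
    spacing = (float(ps[1]), float(ps[0]), dz)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    intensities = _normalize(stack.transpose(2, 1, 0))  # -> (x, y, z)
    grid = GridSpec(dims=intensities.shape, spacing=spacing, origin=origin)
    return ScalarVolume(grid, intensities, depth)


def write_nifti(volume: ScalarVolume, path: str | Path, dtype=np.uint16) -> Path:
    """Write a scalar volume to NIfTI-1, quantized to ``dtype``.

    Integer dtypes store ``round(intensity * max_value)``; reading back
    recovers the intensities exactly when the volume attains both 0 and 1
    (min-max normalization is its own inverse then).
    """
    path = Path(path)
    dtype = np.dtype(dtype)
    if np.issubdtype(dtype, np.integer):
        scale = float(np.iinfo(dtype).max)
        data = np.round(volume.intensities * scale).astype(dtype)
    else:
        data = volume.intensities.astype(dtype)
    affine = np.diag(list(volume.grid.spacing) + [1.0])
    affine[:3, 3] = volume.grid.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))
    return path


def write_dicom_series(volume: ScalarVolume, directory: str | Path, bits: int = 16) -> Path:
    """Write a volume as a minimal axial DICOM series (fixture/round-trip use)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    dtype = np.uint8 if bits == 8 else np.uint16
    scale = float(np.iinfo(dtype).max)
    data = np.round(volume.intensities * scale).astype(dtype)
    nx, ny, nz = volume.grid.dims
    sx, sy, sz = volume.grid.spacing
    ox, oy, oz = volume.grid.origin
    series_uid = generate_uid()
    study_uid = generate_uid()
    for k in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "OT"
        ds.PatientName = "SYNTHETIC^PHANTOM"
        ds.PatientID = "SYNTH"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [ox, oy, oz + k * sz]
        ds.PixelSpacing = [sy, sx]  # (row, col)
        ds.SliceThickness = sz
        ds.Rows = ny
        ds.Columns = nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = bits
        ds.BitsStored = bits
        ds.HighBit = bits - 1
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(data[:, :, k].T).tobytes()
        ds.save_as(
            str(directory / f"slice_{k:04d}.dcm"),
            enforce_file_format=True,
        )
    return directory
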