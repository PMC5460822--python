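"""Volume I/O: NIfTI-1 image/mask pairs and DICOM series directories.

Arrays follow the package convention ``values[x, y, z]``. NIfTI files are
written with a diagonal affine holding the voxel spacing; images as
float32, masks as uint8. DICOM series are assembled by sorting slices on
their position along the slice normal, so shuffled file order is harmless.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .volume import ImageVolume, ROIMask

__all__ = [
    "save_nifti_pair",
    "load_nifti",
    "load_dicom_series",
    "load_volume",
    "write_dicom_series",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_nifti_pair(image: ImageVolume, mask: ROIMask, image_path, mask_path) -> None:
    """Write an image/mask pair as NIfTI-1, spacing recorded in the header."""
    mask.check_congruent(image)
    img = nib.Nifti1Image(image.values.astype(np.float32), _affine(image.spacing))
    img.header.set_zooms(image.spacing)
    nib.save(img, str(image_path))
    msk = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing))
    msk.header.set_zooms(mask.spacing)
    nib.save(msk, str(mask_path))


def _read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_nifti(image_path, mask_path) -> tuple[ImageVolume, ROIMask]:
    """Load an image and its binary mask (> 0) from NIfTI files."""
    values, spacing = _read_nifti(image_path)
    mvals, mspacing = _read_nifti(mask_path)
    if values.shape != mvals.shape:
        raise ValueError(
            f"image shape {values.shape} does not match mask shape {mvals.shape} "
            f"({image_path} vs {mask_path})"
        )
    image = ImageVolume(values, spacing)
    mask = ROIMask(mvals > 0, mspacing)
    mask.check_congruent(image)
    return image, mask


def load_dicom_series(series_dir) -> ImageVolume:
    """Assemble a DICOM series directory into a volume.

    Slices are ordered by the projection of ImagePositionPatient onto the
    slice normal (cross product of the row/column direction cosines), not
    by filename. Rescale slope/intercept are applied when present.
    """
    series_dir = Path(series_dir)
    files = sorted(p for p in series_dir.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no files in DICOM directory {series_dir}")
    slices = []
    for path in files:
        ds = pydicom.dcmread(str(path))
        orient = np.array(ds.ImageOrientationPatient, dtype=float)
        normal = np.cross(orient[:3], orient[3:])
        pos = float(np.dot(np.array(ds.ImagePositionPatient, dtype=float), normal))
        slices.append((pos, ds))
    slices.sort(key=lambda t: t[0])
    positions = [pos for pos, _ in slices]
    datasets = [ds for _, ds in slices]

    first = datasets[0]
    ny, nx = int(first.Rows), int(first.Columns)
    nz = len(datasets)
    values = np.empty((nx, ny, nz), dtype=np.float64)
    for k, ds in enumerate(datasets):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        values[:, :, k] = (arr * slope + intercept).T  # (row, col) -> (x, y)

    sy, sx = (float(v) for v in first.PixelSpacing)  # PixelSpacing is (row, col)
    if nz > 1:
        dz = np.diff(positions)
        sz = float(np.mean(dz))
        if sz <= 0 or not np.allclose(dz, sz, rtol=1e-3):
            raise ValueError(f"non-uniform slice positions in {series_dir}")
    else:
        sz = float(getattr(first, "SliceThickness", 1.0))
    return ImageVolume(values, (sx, sy, sz))


def load_volume(image_path, mask_path) -> tuple[ImageVolume, ROIMask]:
    """Load an image (NIfTI file or DICOM series directory) plus a NIfTI mask."""
    image_path = Path(image_path)
    if image_path.is_dir():
        image = load_dicom_series(image_path)
        mvals, mspacing = _read_nifti(mask_path)
        if mvals.shape != image.shape:
            raise ValueError(
                f"image shape {image.shape} does not match mask shape {mvals.shape} "
                f"({image_path} vs {mask_path})"
            )
        mask = ROIMask(mvals > 0, mspacing)
        mask.check_congruent(image)
        return image, mask
    return load_nifti(image_path, mask_path)


def write_dicom_series(image: ImageVolume, out_dir, filenames=None) -> list[Path]:
    """Write a volume as one secondary-capture DICOM file per slice.

    Intensities are rounded to uint16 (with rescale slope/intercept 1/0);
    intended for synthetic data interchange, not clinical archiving.
    ``filenames`` allows writing slices under arbitrary (e.g. shuffled)
    names to exercise position-based assembly.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    nx, ny, nz = image.shape
    sx, sy, sz = image.spacing
    if filenames is None:
        filenames = [f"slice_{k:04d}.dcm" for k in range(nz)]
    if len(filenames) != nz:
        raise ValueError(f"need {nz} filenames, got {len(filenames)}")
    series_uid = generate_uid()
    vals = np.clip(np.round(image.values), 0, 65535).astype(np.uint16)
    paths = []
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(filenames[k], {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [f"{sy:g}", f"{sx:g}"]
        ds.SliceThickness = f"{sz:g}"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0, 0, float(k * sz)]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = np.ascontiguousarray(vals[:, :, k].T).tobytes()  # (x,y) -> (row,col)
        path = out_dir / filenames[k]
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths
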