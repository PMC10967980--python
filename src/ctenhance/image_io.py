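"""Reading CT volumes and round-tripping 8-bit images and binary masks.

A CT volume arrives either as a directory of single-frame DICOM files (one
series) or as a NIfTI-1 file.  Stored scanner integers are kept as-is in a
:class:`RawVolume` together with the rescale affine; conversion to Hounsfield
units (``HU = stored * slope + intercept``) happens per slice in
:func:`to_hu`.  8-bit grayscale PNG is the export format for enhanced
slices; binary masks travel as {0, 255} PNG or {0, 1} NIfTI and are always
{0, 1} in memory with 1 = foreground (liver).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom

from ctenhance._rounding import to_byte
from ctenhance.errors import FormatError, SeriesInconsistencyError, ValidationError

__all__ = [
    "RawVolume",
    "read_volume",
    "to_hu",
    "normalize_minmax",
    "write_png",
    "read_png",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class RawVolume:
    """Stored scanner integers plus the metadata needed to reach HU.

    ``voxels`` is indexed ``(slice, row, col)``; ``spacing`` is in mm in the
    same axis order.  ``axis_order`` documents that convention for
    downstream consumers.
    """

    voxels: np.ndarray
    rescale_slope: float
    rescale_intercept: float
    spacing: tuple[float, float, float]
    axis_order: str = "slice,row,col"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValidationError(
                f"voxels must be a 3-D array with all extents >= 1, got shape {v.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return int(self.voxels.shape[0])


def read_volume(path: str | Path) -> RawVolume:
    """Read a DICOM series directory or a NIfTI file into a :class:`RawVolume`.

    DICOM slices are ordered by their spatial position along the slice axis
    (ascending), ties broken by instance number.  NIfTI volumes are
    transposed so the last header axis becomes the slice axis.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    raise FormatError(f"not a DICOM directory or NIfTI file: {path}")


def _read_dicom_series(directory: Path) -> RawVolume:
    datasets = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
            ds.pixel_array  # force decode so corrupt pixel data fails here
        except Exception:
            continue
        datasets.append((f, ds))
    if not datasets:
        raise FormatError(f"no readable DICOM files in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for _, ds in datasets}
    if len(uids) > 1:
        raise SeriesInconsistencyError(
            f"directory {directory} mixes {len(uids)} series UIDs: {sorted(uids)}"
        )

    def sort_key(item):
        _, ds = item
        instance = int(getattr(ds, "InstanceNumber", 0))
        pos = getattr(ds, "ImagePositionPatient", None)
        orient = getattr(ds, "ImageOrientationPatient", None)
        if pos is not None:
            if orient is not None:
                row = np.asarray(orient[:3], dtype=float)
                col = np.asarray(orient[3:], dtype=float)
                normal = np.cross(row, col)
                return (float(np.dot(normal, np.asarray(pos, dtype=float))), instance)
            return (float(pos[2]), instance)
        return (float(instance), instance)

    datasets.sort(key=sort_key)
    slices = [ds.pixel_array for _, ds in datasets]
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise SeriesInconsistencyError(f"inconsistent slice shapes in {directory}: {shapes}")
    first = datasets[0][1]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    px = getattr(first, "PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1:
        z0 = sort_key(datasets[0])[0]
        z1 = sort_key(datasets[1])[0]
        dz = abs(z1 - z0) or float(getattr(first, "SliceThickness", 1.0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    voxels = np.stack(slices).astype(np.int32)
    return RawVolume(voxels, slope, intercept, (dz, float(px[0]), float(px[1])))


def _read_nifti(path: Path) -> RawVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    stored = np.asanyarray(img.dataobj.get_unscaled())
    if stored.ndim == 2:
        stored = stored[..., np.newaxis]
    if stored.ndim != 3:
        raise FormatError(f"{path}: expected a 2-D or 3-D volume, got {stored.ndim}-D")
    if not np.issubdtype(stored.dtype, np.integer):
        if not np.allclose(stored, np.round(stored)):
            raise FormatError(f"{path}: stored values are not integers")
        stored = np.round(stored).astype(np.int32)
    hdr = img.header
    slope = float(hdr["scl_slope"]) if np.isfinite(hdr["scl_slope"]) and hdr["scl_slope"] != 0 else 1.0
    inter = float(hdr["scl_inter"]) if np.isfinite(hdr["scl_inter"]) else 0.0
    zooms = img.header.get_zooms()[:3]
    # NIfTI stores (i, j, k); expose (slice, row, col) = (k, j, i)
    voxels = np.ascontiguousarray(stored.transpose(2, 1, 0)).astype(np.int32)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return RawVolume(voxels, slope, inter, spacing)


def to_hu(volume: RawVolume, slice_index: int) -> np.ndarray:
    """Convert one stored slice to Hounsfield units.

    HU = stored * rescale_slope + rescale_intercept, element-wise, float64.
    """
    if not 0 <= slice_index < volume.n_slices:
        raise IndexError(
            f"slice_index {slice_index} out of range for volume with {volume.n_slices} slices"
        )
    return (
        volume.voxels[slice_index].astype(np.float64) * volume.rescale_slope
        + volume.rescale_intercept
    )


def normalize_minmax(img: np.ndarray) -> np.ndarray:
    """Affinely map [min, max] of a finite HU slice onto [0, 255] (uint8).

    A constant image maps to all zeros: any constant is equally
    uninformative and this avoids a divide by zero.
    """
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite values")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return to_byte((img - lo) * (255.0 / (hi - lo)))


def _check_byte(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0 or arr.max() > 255:
            raise ValidationError("8-bit image values must be integers in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def write_png(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale image losslessly to PNG."""
    arr = _check_byte(img)
    path = Path(path)
    try:
        iio.imwrite(path, arr, extension=".png")
    except OSError as exc:
        raise OSError(f"cannot write PNG to {path}: {exc}") from exc


def read_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back into a 2-D uint8 array."""
    try:
        arr = iio.imread(Path(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read PNG {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse redundant gray channels
        if not np.all(arr[..., 0] == arr[..., -1]):
            raise FormatError(f"{path} is not a grayscale image")
        arr = arr[..., 0]
    return arr.astype(np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask: {0, 255} PNG or {0, 1} NIfTI -> {0, 1} uint8."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        values = np.unique(data)
        if not np.all(np.isin(values, (0, 1))):
            raise ValidationError(f"NIfTI mask {path} has values outside {{0, 1}}: {values}")
        if data.ndim == 3:
            data = data.transpose(2, 1, 0)
        elif data.ndim == 2:
            data = data.T
        return data.astype(np.uint8)
    arr = read_png(path)
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 255))):
        raise ValidationError(f"PNG mask {path} has values outside {{0, 255}}: {values}")
    return (arr == 255).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0, 1} mask as {0, 255} PNG or {0, 1} NIfTI by extension."""
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValidationError("mask values must be in {0, 1}")
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        data = arr.astype(np.uint8)
        if data.ndim == 2:
            data = data.T
        elif data.ndim == 3:
            data = data.transpose(2, 1, 0)
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    else:
        write_png((arr * 255).astype(np.uint8), path)
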