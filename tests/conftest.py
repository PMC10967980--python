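from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from ctenhance.phantom import PhantomSpec, make_phantom


def write_dicom_slice(
    path,
    pixels: np.ndarray,
    *,
    series_uid: str,
    instance_number: int,
    z_position: float,
    slope: float = 1.0,
    intercept: float = -1024.0,
) -> None:
    """Write one minimal single-frame CT DICOM file for fixtures."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = series_uid  # fixture: one study per series
    ds.Modality = "CT"
    ds.InstanceNumber = instance_number
    ds.ImagePositionPatient = [0.0, 0.0, float(z_position)]
    ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
    ds.PixelSpacing = [0.8, 0.8]
    ds.SliceThickness = 2.5
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.astype(np.int16).tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


@pytest.fixture
def dicom_series(tmp_path):
    """A 2-slice 64x64 synthetic CT series; returns (dir, stored voxel stack)."""
    rng = np.random.default_rng(7)
    series_dir = tmp_path / "series"
    series_dir.mkdir()
    uid = generate_uid(entropy_srcs=["fixture-series"])
    slices = rng.integers(0, 2000, size=(2, 64, 64), dtype=np.int16)
    # write out of spatial order to exercise position-based sorting
    write_dicom_slice(series_dir / "b.dcm", slices[1], series_uid=uid,
                      instance_number=2, z_position=12.5)
    write_dicom_slice(series_dir / "a.dcm", slices[0], series_uid=uid,
                      instance_number=1, z_position=10.0)
    return series_dir, slices


@pytest.fixture
def phantom_case():
    """Default full-dose phantom, fixed seed."""
    return make_phantom(PhantomSpec(seed=42))


@pytest.fixture
def noisy_phantom_case():
    """Half-dose (noisier) phantom, fixed seed."""
    return make_phantom(PhantomSpec(dose_fraction=0.5, seed=42))
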