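from __future__ import annotations

import numpy as np
import pytest

from dcfseg import PhantomParams, PipelineConfig, generate_phantom


def make_dicom(path, pixels: np.ndarray, pixel_spacing_mm=None):
    """Write a minimal single-frame grayscale DICOM file for tests."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    bits = pixels.dtype.itemsize * 8
    ds.BitsAllocated = bits
    ds.BitsStored = bits
    ds.HighBit = bits - 1
    ds.PixelRepresentation = 0
    if pixel_spacing_mm is not None:
        ds.PixelSpacing = [str(pixel_spacing_mm[0]), str(pixel_spacing_mm[1])]
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


@pytest.fixture(scope="session")
def default_phantom():
    """Phantom for seed 1 with its ground truth (shared; treat as read-only)."""
    return generate_phantom(PhantomParams(seed=1))


@pytest.fixture()
def default_config(default_phantom):
    _, truth = default_phantom
    return PipelineConfig(roi=truth.roi)
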