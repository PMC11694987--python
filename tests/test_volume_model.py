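"""HU/attenuation conversion and volume I/O round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fgict import (
    AttenuationVolume,
    attenuation_to_hu,
    hu_to_attenuation,
    read_volume,
    write_volume,
)
from fgict.volume import (
    GrayImage,
    InvalidCalibrationError,
    VolumeFormatError,
    quantize_to_uint8,
)

MU_W = 0.0192


@pytest.mark.parametrize(
    "hu, expected",
    [(0, MU_W), (-1000, 0.0), (1000, 2 * MU_W), (-1024, 0.0)],
)
def test_hu_to_attenuation_anchors(hu, expected):
    # water is 0 HU, air is -1000 HU by definition; below air clamps to 0
    assert hu_to_attenuation(hu, MU_W) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("mu, expected", [(MU_W, 0.0), (0.0, -1000.0)])
def test_attenuation_to_hu_anchors(mu, expected):
    assert attenuation_to_hu(mu, MU_W) == pytest.approx(expected, abs=1e-9)


def test_invalid_calibration_rejected():
    with pytest.raises(InvalidCalibrationError):
        hu_to_attenuation(0, 0.0)
    with pytest.raises(InvalidCalibrationError):
        attenuation_to_hu(0.01, -1.0)


@settings(deadline=None, max_examples=200)
@given(st.integers(min_value=-1000, max_value=3071))
def test_hu_round_trip(hu):
    """hu -> attenuation -> hu is the identity (well within 0.5 HU) on the
    physical range; below -1000 HU the attenuation clamp makes the map
    many-to-one by design."""
    back = attenuation_to_hu(hu_to_attenuation(hu, MU_W), MU_W)
    assert abs(back - hu) < 0.5


def test_raw_binary_round_trip(tmp_path, rng):
    vol = AttenuationVolume(rng.random((4, 8, 8)), mu_water=0.021, source="derived")
    path = tmp_path / "vol.bin"
    write_volume(vol, path, "raw-binary")
    back = read_volume(path, "raw-binary")
    np.testing.assert_array_equal(back.voxels, vol.voxels)  # bit-exact
    assert back.mu_water == vol.mu_water


def test_raw_binary_wrong_length_errors(tmp_path):
    path = tmp_path / "vol.bin"
    path.write_bytes(b"\x00" * 100)
    with pytest.raises(VolumeFormatError):
        read_volume(path, "raw-binary", layout={"shape": [2, 4, 4], "dtype": "<f8"})


def test_pgm_quantization_anchors(tmp_path):
    # {0, half-max, max} -> {0, 128, 255}; constant positive -> 255; zero -> 0
    v = np.zeros((1, 2, 2))
    v[0] = [[0.0, 0.4], [0.8, 0.8]]
    np.testing.assert_array_equal(quantize_to_uint8(v), [[[0, 128], [255, 255]]])
    assert quantize_to_uint8(np.full((1, 2, 2), 0.3)).min() == 255
    assert quantize_to_uint8(np.zeros((1, 2, 2))).max() == 0


def test_pgm_quantization_monotone(rng):
    v = np.sort(rng.random((1, 4, 64)), axis=-1)
    q = quantize_to_uint8(v).astype(int)
    assert np.all(np.diff(q, axis=-1) >= 0)


def test_pgm_slices_written(tmp_path):
    import imageio.v3 as iio

    vol = AttenuationVolume(np.full((3, 4, 4), 0.5))
    write_volume(vol, tmp_path / "slices", "pgm-slices")
    files = sorted((tmp_path / "slices").iterdir())
    assert len(files) == 3
    assert np.all(iio.imread(files[0]) == 255)


def _make_dicom_slice(path, pixels, instance, z, slope=1.0, intercept=-1024.0):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.InstanceNumber = instance
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelData = pixels.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)


def test_dicom_series_read(tmp_path):
    """A synthetic 2-slice series with slope 1, intercept -1024: stored value
    1024 is water (0 HU), 24 is air (-1000 HU); slices ordered by position
    along the normal, not by filename."""
    s0 = np.full((4, 4), 1024, dtype=np.uint16)  # water slice at z=10
    s0[0, 0] = 24  # air corner
    s1 = np.full((4, 4), 2024, dtype=np.uint16)  # 1000 HU slice at z=5
    _make_dicom_slice(tmp_path / "a.dcm", s0, instance=2, z=10.0)
    _make_dicom_slice(tmp_path / "b.dcm", s1, instance=1, z=5.0)
    vol = read_volume(tmp_path, "dicom-series", mu_water=MU_W)
    assert vol.source == "dicom"
    # z=5 slice comes first
    assert vol.voxels[0, 0, 0] == pytest.approx(2 * MU_W)
    assert vol.voxels[1, 1, 1] == pytest.approx(MU_W)
    assert vol.voxels[1, 0, 0] == pytest.approx(hu_to_attenuation(-1000, MU_W))


def test_dicom_missing_rescale_errors(tmp_path):
    import pydicom

    _make_dicom_slice(tmp_path / "a.dcm", np.zeros((2, 2), dtype=np.uint16), 1, 0.0)
    ds = pydicom.dcmread(tmp_path / "a.dcm")
    del ds.RescaleSlope
    ds.save_as(tmp_path / "a.dcm", enforce_file_format=True)
    with pytest.raises(VolumeFormatError):
        read_volume(tmp_path, "dicom-series")


def test_volume_invariants_enforced():
    with pytest.raises(ValueError):
        AttenuationVolume(np.full((1, 2, 2), -0.1))
    with pytest.raises(ValueError):
        AttenuationVolume(np.full((2, 2), 0.1))
    with pytest.raises(ValueError):
        GrayImage(np.full((2, 2), 1.5))
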