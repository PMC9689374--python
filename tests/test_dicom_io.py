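"""DICOM series round-trips, sorting invariance and deidentification."""

import shutil

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset

from orthosr import CTVolume, VolumeGeometry, deidentify, read_series, write_series


def _int_volume(rng, size=(16, 16, 3), spacing=(0.7, 0.7, 5.0)):
    geom = VolumeGeometry((1.0, -2.0, 30.0), spacing, np.eye(3), size)
    hu = rng.integers(-1000, 1000, size=size).astype(float)
    return CTVolume(hu, geom, slice_thickness=spacing[2])


class TestRoundTrip:
    def test_read_write_is_exact_for_integer_hu(self, tmp_path, rng):
        vol = _int_volume(rng, size=(64, 64, 3))
        write_series(vol, tmp_path)
        back = read_series(tmp_path)
        assert back.shape == (64, 64, 3)
        np.testing.assert_array_equal(back.intensities, vol.intensities)
        assert np.allclose(back.geometry.origin, vol.geometry.origin, atol=1e-6)
        assert np.allclose(back.geometry.spacing, vol.geometry.spacing, atol=1e-6)
        assert np.allclose(back.geometry.direction, vol.geometry.direction, atol=1e-6)

    def test_constant_air_volume_round_trips(self, tmp_path):
        geom = VolumeGeometry((0, 0, 0), (1, 1, 1), np.eye(3), (8, 8, 2))
        vol = CTVolume(np.full((8, 8, 2), -1000.0), geom, slice_thickness=1.0)
        write_series(vol, tmp_path)
        assert np.all(read_series(tmp_path).intensities == -1000.0)

    def test_one_file_per_slice(self, tmp_path, rng):
        paths = write_series(_int_volume(rng, size=(8, 8, 2)), tmp_path)
        assert len(paths) == 2

    def test_rescale_intercept_maps_stored_zero_to_minus_1024(self, tmp_path):
        geom = VolumeGeometry((0, 0, 0), (1, 1, 1), np.eye(3), (4, 4, 1))
        vol = CTVolume(np.full((4, 4, 1), -1024.0), geom, slice_thickness=1.0)
        (path,) = write_series(vol, tmp_path)
        ds = pydicom.dcmread(path)
        assert ds.pixel_array.max() == 0  # stored value 0
        assert float(ds.RescaleIntercept) == -1024.0
        assert read_series(tmp_path).intensities.max() == -1024.0

    def test_out_of_range_intensity_names_extreme(self, tmp_path):
        geom = VolumeGeometry((0, 0, 0), (1, 1, 1), np.eye(3), (4, 4, 1))
        vol = CTVolume(np.full((4, 4, 1), 40000.0), geom)
        with pytest.raises(ValueError, match="40000"):
            write_series(vol, tmp_path)

    def test_provenance_description_survives_round_trip(self, tmp_path, rng):
        write_series(_int_volume(rng), tmp_path, description="EDSR super-resolution")
        assert read_series(tmp_path).metadata["description"] == "EDSR super-resolution"


class TestReadRules:
    def test_shuffled_file_order_yields_identical_volume(self, tmp_path, rng):
        vol = _int_volume(rng, size=(8, 8, 4))
        src = tmp_path / "sorted"
        paths = write_series(vol, src)
        shuffled = tmp_path / "shuffled"
        shuffled.mkdir()
        # reversed file names: read_series must sort by slice position
        for i, p in enumerate(reversed(paths)):
            shutil.copy(p, shuffled / f"slice_{i:04d}.dcm")
        a = read_series(src)
        b = read_series(shuffled)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert np.allclose(a.geometry.origin, b.geometry.origin)

    def test_mixed_series_uids_rejected(self, tmp_path, rng):
        write_series(_int_volume(rng, size=(8, 8, 1)), tmp_path)
        write_series(_int_volume(rng, size=(8, 8, 1)), tmp_path)
        # second call overwrote slice_0000 only if same name; force two files
        files = list(tmp_path.iterdir())
        if len(files) < 2:  # same filename: write to subdir then copy
            other = tmp_path / "b"
            write_series(_int_volume(rng, size=(8, 8, 1)), other)
            shutil.copy(next(other.iterdir()), tmp_path / "slice_0001.dcm")
        with pytest.raises(ValueError, match="mixed series"):
            read_series(tmp_path)

    def test_non_uniform_slice_spacing_rejected(self, tmp_path, rng):
        vol = _int_volume(rng, size=(8, 8, 3))
        paths = write_series(vol, tmp_path)
        ds = pydicom.dcmread(paths[2])
        ipp = [float(v) for v in ds.ImagePositionPatient]
        ipp[2] += 1.7  # push the last slice off the uniform grid
        ds.ImagePositionPatient = [f"{v:.10g}" for v in ipp]
        ds.save_as(paths[2], enforce_file_format=True)
        with pytest.raises(ValueError, match="non-uniform inter-slice"):
            read_series(tmp_path)


class TestDeidentify:
    def _header(self):
        ds = Dataset()
        ds.PatientName = "DOE^JOHN"
        ds.PatientID = "12345"
        ds.StudyDate = "20190715"
        ds.SeriesDate = "20191224"
        ds.PatientBirthDate = "19561130"
        ds.StudyInstanceUID = "1.2.3.4"
        ds.SeriesInstanceUID = "1.2.3.5"
        ds.SOPInstanceUID = "1.2.3.6"
        return ds

    def test_dates_become_january_first_same_year(self):
        out = deidentify(self._header())
        assert out.StudyDate == "20190101"
        assert out.SeriesDate == "20190101"
        assert out.PatientBirthDate == "19560101"

    def test_patient_identity_emptied(self):
        out = deidentify(self._header())
        assert str(out.PatientName) == ""
        assert out.PatientID == ""

    def test_fresh_uids_each_call(self):
        ds = self._header()
        a, b = deidentify(ds), deidentify(ds)
        assert a.SeriesInstanceUID != ds.SeriesInstanceUID
        assert a.SeriesInstanceUID != b.SeriesInstanceUID
        assert a.StudyInstanceUID != b.StudyInstanceUID

    def test_missing_date_tags_skipped(self):
        ds = Dataset()
        ds.PatientName = "X"
        out = deidentify(ds)  # must not raise
        assert str(out.PatientName) == ""
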