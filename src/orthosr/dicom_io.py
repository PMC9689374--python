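"""Read and write single-frame CT DICOM series as geometric volumes.

Reading stacks the files of one series into a :class:`CTVolume`: slices
are sorted by the projection of ImagePositionPatient onto the slice
normal, the rescale slope/intercept is applied so intensities are
Hounsfield units, and the geometry is populated from the position,
orientation and pixel-spacing tags. Mixed series, inconsistent
orientations, non-uniform inter-slice spacing and non-uniform rescale
slopes are rejected rather than silently repaired.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .geometry import CTVolume, VolumeGeometry

__all__ = ["read_series", "write_series", "deidentify"]

#: maximum spread of inter-slice intervals tolerated within a series (mm)
SPACING_UNIFORMITY_TOL = 1e-2
#: maximum deviation of orientation cosines across slices of a series
ORIENTATION_TOL = 1e-4

_STORED_MIN, _STORED_MAX = -32768, 32767


def read_series(directory: str | Path) -> CTVolume:
    """Stack the single-frame CT files of one series into a volume.

    The result is independent of the on-disk file order. Raises
    ``ValueError`` for mixed series UIDs, inconsistent orientation,
    non-uniform inter-slice spacing or non-uniform rescale slope.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = [pydicom.dcmread(p) for p in paths]
    if not datasets:
        raise ValueError(f"no DICOM files in {directory}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"mixed series UIDs in {directory}: {sorted(uids)}")

    iop0 = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    slopes = set()
    for ds in datasets:
        iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
        if np.max(np.abs(iop - iop0)) > ORIENTATION_TOL:
            raise ValueError("inconsistent ImageOrientationPatient across slices")
        slopes.add(float(getattr(ds, "RescaleSlope", 1.0)))
    if len(slopes) != 1:
        raise ValueError(f"non-uniform rescale slope across slices: {sorted(slopes)}")

    row = iop0[:3]
    col = iop0[3:]
    normal = np.cross(row, col)
    datasets.sort(key=lambda ds: float(
        np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal)
    ))
    positions = np.array(
        [np.asarray(ds.ImagePositionPatient, dtype=float) for ds in datasets]
    )
    if len(datasets) > 1:
        proj = positions @ normal
        intervals = np.diff(proj)
        if intervals.max() - intervals.min() > SPACING_UNIFORMITY_TOL:
            raise ValueError(
                f"non-uniform inter-slice spacing: {intervals.min():.4f}"
                f"..{intervals.max():.4f} mm"
            )
        slice_spacing = float(intervals.mean())
    else:
        ds = datasets[0]
        slice_spacing = float(
            getattr(ds, "SpacingBetweenSlices", getattr(ds, "SliceThickness", 1.0))
        )

    first = datasets[0]
    ps = np.asarray(first.PixelSpacing, dtype=float)  # [row, column] spacing
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))

    slices = []
    for ds in datasets:
        hu = slope * ds.pixel_array.astype(float) + float(
            getattr(ds, "RescaleIntercept", intercept)
        )
        slices.append(hu.T)  # (rows, cols) -> (i, j)
    arr = np.stack(slices, axis=2)

    geom = VolumeGeometry(
        origin=positions[0],
        spacing=(ps[1], ps[0], slice_spacing),
        direction=np.column_stack([row, col, normal]),
        size=arr.shape,
    )
    thickness = getattr(first, "SliceThickness", None)
    return CTVolume(
        arr,
        geom,
        slice_thickness=float(thickness) if thickness is not None else None,
        series_id=str(first.SeriesInstanceUID),
        metadata={"description": str(getattr(first, "SeriesDescription", ""))},
    )


def write_series(
    vol: CTVolume,
    out_dir: str | Path,
    template_tags: Dataset | None = None,
    description: str | None = None,
) -> list[Path]:
    """Write one DICOM file per slice along the third volume axis.

    Intensities are rounded to integers and stored with rescale slope 1
    and intercept −1024; values that would leave the signed 16-bit
    stored range raise an error naming the offending extreme.
    ``template_tags`` (e.g. a deidentified source header) contributes
    patient/study-level tags; geometry tags always come from ``vol``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    intercept = -1024.0
    stored = np.round(vol.intensities - intercept).astype(np.int64)
    if stored.min() < _STORED_MIN or stored.max() > _STORED_MAX:
        extreme = vol.intensities.max() if stored.max() > _STORED_MAX else vol.intensities.min()
        raise ValueError(
            f"intensity {extreme:.1f} HU outside the signed 16-bit stored range"
        )
    stored = stored.astype(np.int16)

    geom = vol.geometry
    series_uid = generate_uid()
    study_uid = getattr(template_tags, "StudyInstanceUID", None) or generate_uid()
    frame_uid = generate_uid()
    nx, ny, nz = geom.size
    paths: list[Path] = []
    for k in range(nz):
        ds = Dataset()
        if template_tags is not None:
            for elem in template_tags.iterall():
                if elem.group != 0x7FE0:  # never copy pixel data
                    ds.add(copy.deepcopy(elem))
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageType = ["DERIVED", "SECONDARY"]
        if description is not None:
            ds.SeriesDescription = description
        elif vol.metadata.get("description"):
            ds.SeriesDescription = vol.metadata["description"]

        ds.Rows = ny
        ds.Columns = nx
        ds.PixelSpacing = [f"{geom.spacing[1]:.10g}", f"{geom.spacing[0]:.10g}"]
        ds.SliceThickness = f"{(vol.slice_thickness or geom.spacing[2]):.10g}"
        ds.SpacingBetweenSlices = f"{geom.spacing[2]:.10g}"
        iop = np.concatenate([geom.direction[:, 0], geom.direction[:, 1]])
        ds.ImageOrientationPatient = [f"{v:.10g}" for v in iop]
        ipp = geom.index_to_world(np.array([0.0, 0.0, float(k)]))
        ds.ImagePositionPatient = [f"{v:.10g}" for v in ipp]

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = f"{intercept:.10g}"
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        path = out_dir / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def deidentify(tags: Dataset) -> Dataset:
    """Return a deidentified copy of a DICOM header.

    Patient name and identifier tags are emptied, every date tag is
    replaced by January 1st of its original year, and fresh study,
    series and SOP instance UIDs are generated (two calls on the same
    input therefore yield distinct UIDs). Missing tags are skipped.
    """
    ds = copy.deepcopy(tags)
    for tag_name in (
        "PatientName",
        "PatientID",
        "OtherPatientIDs",
        "PatientBirthName",
        "PatientAddress",
        "PatientTelephoneNumbers",
    ):
        if tag_name in ds:
            setattr(ds, tag_name, "")

    def _fix_dates(dataset: Dataset, elem) -> None:
        if elem.VR == "DA" and elem.value:
            value = str(elem.value)
            if len(value) >= 4:
                elem.value = value[:4] + "0101"

    ds.walk(_fix_dates)

    for uid_name in ("StudyInstanceUID", "SeriesInstanceUID", "SOPInstanceUID"):
        if uid_name in ds:
            setattr(ds, uid_name, generate_uid())
    return ds
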