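"""File I/O: NIfTI and DICOM volumes, mesh export, run configuration.

NIfTI (single file, spacing in the header) is the primary on-disk format;
DICOM series read/write is provided for fidelity to clinical sources.  The
in-memory array order is (z, y, x); on disk NIfTI data are stored in the
conventional (x, y, z) order with an affine built from spacing and origin.
"""

from __future__ import annotations

import json
import logging
import tomllib
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
import trimesh
import yaml

from .volume import ImageVolume

__all__ = [
    "read_volume",
    "write_nifti",
    "read_nifti",
    "write_dicom_series",
    "read_dicom_series",
    "write_mask_nifti",
    "write_boundary_mesh",
    "load_run_config",
]

log = logging.getLogger("orbitmorph.io")


def read_volume(path) -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory into an ImageVolume."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti(path)


def write_nifti(volume: ImageVolume, path) -> None:
    """Write as .nii/.nii.gz; data transposed to (x, y, z) on disk."""
    data = np.asarray(volume.values, dtype=np.float32).transpose(2, 1, 0)
    sz, sy, sx = volume.spacing
    oz, oy, ox = volume.origin
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    sx, sy, sz = img.header.get_zooms()[:3]
    ox, oy, oz = img.affine[:3, 3]
    return ImageVolume(
        values=data, spacing=np.array([sz, sy, sx]), origin=np.array([oz, oy, ox])
    )


def write_dicom_series(volume: ImageVolume, directory) -> None:
    """Write one CT-storage DICOM file per axial slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sz, sy, sx = volume.spacing
    series_uid = generate_uid()
    study_uid = generate_uid()
    data = np.asarray(np.rint(volume.values), dtype=np.int16)
    for k in range(volume.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "phantom"
        ds.PatientID = "phantom"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            float(volume.origin[2]),
            float(volume.origin[1]),
            float(volume.origin[0] + k * sz),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(sy), float(sx)]
        ds.SliceThickness = float(sz)
        ds.RescaleIntercept = 0.0
        ds.RescaleSlope = 1.0
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = data[k].tobytes()
        ds.is_little_endian = True
        ds.is_implicit_VR = False
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)


def read_dicom_series(directory) -> ImageVolume:
    """Read a DICOM series; slices sorted by position along z.

    Raises ``ValueError`` on inconsistent slice spacing (e.g. a missing
    slice) or missing pixel data.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        if "PixelData" not in ds:
            raise ValueError(f"{f} has no pixel data")
        slices.append(ds)
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    if len(zs) > 1:
        steps = np.diff(zs)
        if steps.min() <= 0 or np.ptp(steps) > 1e-3 * steps.mean():
            raise ValueError(
                "inconsistent slice spacing: series has missing or duplicate slices"
            )
        sz = float(steps.mean())
    else:
        sz = float(getattr(slices[0], "SliceThickness", 1.0))
    sy, sx = (float(s) for s in slices[0].PixelSpacing)
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))
    data = np.stack(
        [s.pixel_array.astype(np.float32) * slope + intercept for s in slices]
    )
    origin = np.array(
        [zs[0], float(slices[0].ImagePositionPatient[1]),
         float(slices[0].ImagePositionPatient[0])]
    )
    return ImageVolume(values=data, spacing=np.array([sz, sy, sx]), origin=origin)


def write_mask_nifti(mask: np.ndarray, spacing, origin, path) -> None:
    vol = ImageVolume(values=mask.astype(np.float32), spacing=spacing, origin=origin)
    write_nifti(vol, path)


def write_boundary_mesh(mesh, path, sidecar_path=None) -> None:
    """Export the labelled boundary surface as STL/PLY plus a JSON sidecar.

    The mesh format keeps geometry only; triangle labels (bone vs closure
    caps) go to the sidecar.
    """
    tm = trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.boundary_triangles),
        process=False,
    )
    tm.export(str(path))
    if sidecar_path is not None:
        Path(sidecar_path).write_text(
            json.dumps({"triangle_labels": list(map(str, mesh.boundary_labels))})
        )


def load_run_config(path) -> dict:
    """Read a TOML or YAML run configuration into a plain dict."""
    path = Path(path)
    if path.suffix == ".toml":
        return tomllib.loads(path.read_text())
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(path.read_text())
    raise ValueError(f"unsupported config format {path.suffix!r}")
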