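"""Shared fixtures: voxelized phantom bundles reused across the suite.

The expensive phantom pipelines (voxelize -> signed distance -> mesh ->
descriptors) are session-scoped so geometry tests and acceptance tests share
one computation per shape.
"""

from __future__ import annotations

import os
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import hippomorph as hm
from hippomorph import phantoms as ph


def _bundle(spec: ph.PhantomSpec, shape: tuple[int, int, int],
            noise_sigma: float = 0.0, seed: int = 0) -> SimpleNamespace:
    grid, mask, spec = ph.make_phantom(spec, shape, noise_sigma=noise_sigma,
                                       seed=seed)
    field = hm.reinitialize_sdf(mask)
    mesh = hm.extract_mesh(field)
    desc = hm.describe(field)
    return SimpleNamespace(grid=grid, mask=mask, spec=spec, field=field,
                           mesh=mesh, desc=desc, truth=spec.analytic_truth)


@pytest.fixture(scope="session")
def sphere_bundle() -> SimpleNamespace:
    """Clean sphere phantom, r = 9.2 mm at 0.5 mm spacing."""
    return _bundle(ph.PhantomSpec(family="sphere", radius=9.2), (48, 48, 48))


@pytest.fixture(scope="session")
def capsule_bundle() -> SimpleNamespace:
    """Clean capsule phantom, cap r = 5 mm, cylinder L = 20 mm."""
    return _bundle(ph.PhantomSpec(family="capsule", radius=5.0, length=20.0),
                   (76, 76, 76))


ELLIPSOID_ROTATION = Rotation.from_euler("xyz", [30, 40, 20],
                                         degrees=True).as_matrix()


@pytest.fixture(scope="session")
def ellipsoid_bundle() -> SimpleNamespace:
    """Arbitrarily rotated 20/15/10 mm ellipsoid phantom."""
    spec = ph.PhantomSpec(family="ellipsoid", semi_axes=(20.0, 15.0, 10.0),
                          rotation=ELLIPSOID_ROTATION)
    return _bundle(spec, (104, 104, 104))


def write_dicom_series(grid, directory) -> None:
    """Write a VoxelGrid as a one-file-per-slice uint16 MR DICOM series."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    study_uid = generate_uid()
    data = np.clip(grid.values, 0, None).astype(np.uint16)
    for i in range(data.shape[0]):
        ds = Dataset()
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.4"
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [float(grid.origin[1]), float(grid.origin[2]),
                                   float(grid.origin[0] + i * grid.spacing[0])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[2])]
        ds.SliceThickness = float(grid.spacing[0])
        ds.Rows, ds.Columns = data.shape[1], data.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = data[i].tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        pydicom.dcmwrite(os.path.join(directory, f"slice{i:03d}.dcm"), ds,
                         enforce_file_format=True)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
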