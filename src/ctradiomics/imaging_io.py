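"""Read/write CT volumes and segmentation masks; geometric contract.

Internal convention: every 3-D grid is indexed ``(x, y, z)`` with 0-based
indices, voxel spacing is an ``(sx, sy, sz)`` triple in millimetres and a
voxel's world coordinate is ``origin + index * spacing``.

Supported formats are NIfTI (``.nii`` / ``.nii.gz``) through nibabel and
uncompressed explicit-VR little-endian DICOM series (a directory of
``.dcm`` files) through the bundled minimal codec in :mod:`._dicom`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from ctradiomics import _dicom
from ctradiomics.errors import DegenerateLesionError, FormatError, GeometryError

#: tolerance on non-uniform slice gaps, mm
SLICE_GAP_TOL_MM = 1e-3


@dataclass
class CtVolume:
    """Calibrated CT intensity grid in Hounsfield units.

    Attributes
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        HU values; rescale slope/intercept already applied.
    voxel_spacing_mm : tuple of float
        Strictly positive ``(sx, sy, sz)``.
    origin_mm : tuple of float
        World coordinate of voxel ``(0, 0, 0)``.
    axis_order : str
        Fixed tag ``"xyz"``; all feature code relies on it.
    """

    intensities: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = field(default="xyz")

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise GeometryError("CtVolume requires a 3-D intensity grid")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise GeometryError(
                f"voxel spacing must be strictly positive, got {self.voxel_spacing_mm}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise GeometryError("CtVolume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def world_coordinate(self, index) -> np.ndarray:
        """World position (mm) of a voxel index."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(
            self.voxel_spacing_mm
        )


@dataclass
class SegmentationMask:
    """Binary tumor label grid aligned to a reference :class:`CtVolume`."""

    labels: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(bool)
        if self.labels.ndim != 3:
            raise GeometryError("SegmentationMask requires a 3-D label grid")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.labels.sum())


def _nifti_affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def write_ct(volume: CtVolume, path: str) -> None:
    """Write a volume as NIfTI (``.nii``/``.nii.gz``) or a DICOM series.

    A path ending in ``.nii``/``.nii.gz`` selects NIfTI; any other path is
    treated as a directory and one ``.dcm`` file per axial slice is written.
    """
    if _is_nifti(path):
        img = nib.Nifti1Image(
            np.asarray(volume.intensities),
            _nifti_affine(volume.voxel_spacing_mm, volume.origin_mm),
        )
        img.header.set_zooms(volume.voxel_spacing_mm)
        nib.save(img, path)
    else:
        _dicom.write_series(
            path,
            volume.intensities,
            volume.voxel_spacing_mm,
            volume.origin_mm,
        )


def read_ct_series(path: str) -> CtVolume:
    """Load a CT volume from a NIfTI file or a single-series DICOM directory.

    DICOM slices are sorted by spatial position along the slice normal and
    the rescale slope/intercept is applied so intensities are HU. Mixed
    series, missing spacing and non-uniform slice gaps beyond
    ``SLICE_GAP_TOL_MM`` raise :class:`FormatError` naming the offender.
    """
    if _is_nifti(path):
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path}")
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
        zooms = img.header.get_zooms()[:3]
        origin = tuple(np.asarray(img.affine)[:3, 3])
        return CtVolume(data, tuple(float(z) for z in zooms), origin)
    if not os.path.isdir(path):
        raise FormatError(f"{path}: not a NIfTI file or DICOM directory")
    data, spacing, origin = _dicom.read_series(path, gap_tol_mm=SLICE_GAP_TOL_MM)
    return CtVolume(data, spacing, origin)


def write_mask(mask: SegmentationMask, path: str) -> None:
    """Write a mask as an unsigned 8-bit NIfTI label volume."""
    img = nib.Nifti1Image(
        mask.labels.astype(np.uint8),
        _nifti_affine(mask.voxel_spacing_mm, mask.origin_mm),
    )
    img.header.set_zooms(mask.voxel_spacing_mm)
    nib.save(img, path)


def largest_connected_component(labels: np.ndarray) -> np.ndarray:
    """Keep the largest 26-connected foreground component of a binary grid."""
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(labels, structure=structure)
    if n <= 1:
        return labels.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return comp == keep


def read_mask(path: str, reference: CtVolume) -> SegmentationMask:
    """Load a segmentation aligned to ``reference``.

    Nonzero labels collapse to binary foreground; when several 26-connected
    lesions are present only the largest is kept. Empty masks and geometry
    mismatches raise.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.shape != reference.shape:
        raise GeometryError(
            f"mask shape {data.shape} does not match volume shape {reference.shape}"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not np.allclose(zooms, reference.voxel_spacing_mm, atol=1e-6):
        raise GeometryError(
            f"mask spacing {zooms} does not match volume spacing "
            f"{reference.voxel_spacing_mm}"
        )
    fg = data != 0
    if not fg.any():
        raise DegenerateLesionError(f"{path}: empty segmentation")
    fg = largest_connected_component(fg)
    return SegmentationMask(fg, reference.voxel_spacing_mm, reference.origin_mm)
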