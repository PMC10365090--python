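"""Isotropic ROI construction and equal-probability gray-level quantization.

All texture computation downstream consumes the two types defined here:
an :class:`IsotropicRoi` (nearest-neighbour resampled, cropped to the mask
bounding box plus a 2-voxel margin) and its :class:`QuantizedRoi`, whose
thresholds are empirical quantiles of the in-mask intensities so that
every gray level receives (up to ties) the same number of voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ctradiomics.errors import ConfigurationError, DegenerateLesionError
from ctradiomics.imaging_io import CtVolume, SegmentationMask

#: quantization ladder applied to every texture family
DEFAULT_G_LEVELS: tuple[int, ...] = (8, 16, 24, 32, 40, 48, 64)

#: default isotropic target spacing, mm
DEFAULT_TARGET_SPACING_MM = 1.0

#: crop margin around the mask bounding box, voxels
ROI_MARGIN_VOXELS = 2


@dataclass
class IsotropicRoi:
    """Masked subvolume on an isotropic lattice."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.shape != self.mask.shape:
            raise ConfigurationError("ROI intensity and mask grids must be congruent")
        if self.spacing_mm <= 0:
            raise ConfigurationError("isotropic spacing must be positive")
        if not self.mask.any():
            raise DegenerateLesionError("ROI mask is empty")

    @property
    def masked_values(self) -> np.ndarray:
        """In-mask intensities as a flat array."""
        return self.intensities[self.mask]


@dataclass
class QuantizedRoi:
    """Gray-level map of an ROI: in-mask voxels carry a level in 1..G.

    ``levels`` is 0 outside the mask. ``thresholds`` holds the strictly
    ascending HU decision boundaries actually used (deduplicated when the
    intensity distribution has heavy ties).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    thresholds: np.ndarray
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        inmask = self.levels[self.mask]
        if inmask.size and (inmask.min() < 1 or inmask.max() > self.n_levels):
            raise ConfigurationError("levels outside 1..G")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ConfigurationError("thresholds must be strictly ascending")


def _nearest_index_grid(n_out: int, scale: float, n_in: int) -> np.ndarray:
    idx = np.rint(np.arange(n_out) * scale).astype(np.intp)
    return np.clip(idx, 0, n_in - 1)


def resample_isotropic(
    volume: CtVolume,
    mask: SegmentationMask,
    target_spacing_mm: float = DEFAULT_TARGET_SPACING_MM,
) -> IsotropicRoi:
    """Nearest-neighbour resample of volume+mask onto an isotropic lattice.

    The mask stays binary (nearest-neighbour on the labels), and the result
    is cropped to the mask bounding box plus :data:`ROI_MARGIN_VOXELS`.
    """
    if target_spacing_mm <= 0:
        raise ConfigurationError("target spacing must be positive")
    if volume.shape != mask.shape:
        raise ConfigurationError("volume and mask shapes differ")

    spacing = np.asarray(volume.voxel_spacing_mm)
    shape = np.asarray(volume.shape)
    out_shape = np.maximum(1, np.rint(shape * spacing / target_spacing_mm).astype(int))
    scales = target_spacing_mm / spacing

    ix = _nearest_index_grid(out_shape[0], scales[0], shape[0])
    iy = _nearest_index_grid(out_shape[1], scales[1], shape[1])
    iz = _nearest_index_grid(out_shape[2], scales[2], shape[2])

    grid = volume.intensities[np.ix_(ix, iy, iz)]
    lab = mask.labels[np.ix_(ix, iy, iz)]
    if not lab.any():
        raise DegenerateLesionError("mask empty after resampling")

    nz = np.nonzero(lab)
    lo = [max(0, int(a.min()) - ROI_MARGIN_VOXELS) for a in nz]
    hi = [min(int(s), int(a.max()) + ROI_MARGIN_VOXELS + 1) for a, s in zip(nz, lab.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return IsotropicRoi(grid[sl], lab[sl], float(target_spacing_mm))


def equal_probability_thresholds(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Decision boundaries at ranks ceil(k*N/G), k = 1..G-1, of sorted values.

    Duplicate boundaries produced by ties are removed so the returned array
    is strictly ascending.
    """
    srt = np.sort(np.asarray(values, dtype=np.float64))
    n = srt.size
    ranks = np.ceil(np.arange(1, n_levels) * n / n_levels).astype(int) - 1
    return np.unique(srt[ranks])


def quantize_equal_probability(roi: IsotropicRoi, n_levels: int) -> QuantizedRoi:
    """Map in-mask intensities to ``1..G`` by equal-probability thresholds.

    Voxels equal to a threshold go to the lower level (deterministic and
    order-preserving). When ``G`` exceeds the number of distinct in-mask
    intensities the mapping degrades to dense ranks of the distinct values
    and a warning is emitted; a constant ROI maps everything to level 1.
    """
    if n_levels < 2:
        raise ConfigurationError("need at least 2 gray levels")
    values = roi.masked_values
    distinct = np.unique(values)

    if distinct.size < n_levels:
        if distinct.size > 1:
            warnings.warn(
                f"G={n_levels} exceeds {distinct.size} distinct intensities; "
                "falling back to rank-dense mapping",
                stacklevel=2,
            )
        thresholds = distinct[:-1]  # one level per distinct value
    else:
        thresholds = equal_probability_thresholds(values, n_levels)

    levels = np.zeros(roi.mask.shape, dtype=np.int64)
    levels[roi.mask] = np.searchsorted(thresholds, values, side="left") + 1
    return QuantizedRoi(levels, roi.mask, n_levels, thresholds, roi.spacing_mm)


def write_quantized_debug(q: QuantizedRoi, path: str) -> None:
    """Dump a quantized ROI as a NIfTI label volume for visual inspection."""
    import nibabel as nib

    affine = np.diag([q.spacing_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(q.levels.astype(np.int16), affine), path)
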