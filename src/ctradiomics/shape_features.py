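"""Size, shape, moment-invariant, skeleton and radial-distance features.

All features here are computed from the binary mask alone. The 2-D moment
families (Hu, affine, Zernike) are evaluated on the largest-area axial
slice of the mask; "skelet" and "dist" features are artifact-defined
concrete stand-ins for taxonomy names that have no published definition
(flagged as such in the feature registry).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, spatial
from skimage import measure
from skimage.morphology import skeletonize

from ctradiomics.errors import DegenerateLesionError

ZERNIKE_MAX_ORDER = 8


def _require_nonempty(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if not labels.any():
        raise DegenerateLesionError("empty mask")
    return labels


def boundary_voxels(labels: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one 6-neighbour outside the mask."""
    eroded = ndimage.binary_erosion(labels, structure=ndimage.generate_binary_structure(3, 1))
    return labels & ~eroded


def surface_area_mm2(labels: np.ndarray, spacing) -> float:
    """Total area of exposed voxel faces (exact on digital masks)."""
    sx, sy, sz = spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, area in enumerate(face_areas):
        pad = np.pad(labels, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        total += np.count_nonzero(np.diff(pad.astype(np.int8), axis=axis)) * area
    return float(total)


def max_diameter_mm(labels: np.ndarray, spacing) -> float:
    """Largest pairwise distance between boundary voxel centres."""
    pts = np.argwhere(boundary_voxels(labels)) * np.asarray(spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[spatial.ConvexHull(pts).vertices]
        except spatial.QhullError:  # co-planar / co-linear masks
            pass
    d2 = spatial.distance.pdist(pts, "sqeuclidean")
    return float(np.sqrt(d2.max()))


def size_shape(labels: np.ndarray, spacing) -> dict[str, float]:
    """Volume, surface and derived global shape descriptors."""
    labels = _require_nonempty(labels)
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = spacing[0] * spacing[1] * spacing[2]
    volume = float(labels.sum()) * voxel_volume
    area = surface_area_mm2(labels, spacing)
    radius_eq = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return {
        "volume_mm3": volume,
        "surface_mm2": area,
        "surface_to_volume_ratio": area / volume,
        "sphericity": math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area,
        "compactness1": volume / (math.sqrt(math.pi) * area ** 1.5),
        "compactness2": 36.0 * math.pi * volume**2 / area**3,
        "spherical_disproportion": area / (4.0 * math.pi * radius_eq**2),
        "max_diameter_3d_mm": max_diameter_mm(labels, spacing),
    }


def largest_axial_slice(labels: np.ndarray) -> np.ndarray:
    """The (x, y) binary slice with the most foreground voxels."""
    counts = labels.sum(axis=(0, 1))
    return labels[:, :, int(np.argmax(counts))]


def hu_moments_8(image: np.ndarray) -> np.ndarray:
    """The 7 classical Hu invariants plus the 8th (skew) invariant."""
    image = np.asarray(image, dtype=np.float64)
    mu = measure.moments_central(image)
    eta = measure.moments_normalized(mu)
    hu7 = measure.moments_hu(eta)
    e = eta  # eta[p, q] with p along axis 0
    i8 = e[1, 1] * ((e[3, 0] + e[1, 2]) ** 2 - (e[0, 3] + e[2, 1]) ** 2) - (
        e[2, 0] - e[0, 2]
    ) * (e[3, 0] + e[1, 2]) * (e[0, 3] + e[2, 1])
    return np.concatenate([hu7, [i8]])


def affine_moment_invariants(image: np.ndarray) -> np.ndarray:
    """First six affine moment invariants (orders up to four)."""
    image = np.asarray(image, dtype=np.float64)
    return affine_invariants_from_central_moments(
        measure.moments_central(image, order=4)
    )


def affine_invariants_from_central_moments(mu: np.ndarray) -> np.ndarray:
    """The six invariants from a (5, 5) central-moment array ``mu[p, q]``."""

    def m(p, q):
        return mu[p, q]

    m00 = m(0, 0)
    i1 = (m(2, 0) * m(0, 2) - m(1, 1) ** 2) / m00**4
    i2 = (
        m(3, 0) ** 2 * m(0, 3) ** 2
        - 6 * m(3, 0) * m(2, 1) * m(1, 2) * m(0, 3)
        + 4 * m(3, 0) * m(1, 2) ** 3
        + 4 * m(2, 1) ** 3 * m(0, 3)
        - 3 * m(2, 1) ** 2 * m(1, 2) ** 2
    ) / m00**10
    i3 = (
        m(2, 0) * (m(2, 1) * m(0, 3) - m(1, 2) ** 2)
        - m(1, 1) * (m(3, 0) * m(0, 3) - m(2, 1) * m(1, 2))
        + m(0, 2) * (m(3, 0) * m(1, 2) - m(2, 1) ** 2)
    ) / m00**7
    i4 = (
        m(2, 0) ** 3 * m(0, 3) ** 2
        - 6 * m(2, 0) ** 2 * m(1, 1) * m(1, 2) * m(0, 3)
        - 6 * m(2, 0) ** 2 * m(0, 2) * m(2, 1) * m(0, 3)
        + 9 * m(2, 0) ** 2 * m(0, 2) * m(1, 2) ** 2
        + 12 * m(2, 0) * m(1, 1) ** 2 * m(2, 1) * m(0, 3)
        + 6 * m(2, 0) * m(1, 1) * m(0, 2) * m(3, 0) * m(0, 3)
        - 18 * m(2, 0) * m(1, 1) * m(0, 2) * m(2, 1) * m(1, 2)
        - 8 * m(1, 1) ** 3 * m(3, 0) * m(0, 3)
        - 6 * m(2, 0) * m(0, 2) ** 2 * m(3, 0) * m(1, 2)
        + 9 * m(2, 0) * m(0, 2) ** 2 * m(2, 1) ** 2
        + 12 * m(1, 1) ** 2 * m(0, 2) * m(3, 0) * m(1, 2)
        - 6 * m(1, 1) * m(0, 2) ** 2 * m(3, 0) * m(2, 1)
        + m(0, 2) ** 3 * m(3, 0) ** 2
    ) / m00**11
    i5 = (m(4, 0) * m(0, 4) - 4 * m(3, 1) * m(1, 3) + 3 * m(2, 2) ** 2) / m00**6
    i6 = (
        m(4, 0) * m(2, 2) * m(0, 4)
        - m(4, 0) * m(1, 3) ** 2
        - m(3, 1) ** 2 * m(0, 4)
        + 2 * m(3, 1) * m(2, 2) * m(1, 3)
        - m(2, 2) ** 3
    ) / m00**9
    return np.array([i1, i2, i3, i4, i5, i6])


def zernike_index_pairs(max_order: int = ZERNIKE_MAX_ORDER) -> list[tuple[int, int]]:
    """Unique (n, m) pairs with m >= 0 and n - m even, n <= max_order."""
    return [
        (n, m_rep)
        for n in range(max_order + 1)
        for m_rep in range(n % 2, n + 1, 2)
    ]


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        coeff = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out += coeff * rho ** (n - 2 * s)
    return out


def zernike_magnitudes(
    image: np.ndarray, max_order: int = ZERNIKE_MAX_ORDER
) -> dict[tuple[int, int], float]:
    """Zernike moment magnitudes of a binary slice on its centroid disk.

    The slice is mapped to the unit disk centred on the foreground centroid
    with radius equal to the farthest foreground pixel, which makes the
    magnitudes translation- and rotation-invariant.
    """
    fg = np.argwhere(np.asarray(image).astype(bool)).astype(np.float64)
    pairs = zernike_index_pairs(max_order)
    if len(fg) == 0:
        return {p: 0.0 for p in pairs}
    centroid = fg.mean(axis=0)
    rel = fg - centroid
    radius = np.sqrt((rel**2).sum(axis=1)).max()
    if radius == 0:
        radius = 1.0
    rho = np.sqrt((rel**2).sum(axis=1)) / radius
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    n_pix = len(fg)
    out = {}
    for n, m_idx in pairs:
        basis = _zernike_radial(n, m_idx, rho) * np.exp(-1j * m_idx * theta)
        a = (n + 1) / math.pi * basis.sum() / n_pix
        out[(n, m_idx)] = float(abs(a))
    return out


def moment_invariants(labels: np.ndarray) -> dict[str, float]:
    """Hu (8), affine (6) and Zernike moment features of the largest slice."""
    labels = _require_nonempty(labels)
    sl = largest_axial_slice(labels).astype(np.float64)
    out: dict[str, float] = {}
    for i, v in enumerate(hu_moments_8(sl), start=1):
        out[f"hu_moment_{i}"] = float(v)
    for i, v in enumerate(affine_moment_invariants(sl), start=1):
        out[f"affine_moment_invariant_{i}"] = float(v)
    for (n, m_idx), v in zernike_magnitudes(sl).items():
        out[f"zernike_magnitude_n{n}_m{m_idx}"] = v
    return out


def skeleton_features(labels: np.ndarray, spacing) -> dict[str, float]:
    """Topology statistics of the 3-D thinning skeleton.

    Single-voxel skeletons (and single-voxel masks) yield all zeros.
    """
    labels = _require_nonempty(labels)
    step = float(np.mean(spacing))
    skel = skeletonize(labels)
    n_voxels = int(skel.sum())
    zeros = {
        "skeleton_n_branch_points": 0.0,
        "skeleton_n_endpoints": 0.0,
        "skeleton_length_mm": 0.0,
        "skeleton_mean_branch_length_mm": 0.0,
    }
    if n_voxels <= 1:
        return zeros
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    neighbors = ndimage.convolve(skel.astype(np.int16), kernel, mode="constant")
    n_endpoints = int(((neighbors == 1) & skel).sum())
    n_branch = int(((neighbors > 2) & skel).sum())
    length = n_voxels * step
    n_segments = max(1, n_branch + 1)
    return {
        "skeleton_n_branch_points": float(n_branch),
        "skeleton_n_endpoints": float(n_endpoints),
        "skeleton_length_mm": length,
        "skeleton_mean_branch_length_mm": length / n_segments,
    }


def radial_distance_features(labels: np.ndarray, spacing) -> dict[str, float]:
    """Statistics of centroid-to-surface distances ("dist" family)."""
    labels = _require_nonempty(labels)
    spacing = np.asarray(spacing, dtype=float)
    pts = np.argwhere(boundary_voxels(labels)) * spacing
    centroid = (np.argwhere(labels) * spacing).mean(axis=0)
    dist = np.sqrt(((pts - centroid) ** 2).sum(axis=1))
    mean = float(dist.mean())
    dmax = float(dist.max())
    if dmax == 0:  # single voxel
        return {
            "dist_mean_mm": 0.0,
            "dist_sd_mm": 0.0,
            "dist_min_max_ratio": 1.0,
            "dist_entropy": 0.0,
        }
    hist, _ = np.histogram(dist / dmax, bins=10, range=(0.0, 1.0))
    p = hist / hist.sum()
    p = p[p > 0]
    return {
        "dist_mean_mm": mean,
        "dist_sd_mm": float(dist.std()),
        "dist_min_max_ratio": float(dist.min() / dmax),
        "dist_entropy": float(-(p * np.log2(p)).sum()),
    }
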