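"""First-order statistics and the four texture-matrix families.

GLCM and GLRLM use the four in-plane unit offsets (0, 45, 90, 135 degrees)
with an offset length of one voxel, swept across all slices of the 3-D
isotropic ROI; features are computed per direction and averaged. GLSZM
zones and NGTDM neighbourhoods use 26-connectivity. Formulas follow the
IBSI reference definitions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ctradiomics.errors import DegenerateLesionError
from ctradiomics.preprocessing import IsotropicRoi, QuantizedRoi

#: in-plane unit offsets for 0, 45, 90, 135 degrees, as (dx, dy, dz)
DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (1, 1, 0),
    (0, 1, 0),
    (-1, 1, 0),
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

GLCM_FEATURE_NAMES = (
    "contrast",
    "dissimilarity",
    "correlation",
    "energy",
    "homogeneity",
    "entropy",
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
)
GLRLM_FEATURE_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "long_run_high_gray_level_emphasis",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
)
GLSZM_FEATURE_NAMES = (
    "small_zone_emphasis",
    "large_zone_size_emphasis",
    "gray_level_nonuniformity",
    "zone_size_nonuniformity",
    "zone_percentage",
    "low_gray_level_zone_emphasis",
)
NGTDM_FEATURE_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

FIRST_ORDER_FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "percentile_10",
    "percentile_25",
    "median",
    "percentile_75",
    "percentile_90",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
)

FIRST_ORDER_BINS = 256


# ---------------------------------------------------------------- first order
def first_order(roi: IsotropicRoi) -> dict[str, float]:
    """Histogram / intensity-distribution features of the in-mask HU values.

    Energy and entropy come from a 256-equal-width-bin histogram spanning
    the in-mask min-max range; moments and percentiles from the raw values.
    A constant ROI has entropy 0, variance 0 and skewness/kurtosis 0.
    """
    v = roi.masked_values
    mean = float(v.mean())
    var = float(v.var())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean(((v - mean) / sd) ** 3))
        kurt = float(np.mean(((v - mean) / sd) ** 4))
    else:
        skew = kurt = 0.0
    if v.max() > v.min():
        hist, _ = np.histogram(v, bins=FIRST_ORDER_BINS, range=(v.min(), v.max()))
    else:
        hist = np.array([v.size])
    p = hist / hist.sum()
    p_nz = p[p > 0]
    q10, q25, q50, q75, q90 = np.percentile(v, [10, 25, 50, 75, 90])
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((p**2).sum()),
        "entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "percentile_10": float(q10),
        "percentile_25": float(q25),
        "median": float(q50),
        "percentile_75": float(q75),
        "percentile_90": float(q90),
        "interquartile_range": float(q75 - q25),
        "range": float(v.max() - v.min()),
        "mean_absolute_deviation": float(np.abs(v - mean).mean()),
    }


# ----------------------------------------------------------------------- GLCM
def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Aligned (source, destination) views of ``arr`` offset by ``d``."""
    sl_src, sl_dst = [], []
    for axis, step in enumerate(d):
        n = arr.shape[axis]
        if step > 0:
            sl_src.append(slice(0, n - step))
            sl_dst.append(slice(step, n))
        elif step < 0:
            sl_src.append(slice(-step, n))
            sl_dst.append(slice(0, n + step))
        else:
            sl_src.append(slice(None))
            sl_dst.append(slice(None))
    return arr[tuple(sl_src)], arr[tuple(sl_dst)]


def cooccurrence_matrix(
    q: QuantizedRoi, direction: tuple[int, int, int], normalized: bool = True
) -> np.ndarray:
    """Symmetric G x G co-occurrence matrix for one unit offset."""
    g = q.n_levels
    lv = np.where(q.mask, q.levels, 0)
    a, b = _shifted_views(lv, direction)
    valid = (a > 0) & (b > 0)
    ai, bi = a[valid] - 1, b[valid] - 1
    mat = np.bincount(ai * g + bi, minlength=g * g).reshape(g, g).astype(np.float64)
    mat = mat + mat.T  # symmetric accumulation
    if normalized:
        total = mat.sum()
        if total > 0:
            mat = mat / total
    return mat


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    g = p.shape[0]
    i = np.arange(1, g + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = (p * ii).sum()
    mu_j = (p * jj).sum()
    var_i = (p * (ii - mu_i) ** 2).sum()
    var_j = (p * (jj - mu_j) ** 2).sum()
    diff = np.abs(ii - jj)
    p_nz = p[p > 0]
    if var_i > 0 and var_j > 0:
        corr = float((p * (ii - mu_i) * (jj - mu_j)).sum() / np.sqrt(var_i * var_j))
    else:
        corr = 1.0  # degenerate single-level matrix
    return {
        "contrast": float((p * diff**2).sum()),
        "dissimilarity": float((p * diff).sum()),
        "correlation": corr,
        "energy": float((p**2).sum()),
        "homogeneity": float((p / (1.0 + diff)).sum()),
        "entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "autocorrelation": float((p * ii * jj).sum()),
        "cluster_shade": float((p * (ii + jj - mu_i - mu_j) ** 3).sum()),
        "cluster_prominence": float((p * (ii + jj - mu_i - mu_j) ** 4).sum()),
    }


def _average_directions(per_direction: list[dict[str, float]]) -> dict[str, float]:
    if not per_direction:
        raise DegenerateLesionError("no direction produced a valid texture matrix")
    keys = per_direction[0].keys()
    return {k: float(np.mean([d[k] for d in per_direction])) for k in keys}


def glcm_features(q: QuantizedRoi) -> dict[str, float]:
    """Per-direction GLCM features averaged over the four offsets."""
    per_dir = []
    for d in DIRECTIONS:
        p = cooccurrence_matrix(q, d)
        if p.sum() == 0:  # no valid voxel pair in this direction
            continue
        per_dir.append(_glcm_features_one(p))
    return _average_directions(per_dir)


# ---------------------------------------------------------------------- GLRLM
def _direction_lines(lv: np.ndarray, d: tuple[int, int, int]):
    """Yield every 1-D scan line of ``lv`` along in-plane direction ``d``."""
    nx, ny, nz = lv.shape
    if d == (1, 0, 0):
        yield from lv.transpose(1, 2, 0).reshape(-1, nx)
    elif d == (0, 1, 0):
        yield from lv.transpose(0, 2, 1).reshape(-1, ny)
    elif d in ((1, 1, 0), (-1, 1, 0)):
        for z in range(nz):
            sl = lv[:, :, z] if d == (1, 1, 0) else lv[::-1, :, z]
            for off in range(-nx + 1, ny):
                yield np.diagonal(sl, offset=off)
    else:
        raise ValueError(f"unsupported direction {d}")


def run_length_matrix(q: QuantizedRoi, direction: tuple[int, int, int]) -> np.ndarray:
    """G x Rmax run-length count matrix for one direction."""
    lv = np.where(q.mask, q.levels, 0).astype(np.int64)
    pieces = []
    for line in _direction_lines(lv, direction):
        pieces.append(line)
        pieces.append(np.zeros(1, dtype=np.int64))  # separator between lines
    x = np.concatenate(pieces)
    change = np.flatnonzero(np.diff(x) != 0) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [x.size]]))
    values = x[starts]
    keep = values > 0
    values, lengths = values[keep], lengths[keep]
    g = q.n_levels
    rmax = int(lengths.max()) if lengths.size else 1
    mat = np.bincount(
        (values - 1) * rmax + (lengths - 1), minlength=g * rmax
    ).reshape(g, rmax)
    return mat.astype(np.float64)


def _glrlm_features_one(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    g, rmax = mat.shape
    r = np.arange(1, rmax + 1, dtype=np.float64)
    gl = np.arange(1, g + 1, dtype=np.float64)
    n_runs = mat.sum()
    row = mat.sum(axis=1)  # per gray level
    col = mat.sum(axis=0)  # per run length
    return {
        "short_run_emphasis": float((col / r**2).sum() / n_runs),
        "long_run_emphasis": float((col * r**2).sum() / n_runs),
        "gray_level_nonuniformity": float((row**2).sum() / n_runs),
        "run_length_nonuniformity": float((col**2).sum() / n_runs),
        "run_percentage": float(n_runs / n_voxels),
        "long_run_high_gray_level_emphasis": float(
            (mat * np.outer(gl**2, r**2)).sum() / n_runs
        ),
        "low_gray_level_run_emphasis": float((row / gl**2).sum() / n_runs),
        "high_gray_level_run_emphasis": float((row * gl**2).sum() / n_runs),
    }


def glrlm_features(q: QuantizedRoi) -> dict[str, float]:
    """Per-direction run-length features averaged over the four offsets."""
    n_voxels = int(q.mask.sum())
    per_dir = []
    for d in DIRECTIONS:
        mat = run_length_matrix(q, d)
        if mat.sum() == 0:
            continue
        per_dir.append(_glrlm_features_one(mat, n_voxels))
    return _average_directions(per_dir)


# ---------------------------------------------------------------------- GLSZM
def size_zone_counts(q: QuantizedRoi) -> tuple[np.ndarray, np.ndarray]:
    """(levels, sizes) of all 26-connected constant-level zones."""
    levels_out, sizes_out = [], []
    lv = np.where(q.mask, q.levels, 0)
    for g in np.unique(lv[lv > 0]):
        comp, n = ndimage.label(lv == g, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        levels_out.extend([int(g)] * n)
        sizes_out.extend(sizes.tolist())
    return np.asarray(levels_out, dtype=np.int64), np.asarray(sizes_out, dtype=np.int64)


def size_zone_matrix(q: QuantizedRoi) -> np.ndarray:
    """G x Smax zone count matrix."""
    levels, sizes = size_zone_counts(q)
    g = q.n_levels
    smax = int(sizes.max()) if sizes.size else 1
    mat = np.bincount(
        (levels - 1) * smax + (sizes - 1), minlength=g * smax
    ).reshape(g, smax)
    return mat.astype(np.float64)


def glszm_features(q: QuantizedRoi) -> dict[str, float]:
    """Size-zone features (26-connectivity)."""
    levels, sizes = size_zone_counts(q)
    n_zones = float(len(sizes))
    n_voxels = float(q.mask.sum())
    lv = levels.astype(np.float64)
    sz = sizes.astype(np.float64)
    row = np.bincount(levels, weights=np.ones_like(sz))  # zones per gray level
    col = np.bincount(sizes, weights=np.ones_like(sz))  # zones per size
    return {
        "small_zone_emphasis": float((1.0 / sz**2).sum() / n_zones),
        "large_zone_size_emphasis": float((sz**2).sum() / n_zones),
        "gray_level_nonuniformity": float((row**2).sum() / n_zones),
        "zone_size_nonuniformity": float((col**2).sum() / n_zones),
        "zone_percentage": float(n_zones / n_voxels),
        "low_gray_level_zone_emphasis": float((1.0 / lv**2).sum() / n_zones),
    }


# ---------------------------------------------------------------------- NGTDM
def ngtdm_table(q: QuantizedRoi) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence ``n_g`` and summed absolute difference ``s_g``.

    Neighbourhood means use the 26-neighbourhood restricted to in-mask
    voxels; voxels without any in-mask neighbour are excluded.
    """
    g = q.n_levels
    lv = np.where(q.mask, q.levels, 0).astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    neigh_sum = ndimage.convolve(lv, kernel, mode="constant")
    neigh_cnt = ndimage.convolve(q.mask.astype(np.float64), kernel, mode="constant")
    valid = q.mask & (neigh_cnt > 0)
    mean_neigh = np.zeros_like(lv)
    mean_neigh[valid] = neigh_sum[valid] / neigh_cnt[valid]
    diffs = np.abs(lv[valid] - mean_neigh[valid])
    lv_valid = q.levels[valid].astype(np.int64)
    n_g = np.bincount(lv_valid, minlength=g + 1)[1:].astype(np.float64)
    s_g = np.bincount(lv_valid, weights=diffs, minlength=g + 1)[1:]
    return n_g, s_g


def ngtdm_features(q: QuantizedRoi) -> dict[str, float]:
    """Amadasun coarseness/contrast/busyness/complexity/strength."""
    n_g, s_g = ngtdm_table(q)
    n_total = n_g.sum()
    if n_total == 0:
        raise DegenerateLesionError("no voxel has an in-mask neighbour")
    p = n_g / n_total
    nz = np.flatnonzero(p)
    n_gp = len(nz)
    i = np.arange(1, len(p) + 1, dtype=np.float64)

    dot_ps = float((p * s_g).sum())
    coarseness = 1.0 / dot_ps if dot_ps > 0 else 1e6

    if n_gp > 1:
        pi, pj = p[nz][:, None], p[nz][None, :]
        ii, jj = i[nz][:, None], i[nz][None, :]
        si, sj = s_g[nz][:, None], s_g[nz][None, :]
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum()
            / (n_gp * (n_gp - 1))
            * (s_g.sum() / n_total)
        )
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = dot_ps / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / n_total
        )
        s_sum = float(s_g.sum())
        strength = (
            float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ----------------------------------------------------------------- lacunarity
def _box_counts(mask: np.ndarray, r: int) -> np.ndarray:
    """Foreground counts of every r-cube gliding box fully inside the grid."""
    c = mask.astype(np.float64)
    for axis in range(3):
        c = np.cumsum(c, axis=axis)
    c = np.pad(c, ((1, 0), (1, 0), (1, 0)))
    out = (
        c[r:, r:, r:]
        - c[:-r, r:, r:]
        - c[r:, :-r, r:]
        - c[r:, r:, :-r]
        + c[:-r, :-r, r:]
        + c[:-r, r:, :-r]
        + c[r:, :-r, :-r]
        - c[:-r, :-r, :-r]
    )
    return out


def gliding_box_lacunarity(mask: np.ndarray, box_sizes=None) -> dict[int, float]:
    """Lacunarity E[M^2]/E[M]^2 per box size, inside the mask bounding box."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateLesionError("empty mask")
    nz = np.nonzero(mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    sub = mask[sl]
    min_dim = min(sub.shape)
    if box_sizes is None:
        box_sizes = [r for r in (2, 4, 8, 16) if r <= min_dim] or [min_dim]
    out = {}
    for r in box_sizes:
        r = min(r, min_dim)
        masses = _box_counts(sub, r).ravel()
        mean = masses.mean()
        out[int(r)] = float((masses**2).mean() / mean**2) if mean > 0 else 1.0
    return out


def lacunarity(mask: np.ndarray) -> dict[str, float]:
    """Scalar summary: slope of log-lacunarity against log box size."""
    curve = gliding_box_lacunarity(mask)
    sizes = np.array(sorted(curve))
    vals = np.array([curve[int(r)] for r in sizes])
    if len(sizes) < 2:
        return {"lacunarity": float(np.log(vals[0]))}
    slope = np.polyfit(np.log(sizes), np.log(vals), 1)[0]
    return {"lacunarity": float(slope)}
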