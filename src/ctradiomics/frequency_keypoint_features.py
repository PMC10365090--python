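"""Gabor-bank, Fourier-spectrum and keypoint/gradient/LOSIB descriptors.

All operators are 2-D and applied per axial slice; slice values are
aggregated by mask-weighted mean. Each slice is demeaned with its in-mask
mean before filtering so every feature in this module is invariant to a
constant HU offset. "SURF", "Harris" and "LOSIB" are taxonomy names
without a published definition in this pipeline's context; the statistics
implemented here are artifact-defined stand-ins (so flagged in the
feature registry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import blob_doh, structure_tensor
from skimage.filters import gabor_kernel

from ctradiomics.preprocessing import IsotropicRoi

#: number of radial rings in the Fourier power spectrum
FOURIER_N_RINGS = 6

#: fixed determinant-of-Hessian blob threshold (slices are unit-normalized)
BLOB_DOH_THRESHOLD = 0.01
BLOB_DOH_MAX_SIGMA = 8

#: in-plane offsets for the LOSIB orientation differences
LOSIB_OFFSETS = {"0": (1, 0), "45": (1, 1), "90": (0, 1), "135": (-1, 1)}

MIN_SLICE_PIXELS = 9


@dataclass(frozen=True)
class GaborBankConfig:
    """Bank of ``n_scales * n_orientations`` Gabor filters.

    Wavelengths form a geometric ladder starting at ``min_wavelength``
    with ratio ``scale_multiplier``; orientations are evenly spaced over
    [0, pi).
    """

    n_scales: int = 5
    n_orientations: int = 6
    min_wavelength: float = 3.0
    scale_multiplier: float = float(np.sqrt(2.0))

    @property
    def wavelengths(self) -> np.ndarray:
        return self.min_wavelength * self.scale_multiplier ** np.arange(self.n_scales)

    @property
    def orientations(self) -> np.ndarray:
        return np.arange(self.n_orientations) * np.pi / self.n_orientations

    @property
    def n_filters(self) -> int:
        return self.n_scales * self.n_orientations


def _mask_slices(roi: IsotropicRoi):
    """Yield (demeaned slice, slice mask, weight) for every populated slice."""
    inmask_mean = roi.masked_values.mean()
    for z in range(roi.mask.shape[2]):
        m = roi.mask[:, :, z]
        w = int(m.sum())
        if w == 0:
            continue
        yield roi.intensities[:, :, z] - inmask_mean, m, w


def _weighted_mean(per_slice: list[dict[str, float]], weights: list[float]):
    total = float(sum(weights))
    out: dict[str, float] = {}
    for key in per_slice[0]:
        out[key] = float(
            sum(d[key] * w for d, w in zip(per_slice, weights)) / total
        )
    return out


def gabor_features(
    roi: IsotropicRoi, cfg: GaborBankConfig | None = None
) -> dict[str, float]:
    """In-mask response energy and mean |response| per Gabor filter.

    30 features x 2 statistics under the default 5-scale, 6-orientation
    bank. A constant ROI gives (numerically) zero band-pass energy because
    slices are demeaned first.
    """
    cfg = cfg or GaborBankConfig()
    kernels = [
        (s, o, gabor_kernel(1.0 / wl, theta=th))
        for s, wl in enumerate(cfg.wavelengths)
        for o, th in enumerate(cfg.orientations)
    ]
    slices = list(_mask_slices(roi))
    if not slices:
        raise ValueError("ROI has no populated slice")
    stack = np.stack([img for img, _m, _w in slices], axis=2)
    masks = np.stack([m for _img, m, _w in slices], axis=2)
    weights = np.array([w for _img, _m, w in slices], dtype=float)

    # one FFT of the reflect-padded stack, reused for every filter; the
    # pad is at least each kernel's half-support so circular wrap-around
    # never reaches the ROI
    pad = max(max(k.shape) for _s, _o, k in kernels) // 2 + 1
    padded = np.pad(stack, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    f_img = np.fft.fft2(padded, axes=(0, 1))
    nx, ny = stack.shape[:2]

    feats: dict[str, float] = {}
    total_w = weights.sum()
    for s, o, k in kernels:
        f_k = np.fft.fft2(k, s=padded.shape[:2])
        resp = np.fft.ifft2(f_img * f_k[:, :, None], axes=(0, 1))
        resp = np.roll(resp, (-(k.shape[0] // 2), -(k.shape[1] // 2)), axis=(0, 1))
        resp = resp[pad : pad + nx, pad : pad + ny]
        power = np.abs(resp) ** 2
        energy = np.array(
            [power[:, :, z][masks[:, :, z]].mean() for z in range(len(slices))]
        )
        mean_abs = np.array(
            [
                np.sqrt(power[:, :, z][masks[:, :, z]]).mean()
                for z in range(len(slices))
            ]
        )
        feats[f"gabor_energy_s{s}_o{o}"] = float((energy * weights).sum() / total_w)
        feats[f"gabor_mean_abs_s{s}_o{o}"] = float(
            (mean_abs * weights).sum() / total_w
        )
    return feats


def fourier_features(roi: IsotropicRoi) -> dict[str, float]:
    """Radial ring energy fractions and spectral entropy of the 2-D spectra.

    Power spectra of the demeaned, mask-windowed slices are accumulated,
    binned into ``FOURIER_N_RINGS`` equal-width radial-frequency rings and
    normalized to fractions. An all-zero spectrum (constant ROI) maps to
    all energy in the lowest ring by convention.
    """
    ring_power = np.zeros(FOURIER_N_RINGS)
    for img, m, _w in _mask_slices(roi):
        spec = np.abs(np.fft.fftn(img * m)) ** 2
        fx = np.fft.fftfreq(img.shape[0])[:, None]
        fy = np.fft.fftfreq(img.shape[1])[None, :]
        radius = np.sqrt(fx**2 + fy**2) / np.sqrt(0.5)  # normalized to [0, 1]
        ring = np.minimum(
            (radius * FOURIER_N_RINGS).astype(int), FOURIER_N_RINGS - 1
        )
        ring_power += np.bincount(
            ring.ravel(), weights=spec.ravel(), minlength=FOURIER_N_RINGS
        )
    total = ring_power.sum()
    if total <= 0:
        fractions = np.zeros(FOURIER_N_RINGS)
        fractions[0] = 1.0
    else:
        fractions = ring_power / total
    nz = fractions[fractions > 0]
    out = {
        f"fourier_ring_fraction_{i}": float(f) for i, f in enumerate(fractions)
    }
    out["fourier_spectral_entropy"] = float(-(nz * np.log2(nz)).sum())
    return out


def _slice_keypoint_gradient(img: np.ndarray, m: np.ndarray) -> dict[str, float]:
    feats: dict[str, float] = {}

    # blob-detector keypoint density (determinant-of-Hessian style)
    peak = np.abs(img[m]).max()
    norm = img / peak if peak > 0 else img
    if peak > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            blobs = blob_doh(
                norm, max_sigma=BLOB_DOH_MAX_SIGMA, threshold=BLOB_DOH_THRESHOLD
            )
        inside = [b for b in blobs if m[int(b[0]), int(b[1])]]
    else:
        inside = []
    feats["surf_keypoint_density"] = len(inside) / float(m.sum())

    # corner response from the structure tensor
    axx, axy, ayy = structure_tensor(img, sigma=1.0)
    response = (axx * ayy - axy**2) - 0.05 * (axx + ayy) ** 2
    feats["harris_corner_response"] = float(np.maximum(response[m], 0.0).mean())

    # gradient-magnitude statistics
    gx, gy = np.gradient(img)
    mag = np.sqrt(gx**2 + gy**2)[m]
    feats["grad_magnitude_mean"] = float(mag.mean())
    feats["grad_magnitude_sd"] = float(mag.std())
    if mag.max() > 0:
        hist, _ = np.histogram(mag, bins=32, range=(0, mag.max()))
        p = hist / hist.sum()
        p = p[p > 0]
        feats["grad_magnitude_entropy"] = float(-(p * np.log2(p)).sum())
    else:
        feats["grad_magnitude_entropy"] = 0.0

    # local oriented intensity differences
    for name, (dx, dy) in LOSIB_OFFSETS.items():
        sl_src_x = slice(0, -dx) if dx > 0 else slice(-dx, None) if dx < 0 else slice(None)
        sl_dst_x = slice(dx, None) if dx > 0 else slice(0, dx) if dx < 0 else slice(None)
        sl_src_y = slice(0, -dy) if dy > 0 else slice(None)
        sl_dst_y = slice(dy, None) if dy > 0 else slice(None)
        a = img[sl_src_x, sl_src_y]
        b = img[sl_dst_x, sl_dst_y]
        valid = m[sl_src_x, sl_src_y] & m[sl_dst_x, sl_dst_y]
        if valid.any():
            feats[f"losib_mean_diff_{name}"] = float(np.abs(a - b)[valid].mean())
        else:
            feats[f"losib_mean_diff_{name}"] = 0.0
    return feats


def keypoint_gradient_features(roi: IsotropicRoi) -> dict[str, float]:
    """Blob density, corner response, gradient stats and LOSIB differences.

    Masks with fewer than ``MIN_SLICE_PIXELS`` in-plane voxels on every
    slice return all zeros with a warning.
    """
    per_slice, weights = [], []
    for img, m, w in _mask_slices(roi):
        if w < MIN_SLICE_PIXELS:
            continue
        per_slice.append(_slice_keypoint_gradient(img, m))
        weights.append(w)
    if not per_slice:
        warnings.warn("mask too small on every slice; keypoint features set to 0")
        names = (
            ["surf_keypoint_density", "harris_corner_response"]
            + [f"grad_magnitude_{s}" for s in ("mean", "sd", "entropy")]
            + [f"losib_mean_diff_{o}" for o in LOSIB_OFFSETS]
        )
        return {n: 0.0 for n in names}
    return _weighted_mean(per_slice, weights)
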