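"""Synthetic imaging + transcriptomic cohorts with controllable structure.

Tumors are axis-aligned ellipsoids (per-axis radii jittered +/-20%) filled
with a smoothed Gaussian random field: the smoothing kernel SD (texture
correlation length) and the additive white-noise SD are class-dependent,
so homogeneity can be planted as a class difference or zeroed for null
cohorts. Expression is i.i.d. Gaussian on the log scale around per-gene
baselines, with a mean shift on the signature genes in HOT subjects.

One RNG stream is derived per subject from (seed, subject index), so a
cohort can be extended without reshuffling existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import expit

from ctradiomics.errors import ConfigurationError
from ctradiomics.imaging_io import CtVolume, SegmentationMask, write_ct, write_mask

DEFAULT_N_GENES = 2559
DEFAULT_N_SIGNATURE_GENES = 27

TISSUE_BASELINE_HU = 40.0
LUNG_BACKGROUND_HU = -800.0
SMOOTH_FIELD_AMPLITUDE_HU = 30.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_subjects: int = 20
    prevalence_dc: float = 0.55
    image_shape: tuple[int, int, int] = (40, 40, 32)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: (class 0 = progression, class 1 = disease control) radius ranges, mm
    tumor_radius_mm_by_class: tuple[tuple[float, float], tuple[float, float]] = (
        (6.0, 11.0),
        (6.0, 11.0),
    )
    texture_corr_length_by_class: tuple[float, float] = (1.5, 1.5)
    noise_sd_by_class: tuple[float, float] = (20.0, 20.0)
    n_genes: int = DEFAULT_N_GENES
    n_signature_genes: int = DEFAULT_N_SIGNATURE_GENES
    signature_shift: float = 2.0
    hotcold_response_log_odds: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if not 0.0 < self.prevalence_dc < 1.0:
            raise ConfigurationError("prevalence_dc must lie in (0, 1)")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ConfigurationError("voxel spacing must be positive")
        if any(d <= 0 for d in self.image_shape):
            raise ConfigurationError("image shape must be positive")
        for lo, hi in self.tumor_radius_mm_by_class:
            if lo <= 0 or hi < lo:
                raise ConfigurationError("tumor radius ranges must be positive")
        if any(c <= 0 for c in self.texture_corr_length_by_class):
            raise ConfigurationError("correlation lengths must be positive")
        if any(s < 0 for s in self.noise_sd_by_class):
            raise ConfigurationError("noise SDs must be non-negative")
        if self.n_signature_genes > self.n_genes:
            raise ConfigurationError("n_signature_genes cannot exceed n_genes")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"GENE{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def signature_genes(self) -> list[str]:
        return self.gene_names[: self.n_signature_genes]

    @classmethod
    def null(cls, n_subjects: int, seed: int, **kw) -> "SyntheticCohortConfig":
        """All class-difference parameters zeroed (identical classes)."""
        params = dict(
            tumor_radius_mm_by_class=((6.0, 11.0), (6.0, 11.0)),
            texture_corr_length_by_class=(1.5, 1.5),
            noise_sd_by_class=(20.0, 20.0),
            signature_shift=0.0,
            hotcold_response_log_odds=0.0,
        )
        params.update(kw)
        return cls(n_subjects=n_subjects, seed=seed, **params)

    @classmethod
    def strong_effect(cls, n_subjects: int, seed: int, **kw) -> "SyntheticCohortConfig":
        """Large class differences in size and texture homogeneity."""
        params = dict(
            tumor_radius_mm_by_class=((9.0, 13.0), (5.0, 8.0)),
            texture_corr_length_by_class=(0.7, 2.5),
            noise_sd_by_class=(60.0, 8.0),
            signature_shift=3.0,
            hotcold_response_log_odds=4.0,
        )
        params.update(kw)
        return cls(n_subjects=n_subjects, seed=seed, **params)


@dataclass
class SyntheticSubject:
    subject_id: str
    volume: CtVolume
    mask: SegmentationMask
    expression: pd.Series
    dc_label: int
    hotcold_label: int


def _subject_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, index])


def _ellipsoid_mask(shape, spacing, radii_mm, center_vox) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) for n in shape], indexing="ij", sparse=True
    )
    acc = np.zeros(shape, dtype=float)
    for g, c, s, r in zip(grids, center_vox, spacing, radii_mm):
        acc = acc + (((g - c) * s) / r) ** 2
    return acc <= 1.0


def _subject_image(cfg: SyntheticCohortConfig, rng, dc: int):
    cls = int(dc)
    lo, hi = cfg.tumor_radius_mm_by_class[cls]
    radius = rng.uniform(lo, hi)
    radii = radius * (1.0 + rng.uniform(-0.2, 0.2, size=3))
    shape = cfg.image_shape
    spacing = cfg.voxel_spacing_mm
    center = [n / 2.0 - 0.5 + rng.uniform(-1.5, 1.5) for n in shape]
    labels = _ellipsoid_mask(shape, spacing, radii, center)
    if not labels.any():  # radius below voxel size: force a single voxel
        labels[tuple(int(round(c)) for c in center)] = True

    corr = cfg.texture_corr_length_by_class[cls]
    noise_sd = cfg.noise_sd_by_class[cls]
    smooth = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    intensities = np.full(shape, LUNG_BACKGROUND_HU)
    tumor_signal = (
        TISSUE_BASELINE_HU
        + SMOOTH_FIELD_AMPLITUDE_HU * smooth
        + noise_sd * rng.standard_normal(shape)
    )
    intensities[labels] = tumor_signal[labels]
    vol = CtVolume(intensities, spacing)
    return vol, SegmentationMask(labels, spacing)


def generate_transcriptome(
    cfg: SyntheticCohortConfig, dc_labels
) -> tuple[pd.DataFrame, np.ndarray]:
    """Log-scale expression table and HOT/COLD labels for given DC labels.

    HOT assignment is Bernoulli with log-odds ``hotcold_response_log_odds *
    (dc - 1/2)``; HOT subjects get a ``signature_shift`` mean offset on the
    signature genes.
    """
    dc = np.asarray(dc_labels).astype(int).ravel()
    if dc.size != cfg.n_subjects:
        raise ConfigurationError("dc_labels length must equal n_subjects")
    baseline_rng = np.random.default_rng([cfg.seed, 3])
    baselines = baseline_rng.normal(5.0, 1.0, size=cfg.n_genes)

    names = cfg.gene_names
    n_sig = cfg.n_signature_genes
    rows = np.empty((cfg.n_subjects, cfg.n_genes))
    hot = np.empty(cfg.n_subjects, dtype=int)
    for i in range(cfg.n_subjects):
        rng = _subject_rng(cfg.seed, i, stream=2)
        p_hot = expit(cfg.hotcold_response_log_odds * (dc[i] - 0.5))
        hot[i] = int(rng.random() < p_hot)
        expr = baselines + rng.standard_normal(cfg.n_genes)
        if hot[i]:
            expr[:n_sig] += cfg.signature_shift
        rows[i] = expr
    ids = [f"S{i:04d}" for i in range(cfg.n_subjects)]
    return pd.DataFrame(rows, index=ids, columns=names), hot


def generate_cohort(cfg: SyntheticCohortConfig) -> list[SyntheticSubject]:
    """Deterministically generate ``n_subjects`` synthetic subjects."""
    dc = np.empty(cfg.n_subjects, dtype=int)
    images = []
    for i in range(cfg.n_subjects):
        rng = _subject_rng(cfg.seed, i, stream=1)
        dc[i] = int(rng.random() < cfg.prevalence_dc)
        images.append(_subject_image(cfg, rng, dc[i]))
    expression, hot = generate_transcriptome(cfg, dc)
    return [
        SyntheticSubject(
            subject_id=f"S{i:04d}",
            volume=images[i][0],
            mask=images[i][1],
            expression=expression.iloc[i],
            dc_label=int(dc[i]),
            hotcold_label=int(hot[i]),
        )
        for i in range(cfg.n_subjects)
    ]


def hotcold_from_signature(expression: pd.DataFrame, signature_genes) -> np.ndarray:
    """Reference dichotomizer: HOT iff mean Z-scored signature expression > 0.

    Genes with zero variance across subjects contribute 0; a missing gene
    raises an error naming it.
    """
    for gene in signature_genes:
        if gene not in expression.columns:
            raise ConfigurationError(f"signature gene {gene!r} missing from table")
    sub = expression[list(signature_genes)].to_numpy(dtype=float)
    sd = sub.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (sub - sub.mean(axis=0)) / sd_safe
    z[:, sd == 0] = 0.0
    return (z.mean(axis=1) > 0).astype(int)


def labels_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dc_label": [s.dc_label for s in subjects],
            "hotcold_label": [s.hotcold_label for s in subjects],
        },
        index=[s.subject_id for s in subjects],
    )


def expression_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {s.subject_id: s.expression for s in subjects}
    ).T.loc[[s.subject_id for s in subjects]]


def write_cohort(
    subjects: list[SyntheticSubject],
    directory: str,
    cfg: SyntheticCohortConfig,
    image_format: str = "nifti",
) -> None:
    """Serialize a cohort: per-subject volumes + masks, TSV tables, manifest."""
    import os

    os.makedirs(directory, exist_ok=True)
    for s in subjects:
        if image_format == "nifti":
            write_ct(s.volume, os.path.join(directory, f"{s.subject_id}_ct.nii"))
        elif image_format == "dicom":
            write_ct(s.volume, os.path.join(directory, f"{s.subject_id}_ct"))
        else:
            raise ConfigurationError(f"unknown image format {image_format!r}")
        write_mask(s.mask, os.path.join(directory, f"{s.subject_id}_mask.nii"))
    expression_frame(subjects).to_csv(
        os.path.join(directory, "expression.tsv"), sep="\t", index_label="subject_id"
    )
    labels_frame(subjects).to_csv(
        os.path.join(directory, "labels.tsv"), sep="\t", index_label="subject_id"
    )
    manifest = {
        "n_subjects": cfg.n_subjects,
        "seed": cfg.seed,
        "image_format": image_format,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.__dict__.items()
        },
    }
    with open(os.path.join(directory, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)


def null_config(n_subjects: int, seed: int, **kw) -> SyntheticCohortConfig:
    """Alias for :meth:`SyntheticCohortConfig.null`."""
    return SyntheticCohortConfig.null(n_subjects, seed, **kw)


def strong_effect_config(n_subjects: int, seed: int, **kw) -> SyntheticCohortConfig:
    """Alias for :meth:`SyntheticCohortConfig.strong_effect`."""
    return SyntheticCohortConfig.strong_effect(n_subjects, seed, **kw)


def with_seed(cfg: SyntheticCohortConfig, seed: int) -> SyntheticCohortConfig:
    return replace(cfg, seed=seed)
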