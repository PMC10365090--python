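"""Canonical 342-feature registry, per-lesion extraction, cohort tables.

The registry is a pinned, ordered manifest: 55 mask-shape features, 14
first-order features, 28 texture-matrix features at each of the 7 default
gray-level quantizations (196), one lacunarity summary, 60 Gabor-bank
statistics, 7 Fourier-spectrum features and 9 keypoint/gradient/LOSIB
descriptors. Every entry carries a provenance tag: ``paper-named`` for
features the source taxonomy names explicitly, ``standard`` for
community-standard definitions, ``artifact-defined`` for concrete
stand-ins defined by this package. Adding a feature is a breaking change
(the manifest hash is asserted in the test suite).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ctradiomics import (
    frequency_keypoint_features as fkf,
    shape_features as shf,
    texture_features as txf,
)
from ctradiomics.errors import ConfigurationError, CtRadiomicsError
from ctradiomics.frequency_keypoint_features import GaborBankConfig
from ctradiomics.imaging_io import CtVolume, SegmentationMask
from ctradiomics.preprocessing import (
    DEFAULT_G_LEVELS,
    DEFAULT_TARGET_SPACING_MM,
    quantize_equal_probability,
    resample_isotropic,
)

EXPECTED_N_FEATURES = 342

#: paper-named texture features, keyed by (family, feature key)
_PAPER_NAMES = {
    ("ngtdm", "contrast"): "NGTDM contrast",
    ("glrlm", "gray_level_nonuniformity"): "Gray Level Non-Uniformity",
    ("glszm", "gray_level_nonuniformity"): "Gray Level Non-Uniformity",
    ("glrlm", "long_run_high_gray_level_emphasis"): "Long Run High Gray Level Emphasis",
    ("glszm", "large_zone_size_emphasis"): "Large Zone Size Emphasis",
    ("glszm", "zone_size_nonuniformity"): "Zone Size Non-Uniformity",
}

_ARTIFACT_FAMILIES = {"dist", "skeleton", "fourier", "keypoint", "lacunarity"}


class FeatureExtractionError(CtRadiomicsError):
    """A feature family failed for a lesion; names both."""


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str  # unique registry name, e.g. "glrlm.gray_level_nonuniformity.G8"
    family: str
    feature: str  # family-local key
    n_levels: int | None = None  # quantization G for texture families
    provenance: str = "standard"
    paper_name: str | None = None


def _texture_provenance(family: str, feature: str) -> tuple[str, str | None]:
    paper = _PAPER_NAMES.get((family, feature))
    return ("paper-named", paper) if paper else ("standard", None)


def build_registry(
    g_levels: tuple[int, ...] = DEFAULT_G_LEVELS,
) -> tuple[FeatureDescriptor, ...]:
    """Construct the ordered feature manifest (342 entries under defaults)."""
    entries: list[FeatureDescriptor] = []

    def add(family, feature, g=None, provenance="standard", paper_name=None):
        name = f"{family}.{feature}" + (f".G{g}" if g is not None else "")
        entries.append(
            FeatureDescriptor(name, family, feature, g, provenance, paper_name)
        )

    for key in (
        "volume_mm3",
        "surface_mm2",
        "surface_to_volume_ratio",
        "sphericity",
        "compactness1",
        "compactness2",
        "spherical_disproportion",
        "max_diameter_3d_mm",
    ):
        add("size", key)
    for i in range(1, 9):
        add("hu", f"hu_moment_{i}")
    for i in range(1, 7):
        add("affine", f"affine_moment_invariant_{i}")
    for n, m in shf.zernike_index_pairs():
        add("zernike", f"zernike_magnitude_n{n}_m{m}")
    for key in (
        "skeleton_n_branch_points",
        "skeleton_n_endpoints",
        "skeleton_length_mm",
        "skeleton_mean_branch_length_mm",
    ):
        add("skeleton", key, provenance="artifact-defined")
    for key in ("dist_mean_mm", "dist_sd_mm", "dist_min_max_ratio", "dist_entropy"):
        add("dist", key, provenance="artifact-defined")

    for key in txf.FIRST_ORDER_FEATURE_NAMES:
        add("first_order", key)

    for g in g_levels:
        for family, names in (
            ("glcm", txf.GLCM_FEATURE_NAMES),
            ("glrlm", txf.GLRLM_FEATURE_NAMES),
            ("glszm", txf.GLSZM_FEATURE_NAMES),
            ("ngtdm", txf.NGTDM_FEATURE_NAMES),
        ):
            for key in names:
                prov, paper = _texture_provenance(family, key)
                add(family, key, g=g, provenance=prov, paper_name=paper)

    add("lacunarity", "lacunarity", provenance="artifact-defined")

    cfg = GaborBankConfig()
    for s in range(cfg.n_scales):
        for o in range(cfg.n_orientations):
            add("gabor", f"gabor_energy_s{s}_o{o}")
            add("gabor", f"gabor_mean_abs_s{s}_o{o}")
    for i in range(fkf.FOURIER_N_RINGS):
        add("fourier", f"fourier_ring_fraction_{i}", provenance="artifact-defined")
    add("fourier", "fourier_spectral_entropy", provenance="artifact-defined")
    for key in (
        "surf_keypoint_density",
        "harris_corner_response",
        "grad_magnitude_mean",
        "grad_magnitude_sd",
        "grad_magnitude_entropy",
        "losib_mean_diff_0",
        "losib_mean_diff_45",
        "losib_mean_diff_90",
        "losib_mean_diff_135",
    ):
        add("keypoint", key, provenance="artifact-defined")

    return tuple(entries)


REGISTRY: tuple[FeatureDescriptor, ...] = build_registry()
REGISTRY_NAMES: tuple[str, ...] = tuple(d.name for d in REGISTRY)

assert len(REGISTRY) == EXPECTED_N_FEATURES


def registry_hash(registry=REGISTRY) -> str:
    """SHA-256 over the ordered (name, family, G, provenance) manifest."""
    payload = json.dumps(
        [[d.name, d.family, d.feature, d.n_levels, d.provenance] for d in registry]
    )
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class ExtractionConfig:
    target_spacing_mm: float = DEFAULT_TARGET_SPACING_MM
    g_levels: tuple[int, ...] = DEFAULT_G_LEVELS
    gabor: GaborBankConfig = field(default_factory=GaborBankConfig)


def extract_all(
    volume: CtVolume,
    mask: SegmentationMask,
    config: ExtractionConfig | None = None,
    lesion_id: str = "<lesion>",
) -> pd.Series:
    """Full 342-entry feature vector for one lesion.

    Runs isotropic resampling, the shape families on the native-grid mask,
    and the intensity/texture families on the resampled ROI at every
    quantization in the config. Output order matches the registry exactly;
    any non-finite value or family failure raises
    :class:`FeatureExtractionError` naming the family and lesion.
    """
    config = config or ExtractionConfig()
    values: dict[str, float] = {}

    def run(family: str, fn, prefix: str | None = None, g: int | None = None):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise FeatureExtractionError(
                f"family '{family}' failed for lesion {lesion_id}: {exc}"
            ) from exc
        for key, val in out.items():
            name = f"{prefix or family}.{key}" + (f".G{g}" if g is not None else "")
            values[name] = val

    spacing = mask.voxel_spacing_mm
    run("size", lambda: shf.size_shape(mask.labels, spacing))
    moments = {}
    run("moments", lambda: shf.moment_invariants(mask.labels), prefix="_m")
    for key, val in list(values.items()):
        if key.startswith("_m."):
            moments[key[3:]] = val
            del values[key]
    for fam, prefix in (("hu", "hu_moment_"), ("affine", "affine_moment_"),
                        ("zernike", "zernike_")):
        for key, val in moments.items():
            if key.startswith(prefix):
                values[f"{fam}.{key}"] = val
    run("skeleton", lambda: shf.skeleton_features(mask.labels, spacing))
    run("dist", lambda: shf.radial_distance_features(mask.labels, spacing))

    roi = resample_isotropic(volume, mask, config.target_spacing_mm)
    run("first_order", lambda: txf.first_order(roi))
    for g in config.g_levels:
        q = quantize_equal_probability(roi, g)
        run("glcm", lambda q=q: txf.glcm_features(q), g=g)
        run("glrlm", lambda q=q: txf.glrlm_features(q), g=g)
        run("glszm", lambda q=q: txf.glszm_features(q), g=g)
        run("ngtdm", lambda q=q: txf.ngtdm_features(q), g=g)
    run("lacunarity", lambda: txf.lacunarity(roi.mask))
    run("gabor", lambda: fkf.gabor_features(roi, config.gabor))
    run("fourier", lambda: fkf.fourier_features(roi))
    run("keypoint", lambda: fkf.keypoint_gradient_features(roi))

    missing = [n for n in REGISTRY_NAMES if n not in values]
    if missing:
        raise FeatureExtractionError(
            f"lesion {lesion_id}: extraction produced no value for {missing[:5]}..."
        )
    vec = pd.Series([values[n] for n in REGISTRY_NAMES], index=list(REGISTRY_NAMES))
    bad = vec.index[~np.isfinite(vec.to_numpy(dtype=float))]
    if len(bad):
        raise FeatureExtractionError(
            f"lesion {lesion_id}: non-finite values in {list(bad[:5])}"
        )
    return vec


class FeatureTable:
    """Subjects x features matrix with labels and per-column provenance.

    ``data`` is a numeric DataFrame indexed by subject id; ``labels`` holds
    outcome columns; ``provenance`` maps each feature column to one of
    ``radiomic`` / ``gene`` / ``hotcold``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        labels: pd.DataFrame | None = None,
        provenance: pd.Series | None = None,
        constant_columns: tuple[str, ...] = (),
    ):
        if data.isna().any().any():
            raise ConfigurationError("feature table contains missing values")
        self.data = data.astype(float)
        self.labels = (
            labels if labels is not None else pd.DataFrame(index=data.index)
        )
        if provenance is None:
            provenance = pd.Series("radiomic", index=data.columns)
        self.provenance = provenance.reindex(data.columns).fillna("radiomic")
        self.constant_columns = tuple(constant_columns)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_vectors(
        cls, vectors: dict[str, pd.Series], labels: pd.DataFrame | None = None
    ) -> "FeatureTable":
        data = pd.DataFrame(
            {sid: v for sid, v in vectors.items()}
        ).T.loc[list(vectors)]
        return cls(data, labels)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    # -- operations ---------------------------------------------------------
    def zscore_normalize(self) -> "FeatureTable":
        """Column-wise Z-score using this table's own statistics.

        Train and validation tables are normalized independently (each with
        its own mean/SD). Constant columns become all-zero and are flagged.
        """
        arr = self.data.to_numpy(dtype=float)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0)
        constant = sd == 0
        sd_safe = np.where(constant, 1.0, sd)
        out = (arr - mean) / sd_safe
        out[:, constant] = 0.0
        flagged = tuple(np.asarray(self.data.columns)[constant])
        return FeatureTable(
            pd.DataFrame(out, index=self.data.index, columns=self.data.columns),
            self.labels,
            self.provenance,
            constant_columns=flagged,
        )

    def select(self, feature_names) -> "FeatureTable":
        missing = [f for f in feature_names if f not in self.data.columns]
        if missing:
            raise ConfigurationError(f"missing feature columns: {missing}")
        return FeatureTable(
            self.data[list(feature_names)],
            self.labels,
            self.provenance[list(feature_names)],
        )

    def subset(self, subject_ids) -> "FeatureTable":
        return FeatureTable(
            self.data.loc[list(subject_ids)],
            self.labels.loc[list(subject_ids)],
            self.provenance,
        )

    def merge_omics(self, omics, provenance_flag: str = "gene") -> "FeatureTable":
        """Inner-join omics columns (expression table or a label column).

        Column order is radiomic columns first then omics columns; merged
        provenance flags are set per column.
        """
        if isinstance(omics, pd.Series):
            omics = omics.to_frame()
        shared = self.data.index.intersection(omics.index)
        if len(shared) == 0:
            raise ConfigurationError("no shared subject ids between tables")
        data = pd.concat(
            [self.data.loc[shared], omics.loc[shared].astype(float)], axis=1
        )
        prov = pd.concat(
            [
                self.provenance,
                pd.Series(provenance_flag, index=omics.columns),
            ]
        )
        return FeatureTable(data, self.labels.loc[shared], prov)

    # -- serialization ------------------------------------------------------
    def write_tsv(self, path: str, manifest_path: str | None = None) -> None:
        out = pd.concat([self.data, self.labels], axis=1)
        out.to_csv(path, sep="\t", index_label="subject_id")
        if manifest_path:
            manifest = {
                "registry_hash": registry_hash(),
                "n_features": self.n_features,
                "label_columns": list(self.labels.columns),
                "provenance": self.provenance.to_dict(),
                "constant_columns": list(self.constant_columns),
            }
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=1)

    @classmethod
    def read_tsv(
        cls, path: str, label_columns=(), manifest_path: str | None = None
    ) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
        df.index = df.index.astype(str)
        df.index.name = None
        label_columns = list(label_columns)
        prov = None
        if manifest_path:
            with open(manifest_path) as fh:
                manifest = json.load(fh)
            label_columns = label_columns or manifest.get("label_columns", [])
            prov_map = manifest.get("provenance")
            if prov_map:
                prov = pd.Series(prov_map)
        labels = df[label_columns] if label_columns else None
        data = df.drop(columns=label_columns)
        return cls(data, labels, prov)


def zscore_normalize(table: FeatureTable) -> FeatureTable:
    """Functional alias for :meth:`FeatureTable.zscore_normalize`."""
    return table.zscore_normalize()


def merge_omics(table: FeatureTable, omics, provenance_flag="gene") -> FeatureTable:
    """Functional alias for :meth:`FeatureTable.merge_omics`."""
    return table.merge_omics(omics, provenance_flag)
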