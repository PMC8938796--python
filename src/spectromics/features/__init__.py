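"""Agnostic radiomic feature bank.

From each tumor volume, 851 features are extracted: 14 shape features
(mask-only, computed once), plus 93 intensity/texture features (18
first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM) on the
original image and on each of the 8 one-level wavelet sub-bands
(14 + 9 x 93 = 851).

Feature names follow the convention ``transform_family_feature_source``,
e.g. ``original_shape_Sphericity_EID`` or ``wavelet-LLH_glcm_Contrast_I``.
Per-subject channels are grouped into three feature spaces:

* ``EID``          — the conventional energy-integrating image (851 columns)
* ``PCD``          — the four photon-counting energy bins (3404 columns)
* ``MaterialMaps`` — the decomposed I/PE/CS maps (2553 columns)

To keep texture computation local and translation-invariant, extraction
operates on the mask's bounding box expanded by a fixed 6-voxel margin
(clipped at the volume edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import discretize
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .shape import SHAPE_NAMES, shape_features
from .texture import TEXTURE_FAMILIES, texture_features
from .wavelet import SUBBAND_NAMES, wavelet_subbands

__all__ = [
    "FeatureName",
    "FeatureTable",
    "extract_all",
    "extract_cohort",
    "discretize",
    "firstorder_features",
    "shape_features",
    "texture_features",
    "wavelet_subbands",
    "FEATURES_PER_VOLUME",
    "GROUP_SOURCES",
    "DEFAULT_BIN_WIDTH_CT",
    "DEFAULT_BIN_WIDTH_MATERIALS",
]

#: number of features per single volume: 14 shape + 9 images x 93
FEATURES_PER_VOLUME = 851
_FAMILY_ORDER = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

GROUP_SOURCES = {
    "EID": ("EID",),
    "PCD": ("PCD-E1", "PCD-E2", "PCD-E3", "PCD-E4"),
    "MaterialMaps": ("I", "PE", "CS"),
}

DEFAULT_BIN_WIDTH_CT = 25.0
#: material maps live on a mg/mL-like scale; a CT-sized bin would collapse
#: them to a single gray level
DEFAULT_BIN_WIDTH_MATERIALS = 0.25

_BBOX_MARGIN = 6


@dataclass(frozen=True)
class FeatureName:
    """Structured radiomic feature name."""

    transform: str  # 'original' or 'wavelet-LLL'..'wavelet-HHH'
    family: str  # 'shape', 'firstorder', 'glcm', ...
    feature: str  # canonical feature id, e.g. 'Sphericity'
    source: str  # 'EID', 'PCD-E1'..'PCD-E4', 'I', 'PE', 'CS'

    def __str__(self) -> str:
        return f"{self.transform}_{self.family}_{self.feature}_{self.source}"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        transform, family, feature, source = name.split("_")
        return cls(transform, family, feature, source)


@dataclass
class FeatureTable:
    """Subjects x features matrix for one feature space."""

    data: pd.DataFrame  # index: subject ids, columns: serialized names
    labels: np.ndarray  # class label per row (1 = lymphocyte-present)
    group: str  # 'EID' | 'PCD' | 'MaterialMaps'

    def __post_init__(self):
        if len(self.data) != len(self.labels):
            raise ValueError("one label required per subject row")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()][0]
            raise ValueError(f"NaN feature value in column {bad}")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def _crop_to_mask(arrays, mask, margin=_BBOX_MARGIN):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return [a[sl] for a in arrays], mask[sl]


def extract_all(
    volume: np.ndarray,
    mask: np.ndarray,
    source_tag: str,
    voxel_size_mm: float = 1.0,
    bin_width: float = DEFAULT_BIN_WIDTH_CT,
    wavelet: str = "coif1",
) -> dict:
    """Extract the full 851-feature bank from one volume + mask.

    Each transform image (original and the 8 wavelet sub-bands) is
    re-discretized independently with the same fixed bin width.  Any
    non-finite feature raises with the offending feature name.
    """
    volume = np.asarray(volume, float)
    mask = np.asarray(mask, bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must be co-registered")
    (cvol,), cmask = _crop_to_mask([volume], mask)

    out: dict = {}
    for feat, val in shape_features(cmask, voxel_size_mm).items():
        out[str(FeatureName("original", "shape", feat, source_tag))] = val

    images = {"original": cvol}
    for name, band in wavelet_subbands(cvol, wavelet=wavelet).items():
        images[f"wavelet-{name}"] = band

    for transform, img in images.items():
        fo = firstorder_features(img, cmask, voxel_size_mm, bin_width)
        for feat in FIRSTORDER_NAMES:
            out[str(FeatureName(transform, "firstorder", feat, source_tag))] = fo[feat]
        levels, n_levels = discretize(img, cmask, bin_width)
        for family in _FAMILY_ORDER[1:]:
            vals = texture_features(levels, n_levels, family)
            for feat in TEXTURE_FAMILIES[family][1]:
                out[str(FeatureName(transform, family, feat, source_tag))] = vals[feat]

    if len(out) != FEATURES_PER_VOLUME:
        raise RuntimeError(
            f"feature census mismatch: {len(out)} != {FEATURES_PER_VOLUME}"
        )
    for name, val in out.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite feature value for {name}")
    return out


def _subject_channels(subject, maps):
    """Map source tag -> volume for one subject."""
    channels = {"EID": subject.eid}
    for i in range(subject.spectral.bins.shape[0]):
        channels[f"PCD-E{i + 1}"] = subject.spectral.bins[i]
    channels["I"] = maps.iodine
    channels["PE"] = maps.pe
    channels["CS"] = maps.cs
    return channels


def extract_cohort(
    cohort,
    masks=None,
    maps=None,
    bin_width_ct: float = DEFAULT_BIN_WIDTH_CT,
    bin_width_materials: float = DEFAULT_BIN_WIDTH_MATERIALS,
    wavelet: str = "coif1",
) -> dict:
    """Extract the three grouped feature tables for a whole cohort.

    ``masks`` defaults to each subject's ground-truth tumor mask; ``maps``
    defaults to the ground-truth material maps (pass decomposed maps for the
    full pipeline).  Returns ``{"EID": FeatureTable, "PCD": ..,
    "MaterialMaps": ..}`` with 851 / 3404 / 2553 columns.
    """
    subjects = cohort.subjects
    if masks is None:
        masks = [s.truth.tumor_mask for s in subjects]
    if maps is None:
        maps = [s.truth.as_maps(s.voxel_size_mm) for s in subjects]

    rows: dict = {g: [] for g in GROUP_SOURCES}
    for subject, mask, mmaps in zip(subjects, masks, maps):
        channels = _subject_channels(subject, mmaps)
        missing = [
            src
            for srcs in GROUP_SOURCES.values()
            for src in srcs
            if src not in channels
        ]
        if missing:
            raise ValueError(
                f"subject {subject.subject_id} missing channel(s) {missing}"
            )
        for group, sources in GROUP_SOURCES.items():
            row: dict = {}
            for src in sources:
                bw = bin_width_materials if group == "MaterialMaps" else bin_width_ct
                row.update(
                    extract_all(
                        channels[src],
                        mask,
                        src,
                        voxel_size_mm=subject.voxel_size_mm,
                        bin_width=bw,
                        wavelet=wavelet,
                    )
                )
            rows[group].append(row)

    labels = np.array([s.class_label for s in subjects], dtype=int)
    ids = [s.subject_id for s in subjects]
    return {
        group: FeatureTable(
            data=pd.DataFrame(rows[group], index=ids),
            labels=labels,
            group=group,
        )
        for group in GROUP_SOURCES
    }
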