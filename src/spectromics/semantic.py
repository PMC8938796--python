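"""Conventional ("semantic") tumor metrics from the iodine map.

Five radiologist-interpretable quantities are computed from the decomposed
iodine concentration map and the tumor mask: tumor volume, iodine-enhanced
tumor volume, enhanced tumor percentage, accumulated iodine mass, and mean
iodine concentration.  Voxels below the 1 mg/mL detection floor are
discarded before the iodine quantities are computed.

Unit bookkeeping: 1 mg/mL == 1 ug/mm^3, so concentration [mg/mL] times voxel
volume [mm^3] gives micrograms; the accumulated mass is reported in mg
(divide by 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["SemanticFeatures", "compute_semantic"]


@dataclass(frozen=True)
class SemanticFeatures:
    tumor_volume_mm3: float
    enhanced_volume_mm3: float
    enhanced_percent: float
    iodine_mass_mg: float
    mean_iodine_mgml: float
    #: True when no voxel cleared the threshold and mean/mass default to 0.
    mean_undefined: bool = False

    def __post_init__(self):
        if not (0.0 <= self.enhanced_percent <= 100.0):
            raise ValueError("enhanced_percent outside [0, 100]")
        if self.enhanced_volume_mm3 > self.tumor_volume_mm3 + 1e-9:
            raise ValueError("enhanced volume exceeds tumor volume")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_semantic(
    iodine_map: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float,
    min_mgml: float = 1.0,
    enhanced_only: bool = True,
) -> SemanticFeatures:
    """Compute the five semantic tumor metrics.

    ``enhanced_only=True`` (default) averages iodine over the surviving
    (>= ``min_mgml``) voxels; ``False`` averages over the whole tumor mask
    for sensitivity analysis.  Mass always accumulates surviving voxels.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty tumor mask")
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    v = float(voxel_size_mm) ** 3  # mm^3 per voxel
    values = np.asarray(iodine_map, float)[mask]
    n_tumor = values.size
    enhanced = values[values >= min_mgml]
    n_enh = enhanced.size

    mass_ug = float(enhanced.sum() * v)  # mg/mL * mm^3 = ug
    mean_undefined = n_enh == 0
    if mean_undefined:
        mean = 0.0
    elif enhanced_only:
        mean = float(enhanced.mean())
    else:
        mean = float(values.mean())
    return SemanticFeatures(
        tumor_volume_mm3=n_tumor * v,
        enhanced_volume_mm3=n_enh * v,
        enhanced_percent=100.0 * n_enh / n_tumor,
        iodine_mass_mg=mass_ug / 1000.0,
        mean_iodine_mgml=mean,
        mean_undefined=mean_undefined,
    )
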