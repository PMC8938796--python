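"""Seed-based region-growing tumor segmentation.

Segmentation is performed on the lowest-energy photon-counting bin (best
iodine contrast) and the resulting mask is reused for every co-registered
channel of the same subject.  The grown region is the connected set of
voxels, reachable from the seed, whose intensity lies within an absolute
tolerance band around the mean of the seed's 3x3x3 neighborhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["TumorMask", "region_grow", "propagate_mask", "dice"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class TumorMask:
    mask: np.ndarray
    seed_point: tuple
    tolerance: float
    connectivity: int = 26

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        if not self.mask.any():
            raise ValueError("tumor mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def region_grow(
    volume: np.ndarray,
    seed_point,
    tolerance: float,
    connectivity: int = 26,
    max_fraction: float = 0.5,
) -> TumorMask:
    """Grow a connected region from a seed within an intensity band.

    The band is ``[mu - tolerance, mu + tolerance]`` where ``mu`` is the mean
    intensity over the 3x3x3 neighborhood of the seed.  Deterministic for
    fixed inputs.  A region exceeding ``max_fraction`` of the volume triggers
    a leak warning.
    """
    volume = np.asarray(volume, float)
    seed = tuple(int(c) for c in seed_point)
    if len(seed) != volume.ndim:
        raise ValueError("seed must have one coordinate per axis")
    if any(c < 0 or c >= n for c, n in zip(seed, volume.shape)):
        raise ValueError(f"seed {seed} out of bounds for shape {volume.shape}")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")

    nb = tuple(
        slice(max(0, c - 1), min(n, c + 2)) for c, n in zip(seed, volume.shape)
    )
    mu = volume[nb].mean()
    band = np.abs(volume - mu) <= tolerance
    labels, _ = ndimage.label(band, structure=_STRUCTURES[connectivity])
    seed_label = labels[seed]
    if seed_label == 0:
        # seed itself outside the band (can happen with a hot/cold seed voxel)
        mask = np.zeros_like(band)
        mask[seed] = True
    else:
        mask = labels == seed_label
    frac = mask.mean()
    if frac > max_fraction:
        warnings.warn(
            f"grown region covers {frac:.0%} of the volume "
            f"(leak threshold {max_fraction:.0%})",
            stacklevel=2,
        )
    return TumorMask(
        mask=mask, seed_point=seed, tolerance=tolerance, connectivity=connectivity
    )


def propagate_mask(mask: TumorMask, targets) -> list:
    """Apply one segmentation mask to every co-registered channel.

    Returns the list of masked 1D views (one value vector per channel).
    """
    out = []
    for i, vol in enumerate(targets):
        vol = np.asarray(vol)
        if vol.shape != mask.mask.shape:
            raise ValueError(
                f"channel {i} grid {vol.shape} does not match mask grid "
                f"{mask.mask.shape}"
            )
        out.append(vol[mask.mask])
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
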