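"""Fixed-bin-width gray-level discretization for texture analysis."""

from __future__ import annotations

import numpy as np

__all__ = ["discretize"]


def discretize(volume: np.ndarray, mask: np.ndarray, bin_width: float = 25.0):
    """Map masked intensities to integer gray levels with a fixed bin width.

    ``level(v) = floor((v - min_masked) / bin_width) + 1``, so levels start
    at 1; voxels outside the mask carry level 0.  Returns
    ``(level_volume, n_levels)`` where ``n_levels`` is the highest level
    (the level range is contiguous from 1, though interior levels may be
    unpopulated).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    volume = np.asarray(volume, float)
    vals = volume[mask]
    levels = np.zeros(volume.shape, dtype=np.int32)
    levels[mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return levels, int(levels.max())
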