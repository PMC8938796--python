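"""First-order (intensity histogram) features over a masked region."""

from __future__ import annotations

import numpy as np

__all__ = ["firstorder_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    volume: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float = 1.0,
    bin_width: float = 25.0,
) -> dict:
    """Compute the 18 first-order features of the masked intensities.

    Entropy and uniformity use the fixed-bin-width histogram (same width as
    the texture discretization).  Variance is the population variance;
    kurtosis is non-excess (3 for a normal distribution).  Skewness and
    kurtosis of a constant region are defined as 0.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(volume, float)[mask]
    n = x.size
    mean = x.mean()
    dev = x - mean
    var = float(np.mean(dev**2))
    sd = np.sqrt(var)

    # histogram probabilities on fixed-width bins
    n_bins = int(np.floor((x.max() - x.min()) / bin_width)) + 1
    counts = np.bincount(
        np.floor((x - x.min()) / bin_width).astype(np.int64), minlength=n_bins
    )
    p = counts[counts > 0] / n

    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    core = x[(x >= p10) & (x <= p90)]

    if sd > 0:
        skew = float(np.mean(dev**3) / sd**3)
        kurt = float(np.mean(dev**4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_size_mm**3) * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(median),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(core - core.mean()))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
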