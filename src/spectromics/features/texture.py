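"""Gray-level texture matrices and their derived features (3D).

Five families are implemented on discretized gray-level volumes (level 0
outside the mask, levels 1..Ng inside):

* GLCM  — co-occurrence of level pairs at unit offset; 24 features,
  averaged over the 13 unique 3D directions (symmetric matrices).
* GLRLM — run lengths of equal levels along a direction; 16 features,
  averaged over the 13 directions.
* GLSZM — sizes of 26-connected equal-level zones; 16 features, one matrix.
* NGTDM — difference between each voxel's level and the mean level of its
  in-mask 26-neighborhood; 5 features.
* GLDM  — dependence counts: how many 26-neighbors share the voxel's level
  (within ``alpha``); the dependence of a voxel includes the voxel itself,
  so dependence values run from 1 to 27; 14 features.

Feature definitions follow the common standardized formulations used across
radiomics toolkits; degenerate inputs (single gray level, empty direction)
resolve to documented limit values rather than NaN.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "texture_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "TEXTURE_FAMILIES",
]

#: The 13 unique voxel directions of a 3D 26-neighborhood (one per
#: antipodal pair; the first non-zero component is positive).
DIRECTIONS_13 = tuple(
    d
    for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
)

_ALL_26 = tuple(d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0))

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

#: Degenerate value for NGTDM coarseness when no gray-tone difference exists.
COARSENESS_MAX = 1e6


def _offset_slices(shape, offset):
    """Slices (sa, sb) so arr[sa] and arr[sb] pair voxel x with x+offset."""
    sa, sb = [], []
    for n, d in zip(shape, offset):
        if d == 0:
            sa.append(slice(0, n))
            sb.append(slice(0, n))
        elif d > 0:
            sa.append(slice(0, n - d))
            sb.append(slice(d, n))
        else:
            sa.append(slice(-d, n))
            sb.append(slice(0, n + d))
    return tuple(sa), tuple(sb)


def _log2(p):
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction."""
    sa, sb = _offset_slices(levels.shape, offset)
    a = levels[sa].ravel()
    b = levels[sb].ravel()
    valid = (a > 0) & (b > 0)
    counts = np.bincount(
        (a[valid].astype(np.int64) - 1) * n_levels + (b[valid] - 1),
        minlength=n_levels * n_levels,
    ).reshape(n_levels, n_levels)
    return counts + counts.T


def _glcm_single(P: np.ndarray) -> dict:
    Ng = P.shape[0]
    p = P / P.sum()
    i = np.arange(1, Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    # diagonal-band (|i-j|) and anti-diagonal (i+j) marginals
    k_diff = np.arange(0, Ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    hxy = float(-(p * _log2(p)).sum())
    hx = float(-(px * _log2(px)).sum())
    outer = np.outer(px, px)
    log_outer = _log2(outer)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-(outer * log_outer).sum())

    da = float((k_diff * p_diff).sum())
    autoc = float((ii * jj * p).sum())
    corr = (autoc - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    imc1 = (hxy - hxy1) / max(hx, hx) if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # maximal correlation coefficient via the Q matrix
    if Ng > 1 and (px > 0).sum() > 1:
        nz = px > 0
        pnz = p[np.ix_(nz, nz)]
        pxnz = px[nz]
        Q = (pnz / pxnz[:, None]) @ (pnz / pxnz[None, :]).T
        eigs = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eigs[-2]))) if len(eigs) > 1 else 1.0
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff * _log2(p_diff)).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + k_diff**2 / Ng**2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / Ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p_diff[1:] / k_diff[1:] ** 2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum * _log2(p_sum)).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(levels: np.ndarray, n_levels: int) -> dict:
    """24 GLCM features, averaged over the 13 unique directions."""
    per_dir = []
    for d in DIRECTIONS_13:
        P = glcm_matrix(levels, n_levels, d)
        if P.sum() > 0:
            per_dir.append(_glcm_single(P))
    return _average_dicts(per_dir, GLCM_NAMES)


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(levels: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Run-length count matrix (levels x run length) for one direction."""
    shape = levels.shape
    sa, sb = _offset_slices(shape, offset)
    cont = np.zeros(shape, bool)  # run continues from x to x+offset
    cont[sa] = (levels[sa] > 0) & (levels[sa] == levels[sb])
    has_pred = np.zeros(shape, bool)  # x+offset has an equal-level predecessor
    has_pred[sb] = cont[sa]
    starts = (levels > 0) & ~has_pred

    pos = np.argwhere(starts)
    lv = levels[starts].astype(np.int64)
    run_len = np.ones(len(pos), dtype=np.int64)
    off = np.asarray(offset)
    active = np.arange(len(pos))
    cur = pos.copy()
    while len(active):
        going = cont[tuple(cur[active].T)]
        active = active[going]
        if not len(active):
            break
        run_len[active] += 1
        cur[active] += off

    max_len = int(run_len.max(initial=1))
    P = np.zeros((n_levels, max_len), dtype=np.int64)
    np.add.at(P, (lv - 1, run_len - 1), 1)
    return P


def _rl_style_features(P: np.ndarray, n_voxels: int, style: str) -> dict:
    """Shared gray-level x size/length feature formulas (GLRLM & GLSZM)."""
    Ns = P.sum()
    p = P / Ns
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_g = float((i.ravel() * pg).sum())
    mu_j = float((j.ravel() * pj).sum())
    vals = {
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / Ns),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "GrayLevelVariance": float((((i.ravel() - mu_g) ** 2) * pg).sum()),
        "short": float((p / j**2).sum()),
        "long": float((p * j**2).sum()),
        "low": float((p / i**2).sum()),
        "high": float((p * i**2).sum()),
        "short_low": float((p / (i**2 * j**2)).sum()),
        "short_high": float((p * i**2 / j**2).sum()),
        "long_low": float((p * j**2 / i**2).sum()),
        "long_high": float((p * i**2 * j**2).sum()),
        "len_nonunif": float((P.sum(axis=0) ** 2).sum() / Ns),
        "len_nonunif_norm": float((pj**2).sum()),
        "percentage": float(Ns / n_voxels),
        "len_var": float((((j.ravel() - mu_j) ** 2) * pj).sum()),
        "entropy": float(-(p * _log2(p)).sum()),
    }
    if style == "run":
        return {
            "GrayLevelNonUniformity": vals["GrayLevelNonUniformity"],
            "GrayLevelNonUniformityNormalized": vals["GrayLevelNonUniformityNormalized"],
            "GrayLevelVariance": vals["GrayLevelVariance"],
            "HighGrayLevelRunEmphasis": vals["high"],
            "LongRunEmphasis": vals["long"],
            "LongRunHighGrayLevelEmphasis": vals["long_high"],
            "LongRunLowGrayLevelEmphasis": vals["long_low"],
            "LowGrayLevelRunEmphasis": vals["low"],
            "RunEntropy": vals["entropy"],
            "RunLengthNonUniformity": vals["len_nonunif"],
            "RunLengthNonUniformityNormalized": vals["len_nonunif_norm"],
            "RunPercentage": vals["percentage"],
            "RunVariance": vals["len_var"],
            "ShortRunEmphasis": vals["short"],
            "ShortRunHighGrayLevelEmphasis": vals["short_high"],
            "ShortRunLowGrayLevelEmphasis": vals["short_low"],
        }
    return {
        "GrayLevelNonUniformity": vals["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": vals["GrayLevelNonUniformityNormalized"],
        "GrayLevelVariance": vals["GrayLevelVariance"],
        "HighGrayLevelZoneEmphasis": vals["high"],
        "LargeAreaEmphasis": vals["long"],
        "LargeAreaHighGrayLevelEmphasis": vals["long_high"],
        "LargeAreaLowGrayLevelEmphasis": vals["long_low"],
        "LowGrayLevelZoneEmphasis": vals["low"],
        "SizeZoneNonUniformity": vals["len_nonunif"],
        "SizeZoneNonUniformityNormalized": vals["len_nonunif_norm"],
        "SmallAreaEmphasis": vals["short"],
        "SmallAreaHighGrayLevelEmphasis": vals["short_high"],
        "SmallAreaLowGrayLevelEmphasis": vals["short_low"],
        "ZoneEntropy": vals["entropy"],
        "ZonePercentage": vals["percentage"],
        "ZoneVariance": vals["len_var"],
    }


def glrlm_features(levels: np.ndarray, n_levels: int) -> dict:
    """16 GLRLM features, averaged over the 13 unique directions."""
    n_vox = int((levels > 0).sum())
    per_dir = []
    for d in DIRECTIONS_13:
        P = glrlm_matrix(levels, n_levels, d)
        if P.sum() > 0:
            per_dir.append(_rl_style_features(P, n_vox, "run"))
    return _average_dicts(per_dir, GLRLM_NAMES)


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size count matrix: 26-connected zones of equal gray level."""
    structure = np.ones((3, 3, 3), dtype=bool)
    zone_sizes = {}  # size -> per-level counts
    max_size = 1
    rows = []
    for g in range(1, n_levels + 1):
        binary = levels == g
        if not binary.any():
            rows.append({})
            continue
        lab, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        row = {}
        for s in sizes:
            row[int(s)] = row.get(int(s), 0) + 1
            max_size = max(max_size, int(s))
        rows.append(row)
    P = np.zeros((n_levels, max_size), dtype=np.int64)
    for g, row in enumerate(rows):
        for s, c in row.items():
            P[g, s - 1] = c
    return P


def glszm_features(levels: np.ndarray, n_levels: int) -> dict:
    """16 GLSZM features (single matrix; no directionality)."""
    n_vox = int((levels > 0).sum())
    P = glszm_matrix(levels, n_levels)
    return _rl_style_features(P, n_vox, "zone")


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray, n_levels: int):
    """Per-level counts n_i and absolute gray-tone differences s_i.

    The neighborhood average uses only in-mask neighbors; voxels with no
    in-mask neighbor are excluded from the valid region.
    """
    mask = levels > 0
    nbr_sum = np.zeros(levels.shape, dtype=float)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    for d in _ALL_26:
        sa, sb = _offset_slices(levels.shape, d)
        nbr_sum[sa] += np.where(mask[sb], levels[sb], 0)
        nbr_cnt[sa] += mask[sb]
    valid = mask & (nbr_cnt > 0)
    A = np.zeros(levels.shape)
    A[valid] = nbr_sum[valid] / nbr_cnt[valid]
    lv = levels[valid].astype(np.int64)
    diff = np.abs(levels[valid] - A[valid])
    n_i = np.bincount(lv - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(lv - 1, weights=diff, minlength=n_levels)
    return n_i, s_i


def ngtdm_features(levels: np.ndarray, n_levels: int) -> dict:
    """5 NGTDM features; a texture-free region yields the documented limits
    (coarseness capped at 1e6, the rest 0)."""
    n_i, s_i = ngtdm_table(levels, n_levels)
    Nv = n_i.sum()
    if Nv == 0:
        return {k: 0.0 for k in NGTDM_NAMES} | {"Coarseness": COARSENESS_MAX}
    p_i = n_i / Nv
    i = np.arange(1, n_levels + 1, dtype=float)
    present = p_i > 0
    Ngp = int(present.sum())

    dens = float((p_i * s_i).sum())
    coarseness = 1.0 / dens if dens > 0 else COARSENESS_MAX

    ip = i[present]
    pp = p_i[present]
    sp = s_i[present]
    di = ip[:, None] - ip[None, :]

    if Ngp > 1:
        contrast = (
            float((pp[:, None] * pp[None, :] * di**2).sum())
            / (Ngp * (Ngp - 1))
            * float(sp.sum())
            / Nv
        )
        busy_den = float(np.abs(ip * pp - (ip * pp)[:, None]).sum())
        busyness = dens / busy_den if busy_den > 0 else 0.0
        psum = pp[:, None] + pp[None, :]
        complexity = float(
            (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / psum).sum()
        ) / Nv
        strength = (
            float((psum * di**2).sum()) / sp.sum() if sp.sum() > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": min(coarseness, COARSENESS_MAX),
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix (levels x dependence, dependence >= 1)."""
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    dep[mask] = 1  # the voxel itself
    for d in _ALL_26:
        sa, sb = _offset_slices(levels.shape, d)
        ok = mask[sa] & mask[sb] & (np.abs(levels[sa] - levels[sb]) <= alpha)
        dep[sa] += ok
    lv = levels[mask].astype(np.int64)
    dv = dep[mask]
    P = np.zeros((n_levels, int(dv.max())), dtype=np.int64)
    np.add.at(P, (lv - 1, dv - 1), 1)
    return P


def gldm_features(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> dict:
    """14 GLDM features from the dependence matrix."""
    P = gldm_matrix(levels, n_levels, alpha)
    Nz = P.sum()
    p = P / Nz
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_g = float((i.ravel() * pg).sum())
    mu_d = float((j.ravel() * pd).sum())
    return {
        "DependenceEntropy": float(-(p * _log2(p)).sum()),
        "DependenceNonUniformity": float((P.sum(axis=0) ** 2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum()),
        "DependenceVariance": float((((j.ravel() - mu_d) ** 2) * pd).sum()),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / Nz),
        "GrayLevelVariance": float((((i.ravel() - mu_g) ** 2) * pg).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
    }


# ---------------------------------------------------------------------------


def _average_dicts(dicts, names) -> dict:
    if not dicts:
        return {k: 0.0 for k in names}
    return {k: float(np.mean([d[k] for d in dicts])) for k in names}


TEXTURE_FAMILIES = {
    "glcm": (glcm_features, GLCM_NAMES),
    "glrlm": (glrlm_features, GLRLM_NAMES),
    "glszm": (glszm_features, GLSZM_NAMES),
    "ngtdm": (ngtdm_features, NGTDM_NAMES),
    "gldm": (gldm_features, GLDM_NAMES),
}


def texture_features(levels: np.ndarray, n_levels: int, family: str) -> dict:
    """Dispatch to one texture family on a discretized volume."""
    if family not in TEXTURE_FAMILIES:
        raise ValueError(f"unknown texture family {family!r}")
    fn, _ = TEXTURE_FAMILIES[family]
    return fn(levels, n_levels)
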