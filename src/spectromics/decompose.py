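"""Basis-material decomposition of spectral photon-counting CT volumes.

A photon-counting detector (PCD) bins photons into four energy channels
(lower thresholds 25, 34, 50 and 60 keV; the middle two bracket the iodine
K-edge at 33.2 keV).  At each voxel the measured bin intensities ``b`` are
modelled as a linear mix of three basis materials — iodine (I), photoelectric
effect (PE) and Compton scattering (CS) — through a 4x3 sensitivity matrix
``A`` calibrated from vials of known composition::

    b = A @ x,    x = (iodine [mg/mL], PE [a.u.], CS [a.u.])

Decomposition solves this system per voxel.  With four equations and three
unknowns the system is overdetermined, so the "inverse" is the Moore-Penrose
pseudo-inverse, i.e. the ordinary least-squares solution.  Negative
concentrations are retained here; downstream analysis discards intratumoral
iodine below 1 mg/mL, where noise dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SensitivityMatrix",
    "SpectralVolume",
    "MaterialMaps",
    "VialMeasurements",
    "MaterialDecomposer",
    "estimate_sensitivity",
    "decompose",
    "threshold_iodine",
    "hu_normalize",
]

MATERIALS = ("I", "PE", "CS")
DEFAULT_ENERGIES_KEV = (25.0, 34.0, 50.0, 60.0)

#: Condition number above which a decomposition records a warning in its
#: provenance instead of failing outright.
DEFAULT_CONDITION_LIMIT = 1e6


@dataclass(frozen=True)
class SensitivityMatrix:
    """Calibrated linear map from material concentrations to bin intensities.

    Rows correspond to energy bins, columns to the basis materials
    (I, PE, CS).  Must have full column rank.
    """

    entries: np.ndarray
    energies_keV: tuple = DEFAULT_ENERGIES_KEV
    materials: tuple = MATERIALS

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2:
            raise ValueError("sensitivity entries must be a 2D array")
        n_bins, n_mat = entries.shape
        if len(self.energies_keV) != n_bins:
            raise ValueError("one energy label required per matrix row")
        if len(self.materials) != n_mat:
            raise ValueError("one material label required per matrix column")
        if n_bins < n_mat:
            raise ValueError(
                f"rank-deficient system: {n_bins} energy bins cannot resolve "
                f"{n_mat} materials"
            )
        if np.linalg.matrix_rank(entries) < n_mat:
            raise ValueError("sensitivity matrix does not have full column rank")
        object.__setattr__(self, "entries", entries)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.entries))

    @property
    def n_bins(self) -> int:
        return self.entries.shape[0]

    def pseudo_inverse(self) -> np.ndarray:
        return np.linalg.pinv(self.entries)

    def to_dict(self) -> dict:
        return {
            "energies_keV": list(self.energies_keV),
            "materials": list(self.materials),
            "entries": self.entries.tolist(),
            "condition_number": self.condition_number,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensitivityMatrix":
        return cls(
            entries=np.asarray(d["entries"], dtype=float),
            energies_keV=tuple(d["energies_keV"]),
            materials=tuple(d["materials"]),
        )


@dataclass
class SpectralVolume:
    """Co-registered stack of energy-bin volumes (the per-voxel vector b)."""

    bins: np.ndarray  # (n_bins, *grid)
    voxel_size_mm: float
    energies_keV: tuple = DEFAULT_ENERGIES_KEV

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.ndim != 4:
            raise ValueError("bins must be a 4D array (n_bins, nx, ny, nz)")
        if self.bins.shape[0] != len(self.energies_keV):
            raise ValueError("bin count must match energy labels")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def grid_shape(self):
        return self.bins.shape[1:]


@dataclass
class MaterialMaps:
    """Per-voxel material concentrations (iodine in mg/mL; PE/CS in a.u.)."""

    iodine: np.ndarray
    pe: np.ndarray
    cs: np.ndarray
    voxel_size_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.iodine.shape == self.pe.shape == self.cs.shape):
            raise ValueError("material maps must share a grid")

    @property
    def grid_shape(self):
        return self.iodine.shape

    def as_array(self) -> np.ndarray:
        """Stack maps as (3, *grid) in (I, PE, CS) order."""
        return np.stack([self.iodine, self.pe, self.cs])


@dataclass
class VialMeasurements:
    """Mean bin intensities of calibration vials of known composition.

    ``concentrations`` is (n_vials, n_materials), ``intensities`` is
    (n_vials, n_bins).  ``degenerate`` flags a collinear design.
    """

    concentrations: np.ndarray
    intensities: np.ndarray
    energies_keV: tuple = DEFAULT_ENERGIES_KEV
    materials: tuple = MATERIALS
    degenerate: bool = False

    def __post_init__(self):
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, float))
        self.intensities = np.atleast_2d(np.asarray(self.intensities, float))
        if self.concentrations.shape[0] != self.intensities.shape[0]:
            raise ValueError("one intensity row required per vial")


def estimate_sensitivity(vials: VialMeasurements) -> SensitivityMatrix:
    """Least-squares calibration of the sensitivity matrix from vials.

    Each energy row of A is fit independently by regressing that bin's vial
    intensities on the known concentration vectors.  Requires at least as
    many vials as materials and a full-rank concentration design.
    """
    C = vials.concentrations
    B = vials.intensities
    n_vials, n_mat = C.shape
    if n_vials < n_mat:
        raise ValueError(
            f"underdetermined calibration: {n_vials} vial(s) for {n_mat} materials"
        )
    rank = np.linalg.matrix_rank(C)
    if rank < n_mat:
        # name an offending vial pair to aid debugging of the design
        bad = _find_collinear_pair(C)
        raise ValueError(
            f"rank-deficient vial design (rank {rank} < {n_mat}); "
            f"vials {bad} have collinear concentration vectors"
        )
    # solve C @ A.T = B  ->  A.T = lstsq(C, B)
    at, *_ = np.linalg.lstsq(C, B, rcond=None)
    return SensitivityMatrix(
        entries=at.T, energies_keV=vials.energies_keV, materials=vials.materials
    )


def _find_collinear_pair(C: np.ndarray):
    n = C.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.matrix_rank(C[[i, j]]) < 2:
                return (i, j)
    return tuple(range(n))


def decompose(
    volume: SpectralVolume,
    A: SensitivityMatrix,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> MaterialMaps:
    """Solve ``min_x ||A x - b||`` at every voxel of a spectral volume.

    Negative concentrations are retained; masking/thresholding is a
    downstream concern.  A poorly conditioned matrix is recorded as a
    warning in the output provenance rather than an error.
    """
    if volume.bins.shape[0] != A.n_bins:
        raise ValueError(
            f"bin count {volume.bins.shape[0]} does not match "
            f"sensitivity matrix rows {A.n_bins}"
        )
    provenance = {"condition_number": A.condition_number}
    if A.condition_number > condition_limit:
        provenance["warning"] = (
            f"sensitivity matrix condition number {A.condition_number:.3g} "
            f"exceeds {condition_limit:.3g}"
        )
        warnings.warn(provenance["warning"], stacklevel=2)
    grid = volume.grid_shape
    b = volume.bins.reshape(A.n_bins, -1)
    x = A.pseudo_inverse() @ b  # (3, n_voxels)
    maps = x.reshape((len(A.materials),) + grid)
    return MaterialMaps(
        iodine=maps[0],
        pe=maps[1],
        cs=maps[2],
        voxel_size_mm=volume.voxel_size_mm,
        provenance=provenance,
    )


class MaterialDecomposer(BaseEstimator, TransformerMixin):
    """Sklearn-style estimator: calibrate on vials, decompose voxel spectra.

    ``fit(C, B)`` takes vial concentrations (n_vials, 3) and mean bin
    intensities (n_vials, 4); ``transform(X)`` maps per-voxel bin intensity
    rows (n_voxels, 4) to material concentration rows (n_voxels, 3).
    """

    def __init__(self, energies_keV=DEFAULT_ENERGIES_KEV, materials=MATERIALS):
        self.energies_keV = energies_keV
        self.materials = materials

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("fit requires vial intensities as y")
        vials = VialMeasurements(
            concentrations=np.asarray(X, float),
            intensities=np.asarray(y, float),
            energies_keV=tuple(self.energies_keV),
            materials=tuple(self.materials),
        )
        self.sensitivity_ = estimate_sensitivity(vials)
        self.pinv_ = self.sensitivity_.pseudo_inverse()
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.sensitivity_.n_bins:
            raise ValueError("X must be (n_voxels, n_bins)")
        return X @ self.pinv_.T


def threshold_iodine(maps: MaterialMaps, mask: np.ndarray, min_mgml: float = 1.0):
    """Select intratumoral voxels whose iodine is at or above the detection floor.

    Concentrations below ``min_mgml`` (default 1 mg/mL) within the tumor mask
    are discarded as noise-dominated; the comparison is >= keep / < discard.

    Returns ``(enhanced_mask, values)``: the surviving sub-mask and the
    surviving iodine concentrations.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != maps.grid_shape:
        raise ValueError("mask shape does not match material maps")
    if not mask.any():
        raise ValueError("empty tumor mask")
    enhanced = mask & (maps.iodine >= min_mgml)
    return enhanced, maps.iodine[enhanced]


def hu_normalize(volume: np.ndarray, water_ref: float, air_ref: float) -> np.ndarray:
    """Linearly rescale intensities to Hounsfield units.

    Sends ``water_ref`` to 0 HU and ``air_ref`` to -1000 HU.
    """
    if water_ref == air_ref:
        raise ValueError("water and air references must differ")
    volume = np.asarray(volume, float)
    return 1000.0 * (volume - water_ref) / (water_ref - air_ref)
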