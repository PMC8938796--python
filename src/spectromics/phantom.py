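"""Synthetic spectral micro-CT phantoms with tumor iodine uptake.

The generator emulates a nanoparticle contrast-enhanced small-animal study:
an ellipsoidal soft-tissue tumor retains an iodinated contrast agent (EPR
effect), sitting in a muscle-like background described by photoelectric (PE)
and Compton-scattering (CS) basis levels.  Ground-truth material maps are
pushed through a 4x3 sensitivity matrix to produce four photon-counting
energy-bin volumes, and through a separate broad-spectrum 1x3 row for the
conventional energy-integrating (EID) channel; independent additive Gaussian
noise is applied per bin.

Two classes are simulated: lymphocyte-present tumors (positive) receive a
higher mean intratumoral iodine concentration — leakier vasculature — and a
different spatial texture (correlation length / heterogeneity amplitude) of
the iodine field than lymphocyte-deficient tumors (negative).  Intratumoral
heterogeneity is a Gaussian random field smoothed to the requested
correlation length and clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .decompose import (
    DEFAULT_ENERGIES_KEV,
    MATERIALS,
    MaterialMaps,
    SensitivityMatrix,
    SpectralVolume,
    VialMeasurements,
)

__all__ = [
    "PhantomSpec",
    "TextureSpec",
    "MaterialGroundTruth",
    "Subject",
    "Cohort",
    "CohortEffect",
    "make_sensitivity_model",
    "default_eid_row",
    "simulate_subject",
    "simulate_calibration_vials",
    "simulate_cohort",
]

# Default sensitivity entries (intensity units per unit concentration).
# The iodine column carries the K-edge signature: attenuation per mg/mL jumps
# from the 25 keV bin to the 34 keV bin (K-edge at 33.2 keV) and falls off
# above.  PE decays steeply with energy (~E^-3); CS declines slowly.
DEFAULT_SENSITIVITY = {
    "I": (20.0, 32.0, 18.0, 10.0),
    "PE": (38.0, 22.0, 10.0, 6.0),
    "CS": (9.0, 8.6, 8.0, 7.6),
}

# Broad-spectrum weighting for the energy-integrating detector channel at
# 50 kVp; deliberately distinct from every single PCD bin row.  Without
# energy binning around the K-edge, the energy-integrated iodine contrast
# per mg/mL is well below the 34 keV bin's.
DEFAULT_EID_ROW = (5.0, 30.0, 8.3)


def make_sensitivity_model(
    energies_keV=DEFAULT_ENERGIES_KEV,
    materials=MATERIALS,
    entries: dict | None = None,
) -> SensitivityMatrix:
    """Build the default (documented-constant) sensitivity matrix.

    The matrix is full column rank and its iodine column must rise from the
    25 keV row to the 34 keV row (K-edge step) before decreasing.
    """
    if len(energies_keV) < len(materials):
        raise ValueError(
            f"rank-deficient model: {len(energies_keV)} energies cannot "
            f"resolve {len(materials)} materials"
        )
    table = dict(DEFAULT_SENSITIVITY if entries is None else entries)
    cols = []
    for m in materials:
        col = np.asarray(table[m], dtype=float)
        if col.shape[0] != len(energies_keV):
            raise ValueError(f"material {m}: need one entry per energy bin")
        cols.append(col)
    return SensitivityMatrix(
        entries=np.column_stack(cols),
        energies_keV=tuple(energies_keV),
        materials=tuple(materials),
    )


def default_eid_row(materials=MATERIALS) -> np.ndarray:
    return np.asarray(DEFAULT_EID_ROW[: len(materials)], dtype=float)


@dataclass(frozen=True)
class TextureSpec:
    """Spatial texture of the intratumoral iodine field.

    ``correlation_length_vox`` is the Gaussian-smoothing scale of the random
    field; ``amplitude_mgml`` its pointwise standard deviation.
    """

    correlation_length_vox: float = 2.0
    amplitude_mgml: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 0.125
    tumor_center: tuple | None = None  # defaults to grid centre
    tumor_semiaxes_vox: tuple = (12.0, 10.0, 11.0)
    class_label: int = 1  # 1 = lymphocyte-present, 0 = lymphocyte-deficient
    iodine_mean_mgml: float = 4.0
    iodine_texture: TextureSpec = field(default_factory=TextureSpec)
    background_pe: float = 1.0
    background_cs: float = 1.0
    #: a peripheral shell of the tumor is scaled by ``rim_factor`` —
    #: nanoparticle uptake is often rim-dominant, and how strongly varies
    #: by subject
    rim_width_vox: float = 1.0
    rim_factor: float = 1.0
    noise_sd: float = 15.0
    eid_noise_sd: float | None = None  # defaults to 3 x noise_sd
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid dimensions must be positive")
        if self.iodine_mean_mgml < 0:
            raise ValueError("iodine_mean_mgml must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        center = self.tumor_center
        if center is None:
            center = tuple((n - 1) / 2.0 for n in self.grid_shape)
            object.__setattr__(self, "tumor_center", center)
        for c, r, n in zip(center, self.tumor_semiaxes_vox, self.grid_shape):
            if c - r < -0.5 or c + r > n - 0.5:
                raise ValueError("tumor ellipsoid does not fit inside the grid")


@dataclass
class MaterialGroundTruth:
    iodine_map: np.ndarray
    pe_map: np.ndarray
    cs_map: np.ndarray
    tumor_mask: np.ndarray

    def __post_init__(self):
        shapes = {
            self.iodine_map.shape,
            self.pe_map.shape,
            self.cs_map.shape,
            self.tumor_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("ground-truth maps must share a grid")

    def as_maps(self, voxel_size_mm: float) -> MaterialMaps:
        return MaterialMaps(
            iodine=self.iodine_map,
            pe=self.pe_map,
            cs=self.cs_map,
            voxel_size_mm=voxel_size_mm,
            provenance={"source": "ground_truth"},
        )


@dataclass
class Subject:
    subject_id: str
    class_label: int
    spectral: SpectralVolume
    eid: np.ndarray
    truth: MaterialGroundTruth
    voxel_size_mm: float


@dataclass
class Cohort:
    subjects: list

    def __post_init__(self):
        counts = self.class_counts
        if min(counts.values(), default=0) < 2 or len(counts) < 2:
            raise ValueError("need at least two subjects per class")

    @property
    def class_counts(self) -> dict:
        counts: dict = {}
        for s in self.subjects:
            counts[s.class_label] = counts.get(s.class_label, 0) + 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.class_label for s in self.subjects], dtype=int)


def _ellipsoid_mask(grid_shape, center, semiaxes) -> np.ndarray:
    coords = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    d = sum(
        ((c - c0) / r) ** 2 for c, c0, r in zip(coords, center, semiaxes)
    )
    return d <= 1.0


def _gaussian_random_field(shape, corr_len, amplitude, rng) -> np.ndarray:
    """White noise smoothed to ``corr_len`` and rescaled to sd ``amplitude``."""
    white = rng.standard_normal(shape)
    if corr_len > 0:
        f = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
    else:
        f = white
    sd = f.std()
    if sd > 0 and amplitude > 0:
        f = f * (amplitude / sd)
    else:
        f = np.zeros(shape)
    return f


def simulate_subject(
    spec: PhantomSpec, A: SensitivityMatrix, eid_row: np.ndarray | None = None
):
    """Forward-model one subject: ground truth -> noisy PCD bins + EID volume.

    Noiseless bin intensities equal ``A @ x`` voxelwise with
    ``x = (iodine, pe, cs)``; Gaussian noise of sd ``spec.noise_sd`` is added
    independently per bin.  The EID channel uses a separate 1x3 sensitivity
    row.  All outputs share the grid and the tumor mask.
    """
    if eid_row is None:
        eid_row = default_eid_row(A.materials)
    rng = np.random.default_rng(spec.seed)
    grid = tuple(spec.grid_shape)

    mask = _ellipsoid_mask(grid, spec.tumor_center, spec.tumor_semiaxes_vox)
    tex = spec.iodine_texture
    field_ = _gaussian_random_field(
        grid, tex.correlation_length_vox, tex.amplitude_mgml, rng
    )
    iodine = np.zeros(grid)
    iodine[mask] = np.clip(spec.iodine_mean_mgml + field_[mask], 0.0, None)
    if spec.rim_width_vox > 0 and spec.rim_factor != 1.0:
        depth = ndimage.distance_transform_edt(mask)
        rim = mask & (depth <= spec.rim_width_vox)
        iodine[rim] *= spec.rim_factor
    pe = np.full(grid, spec.background_pe)
    cs = np.full(grid, spec.background_cs)

    truth = MaterialGroundTruth(
        iodine_map=iodine, pe_map=pe, cs_map=cs, tumor_mask=mask
    )

    x = np.stack([iodine, pe, cs]).reshape(3, -1)
    bins = (A.entries @ x).reshape((A.n_bins,) + grid)
    eid = (eid_row @ x).reshape(grid)
    if spec.noise_sd > 0:
        bins = bins + rng.normal(0.0, spec.noise_sd, size=bins.shape)
    eid_sd = spec.eid_noise_sd
    if eid_sd is None:
        eid_sd = 3.0 * spec.noise_sd
    if eid_sd > 0:
        eid = eid + rng.normal(0.0, eid_sd, size=eid.shape)

    spectral = SpectralVolume(
        bins=bins, voxel_size_mm=spec.voxel_size_mm, energies_keV=A.energies_keV
    )
    return spectral, eid, truth


def simulate_calibration_vials(
    A: SensitivityMatrix,
    concentrations,
    noise_sd: float = 0.0,
    n_voxels_per_vial: int = 1000,
    seed: int = 0,
) -> VialMeasurements:
    """Simulate mean bin intensities of calibration vials.

    Each vial is a homogeneous region of ``n_voxels_per_vial`` voxels with a
    known concentration vector; the reported intensity is the voxel mean, so
    its noise scales as ``noise_sd / sqrt(n_voxels_per_vial)``.  A collinear
    concentration design sets the ``degenerate`` flag.
    """
    C = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if C.shape[0] < C.shape[1]:
        raise ValueError(
            f"need at least {C.shape[1]} vials spanning the material basis, "
            f"got {C.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    B = C @ A.entries.T
    if noise_sd > 0:
        B = B + rng.normal(
            0.0, noise_sd / np.sqrt(n_voxels_per_vial), size=B.shape
        )
    degenerate = np.linalg.matrix_rank(C) < C.shape[1]
    return VialMeasurements(
        concentrations=C,
        intensities=B,
        energies_keV=A.energies_keV,
        materials=A.materials,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class CohortEffect:
    """Class effect wiring for a simulated cohort.

    Positive-class tumors get ``iodine_mean_neg + iodine_shift`` mean iodine
    and their own texture spec; per-subject means vary with sd
    ``between_subject_sd``.  ``iodine_shift = 0`` with identical textures
    yields a null cohort.
    """

    iodine_mean_neg: float = 2.5
    iodine_shift: float = 2.0
    between_subject_sd: float = 0.6
    texture_pos: TextureSpec = field(
        default_factory=lambda: TextureSpec(2.0, 0.95)
    )
    texture_neg: TextureSpec = field(
        default_factory=lambda: TextureSpec(1.8, 0.85)
    )
    #: between-subject variability of the soft-tissue background basis
    #: levels (class-independent physiology): confounds raw-intensity
    #: channels but is removed by spectral unmixing.
    background_pe_sd: float = 0.9
    background_cs_sd: float = 0.25
    #: class-independent between-subject spread of the texture parameters,
    #: so neither correlation length nor heterogeneity amplitude is a
    #: noiseless class read-out
    texture_corr_sd: float = 0.25
    texture_amp_sd: float = 0.15
    #: spread of the rim-enhancement factor (mean 1): boundary contrast is
    #: not a clean surrogate for interior iodine concentration
    rim_factor_sd: float = 0.6

    @property
    def is_null(self) -> bool:
        return (
            self.iodine_shift == 0 and self.texture_pos == self.texture_neg
        )


def simulate_cohort(
    n_pos: int,
    n_neg: int,
    effect: CohortEffect | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    A: SensitivityMatrix | None = None,
    size_jitter_vox: float = 1.5,
) -> Cohort:
    """Simulate a two-class cohort of co-registered spectral subjects.

    Subject-level seeds are derived deterministically from the cohort seed.
    Tumor semi-axes are jittered per subject so shape features vary.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least two subjects per class")
    effect = effect or CohortEffect()
    base = base_spec or PhantomSpec()
    A = A or make_sensitivity_model()
    rng = np.random.default_rng(seed)

    subjects = []
    labels = [1] * n_pos + [0] * n_neg
    for i, label in enumerate(labels):
        mean = effect.iodine_mean_neg + (effect.iodine_shift if label else 0.0)
        mean = max(0.0, mean + rng.normal(0.0, effect.between_subject_sd))
        tex_class = effect.texture_pos if label else effect.texture_neg
        texture = TextureSpec(
            correlation_length_vox=max(
                0.5,
                tex_class.correlation_length_vox
                + rng.normal(0.0, effect.texture_corr_sd),
            ),
            amplitude_mgml=max(
                0.1,
                tex_class.amplitude_mgml + rng.normal(0.0, effect.texture_amp_sd),
            ),
        )
        rim = max(0.3, 1.0 + rng.normal(0.0, effect.rim_factor_sd))
        semiaxes = tuple(
            max(3.0, r + rng.uniform(-size_jitter_vox, size_jitter_vox))
            for r in base.tumor_semiaxes_vox
        )
        pe = max(0.2, base.background_pe + rng.normal(0.0, effect.background_pe_sd))
        cs = max(0.2, base.background_cs + rng.normal(0.0, effect.background_cs_sd))
        spec = replace(
            base,
            class_label=label,
            iodine_mean_mgml=mean,
            iodine_texture=texture,
            tumor_semiaxes_vox=semiaxes,
            background_pe=pe,
            background_cs=cs,
            rim_factor=rim,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        spectral, eid, truth = simulate_subject(spec, A)
        subjects.append(
            Subject(
                subject_id=f"S{i:03d}",
                class_label=label,
                spectral=spectral,
                eid=eid,
                truth=truth,
                voxel_size_mm=base.voxel_size_mm,
            )
        )
    return Cohort(subjects=subjects)
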