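"""Sensitivity estimation and per-voxel material decomposition."""

import numpy as np
import pytest

from spectromics.decompose import (
    MaterialDecomposer,
    MaterialMaps,
    SensitivityMatrix,
    SpectralVolume,
    VialMeasurements,
    decompose,
    estimate_sensitivity,
    hu_normalize,
    threshold_iodine,
)
from spectromics.phantom import make_sensitivity_model, simulate_calibration_vials


def test_sensitivity_matrix_invariants(sensitivity):
    assert sensitivity.entries.shape == (4, 3)
    assert np.linalg.matrix_rank(sensitivity.entries) == 3
    assert np.isfinite(sensitivity.condition_number)
    # K-edge step in the iodine column: 34 keV entry above 25 keV, then falling
    iodine = sensitivity.entries[:, 0]
    assert iodine[1] > iodine[0]
    assert iodine[1] > iodine[2] > iodine[3]


def test_square_sensitivity_model_accepted():
    m = make_sensitivity_model(
        energies_keV=(25.0, 34.0, 50.0),
        entries={"I": (20, 32, 18), "PE": (38, 22, 10), "CS": (9, 8.6, 8)},
    )
    assert m.entries.shape == (3, 3)


def test_fewer_energies_than_materials_rejected():
    with pytest.raises(ValueError, match="[Rr]ank"):
        make_sensitivity_model(
            energies_keV=(25.0, 34.0),
            entries={"I": (20, 32), "PE": (38, 22), "CS": (9, 8.6)},
        )


def test_estimate_sensitivity_roundtrip_noiseless(sensitivity):
    vials = simulate_calibration_vials(
        sensitivity,
        [(10, 0, 0), (0, 1, 0), (0, 0, 1), (5, 1, 2)],
        noise_sd=0.0,
    )
    est = estimate_sensitivity(vials)
    np.testing.assert_allclose(est.entries, sensitivity.entries, atol=1e-10)


def test_estimate_sensitivity_noisy_perturbation_bound(sensitivity):
    vials = simulate_calibration_vials(
        sensitivity,
        [(10, 0, 0), (5, 0, 0), (0, 1, 0), (0, 0, 1), (2, 1, 1), (8, 0.5, 1.5)],
        noise_sd=0.5,
        seed=3,
    )
    est = estimate_sensitivity(vials)
    # effective measurement noise is noise_sd/sqrt(n_vox) ~ 0.016
    assert np.abs(est.entries - sensitivity.entries).max() < 0.1


def test_single_vial_underdetermined(sensitivity):
    vials = VialMeasurements(
        concentrations=[[10.0, 0.0, 0.0]], intensities=[[1.0, 2.0, 3.0, 4.0]]
    )
    with pytest.raises(ValueError, match="underdetermined"):
        estimate_sensitivity(vials)


def test_duplicated_vials_match_deduplicated_normal_equations(sensitivity, rng):
    C = np.array([[10, 0, 0], [0, 1, 0], [0, 0, 1], [4, 2, 1]], dtype=float)
    B = C @ sensitivity.entries.T + rng.normal(0, 0.1, size=(4, 4))
    Cd = np.vstack([C, C])
    Bd = np.vstack([B, B])
    est = estimate_sensitivity(VialMeasurements(Cd, Bd))
    # normal-equations oracle on the deduplicated design
    oracle = (np.linalg.inv(C.T @ C) @ C.T @ B).T
    np.testing.assert_allclose(est.entries, oracle, atol=1e-10)


def test_collinear_vials_named(sensitivity):
    vials = simulate_calibration_vials(
        sensitivity, [(10, 0, 0), (5, 0, 0), (2.5, 0, 0)], noise_sd=0.0
    )
    assert vials.degenerate
    with pytest.raises(ValueError, match="collinear"):
        estimate_sensitivity(vials)


def test_decompose_zero_and_exact(sensitivity):
    grid = (4, 5, 6)
    zero = SpectralVolume(bins=np.zeros((4,) + grid), voxel_size_mm=0.125)
    maps = decompose(zero, sensitivity)
    assert np.all(maps.as_array() == 0)

    rng = np.random.default_rng(0)
    x0 = rng.uniform(0, 5, size=(3,) + grid)
    b = np.einsum("em,m...->e...", sensitivity.entries, x0)
    vol = SpectralVolume(bins=b, voxel_size_mm=0.125)
    rec = decompose(vol, sensitivity).as_array()
    np.testing.assert_allclose(rec, x0, atol=1e-8)


def test_decompose_matches_normal_equations_oracle(sensitivity, rng):
    grid = (6, 6, 6)
    b = rng.normal(size=(4,) + grid)
    vol = SpectralVolume(bins=b, voxel_size_mm=0.125)
    rec = decompose(vol, sensitivity).as_array().reshape(3, -1)
    A = sensitivity.entries
    oracle = np.linalg.inv(A.T @ A) @ A.T @ b.reshape(4, -1)
    np.testing.assert_allclose(rec, oracle, atol=1e-10)


def test_decompose_linearity(sensitivity, rng):
    grid = (4, 4, 4)
    b1 = rng.normal(size=(4,) + grid)
    b2 = rng.normal(size=(4,) + grid)
    a, c = 2.5, -1.25
    f = lambda b: decompose(
        SpectralVolume(bins=b, voxel_size_mm=0.1), sensitivity
    ).as_array()
    np.testing.assert_allclose(f(a * b1 + c * b2), a * f(b1) + c * f(b2), atol=1e-9)


def test_decompose_noise_covariance_scaling(sensitivity, rng):
    """Voxelwise estimator covariance approximately sigma^2 (A^T A)^-1."""
    sigma = 2.0
    n = 10_000
    A = sensitivity.entries
    noise = rng.normal(0, sigma, size=(4, n))
    vol = SpectralVolume(bins=noise.reshape(4, n, 1, 1), voxel_size_mm=0.1)
    x = decompose(vol, sensitivity).as_array().reshape(3, -1)
    emp = np.cov(x)
    theo = sigma**2 * np.linalg.inv(A.T @ A)
    np.testing.assert_allclose(np.diag(emp), np.diag(theo), rtol=0.10)


def test_decompose_bin_count_mismatch(sensitivity):
    vol = SpectralVolume(
        bins=np.zeros((3, 4, 4, 4)), voxel_size_mm=0.1, energies_keV=(25.0, 34.0, 50.0)
    )
    with pytest.raises(ValueError, match="bin count"):
        decompose(vol, sensitivity)


def test_material_decomposer_sklearn_roundtrip(sensitivity, rng):
    C = np.array([(10, 0, 0), (0, 1, 0), (0, 0, 1), (3, 1, 2)], dtype=float)
    B = C @ sensitivity.entries.T
    dec = MaterialDecomposer().fit(C, B)
    X = rng.uniform(0, 4, size=(50, 3))
    np.testing.assert_allclose(dec.transform(X @ sensitivity.entries.T), X, atol=1e-8)
    assert dec.get_params()["materials"] == ("I", "PE", "CS")


def test_threshold_iodine_boundary_inclusive():
    iodine = np.array([0.5, 0.9, 1.0, 2.5]).reshape(4, 1, 1)
    maps = MaterialMaps(
        iodine=iodine, pe=np.zeros_like(iodine), cs=np.zeros_like(iodine),
        voxel_size_mm=0.125,
    )
    mask = np.ones_like(iodine, bool)
    enhanced, values = threshold_iodine(maps, mask, min_mgml=1.0)
    assert enhanced.sum() == 2  # 1.0 is kept: strictly-below is discarded
    np.testing.assert_array_equal(np.sort(values), [1.0, 2.5])
    full, _ = threshold_iodine(maps, mask, min_mgml=0.0)
    assert full.sum() == mask.sum()


def test_threshold_iodine_enumeration_oracle(rng):
    iodine = rng.uniform(0, 2, size=(3, 3, 1))
    maps = MaterialMaps(iodine=iodine, pe=np.zeros_like(iodine),
                        cs=np.zeros_like(iodine), voxel_size_mm=0.1)
    mask = np.ones_like(iodine, bool)
    enhanced, _ = threshold_iodine(maps, mask)
    count = sum(
        1 for p in np.ndindex(iodine.shape) if iodine[p] >= 1.0
    )
    assert enhanced.sum() == count


def test_threshold_iodine_empty_mask_errors():
    iodine = np.zeros((2, 2, 2))
    maps = MaterialMaps(iodine=iodine, pe=iodine, cs=iodine, voxel_size_mm=0.1)
    with pytest.raises(ValueError, match="empty"):
        threshold_iodine(maps, np.zeros_like(iodine, bool))


def test_hu_normalize_linear_map():
    assert hu_normalize(np.array(50.0), water_ref=50, air_ref=10) == 0.0
    assert hu_normalize(np.array(10.0), water_ref=50, air_ref=10) == -1000.0
    assert hu_normalize(np.array(30.0), water_ref=50, air_ref=10) == -500.0
    with pytest.raises(ValueError):
        hu_normalize(np.array(1.0), 5, 5)
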