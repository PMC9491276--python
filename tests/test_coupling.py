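"""Core coupling estimator: standardization, weighted covariance,
eigenvalue proportion, logit transform, and the whole-image pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from pimco import (
    ModalityStack,
    NeighborhoodSample,
    PhantomSpec,
    compute_pimco,
    coupling_from_proportion,
    coupling_to_proportion,
    first_eig_proportion,
    generate_phantom,
    standardize_global,
    weighted_covariance,
)
from pimco.coupling import extract_neighborhood, local_covariance_field

from conftest import brute_coupling_at_voxel, brute_weighted_cov


def small_stack(vols, mask=None, dims=(2.0, 2.0, 2.0)):
    vols = np.asarray(vols, float)
    if mask is None:
        mask = np.ones(vols.shape[1:], dtype=bool)
    return ModalityStack(volumes=vols, mask=mask, voxel_dims_mm=dims)


class TestStandardizeGlobal:
    def test_hand_computed_three_values(self):
        vols = np.zeros((2, 3, 1, 1))
        vols[0, :, 0, 0] = [1.0, 2.0, 3.0]
        vols[1, :, 0, 0] = [5.0, -1.0, 0.5]
        out = standardize_global(small_stack(vols))
        np.testing.assert_allclose(
            out.volumes[0, :, 0, 0], [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_mean_zero_unit_variance_over_mask(self, phantom_m3):
        out = standardize_global(phantom_m3)
        for j in range(out.n_modalities):
            vals = out.volumes[j][out.mask]
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.var() - 1.0) < 1e-8
            # out-of-mask voxels are missing
            assert np.all(np.isnan(out.volumes[j][~out.mask]))

    def test_idempotent_and_affine_invariant(self, phantom_m3):
        once = standardize_global(phantom_m3)
        twice = standardize_global(once)
        np.testing.assert_allclose(
            once.volumes[:, once.mask], twice.volumes[:, once.mask], atol=1e-10
        )
        shifted = small_stack(3.7 * phantom_m3.volumes + 11.0, phantom_m3.mask)
        out2 = standardize_global(shifted)
        np.testing.assert_allclose(
            once.volumes[:, once.mask], out2.volumes[:, once.mask], atol=1e-8
        )

    def test_constant_modality_raises_with_name(self, phantom_m3):
        vols = phantom_m3.volumes.copy()
        vols[1] = 4.2
        stack = ModalityStack(
            volumes=vols,
            mask=phantom_m3.mask,
            voxel_dims_mm=phantom_m3.voxel_dims_mm,
            modality_names=["cbf", "alff", "reho"],
        )
        with pytest.raises(ValueError, match="alff"):
            standardize_global(stack)


class TestWeightedCovariance:
    def test_constant_values_give_zero_matrix(self):
        x = np.ones((5, 3)) * [1.0, -2.0, 0.5]
        C = weighted_covariance(x, np.full(5, 0.2))
        np.testing.assert_allclose(C, 0.0, atol=1e-14)

    def test_perfect_correlation_gives_rank_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        vals = np.column_stack([x, x])
        w = rng.uniform(0.1, 1.0, size=8)
        w /= w.sum()
        C = weighted_covariance(vals, w)
        assert C[0, 1] == pytest.approx(np.sqrt(C[0, 0] * C[1, 1]), rel=1e-12)
        assert np.linalg.eigvalsh(C)[0] == pytest.approx(0.0, abs=1e-14)

    def test_matches_brute_force_double_loop(self):
        vals = np.array([[1.0, 2.0], [0.0, -1.0], [3.0, 0.5], [-2.0, 4.0]])
        w = np.full(4, 0.25)
        C = weighted_covariance(vals, w)
        np.testing.assert_allclose(C, brute_weighted_cov(vals, w), atol=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 12), m=st.integers(2, 4))
    def test_psd_and_matches_oracle_randomized(self, seed, n, m):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n, m))
        w = rng.uniform(0.01, 1.0, size=n)
        w /= w.sum()
        C = weighted_covariance(vals, w)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.linalg.eigvalsh(C)[0] > -1e-10
        np.testing.assert_allclose(C, brute_weighted_cov(vals, w), atol=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            weighted_covariance(np.ones((1, 2)), np.array([1.0]))
        with pytest.raises(ValueError):
            weighted_covariance(np.ones((3, 2)), np.array([1.0, 0.0, 0.0]))


class TestFirstEigProportion:
    @pytest.mark.parametrize(
        "C, expected",
        [
            (np.eye(3), 1.0 / 3.0),
            (np.array([[1.0, 0.75], [0.75, 1.0]]), 0.875),
            (np.outer([1.0, 2.0, -1.0], [1.0, 2.0, -1.0]), 1.0),
        ],
    )
    def test_known_matrices(self, C, expected):
        assert first_eig_proportion(C) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_trace_raises(self):
        with pytest.raises(ValueError):
            first_eig_proportion(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            first_eig_proportion(np.full((2, 2), np.nan))


class TestCouplingTransform:
    @pytest.mark.parametrize(
        "p, m, expected",
        [
            (2.0 / 3.0, 3, 0.0),
            (0.75, 2, 0.0),
            (0.875, 2, 1.0986123),  # logit(0.75)
        ],
    )
    def test_forward(self, p, m, expected):
        assert coupling_from_proportion(p, m) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize(
        "c, m, expected_pct",
        [(-2, 3, 41), (0, 3, 67), (2, 3, 92), (-2, 2, 56), (0, 2, 75), (2, 2, 94)],
    )
    def test_inverse_calibration_table(self, c, m, expected_pct):
        assert round(100 * coupling_to_proportion(c, m)) == expected_pct

    def test_zero_coupling_midpoint(self):
        for m in (2, 3, 5):
            assert coupling_to_proportion(0.0, m) == pytest.approx((m + 1) / (2 * m))

    def test_boundaries_clip_to_finite(self):
        lo = coupling_from_proportion(1.0 / 3.0, 3)
        hi = coupling_from_proportion(1.0, 3)
        assert np.isfinite(lo) and np.isfinite(hi)
        assert lo == pytest.approx(-hi, rel=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        c=st.floats(-12, 12),
        m=st.integers(2, 6),
    )
    def test_round_trip_and_range(self, c, m):
        p = coupling_to_proportion(c, m)
        assert 1.0 / m < p < 1.0
        assert coupling_from_proportion(p, m) == pytest.approx(c, abs=1e-8)

    def test_monotone_in_proportion(self):
        p = np.linspace(1 / 3 + 1e-6, 1 - 1e-6, 200)
        c = coupling_from_proportion(p, 3)
        assert np.all(np.diff(c) > 0)


@pytest.mark.parametrize("m", [2, 3, 4, 6])
def test_equicorrelation_closed_form(m):
    """For unit-variance equicorrelated C, coupling equals logit(rho) exactly."""
    for rho in np.linspace(0.05, 0.95, 10):
        C = np.full((m, m), rho)
        np.fill_diagonal(C, 1.0)
        p = first_eig_proportion(C)
        assert p == pytest.approx((1 + (m - 1) * rho) / m, abs=1e-12)
        assert coupling_from_proportion(p, m) == pytest.approx(logit(rho), abs=1e-9)


class TestComputePimco:
    def test_identical_modalities_hit_clipped_maximum(self, kernel3):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(12, 12, 12))
        stack = small_stack(np.stack([vol, 2.0 * vol + 1.0]))
        img = compute_pimco(stack, kernel3)
        vals = img.finite_values
        assert len(vals) > 0
        # p = 1 everywhere -> all voxels at the clipped logit ceiling
        assert np.all(vals == vals.max())
        assert img.provenance["n_clipped_voxels"] == len(vals)

    def test_independent_noise_biased_above_floor_but_finite(self, kernel3):
        stack = generate_phantom(PhantomSpec(shape=(20, 20, 20), rho=0.0, n_modalities=3, seed=9))
        img = compute_pimco(stack, kernel3)
        vals = img.finite_values
        assert np.all(np.isfinite(vals))
        # finite-neighborhood lambda_max bias keeps E[p] above 1/m
        assert np.median(vals) > coupling_from_proportion(1.0 / 3.0 + 1e-9, 3)

    def test_matches_per_voxel_brute_force(self, phantom_m3, kernel3):
        img = compute_pimco(phantom_m3, kernel3)
        st_std = standardize_global(phantom_m3)
        rng = np.random.default_rng(1)
        centers = np.argwhere(phantom_m3.mask)
        for c in centers[rng.choice(len(centers), size=12, replace=False)]:
            expected = brute_coupling_at_voxel(st_std, kernel3, tuple(c))
            got = img.coupling[tuple(c)]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_extract_neighborhood_agrees_with_field(self, phantom_m3, kernel3):
        st_std = standardize_global(phantom_m3)
        cov, n_in, valid = local_covariance_field(st_std, kernel3)
        c = tuple(np.argwhere(phantom_m3.mask)[100])
        sample = extract_neighborhood(st_std, kernel3, c)
        assert sample.n_in_mask == n_in[c]
        np.testing.assert_allclose(weighted_covariance(sample), cov[c], atol=1e-10)

    def test_modality_permutation_symmetry(self, phantom_m3, kernel3):
        base = compute_pimco(phantom_m3, kernel3).coupling
        swapped = compute_pimco(phantom_m3.permuted([2, 0, 1]), kernel3).coupling
        np.testing.assert_allclose(base, swapped, atol=1e-10, equal_nan=True)

    def test_scale_freeness_of_raw_modalities(self, phantom_m3, kernel3):
        base = compute_pimco(phantom_m3, kernel3).coupling
        vols = phantom_m3.volumes.copy()
        vols[0] *= 37.0
        vols[2] = vols[2] * 0.01 - 5.0
        rescaled = ModalityStack(
            volumes=vols, mask=phantom_m3.mask, voxel_dims_mm=phantom_m3.voxel_dims_mm
        )
        np.testing.assert_allclose(
            base, compute_pimco(rescaled, kernel3).coupling, atol=1e-8, equal_nan=True
        )

    def test_denominator_convention_cancels(self, phantom_m3, kernel3):
        a = compute_pimco(phantom_m3, kernel3, denominator="unbiased").coupling
        b = compute_pimco(phantom_m3, kernel3, denominator="biased").coupling
        np.testing.assert_allclose(a, b, atol=1e-9, equal_nan=True)

    def test_minimum_support_rule(self, kernel3):
        # a lone in-mask corner voxel has itself + few neighbors; carve a mask
        # with an isolated island smaller than m+1 voxels
        shape = (15, 15, 15)
        mask = np.zeros(shape, dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        mask[0, 0, 0] = True  # island of 1 < m+1 = 3
        rng = np.random.default_rng(5)
        stack = small_stack(rng.normal(size=(2,) + shape), mask)
        img = compute_pimco(stack, kernel3)
        assert np.isnan(img.coupling[0, 0, 0])
        assert np.isfinite(img.coupling[8, 8, 8])

    def test_equicorrelated_field_recovers_closed_form(self, kernel3):
        stack = generate_phantom(
            PhantomSpec(shape=(30, 30, 30), rho=0.75, n_modalities=2, seed=77)
        )
        img = compute_pimco(stack, kernel3)
        med = np.nanmedian(img.coupling)
        assert med == pytest.approx(logit(0.75), abs=0.15)
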