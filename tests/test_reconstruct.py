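"""Forward projection, pre-processing operators, and per-pixel inversion."""

import numpy as np
import pytest

from subslice.montecarlo import BSEImage
from subslice.phantom import NOMINAL_STAIN_DENSITY, make_block, three_cuboid_model
from subslice.reconstruct import (
    SubSliceVolume,
    apply_shot_noise,
    clip_noise,
    estimate_background_sd,
    evaluate_recovery,
    forward_project,
    scale_low_to_high,
    smooth_lower_subslice,
    solve_subslices,
    stack_from_images,
    subtract_background,
    subtract_stack_background,
)

S_FULL = NOMINAL_STAIN_DENSITY


@pytest.fixture()
def uniform_two_layer(published_matrix):
    """Phantom uniformly stained through the top two 12.5-nm layers."""
    ph = make_block((400, 400, 25), (12.5, 12.5, 12.5))
    ph.stain[:, :, :] = S_FULL / 2
    return ph


class TestForwardProject:
    def test_zero_phantom_zero_signal(self, published_matrix):
        ph = make_block((100, 100, 25), (12.5, 12.5, 12.5))
        stack = forward_project(ph, published_matrix)
        assert np.all(stack.counts == 0)

    def test_single_pixel_hand_value(self, published_matrix, compact_three_cuboid):
        """Pixel inside cuboid 1: B1/J0 = A11 * S * dz = 1.043e-3 * 3.24
        * 12.5 = 4.224e-2 by hand."""
        stack = forward_project(
            compact_three_cuboid, published_matrix, electrons_per_pixel=(10_000, 10_000)
        )
        eta = stack.eta
        assert eta[0, 0].max() == pytest.approx(4.2242e-2, rel=1e-4)
        assert eta[0, 1].max() == pytest.approx(0.898e-3 * S_FULL * 12.5, rel=1e-4)

    def test_linearity_in_density(self, published_matrix, compact_three_cuboid):
        stack1 = forward_project(compact_three_cuboid, published_matrix)
        doubled = compact_three_cuboid.copy()
        doubled.stain = doubled.stain * 2
        stack2 = forward_project(doubled, published_matrix)
        assert np.allclose(stack2.counts, 2 * stack1.counts)

    def test_grid_mismatch_rejected(self, published_matrix):
        ph = make_block((100, 100, 50), (12.5, 12.5, 25.0))
        with pytest.raises(ValueError):
            forward_project(ph, published_matrix)

    def test_background_added_per_energy(self, published_matrix):
        ph = make_block((100, 100, 25), (12.5, 12.5, 12.5))
        stack = forward_project(
            ph, published_matrix, electrons_per_pixel=(1000, 1000),
            background_eta=(0.01, 0.02),
        )
        assert np.allclose(stack.counts[:, 0], 10.0)
        assert np.allclose(stack.counts[:, 1], 20.0)
        assert not stack.background_subtracted


class TestApplyShotNoise:
    def test_poisson_statistics(self, published_matrix):
        ph = make_block((1250, 1250, 25), (12.5, 12.5, 12.5))
        stack = forward_project(
            ph, published_matrix, electrons_per_pixel=(1000, 1000),
            background_eta=(1.0, 1.0),  # expected 1000 counts/pixel
        )
        noisy = apply_shot_noise(stack, np.random.default_rng(8))
        vals = noisy.counts[0, 0].ravel()
        assert vals.size == 10_000
        assert abs(vals.mean() - 1000.0) < 3 * np.sqrt(1000.0 / vals.size)
        ratio = vals.var() / vals.mean()
        assert abs(ratio - 1.0) < 3 * np.sqrt(2.0 / vals.size)

    def test_seed_reproducibility(self, published_matrix, compact_three_cuboid):
        stack = forward_project(compact_three_cuboid, published_matrix)
        a = apply_shot_noise(stack, np.random.default_rng(3))
        b = apply_shot_noise(stack, np.random.default_rng(3))
        assert np.array_equal(a.counts, b.counts)


class TestSubtractBackground:
    def _image(self, counts):
        return BSEImage(counts=counts, energy_keV=1.0, electrons_per_pixel=1000,
                        pixel_nm=12.5)

    def test_constant_image_goes_to_zero(self):
        img = self._image(np.full((8, 8), 37.0))
        out = subtract_background(img, "roi_mean", roi=(slice(0, 4), slice(0, 4)))
        assert np.all(out.counts == 0)
        assert out.meta["background"] == 37.0

    def test_planted_background_centers_noise_at_zero(self):
        rng = np.random.default_rng(0)
        img = self._image(rng.poisson(50.0, (40, 40)).astype(float))
        out = subtract_background(img, "roi_mean", roi=(slice(0, 40), slice(0, 20)))
        right = out.counts[:, 20:]
        assert abs(right.mean()) < 3 * right.std() / np.sqrt(right.size)

    def test_median_percentile_matches_roi_mean_on_symmetric_noise(self):
        rng = np.random.default_rng(1)
        img = self._image(rng.normal(100.0, 5.0, (50, 50)))
        a = subtract_background(img, "roi_mean", roi=(slice(None), slice(None)))
        b = subtract_background(img, "percentile", percentile=50.0)
        assert b.meta["background"] == pytest.approx(a.meta["background"], abs=0.5)

    def test_invalid_inputs(self):
        img = self._image(np.ones((4, 4)))
        with pytest.raises(ValueError):
            subtract_background(img, "roi_mean")
        with pytest.raises(ValueError):
            subtract_background(img, "percentile", percentile=120.0)


class TestScaleLowToHigh:
    def test_equal_row_sums_target_unity(self, uniform_two_layer):
        from subslice.calibration import ResponseMatrix, invert_response

        A = ResponseMatrix(energies=(1.0, 1.4), dz=12.5,
                           A=np.array([[2e-3, 1e-3], [1.5e-3, 1.5e-3]]))
        invert_response(A)
        assert A.scaling_ratio == pytest.approx(1.0)

    def test_printed_matrix_ratio(self, published_matrix):
        # (1.043 + 0.130) / (0.898 + 0.648) = 0.7588 by hand arithmetic
        assert published_matrix.scaling_ratio == pytest.approx(0.7588, abs=1e-4)

    def test_self_consistent_stack_scales_by_about_one(
        self, published_matrix, uniform_two_layer
    ):
        stack = forward_project(
            uniform_two_layer, published_matrix, electrons_per_pixel=(2000, 2000)
        )
        noisy = apply_shot_noise(stack, np.random.default_rng(2))
        noisy.scaled = False
        out = scale_low_to_high(noisy, published_matrix, (slice(0, 32), slice(0, 32)))
        assert out.meta["scale_factor"] == pytest.approx(1.0, abs=0.05)
        assert out.scaled

    def test_requires_background_subtraction(self, published_matrix, uniform_two_layer):
        stack = forward_project(uniform_two_layer, published_matrix,
                                background_eta=(0.01, 0.01))
        with pytest.raises(RuntimeError):
            scale_low_to_high(stack, published_matrix, (slice(0, 8), slice(0, 8)))


class TestSolveSubslices:
    def test_three_cuboid_noiseless_roundtrip(self, published_matrix, compact_three_cuboid):
        """Exact inversion: each full-density cuboid lands in its own
        sub-slice, the half-density cuboid in both."""
        stack = forward_project(compact_three_cuboid, published_matrix)
        vol = solve_subslices(stack, published_matrix)
        truth = compact_three_cuboid.stain[: vol.data.shape[0]].astype(float)
        assert np.abs(vol.data - truth).max() <= 1e-10 * truth.max()

    def test_zero_in_zero_out(self, published_matrix):
        ph = make_block((100, 100, 25), (12.5, 12.5, 12.5))
        vol = solve_subslices(forward_project(ph, published_matrix), published_matrix)
        assert np.all(vol.data == 0)

    def test_single_pixel_hand_computation(self, published_matrix):
        """S = A^-1 eta / dz for one pixel, against a hand 2x2 product."""
        eta = np.array([0.0422415, 0.0363690])  # B/J0 for S = (3.24, 0)
        stack_counts = (eta * 1000).reshape(1, 2, 1, 1)
        stack = stack_from_images(
            [(
                BSEImage(stack_counts[0, 0], 1.0, 1000, 12.5),
                BSEImage(stack_counts[0, 1], 1.4, 1000, 12.5),
            )],
            cut_increment_nm=25.0,
        )
        stack.background_subtracted = True
        stack.scaled = True
        vol = solve_subslices(stack, published_matrix)
        S = published_matrix.A_inv @ eta / 12.5
        assert vol.data[:, 0, 0] == pytest.approx(S, rel=1e-12)
        assert S[0] == pytest.approx(3.24, rel=1e-3)
        assert abs(S[1]) < 1e-3

    def test_state_flags_enforced(self, published_matrix, compact_three_cuboid):
        stack = forward_project(compact_three_cuboid, published_matrix,
                                background_eta=(0.01, 0.01))
        with pytest.raises(RuntimeError):
            solve_subslices(stack, published_matrix)
        stack.background_subtracted = True
        stack.scaled = False
        with pytest.raises(RuntimeError):
            solve_subslices(stack, published_matrix)

    def test_noise_amplification_matches_propagation(self, published_matrix):
        """Inversion amplifies shot noise by the factor implied by the
        rows of A^-1: measured Var(S_n) matches analytic propagation of
        Poisson counts through the inverse within 10%."""
        ph = make_block((1250, 1250, 25), (12.5, 12.5, 12.5))
        ph.stain[0] = S_FULL
        J = (1000, 1000)
        bg = (0.05, 0.05)
        stack = forward_project(ph, published_matrix, electrons_per_pixel=J,
                                background_eta=bg)
        noisy = apply_shot_noise(stack, np.random.default_rng(13))
        # remove the known constant background, restoring state flags
        noisy.counts[:, 0] -= bg[0] * J[0]
        noisy.counts[:, 1] -= bg[1] * J[1]
        noisy.background_subtracted = True
        noisy.scaled = True
        vol = solve_subslices(noisy, published_matrix)
        expected_counts = stack.counts[0]  # (2, ny, nx), includes background
        var_eta = expected_counts[:, 0, 0] / np.array(J, dtype=float) ** 2
        for n in range(2):
            analytic = np.sum((published_matrix.A_inv[n] / 12.5) ** 2 * var_eta)
            measured = vol.data[n].var()
            assert measured == pytest.approx(analytic, rel=0.10)


class TestClipNoise:
    def _volume(self, data):
        return SubSliceVolume(data=data, dz=12.5, n_per_cut=2)

    def test_all_negative_zeroed(self):
        vol = clip_noise(self._volume(-np.ones((2, 4, 4))), background_sd=0.5)
        assert np.all(vol.data == 0)
        assert vol.provenance["clip_fraction"] == 1.0

    def test_strong_signal_survives(self):
        data = np.full((2, 4, 4), 10.0)
        vol = clip_noise(self._volume(data), background_sd=1.0)
        assert np.all(vol.data == 10.0)

    def test_gaussian_noise_clips_one_sided_84_percent(self):
        """Pure N(0, sd) noise: values below +1 sd are zeroed, i.e. the
        normal CDF at one sd, ~84% of voxels."""
        rng = np.random.default_rng(4)
        vol = clip_noise(self._volume(rng.normal(0, 1.0, (2, 100, 100))),
                         background_sd=1.0)
        frac = vol.provenance["clip_fraction"]
        assert frac == pytest.approx(0.8413, abs=0.01)

    def test_robust_sd_estimate_from_negative_tail(self):
        rng = np.random.default_rng(5)
        vol = self._volume(rng.normal(0, 2.0, (2, 80, 80)))
        sd = estimate_background_sd(vol)
        assert sd == pytest.approx(2.0, rel=0.1)


class TestSmoothLowerSubslice:
    def test_constant_algebraic_identity(self):
        data = np.empty((4, 3, 3))
        data[0::2] = 7.0  # upper sub-slices
        data[1::2] = 3.0  # lower sub-slices
        vol = SubSliceVolume(data=data, dz=12.5, n_per_cut=2)
        out = smooth_lower_subslice(vol)
        assert np.allclose(out.data[1], 5.0)  # (3 + mean(7,7)) / 2
        assert np.allclose(out.data[3], 5.0)  # last cut: single neighbor
        assert np.allclose(out.data[0::2], 7.0)

    def test_single_cut_warns_noop(self):
        vol = SubSliceVolume(data=np.ones((2, 3, 3)), dz=12.5, n_per_cut=2)
        with pytest.warns(UserWarning):
            out = smooth_lower_subslice(vol)
        assert np.array_equal(out.data, vol.data)

    def test_noise_variance_reduction(self):
        """For iid noise the averaged lower sub-slice variance drops to
        0.25 var_l + 0.125 var_u (interior cuts)."""
        rng = np.random.default_rng(6)
        data = rng.normal(0, 1.0, (20, 50, 50))
        vol = SubSliceVolume(data=data, dz=12.5, n_per_cut=2)
        out = smooth_lower_subslice(vol)
        interior = np.concatenate([out.data[2 * c + 1].ravel()
                                   for c in range(0, 9)])
        assert interior.var() == pytest.approx(0.375, rel=0.05)


class TestEvaluateRecovery:
    def test_noiseless_peak_at_planted_density(self, published_matrix, compact_three_cuboid):
        stack = forward_project(compact_three_cuboid, published_matrix)
        vol = solve_subslices(stack, published_matrix)
        vol.data = vol.data[:2]
        truth = compact_three_cuboid
        rec = evaluate_recovery(vol, truth)
        full = rec[f"density_{S_FULL:g}"]
        assert full["median"] == pytest.approx(S_FULL, rel=1e-6)
        assert rec["background"]["sd"] == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_rejected(self, compact_three_cuboid):
        vol = SubSliceVolume(data=np.zeros((2, 5, 5)), dz=12.5, n_per_cut=2)
        with pytest.raises(ValueError):
            evaluate_recovery(vol, compact_three_cuboid)


def test_stack_background_subtraction_roundtrip(published_matrix, compact_three_cuboid):
    stack = forward_project(compact_three_cuboid, published_matrix,
                            electrons_per_pixel=(2000, 2000),
                            background_eta=(0.02, 0.03))
    noisy = apply_shot_noise(stack, np.random.default_rng(10))
    out = subtract_stack_background(noisy, "roi_mean",
                                    roi=(slice(0, 10), slice(0, 6)))
    assert out.background_subtracted
    bgs = np.array(out.meta["backgrounds"])
    assert bgs[0, 0] == pytest.approx(0.02 * 2000, rel=0.1)
    assert bgs[0, 1] == pytest.approx(0.03 * 2000, rel=0.1)
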