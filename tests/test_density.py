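"""Map simulation, sharpening, masking, FSC, phase randomization."""

import numpy as np
import pytest

from intasome.density import (
    DensityMap,
    FSCCurve,
    fsc,
    fsc_true,
    model_map_agreement,
    phase_randomize,
    resolution_at_threshold,
    sharpen,
    simulate_map,
    tight_mask,
)


@pytest.fixture(scope="module")
def noise_maps():
    rng = np.random.default_rng(7)
    a = DensityMap(rng.standard_normal((24, 24, 24)), 2.8)
    b = DensityMap(rng.standard_normal((24, 24, 24)), 2.8)
    return a, b


# ---------------------------------------------------------------- simulate

class TestSimulateMap:
    def test_single_atom_peak_at_its_position(self):
        m = simulate_map(np.array([[3.0, -2.0, 1.0]]), voxel=2.0, resolution=8.0)
        peak = np.unravel_index(np.argmax(m.data), m.shape)
        expect = np.round((np.array([3.0, -2.0, 1.0]) - m.origin) / m.voxel)
        assert np.allclose(peak, expect)

    def test_linearity_in_weights(self, excisive_model):
        pos = np.random.default_rng(0).normal(scale=15.0, size=(10, 3))
        m1 = simulate_map(pos, voxel=2.8, resolution=11.0)
        # doubling all weights = two copies of every atom
        m2 = simulate_map(np.vstack([pos, pos]), voxel=2.8, resolution=11.0,
                          shape=m1.shape, origin=m1.origin)
        assert m2.data.sum() == pytest.approx(2 * m1.data.sum(), rel=1e-6)

    def test_whole_voxel_shift_equivariance(self):
        pos = np.random.default_rng(1).normal(scale=10.0, size=(8, 3))
        m1 = simulate_map(pos, voxel=2.0, resolution=8.0, pad=20.0)
        shift = np.array([2.0, 0.0, 0.0])  # one voxel along x
        m2 = simulate_map(pos + shift, voxel=2.0, resolution=8.0,
                          shape=m1.shape, origin=m1.origin + shift)
        assert np.allclose(m1.data, m2.data, atol=1e-6)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_map(np.zeros((1, 3)), voxel=2.8, resolution=4.0)


# ---------------------------------------------------------------- sharpen

class TestSharpen:
    def test_zero_bfactor_is_identity(self, noise_maps):
        a, _ = noise_maps
        out = sharpen(a, 0.0)
        assert np.allclose(out.data, a.data, atol=1e-10)

    def test_dc_term_unchanged(self, noise_maps):
        a, _ = noise_maps
        out = sharpen(a, -300.0)
        assert out.data.sum() == pytest.approx(float(a.data.sum()), rel=1e-9)

    def test_closed_form_amplitude_scaling(self, noise_maps):
        """Amplitudes scale by exp(-B s^2/4); at the map-resolution frequency
        s = 1/11 with the reconstruction's B = -2500 A^2 that is ~175.2."""
        a, _ = noise_maps
        bfac = -300.0  # modest B keeps the corner-voxel gain in float range
        out = sharpen(a, bfac)
        f_in = np.fft.fftn(a.data.astype(float))
        f_out = np.fft.fftn(out.data.astype(float))
        fx = np.fft.fftfreq(24, d=2.8)
        s = np.sqrt(fx[:, None, None]**2 + fx[None, :, None]**2 + fx[None, None, :]**2)
        pick = np.unravel_index(np.argmin(np.abs(s - 1.0 / 11.0)), s.shape)
        expect = np.exp(-bfac * s[pick] ** 2 / 4.0)
        assert np.abs(f_out[pick]) / np.abs(f_in[pick]) == pytest.approx(expect, rel=1e-6)
        assert np.exp(2500.0 * (1 / 11.0) ** 2 / 4.0) == pytest.approx(175.2, abs=0.2)
        # phases untouched
        assert np.angle(f_out[pick]) == pytest.approx(np.angle(f_in[pick]), abs=1e-9)


# ---------------------------------------------------------------- mask

class TestTightMask:
    @pytest.fixture(scope="module")
    def point_map(self):
        return simulate_map(np.zeros((1, 3)), voxel=2.0, resolution=8.0, pad=40.0)

    def test_zero_margin_hard_edge_equals_support(self, point_map):
        mask = tight_mask(point_map, 0.5 * float(point_map.data.max()),
                          margin=0.0, soft_edge_voxels=0.0)
        assert np.array_equal(mask.data > 0, point_map.data > 0.5 * point_map.data.max())

    def test_mask_volume_monotone_in_margin(self, point_map):
        thr = 0.5 * float(point_map.data.max())
        vols = [
            tight_mask(point_map, thr, margin=m, soft_edge_voxels=0.0).data.sum()
            for m in (5.0, 10.0, 15.0)
        ]
        assert vols[0] <= vols[1] <= vols[2]

    def test_point_source_mask_radius(self, point_map):
        """Mask extends ~ support radius + margin around a point source."""
        thr = 0.5 * float(point_map.data.max())
        support = point_map.data > thr
        mask = tight_mask(point_map, thr, margin=15.0, soft_edge_voxels=0.0)
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~support) * point_map.voxel
        outside = dist[mask.data > 0.5].max()
        assert outside == pytest.approx(15.0, abs=point_map.voxel)

    def test_empty_support_rejected(self, point_map):
        with pytest.raises(ValueError, match="threshold"):
            tight_mask(point_map, float(point_map.data.max()) * 2, margin=5.0)


# ---------------------------------------------------------------- randomize

class TestPhaseRandomize:
    def test_per_voxel_amplitudes_preserved(self, noise_maps):
        a, _ = noise_maps
        out = phase_randomize(a, limit=10.0, seed=3)
        f0 = np.abs(np.fft.fftn(a.data.astype(float)))
        f1 = np.abs(np.fft.fftn(out.data.astype(float)))
        assert np.abs(f0 - f1).max() / f0.max() < 1e-6

    def test_map_stays_real(self, noise_maps):
        a, _ = noise_maps
        out = phase_randomize(a, limit=10.0, seed=3)
        assert np.isrealobj(out.data)

    def test_untouched_below_limit(self, noise_maps):
        a, _ = noise_maps
        out = phase_randomize(a, limit=10.0, seed=3)
        curve = fsc(out, a)
        below = curve.freqs <= 1.0 / 10.0
        assert np.allclose(curve.values[below], 1.0, atol=1e-9)

    def test_independent_randomizations_decorrelate(self):
        a = DensityMap(np.random.default_rng(17).standard_normal((40, 40, 40)), 2.8)
        r1 = phase_randomize(a, limit=10.0, seed=3)
        r2 = phase_randomize(a, limit=10.0, seed=4)
        curve = fsc(r1, r2)
        # skip the boundary shell (it mixes randomized and untouched voxels)
        shell = 1.0 / (40 * 2.8)
        sel = (curve.freqs > 1.0 / 10.0 + shell) & (curve.counts >= 500)
        assert np.abs(curve.values[sel]).mean() < 0.05


# ---------------------------------------------------------------- fsc

class TestFSC:
    def test_self_correlation_is_one(self, noise_maps):
        a, _ = noise_maps
        curve = fsc(a, a)
        assert np.allclose(curve.values, 1.0, atol=1e-9)

    def test_negation_gives_minus_one(self, noise_maps):
        a, _ = noise_maps
        curve = fsc(a, a.like(-a.data))
        assert np.allclose(curve.values, -1.0, atol=1e-9)

    def test_independent_noise_decorrelated(self, noise_maps):
        a, b = noise_maps
        curve = fsc(a, b)
        sel = curve.counts >= 500
        assert np.abs(curve.values[sel].mean()) < 0.05

    def test_symmetric_in_arguments(self, noise_maps):
        a, b = noise_maps
        assert np.allclose(fsc(a, b).values, fsc(b, a).values, atol=1e-12)

    def test_grid_mismatch_rejected(self, noise_maps):
        a, _ = noise_maps
        with pytest.raises(ValueError, match="grid"):
            fsc(a, DensityMap(np.zeros((16, 16, 16)), 2.8))

    def test_frequencies_strictly_increasing(self, noise_maps):
        a, b = noise_maps
        curve = fsc(a, b)
        assert np.all(np.diff(curve.freqs) > 0)


# ---------------------------------------------------------------- fsc_true

class TestFSCTrue:
    def _curves(self, ft_vals, fn_vals):
        n = len(ft_vals)
        freqs = np.linspace(0.02, 0.2, n)
        counts = np.full(n, 1000)
        return (
            FSCCurve(freqs, ft_vals, counts),
            FSCCurve(freqs, fn_vals, counts),
        )

    def test_zero_randomized_fsc_leaves_curve(self):
        ft, fn = self._curves(np.linspace(1, 0.2, 10), np.zeros(10))
        out = fsc_true(ft, fn, limit=10.0)
        assert np.allclose(out.values, ft.values)

    def test_equal_curves_correct_to_zero(self):
        vals = np.full(10, 0.6)
        ft, fn = self._curves(vals, vals.copy())
        out = fsc_true(ft, fn, limit=1 / 0.05)
        beyond = ft.freqs > 0.05
        idx = np.argmax(beyond) + 1  # one-shell buffer
        assert np.allclose(out.values[idx:], 0.0, atol=1e-12)

    def test_formula_arithmetic(self):
        ft, fn = self._curves(np.full(10, 0.9), np.full(10, 0.5))
        out = fsc_true(ft, fn, limit=1 / 0.05)
        assert out.values[-1] == pytest.approx((0.9 - 0.5) / (1 - 0.5))
        # below the limit the masked curve is kept
        assert out.values[0] == pytest.approx(0.9)

    def test_fn_equal_one_reported_missing(self):
        ft, fn = self._curves(np.full(10, 0.9), np.ones(10))
        out = fsc_true(ft, fn, limit=1 / 0.05)
        assert np.isnan(out.values[-1])


# ---------------------------------------------------------------- threshold

class TestResolutionAtThreshold:
    def test_never_crossed_reports_nyquist_with_flag(self):
        curve = FSCCurve(np.linspace(0.02, 0.25, 12), np.ones(12), np.full(12, 600))
        res, crossed = resolution_at_threshold(curve, 0.143)
        assert not crossed
        assert res == pytest.approx(1 / 0.25)

    def test_linear_interpolation_value(self):
        curve = FSCCurve([0.08, 0.10], [0.5, 0.1], [600, 700])
        res, crossed = resolution_at_threshold(curve, 0.143)
        s = 0.08 + 0.02 * ((0.5 - 0.143) / 0.4)
        assert crossed and res == pytest.approx(1 / s)

    def test_higher_threshold_crosses_earlier(self):
        freqs = np.linspace(0.02, 0.2, 20)
        vals = np.linspace(1.0, -0.1, 20)
        curve = FSCCurve(freqs, vals, np.full(20, 600))
        r143, _ = resolution_at_threshold(curve, 0.143)
        r50, _ = resolution_at_threshold(curve, 0.5)
        assert r50 >= r143  # 0.5 crossing at lower frequency (coarser)

    def test_bad_threshold_rejected(self):
        curve = FSCCurve([0.1], [0.5], [100])
        with pytest.raises(ValueError):
            resolution_at_threshold(curve, 1.5)


# ---------------------------------------------------------------- agreement

class TestModelMapAgreement:
    @pytest.fixture(scope="module")
    def cloud(self):
        return np.random.default_rng(5).normal(scale=12.0, size=(15, 3))

    def test_map_from_same_model_scores_one(self, cloud):
        ref = simulate_map(cloud, voxel=2.8, resolution=11.0)
        assert model_map_agreement(cloud, ref, limit=11.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_unrelated_model_scores_near_zero(self, cloud):
        ref = simulate_map(cloud, voxel=2.8, resolution=11.0)
        other = np.random.default_rng(99).normal(scale=12.0, size=(15, 3))
        assert abs(model_map_agreement(other, ref, limit=11.0)) < 0.1

    def test_translation_lowers_score(self, cloud):
        ref = simulate_map(cloud, voxel=2.8, resolution=11.0)
        moved = cloud + np.array([20.0, 0.0, 0.0])
        assert model_map_agreement(moved, ref, limit=11.0) < model_map_agreement(
            cloud, ref, limit=11.0
        )


def test_fourier_ops_preserve_realness(noise_maps):
    a, _ = noise_maps
    for out in (
        sharpen(a, -500.0),
        phase_randomize(a, 10.0, seed=1),
    ):
        f = np.fft.fftn(out.data.astype(float))
        back = np.fft.ifftn(f)
        assert np.abs(back.imag).max() < 1e-9
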