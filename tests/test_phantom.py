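"""Synthetic phantom: plasma model, kinetics, frame algebra, determinism."""

import numpy as np
import pytest

from tempopet.grid_io import FrameSchedule, VoiMask
from tempopet.phantom import (
    KineticGroundTruth,
    derive_static_image,
    generate_cohort,
    generate_phantom,
    simulate_dynamic_series,
    simulate_plasma_input,
    sum_frames,
)


class TestPlasmaInput:
    def test_constant_input_integral_is_linear(self, schedule_16x150):
        curve = simulate_plasma_input([(2.5, 0.0)], schedule_16x150)
        t = np.array([1.0, 7.3, 40.0])
        np.testing.assert_allclose(curve.cumulative_integral(t), 2.5 * t, rtol=1e-12)

    def test_single_exponential_matches_closed_form_and_quadrature(self, schedule_16x150):
        a, lam = 3.0, 0.15
        curve = simulate_plasma_input([(a, lam)], schedule_16x150)
        t = np.linspace(0.5, 50, 37)
        closed = (a / lam) * (1 - np.exp(-lam * t))
        np.testing.assert_allclose(curve.cumulative_integral(t), closed, rtol=1e-12)
        # trapezoid oracle on a dense grid
        grid = np.linspace(0, 50, 200_001)
        dense = np.concatenate([[0.0], np.cumsum(
            0.5 * (curve.conc(grid)[1:] + curve.conc(grid)[:-1]) * np.diff(grid))])
        oracle = np.interp(t, grid, dense)
        np.testing.assert_allclose(curve.cumulative_integral(t), oracle, rtol=1e-9)

    def test_deterministic_sampling(self, schedule_16x150):
        c1 = simulate_plasma_input([(3.0, 0.2), (1.0, 0.01)], schedule_16x150)
        c2 = simulate_plasma_input([(3.0, 0.2), (1.0, 0.01)], schedule_16x150)
        np.testing.assert_array_equal(c1.concentrations, c2.concentrations)

    def test_negative_mixture_rejected(self, schedule_16x150):
        with pytest.raises(ValueError, match="negative"):
            simulate_plasma_input([(-2.0, 0.1)], schedule_16x150)


def _uniform_truth(ki, vb, shape=(4, 4, 4)):
    return KineticGroundTruth(np.full(shape, ki), np.full(shape, vb),
                              plasma_glucose=5.0, spacing=np.full(3, 3.0))


class TestDynamicSimulation:
    def test_constant_plasma_zero_vb_gives_linear_tac(self, schedule_16x150):
        c0, ki = 2.0, 0.02
        plasma = simulate_plasma_input([(c0, 0.0)], schedule_16x150)
        ph = simulate_dynamic_series(_uniform_truth(ki, 0.0), plasma, schedule_16x150)
        tac = ph.series.data[0, 0, 0, :]
        np.testing.assert_allclose(tac, ki * c0 * schedule_16x150.midpoints_min,
                                   rtol=1e-12)

    def test_noiseless_patlak_linearity(self, default_plasma, schedule_16x150):
        """The Patlak plot of a noiseless voxel is exactly y = Ki*x + vb."""
        ki, vb = 0.015, 0.05
        ph = simulate_dynamic_series(_uniform_truth(ki, vb), default_plasma,
                                     schedule_16x150)
        s, e = schedule_16x150.starts_s / 60, schedule_16x150.ends_s / 60
        cbar = default_plasma.window_average_conc(s, e)
        ibar = default_plasma.window_average_integral(s, e)
        x, y = ibar / cbar, ph.series.data[1, 2, 3, :] / cbar
        np.testing.assert_allclose(y, ki * x + vb, rtol=1e-10)

    def test_seed_contract(self, default_plasma, schedule_16x150):
        t = _uniform_truth(0.02, 0.05)
        a = simulate_dynamic_series(t, default_plasma, schedule_16x150,
                                    noise_sd=0.05, seed=42)
        b = simulate_dynamic_series(t, default_plasma, schedule_16x150,
                                    noise_sd=0.05, seed=42)
        c = simulate_dynamic_series(t, default_plasma, schedule_16x150,
                                    noise_sd=0.05, seed=43)
        np.testing.assert_array_equal(a.series.data, b.series.data)
        assert not np.array_equal(a.series.data, c.series.data)

    def test_schedule_beyond_plasma_support_rejected(self):
        sched = FrameSchedule.uniform(600.0, 4, 150.0)
        sampled = simulate_plasma_input([(3.0, 0.1)], sched)
        # a curve loaded from samples only supports its sampled range
        from tempopet.phantom import PlasmaCurve
        short = PlasmaCurve(sampled.sample_times_min, sampled.concentrations)
        long_sched = FrameSchedule.uniform(600.0, 16, 150.0)
        with pytest.raises(ValueError, match="support"):
            simulate_dynamic_series(_uniform_truth(0.02, 0.0), short, long_sched)


class TestFrameAlgebra:
    def test_16x150_pairwise_sum_gives_8x300(self, noiseless_phantom):
        out = sum_frames(noiseless_phantom.series, 2)
        assert out.n_frames == 8
        np.testing.assert_allclose(out.schedule.durations_s, 300.0)
        np.testing.assert_allclose(out.schedule.starts_s,
                                   600.0 + 300.0 * np.arange(8))

    def test_constant_series_invariant_and_identity(self, schedule_16x150, default_plasma):
        ph = simulate_dynamic_series(_uniform_truth(0.0, 0.0), default_plasma,
                                     schedule_16x150)
        ph.series.data[:] = 7.0
        out = sum_frames(ph.series, 4)
        np.testing.assert_allclose(out.data, 7.0, rtol=1e-12)
        ident = sum_frames(ph.series, 1)
        np.testing.assert_array_equal(ident.data, ph.series.data)

    def test_duration_weighted_mean(self):
        sched = FrameSchedule(np.array([0.0, 100.0]), np.array([100.0, 300.0]))
        from tempopet.grid_io import DynamicSeries
        data = np.zeros((2, 2, 2, 2))
        data[..., 0], data[..., 1] = 1.0, 3.0
        merged = sum_frames(DynamicSeries(data, 1.0, np.zeros(3), sched), 2)
        np.testing.assert_allclose(merged.data[..., 0], (1 * 100 + 3 * 300) / 400)

    def test_static_window_selection(self, noiseless_phantom):
        series = noiseless_phantom.series
        one = derive_static_image(series, (600.0, 750.0))
        np.testing.assert_allclose(one.values, series.data[..., 0], rtol=1e-12)
        two = derive_static_image(series, (600.0, 900.0))
        np.testing.assert_allclose(two.values, series.data[..., :2].mean(axis=-1))

    def test_sum_then_static_commutes(self, noisy_phantom):
        window = (600.0, 1800.0)
        direct = derive_static_image(noisy_phantom.series, window)
        summed = derive_static_image(sum_frames(noisy_phantom.series, 4), window)
        np.testing.assert_allclose(direct.values, summed.values, atol=1e-12)


class TestPhantomGeneration:
    def test_seed_determinism_bitwise(self):
        a = generate_phantom(7, noise_sd=0.03)
        b = generate_phantom(7, noise_sd=0.03)
        np.testing.assert_array_equal(a.series.data, b.series.data)
        np.testing.assert_array_equal(a.voi_mask.mask, b.voi_mask.mask)
        np.testing.assert_array_equal(a.truth.ki_map, b.truth.ki_map)

    def test_lesion_large_enough_and_structured(self, noiseless_phantom):
        assert noiseless_phantom.voi_mask.n_voxels >= 500
        ki = noiseless_phantom.truth.ki_map[noiseless_phantom.voi_mask.mask]
        assert ki.max() / ki.min() > 1.5     # gradient plus focal spot

    def test_cohort_is_reproducible_and_varied(self):
        c1 = generate_cohort(3, seed=5, noise_sd=0.01)
        c2 = generate_cohort(3, seed=5, noise_sd=0.01)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.phantom.series.data, b.phantom.series.data)
        assert (c1[0].phantom.voi_mask.n_voxels != c1[1].phantom.voi_mask.n_voxels
                or not np.array_equal(c1[0].phantom.truth.ki_map,
                                      c1[1].phantom.truth.ki_map))
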