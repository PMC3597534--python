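"""Trajectory geometry, force-trace processing and non-bonded energies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixpack import traj
from helixpack.structio import TrajectoryFrames
from helixpack.traj import (
    ForceTrace, com_distance, group_interaction_energy,
    integrate_work, lipid_density_profile, membrane_thickness_profile,
    track_shell, window_average,
)


def frames_from(coords_nm, times=None):
    """Frames helper taking coordinates in nm (converted to the Å store)."""
    c = np.asarray(coords_nm, dtype=float) * 10.0
    t = np.arange(c.shape[0]) if times is None else times
    return TrajectoryFrames(coords=c, times=np.asarray(t, dtype=float))


class TestComDistance:
    def test_identical_selections_give_zero(self):
        fr = frames_from(np.random.default_rng(0).normal(0, 1, (4, 6, 3)))
        _, d = com_distance(fr, [0, 1, 2], [0, 1, 2])
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_static_points_50_angstrom_apart(self):
        fr = frames_from(np.tile([[0, 0, 0], [5.0, 0, 0]], (3, 1, 1)))
        _, d = com_distance(fr, [0], [1])
        np.testing.assert_allclose(d, 5.0)

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 2, (5, 8, 3))
        fr1 = frames_from(base)
        fr2 = frames_from(base + rng.normal(0, 30, (5, 1, 3)))
        _, d1 = com_distance(fr1, [0, 1], [4, 5])
        _, d2 = com_distance(fr2, [0, 1], [4, 5])
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_mass_weighting(self):
        fr = frames_from([[[0, 0, 0], [1.0, 0, 0], [4.0, 0, 0]]])
        masses = np.array([1.0, 3.0, 1.0])
        _, d = com_distance(fr, [0, 1], [2], masses=masses)
        assert d[0] == pytest.approx(4.0 - 0.75)

    def test_empty_selection_rejected(self):
        fr = frames_from(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="empty selection"):
            com_distance(fr, [], [0])


class TestWindowAverage:
    def test_constant_series_unchanged(self):
        x = np.linspace(0, 4, 41)
        np.testing.assert_allclose(window_average(x, np.full(41, 7.0)), 7.0)

    def test_linear_ramp_preserved_in_interior(self):
        x = np.linspace(0, 4, 81)
        y = 3.0 * x
        out = window_average(x, y, window=0.5)
        interior = (x > 0.3) & (x < 3.7)
        np.testing.assert_allclose(out[interior], y[interior], atol=1e-9)
        # truncated-edge deviation of a line is bounded by slope·window/4
        assert np.abs(out - y).max() <= 3.0 * 0.5 / 4 + 1e-9

    def test_single_spike_spreads_to_h_over_n(self):
        x = np.arange(0.0, 2.0, 0.1)
        y = np.zeros_like(x)
        y[10] = 5.0
        out = window_average(x, y, window=0.5)
        n = np.sum(np.abs(x - x[10]) <= 0.25)
        assert out[10] == pytest.approx(5.0 / n)

    @given(st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_commutes_with_adding_a_constant(self, c):
        x = np.linspace(0, 3, 31)
        y = np.sin(3 * x)
        np.testing.assert_allclose(window_average(x, y + c),
                                   window_average(x, y) + c, atol=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            window_average(np.array([]), np.array([]))


class TestIntegrateWork:
    def test_constant_force_over_distance(self):
        t = ForceTrace(np.linspace(0, 10, 21), np.linspace(0, 2, 21),
                       np.full(21, 100.0))
        wc = integrate_work(t)
        assert wc.work_pn_nm[-1] == pytest.approx(200.0)

    def test_linear_force_closed_form(self):
        x = np.linspace(0, 3, 301)
        t = ForceTrace(np.linspace(0, 1, 301), x, 7.0 * x)
        wc = integrate_work(t)
        assert wc.work_pn_nm[-1] == pytest.approx(7.0 * 9 / 2, rel=1e-4)

    def test_zero_force_zero_work(self):
        t = ForceTrace([0, 1, 2], [0, 1, 2], [0, 0, 0])
        np.testing.assert_array_equal(integrate_work(t).work_pn_nm, 0.0)

    def test_agrees_with_fine_grid_quadrature(self):
        from scipy.integrate import quad
        f = lambda x: 40.0 * np.sin(2.0 * x) + 55.0
        x = np.linspace(0, 2.5, 20001)
        t = ForceTrace(np.linspace(0, 1, 20001), x, f(x))
        expected = quad(f, 0, 2.5)[0]
        assert integrate_work(t).work_pn_nm[-1] == \
            pytest.approx(expected, rel=1e-6)

    def test_backwards_pull_rejected(self):
        t = ForceTrace([0, 1, 2], [0.0, 0.5, 0.2], [1, 1, 1])
        with pytest.raises(ValueError, match="forward pull"):
            integrate_work(t)

    def test_kbt_conversion(self):
        t = ForceTrace([0, 1], [0, 1], [100.0, 100.0])
        wc = integrate_work(t)
        assert wc.work_kbt(310.0)[-1] == pytest.approx(100.0 / 4.28, rel=1e-3)


class TestDensityProfile:
    def test_uniform_points_recover_flat_density(self):
        rng = np.random.default_rng(7)
        n = rng.poisson(100.0 * 8 * 4 * 2)   # 100/nm³ in an 8×4×2 slab
        pts = np.column_stack([rng.uniform(0, 8, n), rng.uniform(-2, 2, n),
                               rng.uniform(-2, 0, n)])
        fr = frames_from(pts[None, :, :])
        prof = lipid_density_profile(fr, np.arange(n), ((0, 0, 0), (8, 0, 0)),
                                     bin_width_nm=1.0,
                                     transverse_halfwidth_nm=1.0,
                                     z_interval_nm=(-2.0, 0.0))
        per_bin = 100.0 * prof.bin_volume_nm3
        se = 100.0 / np.sqrt(per_bin)
        assert np.all(np.abs(prof.density - 100.0) < 4 * se)
        assert abs(prof.density.mean() - 100.0) < 3 * se / np.sqrt(8)

    def test_empty_region_is_zero(self):
        fr = frames_from(np.full((2, 3, 3), 50.0))  # atoms far outside slab
        prof = lipid_density_profile(fr, [0, 1, 2], ((0, 0, 0), (4, 0, 0)))
        np.testing.assert_array_equal(prof.density, 0.0)

    def test_counts_conserved_per_snapshot(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(0, 4, 500),
                               rng.uniform(-0.8, 0.8, 500),
                               rng.uniform(-1.5, -0.2, 500)])
        fr = frames_from(pts[None, :, :])
        prof = lipid_density_profile(fr, np.arange(500), ((0, 0, 0), (4, 0, 0)),
                                     bin_width_nm=0.5,
                                     transverse_halfwidth_nm=1.0,
                                     z_interval_nm=(-2.0, 0.0))
        total = prof.density.sum() * prof.bin_volume_nm3
        assert total == pytest.approx(500)   # all points inside the slab

    def test_zero_volume_slab_rejected(self):
        fr = frames_from(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="volume"):
            lipid_density_profile(fr, [0, 1], ((0, 0, 0), (4, 0, 0)),
                                  z_interval_nm=(0.0, 0.0))


class TestTrackShell:
    def test_co_translating_chain_keeps_distance(self):
        base = np.array([[0, 0, 0], [1.0, 0, 0]])
        coords = np.stack([base + [0.3 * f, 0, 0] for f in range(5)])
        fr = frames_from(coords)
        _, series = track_shell(fr, [0], [[1]])
        np.testing.assert_allclose(series[0], 1.0, atol=1e-12)

    def test_stationary_chain_falls_behind_at_pull_speed(self):
        # monomer advances 0.5 nm per 1 ps frame; far behind, the
        # separation rate approaches the pull speed
        coords = np.stack([[[0.5 * f, 0, 0], [0, 0, 0]] for f in range(40)])
        fr = frames_from(coords)
        t, series = track_shell(fr, [0], [[1]])
        rate = np.diff(series[0][-5:]) / np.diff(t[-5:])
        np.testing.assert_allclose(rate, 0.5, rtol=1e-3)

    def test_chain_equal_to_monomer_gives_zero(self):
        fr = frames_from(np.random.default_rng(0).normal(0, 1, (3, 4, 3)))
        _, series = track_shell(fr, [0, 1], [[0, 1]])
        np.testing.assert_allclose(series[0], 0.0, atol=1e-12)


class TestThickness:
    def test_flat_slab_thickness(self):
        rng = np.random.default_rng(0)
        n = 400
        up = np.column_stack([rng.uniform(0, 6, n), rng.uniform(-2, 2, n),
                              np.full(n, 2.0)])
        lo = np.column_stack([rng.uniform(0, 6, n), rng.uniform(-2, 2, n),
                              np.full(n, -2.0)])
        fr = frames_from(np.concatenate([up, lo])[None, :, :])
        _, gap = membrane_thickness_profile(fr, np.arange(n),
                                            np.arange(n, 2 * n),
                                            ((0, 0, 0), (6, 0, 0)), 0.5)
        np.testing.assert_allclose(gap, 4.0, atol=1e-9)

    def test_identical_selections_give_zero(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(0, 4, 100),
                               np.zeros(100), rng.normal(0, 1, 100)])
        fr = frames_from(pts[None, :, :])
        _, gap = membrane_thickness_profile(fr, np.arange(100), np.arange(100),
                                            ((0, 0, 0), (4, 0, 0)), 1.0)
        np.testing.assert_allclose(gap[np.isfinite(gap)], 0.0, atol=1e-12)

    def test_unpopulated_bin_reports_nan(self):
        up = np.array([[0.5, 0, 2.0]])
        lo = np.array([[0.5, 0, -2.0]])
        fr = frames_from(np.concatenate([up, lo])[None, :, :])
        _, gap = membrane_thickness_profile(fr, [0], [1],
                                            ((0, 0, 0), (4, 0, 0)), 1.0)
        assert gap[0] == pytest.approx(4.0)
        assert np.all(np.isnan(gap[1:]))


class TestInteractionEnergy:
    @staticmethod
    def _pair_frames(r_nm):
        return frames_from(np.array([[[0, 0, 0], [r_nm, 0, 0]]]))

    def test_lj_minimum_is_minus_epsilon(self):
        eps, sig = 0.8, 0.35
        fr = self._pair_frames(2 ** (1 / 6) * sig)
        params = {0: (eps, sig, 0.0), 1: (eps, sig, 0.0)}
        _, lj, coul = group_interaction_energy(fr, [0], [1], params)
        assert lj[0] == pytest.approx(-eps, rel=1e-12)
        assert coul[0] == 0.0

    def test_pair_beyond_cutoff_is_zero(self):
        fr = self._pair_frames(1.3)
        params = {0: (0.5, 0.35, 1.0), 1: (0.5, 0.35, -1.0)}
        _, lj, coul = group_interaction_energy(fr, [0], [1], params,
                                               cutoff_nm=1.2)
        assert lj[0] == 0.0 and coul[0] == 0.0

    def test_swapping_groups_is_symmetric(self):
        rng = np.random.default_rng(2)
        fr = frames_from(rng.uniform(0, 1.5, (2, 6, 3)))
        params = {i: (0.4 + 0.1 * i, 0.3, (-1) ** i * 0.2) for i in range(6)}
        _, lj1, c1 = group_interaction_energy(fr, [0, 1, 2], [3, 4, 5], params)
        _, lj2, c2 = group_interaction_energy(fr, [3, 4, 5], [0, 1, 2], params)
        np.testing.assert_allclose(lj1, lj2, rtol=1e-12)
        np.testing.assert_allclose(c1, c2, rtol=1e-12)

    def test_coulomb_scales_with_dielectric(self):
        fr = self._pair_frames(0.5)
        params = {0: (0.0, 0.3, 1.0), 1: (0.0, 0.3, 1.0)}
        _, _, c1 = group_interaction_energy(fr, [0], [1], params, dielectric=1.0)
        _, _, c80 = group_interaction_energy(fr, [0], [1], params, dielectric=80.0)
        assert c1[0] == pytest.approx(80.0 * c80[0])
        assert c1[0] == pytest.approx(traj.COULOMB_KJ_NM_PER_MOL_E2 / 0.5)

    def test_overlapping_selections_rejected(self):
        fr = self._pair_frames(0.5)
        params = {0: (0.5, 0.3, 0.0), 1: (0.5, 0.3, 0.0)}
        with pytest.raises(ValueError, match="overlap"):
            group_interaction_energy(fr, [0, 1], [1], params)

    def test_missing_parameters_name_the_atom(self):
        fr = self._pair_frames(0.5)
        with pytest.raises(ValueError, match="atom 1"):
            group_interaction_energy(fr, [0], [1], {0: (0.5, 0.3, 0.0)})
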