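"""Linking, MSD computation, diffusion fitting and mobility classes."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew

from astig3d import (MSDCurve, Track, classify_mobility, fit_diffusion,
                     link_foci, msd_per_dimension, simulate_brownian_4d,
                     summarize_tracks, track_centroid)
from astig3d.localize import Focus


def make_focus(frame, x, y, z=0.0, intensity=100.0, prec=20.0):
    return Focus(frame=frame, x_nm=x, y_nm=y, sigma_x_nm=200, sigma_y_nm=180,
                 intensity=intensity, background=100, snr=10,
                 precision_xy_nm=prec, precision_z_nm=prec, z_nm=z)


def track_from_xyz(xyz_nm, dt_ms=1000.0, intensities=None):
    ints = intensities if intensities is not None else [100.0] * len(xyz_nm)
    return Track([make_focus(i, x, y, z, w)
                  for i, ((x, y, z), w) in enumerate(zip(xyz_nm, ints))],
                 dt_ms=dt_ms)


class TestLinking:
    def test_single_clean_molecule_gives_one_full_track(self):
        by_frame = {f: [make_focus(f, 1000 + 50 * f, 800)] for f in range(8)}
        tracks = link_foci(by_frame, max_jump_nm=500)
        assert len(tracks) == 1
        assert len(tracks[0]) == 8

    def test_two_distant_molecules_never_switch(self):
        rng = np.random.default_rng(0)
        by_frame = {}
        for f in range(12):
            by_frame[f] = [
                make_focus(f, 1000 + rng.normal(0, 30), 1000),
                make_focus(f, 5000 + rng.normal(0, 30), 5000),
            ]
        tracks = link_foci(by_frame, max_jump_nm=500)
        assert len(tracks) == 2
        for tr in tracks:
            xs = tr.positions_nm[:, 0]
            assert np.ptp(xs) < 1000  # all localizations from one molecule

    def test_greedy_matches_hungarian_on_unambiguous_instance(self):
        rng = np.random.default_rng(1)
        prev = [make_focus(0, x, y) for x, y in rng.uniform(0, 6000, (5, 2))]
        nxt = [make_focus(1, f.x_nm + rng.normal(0, 40),
                          f.y_nm + rng.normal(0, 40)) for f in prev]
        order = rng.permutation(5)
        tracks = link_foci({0: prev, 1: [nxt[i] for i in order]},
                           max_jump_nm=500)
        cost = np.array([[np.hypot(p.x_nm - n.x_nm, p.y_nm - n.y_nm)
                          for n in nxt] for p in prev])
        ri, ci = linear_sum_assignment(cost)
        expected = {(prev[i].x_nm, nxt[j].x_nm) for i, j in zip(ri, ci)}
        got = {(tr.localizations[0].x_nm, tr.localizations[1].x_nm)
               for tr in tracks if len(tr) == 2}
        assert got == expected

    def test_equidistant_candidates_resolve_to_lower_index(self):
        head = make_focus(0, 1000, 1000)
        c0 = make_focus(1, 1100, 1000)   # index 0, distance 100
        c1 = make_focus(1, 900, 1000)    # index 1, distance 100
        tracks = link_foci({0: [head], 1: [c0, c1]}, max_jump_nm=500)
        two = [t for t in tracks if len(t) == 2]
        assert len(two) == 1
        assert two[0].localizations[1].x_nm == 1100

    def test_within_frame_order_does_not_change_tracks(self):
        rng = np.random.default_rng(2)
        frames = {}
        for f in range(6):
            frames[f] = [make_focus(f, 1000 + 40 * f, 1000),
                         make_focus(f, 4000 - 40 * f, 4000)]
        t1 = link_foci(frames, max_jump_nm=600)
        t2 = link_foci({f: list(reversed(v)) for f, v in frames.items()},
                       max_jump_nm=600)
        paths1 = {tuple(np.round(t.positions_nm[:, 0], 6)) for t in t1}
        paths2 = {tuple(np.round(t.positions_nm[:, 0], 6)) for t in t2}
        assert paths1 == paths2


class TestMSD:
    def test_uniform_1d_motion_hand_enumeration(self):
        # x = 0, 1, 2, 3 um at 1 s intervals: MSD(k) = k^2 um^2
        xyz = [(0, 0, 0), (1000, 0, 0), (2000, 0, 0), (3000, 0, 0)]
        msd = msd_per_dimension(track_from_xyz(xyz))
        assert np.allclose(msd.msd_x, [1, 4, 9])
        assert np.allclose(msd.msd_y, 0)
        assert np.allclose(msd.n_pairs, [3, 2, 1])

    def test_constant_track_has_zero_msd(self):
        msd = msd_per_dimension(track_from_xyz([(500, 500, 100)] * 6))
        assert np.allclose(msd.msd_3d, 0)

    def test_matches_brute_force_double_loop_on_random_tracks(self, rng):
        for _ in range(25):
            n = rng.integers(3, 12)
            xyz = rng.normal(0, 500, size=(n, 3))
            tr = track_from_xyz(xyz, dt_ms=5.0)
            msd = msd_per_dimension(tr)
            pos = xyz / 1000.0
            for li, k in enumerate(range(1, n)):
                disp = [pos[i + k] - pos[i] for i in range(n - k)]
                oracle = np.mean(np.sum(np.square(disp), axis=1))
                assert msd.msd_3d[li] == pytest.approx(oracle, abs=1e-9)

    def test_ensemble_slope_near_2D_per_dimension(self):
        trajs = simulate_brownian_4d(1.0, 150, 25, dt_ms=5.0, seed=4)
        slopes = []
        for t in trajs:
            tr = track_from_xyz(t.positions, dt_ms=5.0)
            msd = msd_per_dimension(tr, max_lag=4)
            tau = msd.lags_ms / 1000.0
            slopes.append(np.sum(msd.msd_x * tau) / np.sum(tau**2))
        assert np.mean(slopes) == pytest.approx(2.0, rel=0.1)

    def test_overlong_lag_request_truncates_with_warning(self):
        tr = track_from_xyz([(0, 0, 0), (1000, 0, 0), (2000, 0, 0)])
        with pytest.warns(UserWarning, match="truncat"):
            msd = msd_per_dimension(tr, max_lag=10)
        assert len(msd.lags_ms) == 2


class TestDiffusionFit:
    def make_msd(self, D, C, dt_s=0.005, d=1, n=4):
        tau = dt_s * np.arange(1, n + 1)
        y = 2 * d * D * tau + C
        return MSDCurve(lags_ms=tau * 1000, msd_x=y, msd_y=y, msd_z=y,
                        msd_3d=y, n_pairs=np.full(n, 10))

    def test_exact_line_recovers_diffusion_exactly(self):
        prec_nm = 30.0
        C = 2 * 3 * (prec_nm / 1000.0) ** 2
        msd = self.make_msd(0.5, C, d=3)
        est = fit_diffusion(msd, prec_nm, dimensionality=3, component="3d")
        assert est.D == pytest.approx(0.5, abs=1e-12)
        assert est.intercept == pytest.approx(C, rel=1e-12)

    def test_slope_matches_closed_form_oracle(self, rng):
        for _ in range(30):
            y = rng.uniform(0, 0.1, 4)
            prec = rng.uniform(5, 60)
            curve = MSDCurve(lags_ms=5.0 * np.arange(1, 5), msd_x=y,
                             msd_y=y, msd_z=y, msd_3d=y,
                             n_pairs=np.full(4, 5))
            est = fit_diffusion(curve, prec, dimensionality=1)
            tau = 0.005 * np.arange(1, 5)
            C = 2 * (prec / 1000.0) ** 2
            oracle = np.sum((y - C) * tau) / np.sum(tau**2) / 2.0
            assert est.D == pytest.approx(oracle, abs=1e-9)

    def test_negative_slope_flagged_and_immobile(self):
        msd = self.make_msd(0.0, 0.0)
        msd.msd_x = np.array([0.04, 0.03, 0.02, 0.01])
        est = fit_diffusion(msd, 150.0, dimensionality=1)
        assert est.D <= 0
        assert est.flag == "nonpositive_slope"
        assert classify_mobility(est) == "immobile"

    def test_short_curve_fitted_over_available_points(self):
        tau = 0.005 * np.arange(1, 3)
        y = 2 * 1.0 * tau
        msd = MSDCurve(lags_ms=tau * 1000, msd_x=y, msd_y=y, msd_z=y,
                       msd_3d=y, n_pairs=np.array([3, 2]))
        est = fit_diffusion(msd, 0.0, dimensionality=1)
        assert est.flag == "short_track"
        assert est.n_points_fit == 2
        assert est.D == pytest.approx(1.0, abs=1e-12)


class TestMobilityAndCentroid:
    @pytest.mark.parametrize("D, expected", [(0.1, "immobile"),
                                             (0.11, "mobile"),
                                             (0.0, "immobile")])
    def test_immobile_threshold_is_inclusive(self, D, expected):
        from astig3d import DiffusionEstimate
        est = DiffusionEstimate(D=D, intercept=0.0, dimensionality=3,
                                fit_error=0.0)
        assert classify_mobility(est) == expected

    def test_equal_intensity_centroid_is_midpoint(self):
        tr = track_from_xyz([(0, 0, 0), (1000, 0, 0)])
        assert np.allclose(track_centroid(tr), [500, 0, 0])

    def test_intensity_weighted_centroid(self):
        tr = track_from_xyz([(0, 0, 0), (1000, 0, 0)], intensities=[1, 3])
        assert np.allclose(track_centroid(tr), [750, 0, 0])

    def test_zero_total_intensity_rejected(self):
        tr = track_from_xyz([(0, 0, 0), (1000, 0, 0)], intensities=[0, 0])
        with pytest.raises(ValueError, match="intensity"):
            track_centroid(tr)


class TestEnsembleProperties:
    @pytest.fixture(scope="class")
    @staticmethod
    def summary():
        trajs = simulate_brownian_4d(1.0, 250, 20, dt_ms=5.0, seed=9)
        tracks = [Track([make_focus(i, *p) for i, p in
                         enumerate(t.positions)], dt_ms=5.0, id=t.molecule_id)
                  for t in trajs]
        return summarize_tracks(tracks)

    def test_recovered_axes_are_statistically_indistinguishable(self, summary):
        # isotropic input: Dx, Dy, Dz should agree within sampling error
        from scipy.stats import ttest_ind
        for a, b in (("D_x", "D_y"), ("D_x", "D_z"), ("D_y", "D_z")):
            _, p = ttest_ind(summary[a], summary[b])
            assert p > 0.01

    def test_single_track_estimates_positively_skewed(self, summary):
        # few-point MSD fits produce a Gamma-like long right tail
        assert skew(summary["D_3d"]) > 0
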