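"""Analysis windows, activation/recovery detection, origin localization."""

import numpy as np
import pytest

from pbrecgi import (AnalysisWindows, Electrogram, PropagationParams,
                     SpatialGradientOperator, TimingMap,
                     activation_time_spatiotemporal, activation_time_temporal,
                     compute_timing_map, estimate_windows, localization_error,
                     localize_origin, recovery_time_spatiotemporal,
                     recovery_time_temporal, simulate_beat, sphere_mesh)
from pbrecgi.mesh import TriSurfaceMesh
from pbrecgi.postprocessing import WindowingError


@pytest.fixture(scope="module")
def paced_beat(small_heart):
    params = PropagationParams(gbar=4.0)
    return simulate_beat(small_heart, "fhn", params, origin=42)


def grid_patch_mesh(n=6, spacing=1.0):
    """Flat triangulated n x n patch (open; fine for gradient tests)."""
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return TriSurfaceMesh(verts, np.array(faces))


def plane_wave(mesh, speed=1.0, dt=1.0, n_steps=40, width=1.5, amp=100.0):
    """AP-like upstroke wavefront sweeping along +x."""
    x = mesh.vertices[:, 0]
    t = np.arange(n_steps) * dt
    phase = (speed * t[None, :] - x[:, None]) / width
    return amp * 0.5 * (1 + np.tanh(phase)) - 80.0


class TestWindows:
    def test_windows_bracket_stimulus_and_recovery(self, paced_beat):
        w = estimate_windows(paced_beat.phi_H, paced_beat.dt)
        assert abs(w.qrs[0] - 10.0) <= 10.0  # stimulus delivered at 10 ms
        assert w.qrs[1] <= w.t_wave[0]
        act = paced_beat.activation_times()
        assert np.nanmax(act) <= w.qrs[1] + 10.0

    def test_flat_record_rejected(self):
        with pytest.raises(WindowingError):
            estimate_windows(np.zeros((5, 100)), 1.0)

    def test_manual_override_returned_verbatim(self):
        w = AnalysisWindows(qrs=(5.0, 50.0), t_wave=(80.0, 120.0))
        assert estimate_windows(np.zeros((3, 10)), 1.0, override=w) is w

    def test_inconsistent_windows_rejected(self):
        with pytest.raises(ValueError):
            AnalysisWindows(qrs=(50.0, 5.0), t_wave=(80.0, 120.0))


class TestTemporalCriteria:
    def test_tanh_downslope_found_at_inflection(self):
        t = np.arange(0.0, 60.0, 1.0)
        egm = Electrogram(-np.tanh((t - 30.0) / 2.0), dt=1.0)
        w = AnalysisWindows(qrs=(0.0, 59.0), t_wave=(59.0, 60.0))
        tau = activation_time_temporal(egm, w)
        assert abs(tau - 30.0) <= 1.0

    def test_enumerated_example(self):
        egm = Electrogram([1.0, 1.0, 0.5, -0.5, -1.0, -1.0], dt=1.0)
        w = AnalysisWindows(qrs=(0.0, 5.0), t_wave=(5.0, 6.0))
        assert activation_time_temporal(egm, w) == 2.0

    def test_no_downslope_flagged_undefined(self):
        egm = Electrogram(np.arange(10.0), dt=1.0)
        w = AnalysisWindows(qrs=(0.0, 9.0), t_wave=(9.0, 10.0))
        assert np.isnan(activation_time_temporal(egm, w))

    def test_recovery_mirrors_activation(self):
        t = np.arange(0.0, 100.0, 1.0)
        sig = np.where(t < 50, -np.tanh((t - 25.0) / 2.0),
                       np.tanh((t - 75.0) / 2.0) )
        egm = Electrogram(sig, dt=1.0)
        w = AnalysisWindows(qrs=(0.0, 50.0), t_wave=(50.0, 100.0))
        assert abs(recovery_time_temporal(egm, w) - 75.0) <= 1.0

    def test_flat_t_window_undefined(self):
        egm = Electrogram(np.concatenate([np.linspace(1, 0, 10),
                                          np.zeros(10)]), dt=1.0)
        w = AnalysisWindows(qrs=(0.0, 10.0), t_wave=(10.0, 20.0))
        assert np.isnan(recovery_time_temporal(egm, w))

    def test_ap_polarity_flips_slope_sign(self):
        t = np.arange(0.0, 60.0, 1.0)
        egm = Electrogram(np.tanh((t - 30.0) / 2.0), dt=1.0)  # upstroke
        w = AnalysisWindows(qrs=(0.0, 59.0), t_wave=(59.0, 60.0))
        assert np.isnan(activation_time_temporal(egm, w, polarity="egm"))
        assert abs(activation_time_temporal(egm, w, polarity="ap")
                   - 30.0) <= 1.0


class TestSpatialGradient:
    def test_annihilates_constants(self, small_heart):
        op = SpatialGradientOperator(small_heart)
        mag = op.magnitude(np.full((small_heart.n_vertices, 3), 5.0))
        assert np.abs(mag).max() < 1e-10

    def test_linear_field_gradient_magnitude(self):
        mesh = grid_patch_mesh(6)
        op = SpatialGradientOperator(mesh)
        phi = (2.0 * mesh.vertices[:, 0])[:, None]
        mag = op.magnitude(phi)
        np.testing.assert_allclose(mag, 2.0, rtol=1e-10)


class TestSpatiotemporal:
    def test_plane_wave_ordering_matches_passage(self):
        mesh = grid_patch_mesh(6)
        phi = plane_wave(mesh, speed=0.25, n_steps=60)
        w = AnalysisWindows(qrs=(0.0, 59.0), t_wave=(59.0, 60.0))
        tm = activation_time_spatiotemporal(phi, mesh, w, polarity="ap")
        x = mesh.vertices[:, 0]
        # later passage for larger x
        for xa in np.unique(x)[:-1]:
            assert (tm.tau_act[x == xa].mean()
                    <= tm.tau_act[x == xa + 1.0].mean())

    def test_agrees_with_temporal_on_clean_plane_wave(self):
        mesh = grid_patch_mesh(6)
        phi = plane_wave(mesh, speed=0.25, n_steps=60)
        w = AnalysisWindows(qrs=(0.0, 59.0), t_wave=(59.0, 60.0))
        st = activation_time_spatiotemporal(phi, mesh, w, polarity="ap")
        tmp = compute_timing_map(phi, mesh, w, 1.0, "temporal", "ap")
        inner = ~st.fallback
        assert np.all(np.abs(st.tau_act[inner] - tmp.tau_act[inner]) <= 2.0)

    def test_uniform_activation_falls_back(self):
        mesh = grid_patch_mesh(4)
        t = np.arange(40.0)
        sig = 100.0 * 0.5 * (1 + np.tanh((t - 20.0) / 2.0)) - 80.0
        phi = np.tile(sig, (mesh.n_vertices, 1))
        w = AnalysisWindows(qrs=(0.0, 39.0), t_wave=(39.0, 40.0))
        tm = activation_time_spatiotemporal(phi, mesh, w, polarity="ap")
        assert tm.fallback.all()

    def test_time_reversed_wave_gives_reversed_recovery_order(self):
        mesh = grid_patch_mesh(6)
        phi = plane_wave(mesh, speed=0.25, n_steps=60)
        rev = phi[:, ::-1]
        w_act = AnalysisWindows(qrs=(0.0, 59.0), t_wave=(59.0, 60.0))
        w_rec = AnalysisWindows(qrs=(0.0, 1.0), t_wave=(1.0, 60.0))
        act = activation_time_spatiotemporal(phi, mesh, w_act, polarity="ap")
        rec = recovery_time_spatiotemporal(rev, mesh, w_rec, polarity="ap")
        inner = ~act.fallback
        order_a = np.argsort(act.tau_act[inner])
        order_r = np.argsort(-rec.tau_rec[inner], kind="stable")
        x = mesh.vertices[inner, 0]
        np.testing.assert_allclose(np.sort(x[order_a[:6]]),
                                   np.sort(x[order_r[:6]]))

    def test_empty_t_window_rejected(self):
        mesh = grid_patch_mesh(4)
        phi = plane_wave(mesh, n_steps=30)
        w = AnalysisWindows(qrs=(0.0, 29.0), t_wave=(29.0, 30.0))
        with pytest.raises(WindowingError):
            recovery_time_spatiotemporal(phi, mesh, w, polarity="ap")


class TestTimingMapOnSimulatedBeat:
    def test_temporal_times_track_simulator_ground_truth(self, small_heart,
                                                         paced_beat):
        from scipy.stats import spearmanr
        w = estimate_windows(paced_beat.phi_H, paced_beat.dt)
        tm = compute_timing_map(paced_beat.phi_H, small_heart, w,
                                paced_beat.dt, "temporal", polarity="ap")
        truth = paced_beat.activation_times()
        rho = spearmanr(tm.tau_act, truth).statistic
        assert rho > 0.98

    def test_recovery_after_activation_everywhere(self, small_heart,
                                                  paced_beat):
        w = estimate_windows(paced_beat.phi_H, paced_beat.dt)
        tm = compute_timing_map(paced_beat.phi_H, small_heart, w,
                                paced_beat.dt, "temporal", polarity="ap")
        assert np.all(tm.tau_rec > tm.tau_act)


class TestLocalization:
    def test_earliest_node_and_tie_break(self, small_heart):
        tau = np.linalg.norm(small_heart.vertices
                             - small_heart.vertices[5], axis=1)
        tm = TimingMap(tau_act=tau, tau_rec=tau + 1.0, method="temporal")
        assert localize_origin(tm, small_heart) == 5
        tau2 = np.ones(small_heart.n_vertices)
        tau2[[3, 9]] = 0.0
        tm2 = TimingMap(tau_act=tau2, tau_rec=tau2 + 1, method="temporal")
        assert localize_origin(tm2, small_heart) == 3

    def test_all_undefined_rejected(self, small_heart):
        tm = TimingMap(tau_act=np.full(small_heart.n_vertices, np.nan),
                       tau_rec=np.full(small_heart.n_vertices, np.nan),
                       method="temporal")
        with pytest.raises(ValueError):
            localize_origin(tm, small_heart)

    def test_localization_error_euclidean(self, small_heart):
        v = small_heart.vertices
        assert localization_error(4, v[4], small_heart) == 0.0
        # antipode on a radius-40 sphere is a diameter away
        anti = -v[4]
        idx = np.argmin(np.linalg.norm(v - anti, axis=1))
        err = localization_error(int(idx), v[4], small_heart)
        assert err == pytest.approx(80.0, rel=0.05)

    def test_noiseless_phantom_localizes_to_pacing_site(self, small_heart,
                                                        paced_beat):
        w = estimate_windows(paced_beat.phi_H, paced_beat.dt)
        tm = compute_timing_map(paced_beat.phi_H, small_heart, w,
                                paced_beat.dt, "temporal", polarity="ap")
        pred = localize_origin(tm, small_heart)
        err = localization_error(pred, small_heart.vertices[42], small_heart)
        assert err <= small_heart.edge_lengths().max()
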