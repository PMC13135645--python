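"""Wall-shear metric suite: closed-form cases, quadrature oracles,
scaling/convergence properties and the lumped pressure network."""

import numpy as np
import pytest
import trimesh

from avflow import (
    Centreline,
    FlowWaveform,
    SurfaceFieldSeries,
    VolumeSnapshot,
    build_tube,
    lnh,
    lumped_pressure_network,
    osi,
    peak_systole_index,
    poiseuille_resistance,
    segment_aggregate,
    tawss,
    transwss,
    womersley_surface_series,
    wssg,
)
from avflow.metrics import compute_metric_maps


@pytest.fixture(scope="module")
def small_tube():
    x = np.linspace(0.0, 100.0, 101)
    cl = Centreline(np.column_stack([x, 0 * x, 0 * x]), "feeding_artery", 0 * x)
    return build_tube(cl, 5.0, mesh_edge_target=1.0), cl


def _series(mesh, amp_fn, n_t=64, period=1.0):
    """Axial traction with per-time scalar amplitude amp_fn(t)."""
    t = np.linspace(0.0, period, n_t, endpoint=False)
    normals = mesh.face_normals
    axial = np.array([1.0, 0.0, 0.0])
    tang = axial - normals * (normals @ axial)[:, None]
    nrm = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = np.where(nrm > 1e-12, tang / np.where(nrm == 0, 1, nrm), 0.0)
    amps = np.array([amp_fn(ti) for ti in t])
    traction = amps[:, None, None] * tang[None, :, :]
    return SurfaceFieldSeries(mesh=mesh, times=t, traction=traction, period=period)


class TestTAWSS:
    def test_constant_magnitude(self, small_tube):
        mesh, _ = small_tube
        s = _series(mesh, lambda t: 2.0)
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        assert np.allclose(tawss(s)[lateral], 2.0)

    def test_sinusoid_mean_of_abs(self, small_tube):
        # |A sin| averages to 2A/pi
        mesh, _ = small_tube
        s = _series(mesh, lambda t: 3.0 * np.sin(2 * np.pi * t), n_t=256)
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        assert np.allclose(tawss(s)[lateral], 6.0 / np.pi, rtol=1e-3)

    def test_gap_rejected(self, small_tube):
        mesh, _ = small_tube
        s = _series(mesh, lambda t: 1.0, n_t=64)
        bad = SurfaceFieldSeries(mesh=mesh, times=s.times[s.times < 0.6],
                                 traction=s.traction[s.times < 0.6], period=1.0)
        with pytest.raises(ValueError, match="gap"):
            tawss(bad)

    def test_needs_three_samples(self, small_tube):
        mesh, _ = small_tube
        t = np.array([0.0, 0.5])
        tr = np.zeros((2, len(mesh.faces), 3))
        s = SurfaceFieldSeries(mesh=mesh, times=t, traction=tr, period=1.0)
        with pytest.raises(ValueError, match="3 time samples"):
            tawss(s)


class TestOSI:
    def test_unidirectional_zero(self, small_tube):
        mesh, _ = small_tube
        s = _series(mesh, lambda t: 1.5 + np.sin(2 * np.pi * t) ** 2)
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        assert np.allclose(osi(s)[lateral], 0.0, atol=1e-12)

    def test_zero_mean_oscillation_half(self, small_tube):
        mesh, _ = small_tube
        s = _series(mesh, lambda t: np.sin(2 * np.pi * t), n_t=128)
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        assert np.allclose(osi(s)[lateral], 0.5, atol=1e-6)

    def test_offset_sinusoid_against_quadrature(self, small_tube):
        # B + A sin with B = 1, A = 2: OSI = 0.5*(1 - B*T/int|B+A sin|dt)
        mesh, _ = small_tube
        B, A = 1.0, 2.0
        s = _series(mesh, lambda t: B + A * np.sin(2 * np.pi * t), n_t=512)
        tt = np.linspace(0, 1, 200001)
        integral = np.trapezoid(np.abs(B + A * np.sin(2 * np.pi * tt)), tt)
        expected = 0.5 * (1 - B / integral)
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        assert np.allclose(osi(s)[lateral], expected, atol=5e-4)


class TestTransWSS:
    def test_fixed_direction_zero(self, small_tube):
        mesh, _ = small_tube
        s = _series(mesh, lambda t: 1.0 + 0.8 * np.cos(2 * np.pi * t))
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        assert np.allclose(transwss(s)[lateral], 0.0, atol=1e-12)

    def test_rotating_vector_two_over_pi(self):
        # traction rotating uniformly in the tangent plane of a flat patch
        # at constant 1 Pa, with a small constant bias fixing the mean
        # direction: transverse mean -> 2/pi as the bias vanishes
        grid = trimesh.creation.box(extents=[1, 1, 0.02])
        n_t = 720
        t = np.linspace(0, 1, n_t, endpoint=False)
        nf = len(grid.faces)
        traction = np.zeros((n_t, nf, 3))
        top = grid.face_normals[:, 2] > 0.9
        eps = 1e-6
        for i, ti in enumerate(t):
            vec = np.array([np.cos(2 * np.pi * ti) + eps, np.sin(2 * np.pi * ti), 0.0])
            traction[i, top, :] = vec
        s = SurfaceFieldSeries(mesh=grid, times=t, traction=traction, period=1.0)
        got = transwss(s)[top]
        assert np.allclose(got, 2.0 / np.pi, rtol=1e-3)

    def test_zero_mean_missing_not_zero(self, small_tube):
        mesh, _ = small_tube
        s = _series(mesh, lambda t: np.sin(2 * np.pi * t), n_t=128)
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        assert np.isnan(transwss(s)[lateral]).all()


class TestWSSG:
    def test_uniform_field_zero(self, small_tube):
        mesh, _ = small_tube
        g = wssg(np.full(len(mesh.faces), 2.5), mesh)
        assert np.allclose(g[np.isfinite(g)], 0.0, atol=1e-9)

    def test_linear_field_on_flat_patch(self):
        xs = np.linspace(0, 20, 41)
        X, Y = np.meshgrid(xs, xs)
        verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        n = len(xs)
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
        patch = trimesh.Trimesh(verts, np.array(faces), process=False)
        g = wssg(0.2 * patch.triangles_center[:, 0], patch)
        c = patch.triangles_center
        interior = (c[:, 0] > 2) & (c[:, 0] < 18) & (c[:, 1] > 2) & (c[:, 1] < 18)
        assert np.allclose(g[interior], 0.2, rtol=0.05)

    def test_axial_linear_field_on_cylinder(self, small_tube):
        mesh, _ = small_tube
        g = wssg(0.1 * mesh.triangles_center[:, 0], mesh)
        c = mesh.triangles_center
        lateral = (np.abs(mesh.face_normals[:, 0]) < 0.5) & (c[:, 0] > 5) & (c[:, 0] < 95)
        assert np.allclose(g[lateral], 0.1, rtol=0.05)


class TestLNH:
    def test_poiseuille_orthogonal(self):
        # axial velocity, azimuthal vorticity: v.omega = 0 everywhere
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1, 1, (200, 3))
        r = np.hypot(pts[:, 0], pts[:, 1]) + 0.05
        v = np.column_stack([0 * r, 0 * r, 1 - r**2])
        # omega = curl v is purely azimuthal
        phi_hat = np.column_stack([-pts[:, 1] / r, pts[:, 0] / r, 0 * r])
        w = 2 * r[:, None] * phi_hat
        out = lnh(VolumeSnapshot(pts, v, w))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_swirl_closed_form(self):
        # v = W e_z + Gamma*r e_phi, omega = 2 Gamma e_z:
        # LNH = W / sqrt(W^2 + Gamma^2 r^2)
        W, Gamma = 0.8, 1.7
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1, 1, (300, 3))
        r = np.hypot(pts[:, 0], pts[:, 1])
        phi_hat = np.column_stack([-pts[:, 1], pts[:, 0], 0 * r])
        phi_hat /= np.maximum(np.linalg.norm(phi_hat, axis=1, keepdims=True), 1e-12)
        v = W * np.array([0, 0, 1.0]) + Gamma * r[:, None] * phi_hat
        w = np.tile([0.0, 0.0, 2 * Gamma], (len(pts), 1))
        out = lnh(VolumeSnapshot(pts, v, w))
        expected = W / np.sqrt(W**2 + Gamma**2 * r**2)
        assert np.allclose(out, expected, rtol=1e-9)

    def test_zero_velocity_missing(self):
        pts = np.zeros((3, 3))
        v = np.zeros((3, 3))
        w = np.ones((3, 3))
        assert np.isnan(lnh(VolumeSnapshot(pts, v, w))).all()


class TestPeakSystole:
    def test_steady_tie_goes_first(self):
        assert peak_systole_index(FlowWaveform(period=1.0, mean_flow=500.0)) == 0

    def test_sinusoid_peak_near_quarter_period(self):
        wf = FlowWaveform(period=1.0, mean_flow=10.0, harmonics=[(1, -3j)],
                          sample_times=np.linspace(0, 1, 100, endpoint=False))
        # Re(-3i e^{i w t}) = 3 sin(w t): maximum at T/4
        idx = peak_systole_index(wf)
        assert wf.sample_times[idx] == pytest.approx(0.25, abs=0.011)

    def test_two_equal_maxima_earlier_wins(self):
        wf = FlowWaveform(period=1.0, mean_flow=10.0, harmonics=[(2, 2.0 + 0j)],
                          sample_times=np.linspace(0, 1, 64, endpoint=False))
        # second harmonic: equal maxima at t = 0 and t = T/2
        assert peak_systole_index(wf) == 0


@pytest.fixture(scope="module")
def segmented_tube(small_tube):
    from avflow import partition_segments

    mesh, cl = small_tube
    table = partition_segments(mesh, {"feeding_artery": cl}, np.array([], dtype=int))
    return mesh, cl, table


class TestSegmentAggregate:
    def test_uniform_field(self, segmented_tube):
        mesh, _, table = segmented_tube
        out = segment_aggregate({"m": np.full(len(mesh.faces), 3.3)}, table, mesh)
        vals = out[out.limb == "feeding_artery"].value
        assert np.allclose(vals, 3.3)

    def test_step_field(self, segmented_tube):
        mesh, _, table = segmented_tube
        field = np.where(mesh.triangles_center[:, 0] < 50.0, 2.0, 1.0)
        out = segment_aggregate({"m": field}, table, mesh)
        sub = out[out.limb == "feeding_artery"].sort_values("seg_index")
        assert np.allclose(sub.value.iloc[:5], 2.0, atol=0.05)
        assert np.allclose(sub.value.iloc[5:], 1.0, atol=0.05)

    def test_all_missing_segment_warns(self, segmented_tube):
        mesh, _, table = segmented_tube
        field = np.full(len(mesh.faces), np.nan)
        field[mesh.triangles_center[:, 0] < 50.0] = 1.0
        with pytest.warns(RuntimeWarning, match="all-missing"):
            out = segment_aggregate({"m": field}, table, mesh)
        sub = out[out.limb == "feeding_artery"].sort_values("seg_index")
        assert np.isnan(sub.value.iloc[-1])
        assert np.isfinite(sub.value.iloc[0])

    def test_consistency_with_global_mean(self, segmented_tube):
        # the area-weighted mean of the segment means recovers the global
        # area-weighted mean (conservation of the aggregation)
        mesh, _, table = segmented_tube
        rng = np.random.default_rng(4)
        field = rng.uniform(0.5, 2.0, len(mesh.faces))
        out = segment_aggregate({"m": field}, table, mesh)
        areas = mesh.area_faces
        seg_area = np.array([areas[table.faces_of(i)].sum()
                             for i in range(len(table.segments))])
        keep = seg_area > 0  # the (empty) anastomosis segment drops out
        recombined = np.average(out.value.to_numpy()[keep], weights=seg_area[keep])
        assert recombined == pytest.approx(np.average(field, weights=areas), rel=1e-9)


class TestScalingAndConvergence:
    def test_linear_scaling(self, small_tube, pulsatile_waveform):
        mesh, cl = small_tube
        s = womersley_surface_series(mesh, cl, pulsatile_waveform, radius=2.5)
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        t1, o1, tr1 = tawss(s), osi(s), transwss(s)
        s3 = s.scaled(3.0)
        assert np.allclose(tawss(s3)[lateral], 3.0 * t1[lateral], rtol=1e-9)
        assert np.allclose(transwss(s3)[lateral], 3.0 * tr1[lateral],
                           rtol=1e-9, equal_nan=True)
        assert np.allclose(osi(s3)[lateral], o1[lateral], atol=1e-12)

    def test_timestep_halving(self, small_tube):
        mesh, cl = small_tube
        wf64 = FlowWaveform.physiologic(mean_flow=600.0, n_samples=64)
        wf128 = FlowWaveform.physiologic(mean_flow=600.0, n_samples=128)
        lateral = np.abs(mesh.face_normals[:, 0]) < 0.9
        a = womersley_surface_series(mesh, cl, wf64, radius=2.5)
        b = womersley_surface_series(mesh, cl, wf128, radius=2.5)
        for fn in (tawss, osi, transwss):
            va, vb = fn(a)[lateral], fn(b)[lateral]
            ok = np.isfinite(va) & np.isfinite(vb)
            scale = max(np.abs(vb[ok]).max(), 1e-12)
            assert np.max(np.abs(va[ok] - vb[ok])) / scale < 0.002

    def test_metric_ranges_on_random_fields(self, small_tube):
        # property sweep: OSI in [0, 0.5], magnitudes >= 0 on random fields
        mesh, _ = small_tube
        rng = np.random.default_rng(9)
        n_t = 32
        t = np.linspace(0, 1, n_t, endpoint=False)
        normals = mesh.face_normals
        for _ in range(5):
            raw = rng.normal(size=(n_t, len(mesh.faces), 3))
            raw -= np.einsum("tfk,fk->tf", raw, normals)[:, :, None] * normals
            s = SurfaceFieldSeries(mesh=mesh, times=t, traction=raw, period=1.0)
            o = osi(s)
            maps = compute_metric_maps(s)
            assert np.nanmin(o) >= 0.0 and np.nanmax(o) <= 0.5
            assert np.nanmin(maps.tawss) >= 0.0
            assert np.nanmin(maps.transwss) >= 0.0
            assert np.nanmin(maps.wssg) >= 0.0


class TestLumpedNetwork:
    LENGTHS = dict(feeding_artery=100.0, draining_vein=100.0, distal_artery=100.0)
    RADII = dict(feeding_artery=2.5, draining_vein=2.5, distal_artery=2.5)

    def test_single_tube_poiseuille_drop(self):
        # Q = 1e-5 m^3/s through L = 100 mm, R = 2.5 mm: dP ~ 228 Pa
        res = lumped_pressure_network(self.LENGTHS, self.RADII, 600.0,
                                      viscosity=3.5e-3)
        drop = res.pressures["feeding_artery_inlet"] - res.pressures["anastomosis"]
        assert drop == pytest.approx(8 * 3.5e-3 * 0.1 * 1e-5 / (np.pi * 2.5e-3**4),
                                     rel=1e-9)
        assert drop == pytest.approx(228.0, rel=0.01)

    def test_tiny_anastomosis_resistance_causes_steal(self):
        # limit analysis: a very large anastomotic area (resistance scale
        # 1e-3) drops the anastomotic pressure below a collateral-perfused
        # distal bed -> distal flow reverses
        bed = 300.0  # Pa, collateral perfusion of the distal arm
        normal = lumped_pressure_network(self.LENGTHS, self.RADII, 600.0,
                                         anastomosis_resistance_scale=1.0,
                                         distal_pressure=bed)
        steal = lumped_pressure_network(self.LENGTHS, self.RADII, 600.0,
                                        anastomosis_resistance_scale=1e-3,
                                        distal_pressure=bed)
        assert not normal.distal_reversal
        assert steal.distal_reversal
        assert steal.pressures["anastomosis"] < bed
        assert steal.flows["distal_artery"] < 0 < normal.flows["distal_artery"]

    def test_zero_flow_equal_pressures(self):
        res = lumped_pressure_network(self.LENGTHS, self.RADII, 0.0)
        assert np.allclose(list(res.pressures.values()), 0.0, atol=1e-12)
        assert not res.distal_reversal

    def test_pressure_ordering_physiologic(self):
        # feeding artery > anastomosis > vein inlet > vein outlet
        res = lumped_pressure_network(self.LENGTHS, self.RADII, 900.0)
        p = res.pressures
        assert (p["feeding_artery_inlet"] > p["anastomosis"]
                > p["vein_inlet"] > p["venous_outlet"])

    def test_invalid_inputs(self):
        bad = dict(self.RADII, draining_vein=-1.0)
        with pytest.raises(ValueError):
            lumped_pressure_network(self.LENGTHS, bad, 600.0)
        with pytest.raises(ValueError):
            lumped_pressure_network(self.LENGTHS, self.RADII, -5.0)

    def test_poiseuille_resistance_value(self):
        r = poiseuille_resistance(100.0, 2.5, 3.5e-3)
        assert r == pytest.approx(8 * 3.5e-3 * 0.1 / (np.pi * (2.5e-3) ** 4), rel=1e-12)
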