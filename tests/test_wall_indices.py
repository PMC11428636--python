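"""Wall indices: quadrature oracles, closed forms, sentinels, thresholds."""

import numpy as np
import pytest

from hemowall.synthetic_data import SynthConfig, synth_tube_mesh, synth_wss_series
from hemowall.wall_indices import (
    SurfaceMesh,
    WSSFieldSeries,
    compute_ecap,
    compute_indices,
    compute_osi,
    compute_rrt,
    compute_tawss,
    tangential_project,
    threshold_area,
)


def flat_patch(n_cells: int = 4) -> SurfaceMesh:
    """Unit-normal (+z) strip of right triangles in the z = 0 plane."""
    n_quads = (n_cells + 1) // 2
    verts = []
    for i in range(n_quads + 1):
        verts += [[i, 0.0, 0.0], [i, 1.0, 0.0]]
    verts = np.array(verts, dtype=float)
    tris = []
    for i in range(n_quads):
        a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
        tris += [[a, c, b], [b, c, d]]
    return SurfaceMesh(verts, np.array(tris[:n_cells]))


def series_from_components(mesh, times, T, fn):
    """Build a WSS series from a vectorized function t -> (nt, cells, 3)."""
    return WSSFieldSeries(mesh, times, fn(times), T)


@pytest.fixture
def smooth_series():
    """Low-order Fourier WSS vectors bounded away from zero (analytic |WSS|)."""
    mesh = flat_patch(4)
    rng = np.random.default_rng(11)
    c = rng.normal(0, 1, (mesh.n_cells, 3)) * np.array([1, 1, 0.0]) + [5.0, 0, 0]
    a = rng.normal(0, 0.5, (2, mesh.n_cells, 3)) * np.array([1, 1, 0.0])
    b = rng.normal(0, 0.5, (2, mesh.n_cells, 3)) * np.array([1, 1, 0.0])

    def f(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.tile(c, (t.size, 1, 1))
        for k in (1, 2):
            out += np.cos(2 * np.pi * k * t)[:, None, None] * a[k - 1]
            out += np.sin(2 * np.pi * k * t)[:, None, None] * b[k - 1]
        return out

    times = np.arange(256) / 256.0
    return series_from_components(mesh, times, 1.0, f), f


def dense_oracle(f, n=1_000_000):
    """High-resolution quadrature of the underlying continuous field."""
    t = np.arange(n) / n
    acc_vec = 0.0
    acc_mag = 0.0
    for chunk in np.array_split(t, 50):
        vals = f(chunk)
        acc_vec = acc_vec + vals.sum(axis=0)
        acc_mag = acc_mag + np.linalg.norm(vals, axis=2).sum(axis=0)
    vec_int = acc_vec / n
    mag_int = acc_mag / n
    tawss = mag_int
    osi = 0.5 * (1 - np.linalg.norm(vec_int, axis=1) / mag_int)
    return tawss, osi


class TestMeshGeometry:
    def test_areas_match_cross_product_recomputation(self):
        mesh = synth_tube_mesh(0.01, 0.05, 1.0)
        p = mesh.vertices[mesh.triangles]
        areas = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        assert np.allclose(mesh.cell_areas, areas, rtol=1e-12, atol=0.0)
        assert np.allclose(np.linalg.norm(mesh.cell_normals, axis=1), 1.0)

    def test_degenerate_meshes_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):  # collinear -> zero area
            SurfaceMesh(verts, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError):  # index out of range
            SurfaceMesh(verts, np.array([[0, 1, 5]]))


class TestTangentialProject:
    def test_tangential_vectors_unchanged(self):
        mesh = flat_patch(2)
        times = np.arange(8) / 8.0
        wss = np.tile([1.0, 2.0, 0.0], (8, mesh.n_cells, 1))
        s = WSSFieldSeries(mesh, times, wss, 1.0)
        out = tangential_project(s)
        assert np.array_equal(out.wss, wss)

    def test_normal_vector_projects_to_zero(self):
        mesh = flat_patch(2)
        times = np.arange(8) / 8.0
        wss = np.tile([0.0, 0.0, 3.0], (8, mesh.n_cells, 1))
        out = tangential_project(WSSFieldSeries(mesh, times, wss, 1.0))
        assert np.max(np.abs(out.wss)) < 1e-15

    def test_random_vectors_become_orthogonal_and_shorter(self):
        mesh = synth_tube_mesh(0.01, 0.03, 1.0)
        rng = np.random.default_rng(3)
        times = np.arange(8) / 8.0
        wss = rng.normal(0, 2, (8, mesh.n_cells, 3))
        s = WSSFieldSeries(mesh, times, wss, 1.0)
        out = tangential_project(s)
        dots = np.einsum("tcx,cx->tc", out.wss, mesh.cell_normals)
        assert np.max(np.abs(dots)) < 1e-12
        assert np.all(
            np.linalg.norm(out.wss, axis=2) <= np.linalg.norm(wss, axis=2) + 1e-15
        )


class TestTAWSS:
    def test_constant_vector(self):
        mesh = flat_patch(2)
        times = np.arange(16) / 16.0
        wss = np.tile([3.0, 4.0, 0.0], (16, mesh.n_cells, 1))  # |WSS| = 5
        tawss = compute_tawss(WSSFieldSeries(mesh, times, wss, 1.0))
        assert tawss == pytest.approx([5.0, 5.0], rel=1e-14)

    def test_square_wave_any_duty_cycle(self):
        mesh = flat_patch(1)
        times = np.arange(40) / 40.0
        s = np.where(np.arange(40) < 13, 1.0, -1.0)
        wss = np.zeros((40, 1, 3))
        wss[:, 0, 0] = s
        tawss = compute_tawss(WSSFieldSeries(mesh, times, wss, 1.0))
        assert tawss[0] == pytest.approx(1.0, rel=1e-14)

    def test_offset_sine_against_dense_quadrature(self, smooth_series):
        series, f = smooth_series
        tawss_oracle, _ = dense_oracle(f)
        tawss = compute_tawss(series)
        assert tawss == pytest.approx(tawss_oracle, rel=2e-6)

    def test_too_few_samples_rejected(self):
        mesh = flat_patch(1)
        s = WSSFieldSeries(mesh, np.array([0.0, 0.5]), np.ones((2, 1, 3)), 1.0)
        with pytest.raises(ValueError):
            compute_tawss(s)


class TestOSI:
    def test_unidirectional_is_zero(self):
        mesh = flat_patch(2)
        times = np.arange(32) / 32.0
        mag = 2.0 + np.sin(2 * np.pi * times)  # >= 1, same direction
        wss = np.zeros((32, mesh.n_cells, 3))
        wss[:, :, 0] = mag[:, None]
        osi = compute_osi(WSSFieldSeries(mesh, times, wss, 1.0))
        assert np.max(osi) < 1e-14

    def test_square_wave_duty_cycle_closed_form(self):
        cfg = SynthConfig(seed=0, osi_targets=(0.25,), wss_magnitudes=(1.0,))
        mesh = synth_tube_mesh(0.01, 0.03, 1.0)
        series, truth = synth_wss_series(mesh, cfg)
        osi = compute_osi(series)
        assert osi == pytest.approx(np.full(mesh.n_cells, 0.25), abs=1e-14)

    def test_smooth_series_against_dense_quadrature(self, smooth_series):
        series, f = smooth_series
        _, osi_oracle = dense_oracle(f)
        osi = compute_osi(series)
        assert osi == pytest.approx(osi_oracle, abs=1e-6)

    def test_all_zero_cell_degenerates_to_zero(self, caplog):
        mesh = flat_patch(2)
        times = np.arange(16) / 16.0
        wss = np.zeros((16, mesh.n_cells, 3))
        wss[:, 1, 0] = 1.0
        with caplog.at_level("WARNING"):
            osi = compute_osi(WSSFieldSeries(mesh, times, wss, 1.0))
        assert osi[0] == 0.0
        assert "zero WSS" in caplog.text

    def test_bounds_on_adversarial_sign_flipping(self):
        mesh = flat_patch(6)
        rng = np.random.default_rng(99)
        times = np.sort(rng.uniform(0.001, 0.999, 198))
        times = np.concatenate([[0.0], times])
        wss = rng.choice([-1.0, 1.0], size=(199, mesh.n_cells, 3)) * rng.uniform(
            0, 30, size=(199, mesh.n_cells, 3)
        )
        osi = compute_osi(WSSFieldSeries(mesh, times, wss, 1.0))
        assert np.all(osi >= 0.0) and np.all(osi <= 0.5)


class TestRRTandECAP:
    def test_direct_values(self):
        rrt = compute_rrt(np.array([1.0]), np.array([0.25]))
        assert rrt[0] == pytest.approx(2.0, rel=1e-14)
        ecap = compute_ecap(np.array([1.0]), np.array([0.25]))
        assert ecap[0] == pytest.approx(0.25, rel=1e-14)

    def test_singularities_give_inf_sentinels(self):
        rrt = compute_rrt(np.array([1.0, 0.0]), np.array([0.5, 0.1]))
        assert np.isinf(rrt).all()
        ecap = compute_ecap(np.array([0.0, 0.0]), np.array([0.3, 0.0]))
        assert np.isinf(ecap[0]) and ecap[1] == 0.0

    def test_random_fields_elementwise_recomputation(self):
        rng = np.random.default_rng(5)
        tawss = rng.uniform(0.1, 30, 100)
        osi = rng.uniform(0, 0.49, 100)
        assert np.array_equal(compute_rrt(tawss, osi), 1.0 / ((1 - 2 * osi) * tawss))
        assert np.array_equal(compute_ecap(tawss, osi), osi / tawss)

    def test_consistency_triplet_is_bitwise(self, smooth_series):
        series, _ = smooth_series
        m = compute_indices(series)
        assert np.array_equal(m.rrt, compute_rrt(m.tawss, m.osi))
        assert np.array_equal(m.ecap, compute_ecap(m.tawss, m.osi))
        ok = np.isfinite(m.rrt)
        assert np.allclose(m.rrt[ok] * (1 - 2 * m.osi[ok]) * m.tawss[ok], 1.0,
                           rtol=1e-9)
        assert np.allclose(m.ecap * m.tawss, m.osi, rtol=1e-9)


class TestScaleEquivariance:
    def test_scaling_laws(self, smooth_series):
        series, _ = smooth_series
        m1 = compute_indices(series)
        c = 3.7
        scaled = WSSFieldSeries(series.mesh, series.times, c * series.wss,
                                series.period_T)
        m2 = compute_indices(scaled)
        assert m2.tawss == pytest.approx(c * m1.tawss, rel=1e-12)
        assert m2.osi == pytest.approx(m1.osi, abs=1e-12)
        assert m2.rrt == pytest.approx(m1.rrt / c, rel=1e-12)
        assert m2.ecap == pytest.approx(m1.ecap / c, rel=1e-12)


class TestTimeGridInvariance:
    def test_uniform_vs_nonuniform_sampling(self, smooth_series):
        series, f = smooth_series
        m1 = compute_indices(series)
        rng = np.random.default_rng(8)
        tnu = np.sort(rng.uniform(0, 1, 299))
        tnu = np.concatenate([[0.0], tnu])
        s2 = series_from_components(series.mesh, tnu, 1.0, f)
        m2 = compute_indices(s2)
        assert np.max(np.abs(m2.tawss - m1.tawss) / m1.tawss) < 1e-3
        assert np.max(np.abs(m2.osi - m1.osi)) < 1e-3


class TestThresholdArea:
    def test_uniform_field_above(self):
        mesh = flat_patch(4)
        m = compute_indices(
            WSSFieldSeries(mesh, np.arange(8) / 8.0,
                           np.tile([6.0, 0, 0], (8, mesh.n_cells, 1)), 1.0)
        )
        res = threshold_area(m, "tawss", 5.0, "above")
        assert res.fraction == 1.0
        assert res.area_m2 == pytest.approx(mesh.total_area)

    def test_infinite_threshold_gives_empty_mask(self):
        mesh = flat_patch(4)
        m = compute_indices(
            WSSFieldSeries(mesh, np.arange(8) / 8.0,
                           np.tile([6.0, 0, 0], (8, mesh.n_cells, 1)), 1.0)
        )
        assert threshold_area(m, "tawss", np.inf, "above").fraction == 0.0

    def test_planted_two_region_fraction(self):
        mesh = synth_tube_mesh(0.01, 0.04, 1.0)
        z = mesh.cell_centers[:, 2]
        hot = z > 0.02
        wss = np.zeros((8, mesh.n_cells, 3))
        wss[:, :, 0] = np.where(hot, 10.0, 1.0)
        m = compute_indices(WSSFieldSeries(mesh, np.arange(8) / 8.0, wss, 1.0))
        res = threshold_area(m, "tawss", 5.0, "above")
        expected = mesh.cell_areas[hot].sum() / mesh.total_area
        assert res.fraction == pytest.approx(expected, abs=1e-12)
        assert np.array_equal(res.cell_mask, hot)

    def test_unknown_field_rejected(self):
        mesh = flat_patch(2)
        m = compute_indices(
            WSSFieldSeries(mesh, np.arange(8) / 8.0,
                           np.ones((8, mesh.n_cells, 3)), 1.0)
        )
        with pytest.raises(ValueError):
            threshold_area(m, "transwss", 1.0)


def test_solver_generated_unidirectional_flow_has_zero_osi():
    """High TAWSS goes with low OSI: a non-reversing pulsatile solve plants
    OSI = 0 at every cell and the pipeline recovers exactly that."""
    cfg = SynthConfig(seed=4, wss_samples_per_cycle=100)
    mesh = synth_tube_mesh(cfg.radius, cfg.length, 1.0)
    series, truth = synth_wss_series(mesh, cfg, mode="solver")
    m = compute_indices(series)
    assert np.max(truth.osi) == 0.0
    assert np.max(m.osi) < 1e-12
    assert m.tawss == pytest.approx(truth.tawss, rel=1e-9)
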