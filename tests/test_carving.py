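"""The SDF carving engine: primitives, ingestion, surfaces, overlays."""

import numpy as np
import pytest

from resectmap import (
    BinaryMask,
    CarveConfig,
    GridGeometry,
    ScalarVolume,
    TrackingLog,
    extract_surface,
    init_map,
    overlay_slice,
    time_colored_surface,
)
from resectmap.carving import export_mesh, load_map, load_time_colored_ply, save_map
from resectmap.tracking import concat_logs


def make_log(t, xyz):
    t = np.asarray(t, float)
    return TrackingLog(t, np.asarray(xyz, float), np.full(len(t), "sim", dtype=object).astype(str))


def dense_sdf_oracle(geom, primitives, config):
    """Brute-force clamped min-distance field over the whole grid.

    ``primitives`` is a list of ("sphere", p) / ("capsule", p0, p1) entries;
    the oracle evaluates every primitive densely at every voxel center and
    takes the pointwise min — no narrow band, no incremental updates.
    """
    X, Y, Z = geom.center_grid()
    X, Y, Z = (np.broadcast_to(a, geom.shape).astype(float) for a in (X, Y, Z))
    sdf = np.full(geom.shape, config.band_mm, dtype=float)
    for prim in primitives:
        if prim[0] == "sphere":
            p = prim[1]
            d = np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2)
        else:
            p0, p1 = prim[1], prim[2]
            v = p1 - p0
            dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
            tt = np.clip((dx * v[0] + dy * v[1] + dz * v[2]) / float(v @ v), 0.0, 1.0)
            d = np.sqrt((dx - tt * v[0]) ** 2 + (dy - tt * v[1]) ** 2 + (dz - tt * v[2]) ** 2)
        sdf = np.minimum(sdf, np.maximum(d - config.tool_radius_mm, -config.band_mm))
    return sdf


class TestInit:
    def test_box_grid_includes_both_faces(self, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        assert m.geometry.shape == (21, 21, 21)
        assert np.all(m.sdf == fine_config.band_mm)
        assert m.binarize().count == 0
        assert m.carved_volume_cm3() == 0.0

    def test_degenerate_box_rejected(self, fine_config):
        with pytest.raises(ValueError, match="degenerate"):
            init_map((0, 0, 0), (10, 0, 10), fine_config)

    @pytest.mark.parametrize("kwargs", [
        dict(tool_radius_mm=0),
        dict(band_mm=1.0, tool_radius_mm=1.5),
        dict(grid_spacing_mm=-0.5),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CarveConfig(**kwargs)


class TestCarvePrimitives:
    def test_sphere_center_and_zero_level(self, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        m.carve_sample((5.0, 5.0, 5.0), 1.0)  # on a voxel center
        r, tau = fine_config.tool_radius_mm, fine_config.band_mm
        assert m.sdf[10, 10, 10] == max(-tau, -r)
        assert m.sdf[10, 10, 13] == pytest.approx(0.0)  # exactly r=1.5 away
        assert m.first_carved_s[10, 10, 10] == 1.0

    def test_many_spheres_match_dense_oracle_bit_exact(self, rng, fine_config):
        m = init_map((0, 0, 0), (8, 8, 8), fine_config)
        prims = [("sphere", rng.uniform(0, 8, size=3)) for _ in range(50)]
        for i, (_, p) in enumerate(prims):
            m.carve_sample(p, float(i))
        assert np.array_equal(m.sdf, dense_sdf_oracle(m.geometry, prims, fine_config))

    def test_capsule_degenerate_equals_sphere(self, fine_config):
        a = init_map((0, 0, 0), (8, 8, 8), fine_config)
        b = init_map((0, 0, 0), (8, 8, 8), fine_config)
        p = np.array([3.3, 4.1, 2.7])
        a.carve_sample(p, 0.5)
        b.carve_capsule(p, p, 0.5)
        assert np.array_equal(a.sdf, b.sdf)
        assert np.array_equal(a.first_carved_s, b.first_carved_s, equal_nan=True)

    def test_capsule_midpoint_is_interior(self, fine_config):
        r = fine_config.tool_radius_mm
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        m.carve_capsule((5 - r, 5, 5), (5 + r, 5, 5), 0.0)  # endpoints 2r apart
        assert m.sdf[10, 10, 10] == pytest.approx(-r)

    def test_random_capsules_match_dense_oracle_bit_exact(self, rng, fine_config):
        m = init_map((0, 0, 0), (8, 8, 8), fine_config)
        prims = []
        for i in range(30):
            p0, p1 = rng.uniform(0, 8, size=3), rng.uniform(0, 8, size=3)
            prims.append(("capsule", p0, p1))
            m.carve_capsule(p0, p1, float(i))
        assert np.array_equal(m.sdf, dense_sdf_oracle(m.geometry, prims, fine_config))

    def test_far_outside_sample_is_noop(self, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        m.carve_sample((500.0, 0.0, 0.0), 0.0)
        assert np.all(m.sdf == fine_config.band_mm)


class TestIngest:
    def test_empty_log_is_noop(self, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        before = m.sdf.copy()
        m.ingest(make_log([], np.zeros((0, 3))))
        assert np.array_equal(m.sdf, before)

    def test_chronological_split_equals_batch(self, rng, fine_config):
        t = np.sort(rng.uniform(0, 10, size=120))
        xyz = np.cumsum(rng.normal(scale=0.4, size=(120, 3)), axis=0) + 5.0
        log = make_log(t, xyz)
        batch = init_map((0, 0, 0), (10, 10, 10), fine_config).ingest(log)
        chunked = init_map((0, 0, 0), (10, 10, 10), fine_config)
        for k in range(0, 120, 7):
            chunked.ingest(log[k:k + 7])
        assert np.array_equal(batch.sdf, chunked.sdf)
        assert np.array_equal(batch.first_carved_s, chunked.first_carved_s, equal_nan=True)

    def test_straight_pass_matches_analytic_capsule(self, fine_config):
        """A 20 Hz pass at 5 mm/s must carve the analytic capsule of the full
        path to within one voxel (symmetric Hausdorff distance on masks)."""
        from scipy.ndimage import distance_transform_edt

        speed, rate, L = 5.0, 20.0, 14.0
        n = int(L / speed * rate) + 1
        t = np.arange(n) / rate
        xyz = np.stack([3.0 + speed * t, np.full(n, 10.0), np.full(n, 10.0)], axis=1)
        m = init_map((0, 0, 0), (20, 20, 20), fine_config).ingest(make_log(t, xyz))
        carved = m.binarize().voxels

        X, Y, Z = (np.broadcast_to(a, m.geometry.shape) for a in m.geometry.center_grid())
        dx = np.clip(X - 3.0, None, 0) + np.clip(X - (3.0 + L), 0, None)
        d = np.sqrt(dx ** 2 + (Y - 10.0) ** 2 + (Z - 10.0) ** 2)
        truth = d < fine_config.tool_radius_mm

        h = fine_config.grid_spacing_mm
        voxel_diag = np.sqrt(3) * h
        if np.any(carved & ~truth):
            assert distance_transform_edt(~truth, sampling=m.geometry.spacing)[carved & ~truth].max() <= voxel_diag
        if np.any(truth & ~carved):
            assert distance_transform_edt(~carved, sampling=m.geometry.spacing)[truth & ~carved].max() <= voxel_diag

    def test_unordered_log_rejected(self, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        bad = TrackingLog(np.array([0.0, 1.0]), np.zeros((2, 3)), np.array(["a", "a"]))
        bad.t = np.array([1.0, 0.0])  # bypass constructor validation
        with pytest.raises(ValueError, match="non-decreasing"):
            m.ingest(bad)

    def test_gap_jump_carves_isolated_spheres_not_tunnels(self, fine_config):
        m = init_map((0, 0, 0), (30, 10, 10), fine_config)
        m.ingest(make_log([0.0, 10.0], [(4.0, 5.0, 5.0), (26.0, 5.0, 5.0)]))  # 10 s dropout
        mid = np.rint(m.geometry.world_to_index((15.0, 5.0, 5.0))).astype(int)
        assert m.sdf[tuple(mid)] == fine_config.band_mm  # no fictitious tunnel


class TestBinarizeAndVolume:
    def test_sphere_volume_close_to_analytic(self, fine_config):
        m = init_map((0, 0, 0), (12, 12, 12), fine_config)
        m.carve_sample((6.13, 5.87, 6.21), 0.0)  # generic off-lattice position
        r = fine_config.tool_radius_mm
        analytic = 4.0 / 3.0 * np.pi * r ** 3 / 1000.0
        assert m.carved_volume_cm3() == pytest.approx(analytic, rel=0.15)

    def test_carving_is_monotone(self, rng, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        prev = 0
        for _ in range(10):
            m.carve_sample(rng.uniform(2, 8, size=3), 0.0)
            count = m.binarize().count
            assert count >= prev
            prev = count

    def test_lipschitz_bound_on_random_pairs(self, rng, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        for i in range(15):
            m.carve_sample(rng.uniform(1, 9, size=3), float(i))
        tau = fine_config.band_mm
        inside = np.array(np.nonzero(np.abs(m.sdf) < tau)).T
        sel = inside[rng.integers(0, len(inside), size=2000)]
        a, b = sel[:1000], sel[1000:]
        pa = m.geometry.index_to_world(a.astype(float))
        pb = m.geometry.index_to_world(b.astype(float))
        lhs = np.abs(m.sdf[tuple(a.T)] - m.sdf[tuple(b.T)])
        assert np.all(lhs <= np.linalg.norm(pa - pb, axis=1) + 1e-6)


class TestSurface:
    def test_sphere_area_close_to_analytic(self, fine_config):
        m = init_map((0, 0, 0), (12, 12, 12), fine_config)
        m.carve_sample((6.13, 5.87, 6.21), 0.0)
        mesh = extract_surface(m)
        r = fine_config.tool_radius_mm
        assert mesh.area == pytest.approx(4 * np.pi * r ** 2, rel=0.10)

    def test_vertices_lie_on_zero_crossing(self, fine_config):
        from scipy.ndimage import map_coordinates

        m = init_map((0, 0, 0), (12, 12, 12), fine_config)
        m.carve_sample((6.13, 5.87, 6.21), 0.0)
        mesh = extract_surface(m)
        idx = m.geometry.world_to_index(mesh.vertices)
        vals = map_coordinates(m.sdf, idx.T, order=1)
        assert np.max(np.abs(vals)) <= fine_config.grid_spacing_mm / 2

    def test_two_spheres_two_components_and_time_attribution(self, fine_config):
        m = init_map((0, 0, 0), (24, 12, 12), fine_config)
        m.carve_sample((5.0, 6.0, 6.0), 1.0)
        m.carve_sample((19.0, 6.0, 6.0), 100.0)
        mesh = time_colored_surface(m)
        parts = mesh.split(only_watertight=False)
        assert len(parts) == 2
        times = mesh.vertex_attributes["time_s"]
        early = times[mesh.vertices[:, 0] < 12]
        late = times[mesh.vertices[:, 0] >= 12]
        assert late.mean() - early.mean() == pytest.approx(99.0, abs=1e-6)

    def test_single_sample_uniform_time(self, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        m.carve_sample((5.0, 5.0, 5.0), 7.25)
        mesh = time_colored_surface(m)
        assert np.all(mesh.vertex_attributes["time_s"] == 7.25)

    def test_empty_map_raises(self, fine_config):
        with pytest.raises(ValueError, match="[Nn]othing carved"):
            extract_surface(init_map((0, 0, 0), (10, 10, 10), fine_config))


class TestOverlay:
    @pytest.fixture
    def background(self, fine_config):
        m = init_map((0, 0, 0), (12, 12, 12), fine_config)
        rng = np.random.default_rng(7)
        return m, ScalarVolume(m.geometry, rng.random(m.geometry.shape))

    def test_empty_map_overlay_equals_background(self, background):
        m, bg = background
        img = overlay_slice(m, bg, axis=2, index=10)
        sl = bg.voxels[:, :, 10]
        lo, hi = np.percentile(sl, [1, 99])
        gray = np.repeat((np.clip((sl - lo) / (hi - lo), 0, 1)[..., None] * 255).astype(np.uint8), 3, axis=2)
        assert np.array_equal(img, gray)

    def test_flagged_pixels_are_exactly_mask_voxels(self, background):
        m, bg = background
        m.carve_sample((6.0, 6.0, 6.0), 0.0)
        k = 12
        img = overlay_slice(m, bg, axis=2, index=k)
        mask_sl = m.sdf[:, :, k] < 0
        sl = bg.voxels[:, :, k]
        lo, hi = np.percentile(sl, [1, 99])
        gray = np.repeat((np.clip((sl - lo) / (hi - lo), 0, 1)[..., None] * 255).astype(np.uint8), 3, axis=2)
        differs = np.any(img != gray, axis=2)
        assert np.array_equal(differs, mask_sl)

    def test_sphere_sections_have_consistent_radii(self, background, fine_config):
        m, bg = background
        c = (6.0, 6.0, 6.0)
        m.carve_sample(c, 0.0)
        h = fine_config.grid_spacing_mm
        widths = []
        for axis in range(3):
            img = overlay_slice(m, bg, axis=axis, index=12)
            flagged = np.any(img != overlay_slice(init_map((0, 0, 0), (12, 12, 12), fine_config), bg, axis=axis, index=12), axis=2)
            rows = np.nonzero(flagged.any(axis=1))[0]
            widths.append((rows.max() - rows.min() + 1))
        assert max(widths) - min(widths) <= 2  # +/- 1 voxel across axes

    def test_out_of_range_rejected(self, background):
        m, bg = background
        with pytest.raises(ValueError):
            overlay_slice(m, bg, axis=3, index=0)
        with pytest.raises(ValueError):
            overlay_slice(m, bg, axis=0, index=999)


class TestCheckpoint:
    def test_roundtrip_preserves_sdf_and_timestamps(self, rng, tmp_path, fine_config):
        m = init_map((0, 0, 0), (10, 10, 10), fine_config)
        for i in range(5):
            m.carve_sample(rng.uniform(2, 8, size=3), float(i))
        save_map(m, tmp_path / "sdf.nrrd", tmp_path / "fc.nrrd")
        back = load_map(tmp_path / "sdf.nrrd", tmp_path / "fc.nrrd", fine_config)
        assert np.array_equal(back.sdf, m.sdf)
        assert np.array_equal(back.first_carved_s, m.first_carved_s, equal_nan=True)
        assert back.geometry.same_lattice(m.geometry)


def test_ply_export_preserves_time_scalars(tmp_path, fine_config):
    m = init_map((0, 0, 0), (10, 10, 10), fine_config)
    m.carve_sample((5.0, 5.0, 5.0), 3.5)
    mesh = time_colored_surface(m)
    export_mesh(mesh, tmp_path / "cav.ply")
    back = load_time_colored_ply(tmp_path / "cav.ply")
    assert np.array_equal(np.asarray(back.vertices, dtype=np.float32),
                          np.asarray(mesh.vertices, dtype=np.float32))
    assert np.array_equal(back.faces, mesh.faces)
    assert np.array_equal(back.vertex_attributes["time_s"], mesh.vertex_attributes["time_s"])


class TestAutoRoi:
    def test_margin_respected_and_clipped_to_brain(self, fine_config):
        from resectmap import auto_roi

        g = GridGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(40, 40, 40))
        tumor_vox = np.zeros(g.shape, dtype=bool)
        tumor_vox[15:25, 15:25, 15:25] = True
        tumor = BinaryMask(g, tumor_vox)
        lo, hi = auto_roi(tumor, margin_mm=10.0)
        assert np.allclose(lo, (5, 5, 5)) and np.allclose(hi, (34, 34, 34))

        brain_vox = np.zeros(g.shape, dtype=bool)
        brain_vox[10:32, 10:32, 10:32] = True
        lo_c, hi_c = auto_roi(tumor, margin_mm=10.0, clip_to=BinaryMask(g, brain_vox))
        assert np.allclose(lo_c, (10, 10, 10)) and np.allclose(hi_c, (31, 31, 31))

    def test_empty_tumor_rejected(self, unit_grid):
        from resectmap import auto_roi

        with pytest.raises(ValueError, match="empty"):
            auto_roi(BinaryMask(unit_grid, np.zeros(unit_grid.shape, dtype=bool)))


def test_overlay_png_roundtrip(tmp_path, fine_config):
    import imageio.v3 as iio

    from resectmap.carving import save_overlay_png

    m = init_map((0, 0, 0), (10, 10, 10), fine_config)
    m.carve_sample((5.0, 5.0, 5.0), 0.0)
    bg = ScalarVolume(m.geometry, np.random.default_rng(1).random(m.geometry.shape))
    rgb = overlay_slice(m, bg, axis=2, index=10)
    save_overlay_png(tmp_path / "o.png", rgb)
    assert np.array_equal(iio.imread(tmp_path / "o.png"), rgb)
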