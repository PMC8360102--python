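"""TPS interpolation, bending-energy sliding, mirroring, template completion."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from palasym import (
    LandmarkConfiguration,
    bending_energy_matrix,
    complete_template_by_mirroring,
    mirror_configuration,
    slide_semilandmarks,
    tps_fit,
)
from palasym.io import GeometryBundle
from palasym.semilandmarks import (
    TpsError,
    closest_point_on_mesh,
    midsagittal_frame,
    project_to_polyline,
    to_midsagittal_frame,
)


class TestTps:
    def test_identity_map_zero_energy(self, rng):
        ref = rng.normal(size=(15, 3))
        f = tps_fit(ref, ref)
        assert f.bending_energy == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f(ref) - ref).max() < 1e-10

    def test_affine_target_zero_energy(self, rng):
        ref = rng.normal(size=(20, 3))
        A = rng.normal(size=(3, 3))
        t = rng.normal(size=3)
        f = tps_fit(ref, ref @ A + t)
        assert f.bending_energy < 1e-10

    def test_exact_interpolation_and_energy_quadratic_form(self, rng):
        ref = rng.normal(size=(25, 3))
        target = ref + 0.05 * rng.normal(size=(25, 3))
        f = tps_fit(ref, target)
        assert np.abs(f(ref) - target).max() < 1e-8
        B = bending_energy_matrix(ref)
        assert f.bending_energy == pytest.approx(
            float(np.trace(target.T @ B @ target)), abs=1e-9
        )

    def test_duplicate_reference_raises(self, rng):
        ref = rng.normal(size=(10, 3))
        ref[4] = ref[7]
        with pytest.raises(TpsError, match="duplicate"):
            tps_fit(ref, ref)

    def test_coplanar_reference_raises(self, rng):
        ref = rng.normal(size=(10, 3))
        ref[:, 2] = 0.0
        with pytest.raises(TpsError, match="coplanar"):
            tps_fit(ref, ref)


class TestBendingEnergyMatrix:
    def test_symmetric_psd_with_affine_null_space(self, rng):
        ref = rng.normal(size=(30, 3))
        B = bending_energy_matrix(ref)
        assert np.abs(B - B.T).max() < 1e-12
        w = np.linalg.eigvalsh(B)
        assert w.min() > -1e-10
        assert int((np.abs(w) < 1e-10 * max(w.max(), 1)).sum()) == 4
        P = np.hstack([np.ones((30, 1)), ref])
        assert np.abs(B @ P).max() < 1e-10

    def test_energy_invariant_to_affine_maps_of_target(self, rng):
        ref = rng.normal(size=(20, 3))
        Y = ref + 0.1 * rng.normal(size=(20, 3))
        B = bending_energy_matrix(ref)
        e0 = float(np.trace(Y.T @ B @ Y))
        R = special_ortho_group.rvs(3, random_state=rng)
        Y2 = Y @ R + rng.normal(size=3)
        assert float(np.trace(Y2.T @ B @ Y2)) == pytest.approx(e0, rel=1e-9)


class TestSliding:
    def _perturbed(self, schema, palate, rng, scale=1.0):
        geo, tpl = palate
        cur = tpl.copy()
        for cid in ("curve_left", "curve_right", "curve_middle"):
            for lid in schema.curve(cid).semilandmark_ids:
                r = schema.index_of(lid)
                cur[r] = project_to_polyline(
                    cur[r] + scale * rng.normal(0, 1.0, 3), geo.curves[cid]
                )[0]
        surf = [schema.index_of(p.id) for p in schema.points if p.role == "surface"]
        cur[surf], _, _ = closest_point_on_mesh(
            cur[surf] + scale * rng.normal(0, 1.0, (len(surf), 3)), geo.vertices, geo.faces
        )
        return cur

    def test_energy_trace_non_increasing_and_fixed_points_immobile(
        self, schema, palate, rng
    ):
        geo, tpl = palate
        cur = self._perturbed(schema, palate, rng)
        res = slide_semilandmarks(cur, tpl, schema, geo, max_iter=8)
        tr = np.array(res.bending_energy_trace)
        assert np.all(np.diff(tr) <= 1e-12)
        fixed = [schema.index_of(p.id) for p in schema.points if p.role == "fixed"]
        assert np.abs(res.positions[fixed] - cur[fixed]).max() == 0.0

    def test_slid_points_stay_on_geometry(self, schema, palate, rng):
        geo, tpl = palate
        cur = self._perturbed(schema, palate, rng)
        res = slide_semilandmarks(cur, tpl, schema, geo, max_iter=8)
        for cid in ("curve_left", "curve_right", "curve_middle"):
            rows = [schema.index_of(i) for i in schema.curve(cid).semilandmark_ids]
            proj = project_to_polyline(res.positions[rows], geo.curves[cid])
            assert np.abs(proj - res.positions[rows]).max() < 1e-6 * geo.diameter()
        surf = [schema.index_of(p.id) for p in schema.points if p.role == "surface"]
        _, dist, _ = closest_point_on_mesh(res.positions[surf], geo.vertices, geo.faces)
        assert dist.max() < 1e-6 * geo.diameter()

    def test_already_minimal_configuration_does_not_move(self, schema, palate):
        geo, tpl = palate
        res = slide_semilandmarks(tpl, tpl, schema, geo, max_iter=5)
        assert np.abs(res.positions - tpl).max() < 1e-8

    def test_straight_line_curve_relaxes_to_equal_spacing(self, schema, palate):
        """Closed-form oracle: on a straight median curve with an equally
        spaced reference, the bending-energy minimum restores equal spacing."""
        geo, tpl = palate
        ref = tpl.copy()
        i4, i5 = schema.index_of(4), schema.index_of(5)
        A, Bp = ref[i4], ref[i5]
        line = np.linspace(A, Bp, 200)
        mid_rows = [schema.index_of(i) for i in schema.curve("curve_middle").semilandmark_ids]
        for k, r in enumerate(mid_rows):
            ref[r] = A + (0.2 * (k + 1)) * (Bp - A)
        geo2 = GeometryBundle(
            vertices=geo.vertices, faces=geo.faces,
            curves={**geo.curves, "curve_middle": line},
        )
        cur = ref.copy()
        uneven = [0.05, 0.35, 0.5, 0.93]
        for t, r in zip(uneven, mid_rows):
            cur[r] = A + t * (Bp - A)
        res = slide_semilandmarks(cur, ref, schema, geo2, max_iter=20, tol=1e-14)
        expected = np.array([A + (0.2 * (k + 1)) * (Bp - A) for k in range(4)])
        assert np.abs(res.positions[mid_rows] - expected).max() < 1e-6


class TestMirroring:
    def test_mirror_twice_is_identity(self, schema, rng):
        cfg = LandmarkConfiguration("a", rng.normal(size=(41, 3)))
        twice = mirror_configuration(mirror_configuration(cfg, schema), schema)
        np.testing.assert_array_equal(twice.coordinates, cfg.coordinates)
        assert not twice.is_reflected_copy

    def test_symmetric_configuration_is_fixed_point(self, schema, palate):
        _, tpl = palate
        cfg = LandmarkConfiguration("t", tpl)
        mirrored = mirror_configuration(cfg, schema)
        assert np.abs(mirrored.coordinates - tpl).max() < 1e-12

    def test_displacement_maps_to_the_paired_landmark(self, schema, palate):
        _, tpl = palate
        eps = 1e-3
        coords = tpl.copy()
        coords[schema.index_of(2), 2] += eps  # push Ento-left up
        cfg = LandmarkConfiguration("a", coords)
        mirrored = mirror_configuration(cfg, schema)
        delta = mirrored.coordinates - tpl
        assert delta[schema.index_of(3), 2] == pytest.approx(eps, abs=1e-12)
        assert np.abs(np.delete(delta, schema.index_of(3), axis=0)).max() < 1e-12

    def test_midsagittal_frame_recovery(self, schema, palate, rng):
        _, tpl = palate
        R = special_ortho_group.rvs(3, random_state=rng)
        moved = tpl @ R + rng.uniform(-10, 10, 3)
        back = to_midsagittal_frame(moved, schema)
        assert np.abs(back[schema.midline_mask][:, 0]).max() < 1e-8


class TestTemplateCompletion:
    def _left_rows(self, schema):
        return [
            schema.index_of(p.id)
            for p in schema.points
            if p.role == "surface" and p.side == "left"
        ]

    def test_symmetric_dome_completion_is_exact(self, schema, palate):
        geo, tpl = palate
        half = tpl.copy()
        left = self._left_rows(schema)
        half[left] = np.nan
        full = complete_template_by_mirroring(half, schema, geo)
        assert np.abs(full - tpl).max() < 1e-8
        assert full.shape == (41, 3)

    def test_asymmetric_dome_points_land_on_the_surface(self, schema, palate):
        geo, tpl = palate
        # shear the dome: left half is no longer the mirror of the right
        verts = geo.vertices.copy()
        verts[:, 2] += 0.04 * verts[:, 0]
        warped = GeometryBundle(vertices=verts, faces=geo.faces, curves=geo.curves)
        half = tpl.copy()
        left = self._left_rows(schema)
        half[left] = np.nan
        full = complete_template_by_mirroring(half, schema, warped)
        _, dist, _ = closest_point_on_mesh(full[left], warped.vertices, warped.faces)
        assert dist.max() < 1e-6 * warped.diameter()
        # and they are NOT at the naive mirror positions
        naive = tpl[[schema.index_of(schema.pair(schema.ids[r])) for r in left]].copy()
        naive[:, 0] *= -1
        assert np.abs(full[left] - naive).max() > 0.05


class TestMeshProjection:
    def test_projection_beats_dense_surface_sampling(self, palate, rng):
        geo, _ = palate
        pts = rng.uniform(-30, 30, (4, 3))
        _, dist, _ = closest_point_on_mesh(pts, geo.vertices, geo.faces)
        A = geo.vertices[geo.faces[:, 0]]
        Bv = geo.vertices[geo.faces[:, 1]]
        C = geo.vertices[geo.faces[:, 2]]
        for i, p in enumerate(pts):
            for u in np.linspace(0, 1, 12):
                for v in np.linspace(0, 1 - u, 12):
                    q = A * (1 - u - v) + Bv * u + C * v
                    sampled = np.sqrt(((q - p) ** 2).sum(axis=1)).min()
                    assert dist[i] <= sampled + 1e-9
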