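import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfdiff.geometry import (
    MeshError,
    PropagationError,
    SurfacePosition,
    build_mesh,
    from_world,
    propagate,
    to_world,
)


class TestBuildMesh:
    def test_square_adjacency(self, square_mesh):
        # two coplanar triangles sharing the diagonal: one shared edge, four walls
        shared = (square_mesh.neighbor_panel >= 0).sum()
        assert shared == 2  # symmetric: recorded once per owner
        assert (square_mesh.neighbor_panel == -1).sum() == 4
        assert square_mesh.surface_area["fast"] == pytest.approx(0.5)
        assert square_mesh.surface_area["slow"] == pytest.approx(0.5)

    def test_adjacency_is_symmetric(self, square_mesh):
        m = square_mesh
        for p in range(m.n_panels):
            for e in range(3):
                q = m.neighbor_panel[p, e]
                if q >= 0:
                    f = m.neighbor_edge[p, e]
                    assert m.neighbor_panel[q, f] == p
                    assert m.neighbor_edge[q, f] == e

    def test_single_triangle_all_boundary(self):
        m = build_mesh([[(0, 0, 0), (1, 0, 0), (0, 1, 0)]], ["s"])
        assert (m.neighbor_panel == -1).all()

    def test_duplicate_triangle_rejected(self):
        tri = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        with pytest.raises(MeshError, match="shared by"):
            build_mesh([tri, tri, tri], ["s", "s", "s"])

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(MeshError, match="degenerate"):
            build_mesh([[(0, 0, 0), (1, 1, 1), (2, 2, 2)]], ["s"])


class TestWorldMapping:
    def test_origin_is_first_vertex(self, roof_mesh):
        p = to_world(SurfacePosition(0, (0.0, 0.0)), roof_mesh)
        np.testing.assert_allclose(p, roof_mesh.panels[0].vertices[0])

    def test_centroid_matches_vertex_mean(self, roof_mesh):
        panel = roof_mesh.panels[1]
        cen = panel.local.mean(axis=0)
        p = to_world(SurfacePosition(1, tuple(cen)), roof_mesh)
        np.testing.assert_allclose(p, panel.vertices.mean(axis=0), atol=1e-12)

    def test_round_trip_identity(self, roof_mesh, rng):
        # 1000 random in-panel points survive to_world ∘ from_world within 1e-9
        for _ in range(1000):
            r1, r2 = rng.random(2)
            if r1 + r2 > 1:
                r1, r2 = 1 - r1, 1 - r2
            a, b, c = roof_mesh.local[0]
            xy = a + r1 * (b - a) + r2 * (c - a)
            w = to_world(SurfacePosition(0, tuple(xy)), roof_mesh)
            back = from_world(w, 0, roof_mesh)
            np.testing.assert_allclose(back.xy, xy, atol=1e-9)

    def test_unknown_panel_rejected(self, roof_mesh):
        with pytest.raises(KeyError):
            to_world(SurfacePosition(99, (0.0, 0.0)), roof_mesh)


class TestPropagate:
    def test_step_inside_panel(self, square_mesh):
        pos, crossings = propagate(
            SurfacePosition(0, (0.5, 0.1)), (0.1, 0.05), square_mesh
        )
        assert pos.panel == 0
        assert pos.xy == (0.6, 0.15000000000000002)
        assert crossings == []

    def test_coplanar_crossing_equals_flat_motion(self, square_mesh, rng):
        # the square is flat, so crossing the diagonal must reproduce straight
        # planar motion exactly
        for _ in range(200):
            start = SurfacePosition(0, (0.6 + 0.2 * rng.random(), 0.05))
            d = rng.normal(0, 0.15, 2)
            w0 = to_world(start, square_mesh)
            target = w0 + d[0] * square_mesh.e1[0] + d[1] * square_mesh.e2[0]
            inside = 0 <= target[0] <= 1 and 0 <= target[1] <= 1
            if not inside:
                continue
            end, _ = propagate(start, d, square_mesh)
            np.testing.assert_allclose(
                to_world(end, square_mesh), target, atol=1e-12
            )

    def test_specular_reflection_returns_to_start(self, square_mesh):
        # perpendicular distance d to a wall, step 2d straight at it
        start = SurfacePosition(0, (0.5, 0.3))  # edge y=0 is a boundary wall
        end, crossings = propagate(start, (0.0, -0.6), square_mesh)
        assert end.panel == 0
        np.testing.assert_allclose(end.xy, start.xy, atol=1e-12)
        assert crossings == []

    def test_double_reflection_reproduces_unreflected_endpoint(self, square_mesh):
        # reflecting twice off the same wall equals not reflecting at all
        start = SurfacePosition(0, (0.5, 0.2))
        d = np.array([0.05, -0.1])
        end, _ = propagate(start, d, square_mesh)
        mirrored = np.array([start.xy[0] + d[0], -(start.xy[1] + d[1])])
        np.testing.assert_allclose(np.abs(end.xy[1]), np.abs(mirrored[1]), atol=1e-12)

    def test_crossing_records_panels_entered(self, square_mesh):
        _, crossings = propagate(
            SurfacePosition(0, (0.5, 0.2)), (0.0, 0.6), square_mesh
        )
        assert crossings == [(1, "slow")]

    def test_confinement_blocks_crossing(self, square_mesh):
        end, crossings = propagate(
            SurfacePosition(0, (0.5, 0.2)), (0.0, 0.6), square_mesh,
            allow_cross=False,
        )
        assert end.panel == 0
        assert crossings == []

    def test_max_crossings_guard(self, square_mesh):
        with pytest.raises(PropagationError):
            propagate(
                SurfacePosition(0, (0.5, 0.1)), (500.0, 0.1), square_mesh,
                max_crossings=10,
            )

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.floats(0.05, 0.95),
        y=st.floats(0.01, 0.6),
        dx=st.floats(-2.0, 2.0),
        dy=st.floats(-2.0, 2.0),
    )
    def test_billiard_oracle_on_flat_square(self, square_mesh, x, y, dx, dy):
        """On a flat square, crossing + wall reflections equal billiard folding.

        The exact endpoint of straight motion with specular walls on [0,1]² is
        the triangle-wave fold of start + d — an independent closed form.
        """
        if y >= x:  # keep the start strictly inside the 'fast' triangle
            return
        end, _ = propagate(SurfacePosition(0, (x, y)), (dx, dy), square_mesh)
        world = to_world(end, square_mesh)
        expected = _billiard_fold(np.array([x + dx, y + dy]))
        np.testing.assert_allclose(world[:2], expected, atol=1e-9)
        assert abs(world[2]) < 1e-12

    def test_single_fold_matches_rotation_oracle(self, roof_mesh, rng):
        """Crossing the roof ridge equals rotating the straight continuation
        about the shared edge by the dihedral angle (scipy Rotation oracle)."""
        from scipy.spatial.transform import Rotation

        m = roof_mesh
        # shared edge of panel 0 is edge 2 (from (1,1,1) back to (0,0,0))
        e = int(np.flatnonzero(m.neighbor_panel[0] >= 0)[0])
        axis_pts = m.vertices3[0, [e, (e + 1) % 3]]
        axis = axis_pts[1] - axis_pts[0]
        axis /= np.linalg.norm(axis)
        n0, n1 = m.normal[0], m.normal[int(m.neighbor_panel[0, e])]
        angle = np.arctan2(np.dot(np.cross(n0, n1), axis), np.dot(n0, n1))
        rot = Rotation.from_rotvec(axis * angle)
        checked = 0
        while checked < 200:
            xy = np.array([0.3 + 0.4 * rng.random(), 0.02 + 0.1 * rng.random()])
            d = rng.normal(0, 0.25, 2)
            end, crossings = propagate(SurfacePosition(0, tuple(xy)), d, m)
            if [c[0] for c in crossings] != [1]:
                continue  # want exactly one ridge crossing, no reflections
            flat = (
                m.origin[0]
                + (xy[0] + d[0]) * m.e1[0]
                + (xy[1] + d[1]) * m.e2[0]
            )
            expected = rot.apply(flat - axis_pts[0]) + axis_pts[0]
            loc = from_world(expected, 1, m)
            if not m.contains_local(1, np.array(loc.xy), tol=-1e-9):
                continue  # endpoint outside panel 1: a wall reflection occurred
            np.testing.assert_allclose(to_world(end, m), expected, atol=1e-9)
            checked += 1


def _billiard_fold(p: np.ndarray) -> np.ndarray:
    """Fold a point into [0,1]² by repeated specular reflection (exact)."""
    q = np.mod(p, 2.0)
    return np.where(q > 1.0, 2.0 - q, q)
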