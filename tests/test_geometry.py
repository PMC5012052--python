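import numpy as np
import pytest

from osic.geometry import (CollinearSafetyPointWarning, CorridorShape,
                           DegenerateShapeError, ImplantAxis, SafetyMargins,
                           TangentUndefinedError, UndefinedDirectionError,
                           ZeroLengthImplantError, centered_axis,
                           corridor_width, direction_from_angles,
                           load_site_catalog, projected_angles, safety_angle,
                           safety_angles, simulate_optimal_implant)

from conftest import random_rigid_transform
from oracles import planar_width_oracle, projection_angle_oracle, tangent_angle_oracle


class TestProjectedAngles:
    def test_pure_craniocaudal_direction_has_zero_angles(self):
        pa = projected_angles((1, 0, 0))
        assert pa.sagittal == 0.0 and pa.dorsal == 0.0

    @pytest.mark.parametrize("v,name,expect", [
        ((1, 0, 1), "sagittal", 45.0),
        ((1, 1, 0), "dorsal", 45.0),
        ((0, 1, 1), "transverse", 45.0),
        ((1, 0, -1), "sagittal", -45.0),
    ])
    def test_symmetry_examples(self, v, name, expect):
        assert getattr(projected_angles(v), name) == pytest.approx(expect)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedDirectionError):
            projected_angles((0, 0, 0))

    def test_indeterminate_projection_flagged(self):
        pa = projected_angles((0, 0, 1))   # no in-plane magnitude dorsally
        assert "dorsal" in pa.indeterminate

    def test_agrees_with_projection_oracle(self, rng):
        """All three angles equal a brute-force plane-projection oracle."""
        for _ in range(1000):
            v = rng.uniform(-10, 10, size=3)
            if min(abs(v)) < 1e-3:
                continue
            pa = projected_angles(v)
            for plane in ("sagittal", "dorsal", "transverse"):
                assert getattr(pa, plane) == pytest.approx(
                    projection_angle_oracle(v, plane), abs=1e-6)

    def test_round_trip_from_prescribed_angles(self, rng):
        """Directions built from prescribed ProjA recover them to 1e-9 deg."""
        for _ in range(500):
            sag, dors = rng.uniform(-89, 89, size=2)
            pa = projected_angles(direction_from_angles(sag, dors))
            assert pa.sagittal == pytest.approx(sag, abs=1e-9)
            assert pa.dorsal == pytest.approx(dors, abs=1e-9)

    def test_reported_pair_follows_catalog(self):
        catalog = load_site_catalog()
        pa = projected_angles((1, 0.3, 0.2), catalog["c1_ventral_arch"])
        assert len(pa.reported_pair) == 1
        pa = projected_angles((1, 0.3, 0.2), catalog["0"])
        assert len(pa.reported_pair) == 2


class TestSafetyAngle:
    def test_zero_radius_reduces_to_planar_angle(self):
        assert safety_angle((0, 0, 0), (0, 0, 10), (0, 5, 5), 0) == pytest.approx(45)

    def test_finite_radius_example(self):
        got = safety_angle((0, 0, 0), (0, 0, 10), (0, 5, 5), 0.75)
        assert got == pytest.approx(45 - np.degrees(np.arcsin(0.75 / np.sqrt(50))),
                                    abs=1e-9)
        assert got == pytest.approx(38.91, abs=0.005)

    def test_degenerate_tangent_rejected(self):
        with pytest.raises(TangentUndefinedError):
            safety_angle((0, 0, 0), (0, 0, 10), (0, 5, 5), np.sqrt(50))

    def test_collinear_safety_point_warns_and_is_negative(self):
        with pytest.warns(CollinearSafetyPointWarning):
            got = safety_angle((0, 0, 0), (0, 0, 10), (0, 0, 5), 1.0)
        assert got == pytest.approx(-np.degrees(np.arcsin(1 / 5)))

    def test_agrees_with_tangent_construction_oracle(self, rng):
        """SafA equals the sampled rotating-ray tangency construction."""
        for _ in range(1000):
            I = rng.uniform(-20, 20, size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            E = I + rng.uniform(5, 20) * d
            S = I + rng.uniform(3, 15) * _random_offaxis_dir(rng, d)
            r = rng.uniform(0, 0.8 * np.linalg.norm(S - I))
            assert safety_angle(I, E, S, r) == pytest.approx(
                tangent_angle_oracle(I, E, S, r), abs=1e-6)

    def test_monotonically_decreasing_in_radius(self, rng):
        I, E, S = (0, 0, 0), (0, 0, 10), (1, 5, 5)
        radii = np.linspace(0, 4, 30)
        vals = [safety_angle(I, E, S, r) for r in radii]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_rigid_invariance(self, rng):
        I, E, S, r = np.zeros(3), np.array([0, 0, 10.0]), np.array([1, 5, 5.0]), 0.75
        ref = safety_angle(I, E, S, r)
        for _ in range(25):
            R, t = random_rigid_transform(rng)
            assert safety_angle(R @ I + t, R @ E + t, R @ S + t, r) == \
                pytest.approx(ref, abs=1e-7)


def _random_offaxis_dir(rng, axis):
    while True:
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        if abs(np.dot(w, axis)) < 0.95:
            return w


class TestCorridorWidth:
    def test_symmetric_flanking_points(self):
        implant = ImplantAxis((0, 0, 0), (0, 0, 10))
        assert corridor_width(implant, ((0, 5, 5), (0, -5, 5))) == pytest.approx(10)

    def test_same_side_pair_flagged_nonpositive(self):
        implant = ImplantAxis((0, 0, 0), (0, 0, 10))
        assert corridor_width(implant, ((0, 5, 5), (0, 3, 5))) <= 0

    def test_agrees_with_planar_oracle(self, rng):
        """Random in-plane configurations match the 2D geometry oracle."""
        for _ in range(1000):
            I = rng.uniform(-20, 20, size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            E = I + rng.uniform(5, 20) * d
            n = _random_offaxis_dir(rng, d)
            n -= np.dot(n, d) * d
            n /= np.linalg.norm(n)
            ta, tb = rng.uniform(0, 1, size=2) * np.linalg.norm(E - I)
            sa, sb = rng.uniform(-6, 6, size=2)
            Sa, Sb = I + ta * d + sa * n, I + tb * d + sb * n
            if min(abs(sa), abs(sb)) < 1e-6:
                continue
            implant = ImplantAxis(I, E)
            assert corridor_width(implant, (Sa, Sb)) == pytest.approx(
                planar_width_oracle(I, E, Sa, Sb), abs=1e-6)

    def test_rigid_invariance(self, rng):
        I, E = np.zeros(3), np.array([0, 0, 10.0])
        Sa, Sb = np.array([2, 3, 5.0]), np.array([-1, -4, 6.0])
        ref = corridor_width(ImplantAxis(I, E), (Sa, Sb))
        for _ in range(25):
            R, t = random_rigid_transform(rng)
            got = corridor_width(ImplantAxis(R @ I + t, R @ E + t),
                                 (R @ Sa + t, R @ Sb + t))
            assert got == pytest.approx(ref, abs=1e-7)


class TestSafetyAngles:
    def test_symmetric_margins_give_equal_angles(self):
        implant = ImplantAxis((0, 0, 0), (0, 0, 10))
        m = SafetyMargins(S1=(5, 0, 5), S2=(-5, 0, 5), S3=(0, 5, 5),
                          S4=(0, -5, 5), implant_radius_r=0.0)
        sa = safety_angles(implant, m)
        assert len(set(round(v, 9) for v in sa.values)) == 1
        assert sa.implant_length == pytest.approx(10)
        assert sa.width_plane1 == pytest.approx(10)
        assert sa.width_plane2 == pytest.approx(10)

    def test_matches_tangent_oracle_at_validation_scale(self):
        """Mid-axis margins with the 1.5 mm implant match the oracle to 1e-6."""
        I, E = np.array([3, 2, 1.0]), np.array([8, 9, 7.0])
        u = (E - I) / np.linalg.norm(E - I)
        n1 = np.cross(u, [0, 0, 1.0])
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(u, n1)
        mid = I + 0.5 * (E - I)
        m = SafetyMargins(S1=mid + 2.1 * n1 + 0.8 * u, S2=mid - 3.4 * n1,
                          S3=mid + 2.8 * n2, S4=mid - 1.9 * n2 - 1.2 * u,
                          implant_radius_r=0.75)
        sa = safety_angles(ImplantAxis(I, E), m)
        for got, S in zip(sa.values, m.points):
            assert got == pytest.approx(tangent_angle_oracle(I, E, S, 0.75),
                                        abs=1e-6)

    def test_rigid_invariance(self, rng):
        I, E = np.zeros(3), np.array([0, 0, 10.0])
        m0 = SafetyMargins(S1=(5, 0, 5), S2=(-4, 0, 6), S3=(0, 5, 4),
                           S4=(0, -6, 5), implant_radius_r=0.75)
        ref = safety_angles(ImplantAxis(I, E), m0)
        for _ in range(10):
            R, t = random_rigid_transform(rng)
            m1 = SafetyMargins(*[R @ np.asarray(S, float) + t for S in m0.points],
                               implant_radius_r=0.75)
            got = safety_angles(ImplantAxis(R @ I + t, R @ E + t), m1)
            np.testing.assert_allclose(got.values, ref.values, atol=1e-7)
            np.testing.assert_allclose(
                (got.width_plane1, got.width_plane2, got.implant_length),
                (ref.width_plane1, ref.width_plane2, ref.implant_length),
                atol=1e-7)

    def test_negative_angle_flagged(self):
        implant = ImplantAxis((0, 0, 0), (0, 0, 10))
        m = SafetyMargins(S1=(0, 0.5, 5), S2=(0, -5, 5), S3=(5, 0, 5),
                          S4=(-5, 0, 5), implant_radius_r=0.75)
        sa = safety_angles(implant, m)
        assert sa.saf_a1 < 0 and "saf_a1" in sa.negative_flags


class TestCenteredAxis:
    def test_square_base_pyramid(self):
        shape = CorridorShape("pyramid", {
            "apex": [(0, 0, 10)],
            "base": [(1, 1, 0), (1, -1, 0), (-1, -1, 0), (-1, 1, 0)]})
        p, d = centered_axis(shape)
        np.testing.assert_allclose(p, [0, 0, 10])
        np.testing.assert_allclose(d, [0, 0, -1], atol=1e-12)

    def test_prism_joins_face_centroids(self):
        shape = CorridorShape("prism", {
            "face1": [(0, 0, 0), (2, 0, 0), (1, 2, 0)],
            "face2": [(0, 0, 5), (2, 0, 5), (1, 2, 5)]})
        p, d = centered_axis(shape)
        np.testing.assert_allclose(p, [1, 2 / 3, 0])
        np.testing.assert_allclose(d, [0, 0, 1], atol=1e-12)

    def test_hemi_ellipsoid_principal_axis(self, rng):
        """Surface samples of a hemi-ellipsoid recover its long axis."""
        a, b, c = 8.0, 3.0, 2.0   # long axis along x
        th = rng.uniform(0, np.pi, 60)
        ph = rng.uniform(0, np.pi, 60)   # half: x >= 0 dome
        pts = np.column_stack([a * np.abs(np.sin(ph) * np.cos(th)),
                               b * np.sin(ph) * np.sin(th),
                               c * np.cos(ph)])
        shape = CorridorShape("hemi_ellipsoid", {
            "surface": pts, "base": [(0, b, 0), (0, -b, 0), (0, 0, c), (0, 0, -c)]})
        p, d = centered_axis(shape)
        np.testing.assert_allclose(p, [0, 0, 0], atol=1e-9)
        assert abs(d[0]) > 0.999   # aligned with the long axis
        assert d[0] > 0            # oriented base -> dome

    def test_axis_transforms_rigidly(self, rng):
        shape0 = CorridorShape("pyramid", {
            "apex": [(0, 0, 10)],
            "base": [(1, 1, 0), (1, -1, 0), (-1, -1, 0), (-1, 1, 0)]})
        p0, d0 = centered_axis(shape0)
        for _ in range(10):
            R, t = random_rigid_transform(rng)
            shape1 = CorridorShape("pyramid", {
                "apex": [R @ (0, 0, 10) + t],
                "base": [R @ np.array(v, float) + t
                         for v in [(1, 1, 0), (1, -1, 0), (-1, -1, 0), (-1, 1, 0)]]})
            p1, d1 = centered_axis(shape1)
            np.testing.assert_allclose(p1, R @ p0 + t, atol=1e-9)
            np.testing.assert_allclose(d1, R @ d0, atol=1e-9)

    @pytest.mark.parametrize("kind,pts", [
        ("pyramid", {"apex": [(0, 0, 0)], "base": [(0, 0, 0)] * 3}),
        ("prism", {"face1": [(0, 0, 0), (1, 0, 0), (0, 1, 0)],
                   "face2": [(0, 0, 0), (1, 0, 0), (0, 1, 0)]}),
    ])
    def test_degenerate_shapes_rejected(self, kind, pts):
        with pytest.raises(DegenerateShapeError):
            centered_axis(CorridorShape(kind, pts))


class TestSimulateOptimalImplant:
    def test_nearest_point_projection(self):
        axis = ((0, 0, 0), (0, 0, 1))
        implant = simulate_optimal_implant(axis, [(0.1, 0, 0)], [(0, 0.1, 10)])
        np.testing.assert_allclose(implant.insertion_I, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(implant.exit_E, [0, 0, 10], atol=1e-12)

    def test_length_matches_projection_oracle(self, rng):
        for _ in range(200):
            p0 = rng.uniform(-10, 10, 3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            near = p0 + rng.uniform(-5, 0) * u + 0.3 * _random_offaxis_dir(rng, u)
            far = p0 + rng.uniform(2, 15) * u + 0.3 * _random_offaxis_dir(rng, u)
            implant = simulate_optimal_implant((p0, u), [near], [far])
            # brute-force: project both boundary points onto the axis
            expect = abs(np.dot(far - p0, u) - np.dot(near - p0, u))
            assert implant.length == pytest.approx(expect, abs=1e-9)

    def test_coincident_boundaries_rejected(self):
        with pytest.raises(ZeroLengthImplantError):
            simulate_optimal_implant(((0, 0, 0), (0, 0, 1)),
                                     [(0.1, 0, 5)], [(0, 0.1, 5)])


def test_site_catalog_structure():
    catalog = load_site_catalog()
    assert len(catalog) == 13
    shapes = [d.shape for d in catalog.values()]
    assert set(shapes) == {"pyramid", "prism", "hemi_ellipsoid"}
    sagittal = [d for d in catalog.values() if d.sagittal_site]
    assert len(sagittal) == 3
    assert all(len(d.projection_pair) == 1 for d in sagittal)
    assert all(len(d.projection_pair) == 2 for d in catalog.values()
               if not d.sagittal_site)
    # transarticular implants project in the C1 frame
    assert catalog["2"].frame == "C1" and catalog["3"].frame == "C1"
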