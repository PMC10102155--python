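"""The discrete H² inner product: split identities, closed forms, invariances."""

import itertools

import numpy as np
import pytest

from elastishape import _ad as ad
from elastishape.h2metric import (
    MetricCoefficients,
    inner_product,
    metric_inner_of,
    rigid_invariance_check,
    split_differential,
    trace_pairing,
)
from elastishape.meshkit import (
    TangentField,
    face_frames,
    face_geometry,
    icosphere,
    rotation_matrix,
    translated,
)

A0_ONLY = MetricCoefficients(1, 0, 0, 0, 0, 0)
B1_ONLY = MetricCoefficients(0, 0, 1, 0, 0, 0)
ALL_ONES = MetricCoefficients()


def _random_field(mesh, rng, scale=1.0):
    return TangentField(scale * rng.standard_normal((mesh.n_vertices, 3)))


class TestSplitDifferential:
    def test_constant_field_gives_zero_parts(self, bumpy_sphere):
        h = TangentField(np.tile([0.3, -1.0, 2.0], (bumpy_sphere.n_vertices, 1)))
        sd = split_differential(bumpy_sphere, h)
        for part in (sd.dh_m, sd.dh_plus, sd.dh_perp, sd.dh_0):
            np.testing.assert_allclose(part, 0, atol=1e-12)

    def test_identity_field_is_pure_scaling(self, bumpy_sphere):
        """h = q gives dh = dq: only the volume-density part survives."""
        h = TangentField(bumpy_sphere.vertices.copy())
        sd = split_differential(bumpy_sphere, h)
        np.testing.assert_allclose(sd.dh_plus, face_geometry(bumpy_sphere).dq, atol=1e-10)
        for part in (sd.dh_m, sd.dh_perp, sd.dh_0):
            np.testing.assert_allclose(part, 0, atol=1e-10)

    def test_parts_sum_to_dh(self, bumpy_sphere, rng):
        h = _random_field(bumpy_sphere, rng)
        sd = split_differential(bumpy_sphere, h)
        f = bumpy_sphere.faces
        dh = np.stack(
            [h.values[f[:, 1]] - h.values[f[:, 0]], h.values[f[:, 2]] - h.values[f[:, 0]]],
            axis=1,
        )
        np.testing.assert_allclose(sd.total(), dh, atol=1e-12 * np.abs(dh).max())

    def test_parts_pairwise_orthogonal(self, bumpy_sphere, rng):
        h = _random_field(bumpy_sphere, rng)
        sd = split_differential(bumpy_sphere, h)
        fr = face_frames(bumpy_sphere.vertices, bumpy_sphere.faces)
        vol = ad.value(fr["vol"])

        def pair(A, B):
            return float(np.sum(ad.value(
                trace_pairing(fr, (A[:, 0], A[:, 1]), (B[:, 0], B[:, 1]))
            ) * vol))

        parts = [sd.dh_m, sd.dh_plus, sd.dh_perp, sd.dh_0]
        norms = [pair(p, p) for p in parts]
        for (i, a), (j, b) in itertools.combinations(enumerate(parts), 2):
            assert abs(pair(a, b)) <= 1e-9 * np.sqrt(norms[i] * norms[j])

    def test_decomposition_recovers_unsplit_energy(self, bumpy_sphere, rng):
        """With a1=b1=c1=d1=1 the split first-order energy equals tr(g^-1 dh dh^T)."""
        h = _random_field(bumpy_sphere, rng)
        split_coeffs = MetricCoefficients(0, 1, 1, 1, 1, 0)
        split_energy = inner_product(bumpy_sphere, h, h, split_coeffs)
        fr = face_frames(bumpy_sphere.vertices, bumpy_sphere.faces)
        f = bumpy_sphere.faces
        dh = (h.values[f[:, 1]] - h.values[f[:, 0]], h.values[f[:, 2]] - h.values[f[:, 0]])
        unsplit = float(np.sum(ad.value(trace_pairing(fr, dh, dh)) * ad.value(fr["vol"])))
        assert split_energy == pytest.approx(unsplit, rel=1e-9)

    def test_trace_anchor(self, bumpy_sphere):
        """tr(g^-1 dq dq^T) = 2 on every face: the fixed matrix convention."""
        fr = face_frames(bumpy_sphere.vertices, bumpy_sphere.faces)
        t = ad.value(trace_pairing(fr, (fr["e1"], fr["e2"]), (fr["e1"], fr["e2"])))
        np.testing.assert_allclose(t, 2.0, rtol=1e-12)


class TestInnerProduct:
    def test_translation_field_closed_form(self, unit_square):
        """Only the L² term sees a constant field: G = a0 |tau|^2 * Area."""
        tau = TangentField(np.tile([0.0, 0.0, 1.0], (4, 1)))
        assert inner_product(unit_square, tau, tau, A0_ONLY) == pytest.approx(1.0, rel=1e-12)
        # the same constant field through the full metric: first/second order vanish
        assert inner_product(unit_square, tau, tau, ALL_ONES) == pytest.approx(1.0, rel=1e-12)

    def test_scaling_field_closed_form(self, unit_square):
        """h = q is pure scaling: G = b1 * 2 * Area."""
        q = TangentField(unit_square.vertices.copy())
        assert inner_product(unit_square, q, q, B1_ONLY) == pytest.approx(2.0, rel=1e-12)

    def test_zero_field(self, unit_square):
        z = TangentField.zeros(unit_square)
        assert inner_product(unit_square, z, z, ALL_ONES) == 0.0

    def test_symmetry_and_bilinearity(self, bumpy_sphere, rng):
        h = _random_field(bumpy_sphere, rng)
        k = _random_field(bumpy_sphere, rng)
        hp = _random_field(bumpy_sphere, rng)
        ghk = inner_product(bumpy_sphere, h, k, ALL_ONES)
        assert ghk == pytest.approx(inner_product(bumpy_sphere, k, h, ALL_ONES), rel=1e-12)
        a, b = 0.7, -1.3
        combo = TangentField(a * h.values + b * hp.values)
        lhs = inner_product(bumpy_sphere, combo, k, ALL_ONES)
        rhs = a * ghk + b * inner_product(bumpy_sphere, hp, k, ALL_ONES)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_positive_definite_on_closed_mesh(self, bumpy_sphere, rng):
        h = _random_field(bumpy_sphere, rng)
        assert inner_product(bumpy_sphere, h, h, ALL_ONES) > 0

    def test_scaling_law_per_term(self, bumpy_sphere, rng):
        """V -> sV, h -> sh: L² term x s^4, first-order terms x s^2.

        The Laplacian term scales as s^2 for the raw integrated operator and
        picks up the extra s^2 of the vertex areas when they weight it.
        """
        h = _random_field(bumpy_sphere, rng)
        s = 1.7
        big = bumpy_sphere.with_vertices(s * bumpy_sphere.vertices)
        hs = TangentField(s * h.values)
        a2 = MetricCoefficients(0, 0, 0, 0, 0, 1)
        for coeffs, weighting, power in [
            (A0_ONLY, "vertex_area", 4),
            (MetricCoefficients(0, 1, 1, 1, 1, 0), "vertex_area", 2),
            (a2, "none", 2),
            (a2, "vertex_area", 4),
        ]:
            g1 = inner_product(bumpy_sphere, h, h, coeffs, a2_weighting=weighting)
            g2 = inner_product(big, hs, hs, coeffs, a2_weighting=weighting)
            assert g2 == pytest.approx(s**power * g1, rel=1e-10)

    def test_size_mismatch_raises(self, unit_square, sphere1):
        h = TangentField.zeros(sphere1)
        with pytest.raises(Exception):
            inner_product(unit_square, h, h, ALL_ONES)

    def test_a2_weighting_modes_differ(self, bumpy_sphere, rng):
        h = _random_field(bumpy_sphere, rng)
        c = MetricCoefficients(0, 0, 0, 0, 0, 1)
        gv = inner_product(bumpy_sphere, h, h, c, a2_weighting="vertex_area")
        gn = inner_product(bumpy_sphere, h, h, c, a2_weighting="none")
        assert gv != pytest.approx(gn)
        with pytest.raises(ValueError):
            inner_product(bumpy_sphere, h, h, c, a2_weighting="bogus")


class TestRigidInvariance:
    def test_identity_motion_zero_residual(self, bumpy_sphere, rng):
        h = _random_field(bumpy_sphere, rng)
        res = rigid_invariance_check(bumpy_sphere, h, h, ALL_ONES, np.eye(3), np.zeros(3))
        assert res == 0.0

    def test_random_rotation_translation(self, bumpy_sphere, rng):
        h = _random_field(bumpy_sphere, rng)
        k = _random_field(bumpy_sphere, rng)
        R = rotation_matrix(17)
        tau = np.array([2.0, -1.0, 0.5])
        res = rigid_invariance_check(bumpy_sphere, h, k, ALL_ONES, R, tau)
        scale = abs(inner_product(bumpy_sphere, h, k, ALL_ONES))
        assert res <= 1e-9 * max(scale, 1.0)

    def test_reflection_refused(self, bumpy_sphere, rng):
        h = _random_field(bumpy_sphere, rng)
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="rotation"):
            rigid_invariance_check(bumpy_sphere, h, h, ALL_ONES, refl, np.zeros(3))


class TestCoefficients:
    def test_validation(self):
        with pytest.raises(ValueError):
            MetricCoefficients(-1, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            MetricCoefficients(0, 0, 0, 0, 0, 0)

    def test_serialization_roundtrip(self):
        c = MetricCoefficients(1, 2, 3, 4, 5, 6)
        assert MetricCoefficients.from_dict(c.to_dict()) == c
        assert MetricCoefficients.from_sequence("1,2,3,4,5,6".split(",")) == c


def test_metric_gradient_matches_finite_differences(bumpy_sphere, rng):
    """G_q(h,h) must be exactly differentiable in both q and h."""
    h0 = rng.standard_normal((bumpy_sphere.n_vertices, 3)) * 0.1
    v0 = bumpy_sphere.vertices
    faces = bumpy_sphere.faces

    def f(v, h):
        return float(ad.value(metric_inner_of(v, faces, h, h, ALL_ONES)))

    xv, xh = ad.var(v0), ad.var(h0)
    (gv, gh) = ad.grad(metric_inner_of(xv, faces, xh, xh, ALL_ONES), [xv, xh])
    eps = 1e-6
    rng2 = np.random.default_rng(0)
    for _ in range(12):
        i = rng2.integers(bumpy_sphere.n_vertices)
        j = rng2.integers(3)
        vp, vm = v0.copy(), v0.copy()
        vp[i, j] += eps
        vm[i, j] -= eps
        fd = (f(vp, h0) - f(vm, h0)) / (2 * eps)
        assert gv[i, j] == pytest.approx(fd, rel=2e-5, abs=1e-8)
        hp, hm = h0.copy(), h0.copy()
        hp[i, j] += eps
        hm[i, j] -= eps
        fd = (f(v0, hp) - f(v0, hm)) / (2 * eps)
        assert gh[i, j] == pytest.approx(fd, rel=2e-5, abs=1e-8)


class TestMetricProperties:
    """Bilinearity/symmetry as a property over random scalings (hypothesis)."""

    from hypothesis import given, settings, strategies as st

    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bilinearity_property(self, a, b):
        mesh = icosphere(0)
        rng = np.random.default_rng(7)
        h = TangentField(rng.standard_normal((mesh.n_vertices, 3)))
        hp = TangentField(rng.standard_normal((mesh.n_vertices, 3)))
        k = TangentField(rng.standard_normal((mesh.n_vertices, 3)))
        combo = TangentField(a * h.values + b * hp.values)
        lhs = inner_product(mesh, combo, k, ALL_ONES)
        rhs = a * inner_product(mesh, h, k, ALL_ONES) + b * inner_product(mesh, hp, k, ALL_ONES)
        scale = max(abs(lhs), abs(rhs), 1.0)
        assert abs(lhs - rhs) <= 1e-10 * scale
        assert inner_product(mesh, combo, combo, ALL_ONES) >= -1e-12 * scale
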