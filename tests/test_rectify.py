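import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socketfit import (
    DeformationSpec,
    LogisticParams,
    RegionPressure,
    apply_actions,
    blend_coefficient,
    displace_constant,
    enclosed_volume,
    infer,
    logistic_blend,
    partition_vertices,
    rectify_anterolateral,
)
from socketfit.defaults import DISTAL, SCARPA, default_config, default_thresholds
from socketfit.rectify import DeformationError, LOG99, default_template

WIDE = DeformationSpec(theta_AS=0.0, theta_AL=130.0, theta_LE=180.0,
                       m_A=20.0, m_L=8.0, h_min=0.0, h_max=200.0)


def naive_blend(theta, h, spec, h_max=None):
    """Independent scalar re-implementation of the piecewise blend."""
    d = (spec.theta_LE - spec.theta_AS) % 360.0
    u = (theta - spec.theta_AS) % 360.0
    in_theta = (u <= d) if d >= 360.0 - 1e-9 else (u < d)
    if not (in_theta and spec.h_min <= h <= spec.h_max):
        return 0.0
    u_al = (spec.theta_AL - spec.theta_AS) % 360.0
    b1 = spec.edge_frac * d
    b4 = (1 - spec.edge_frac) * d
    b2 = min(max(u_al - d / 2, b1), b4)
    b3 = min(max(u_al + d / 2, b1), b4)
    k_edge = LOG99 / (spec.edge_frac * d)
    k_mid = LOG99 / max(b3 - b2, 1e-12)
    if u < b1:
        c = spec.m_A / (1 + math.exp(-k_edge * (u - b1 / 2)))
    elif u < b2:
        c = spec.m_A
    elif u < b3:
        s = 1.0 / (1 + math.exp(k_mid * (u - (b2 + b3) / 2)))
        c = spec.m_L + (spec.m_A - spec.m_L) * s
    elif u < b4:
        c = spec.m_L
    else:
        c = spec.m_L / (1 + math.exp(k_edge * (u - (b4 + d) / 2)))
    if spec.height_scale:
        c *= h / (spec.h_max if h_max is None else h_max)
    return c


class TestPartition:
    def test_full_span_is_all_vertices(self, coarse_socket):
        spec = DeformationSpec(theta_AS=0.0, theta_AL=180.0, theta_LE=360.0,
                               h_min=0.0, h_max=300.0)
        part = partition_vertices(coarse_socket, spec)
        assert len(part.H) == len(coarse_socket.vertices)
        assert len(part.F) == 0

    def test_zero_angular_width_rejected(self):
        with pytest.raises(DeformationError):
            DeformationSpec(theta_AS=30.0, theta_AL=30.0, theta_LE=30.0)

    def test_partition_is_disjoint_cover(self, coarse_socket):
        part = partition_vertices(coarse_socket, WIDE)
        assert len(np.intersect1d(part.H, part.F)) == 0
        assert len(part.H) + len(part.F) == len(coarse_socket.vertices)

    def test_start_edge_closed(self, coarse_socket):
        part = partition_vertices(coarse_socket, WIDE)
        cyl = coarse_socket.cylindrical()
        on_start = np.isclose(cyl[:, 1], WIDE.theta_AS) & (cyl[:, 0] <= WIDE.h_max)
        assert on_start.any()
        assert set(np.flatnonzero(on_start)) <= set(part.H.tolist())


class TestDisplaceConstant:
    def test_zero_displacement_is_identity(self, cylinder_socket):
        out = displace_constant(cylinder_socket, 0.0, 30.0, 120.0)
        assert np.allclose(out.vertices, cylinder_socket.vertices)

    def test_cylinder_radii_decrease_by_exactly_C(self, cylinder_socket):
        C = 4.0
        out = displace_constant(cylinder_socket, C, 30.0, 120.0)
        c0, c1 = cylinder_socket.cylindrical(), out.cylindrical()
        # interior wall vertices (away from brim ring and distal cap)
        mask = (
            (c0[:, 1] >= 40) & (c0[:, 1] < 110)
            & (c0[:, 0] > 30) & (c0[:, 0] < 270) & (c0[:, 2] > 1)
        )
        assert mask.any()
        assert np.allclose(c0[mask, 2] - c1[mask, 2], C, atol=1e-9)

    def test_volume_strictly_decreases(self, coarse_socket):
        out = displace_constant(coarse_socket, 3.0, 30.0, 150.0)
        assert enclosed_volume(out) < enclosed_volume(coarse_socket)

    def test_fixed_region_unmoved(self, coarse_socket):
        out = displace_constant(coarse_socket, 3.0, 30.0, 120.0)
        cyl = coarse_socket.cylindrical()
        off = (cyl[:, 1] - 30.0) % 360.0
        fixed = off >= (120.0 - 30.0)
        assert np.array_equal(out.vertices[fixed], coarse_socket.vertices[fixed])

    def test_negative_displacement_rejected(self, coarse_socket):
        with pytest.raises(DeformationError):
            displace_constant(coarse_socket, -1.0, 0.0, 90.0)

    def test_axis_crossing_rejected(self, cylinder_socket):
        with pytest.raises(DeformationError, match="axis"):
            displace_constant(cylinder_socket, 100.0, 0.0, 359.0)


class TestLogisticBlend:
    def test_midpoint_is_half_L(self):
        p = LogisticParams(L=10.0, k=0.3, n=1, x0=45.0)
        assert logistic_blend(45.0, p) == pytest.approx(5.0)

    def test_asymptotes(self):
        p = LogisticParams(L=10.0, k=0.3, n=1, x0=0.0)
        assert logistic_blend(1e4, p) == pytest.approx(0.0, abs=1e-12)
        assert logistic_blend(-1e4, p) == pytest.approx(10.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        x=st.floats(-200, 200), L=st.floats(0.1, 50), k=st.floats(0.01, 5),
        n=st.sampled_from([1, -1]), x0=st.floats(-100, 100),
    )
    def test_matches_closed_form(self, x, L, k, n, x0):
        expected = L / (1.0 + math.exp(min(500, max(-500, n * k * (x - x0)))))
        assert logistic_blend(x, LogisticParams(L, k, n, x0)) == pytest.approx(
            expected, rel=1e-12, abs=1e-300
        )


class TestBlendCoefficient:
    def test_fixed_region_is_zero(self):
        assert blend_coefficient(250.0, 100.0, WIDE) == 0.0  # outside angles
        assert blend_coefficient(90.0, 500.0, WIDE) == 0.0  # outside heights

    def test_plateau_value_at_hmax(self):
        b1, b2, _, _ = WIDE.breakpoints()
        u_plateau = (b1 + b2) / 2.0
        assert blend_coefficient(WIDE.theta_AS + u_plateau, WIDE.h_max, WIDE) == WIDE.m_A

    def test_sigmoid_midpoint_at_theta_AL(self):
        # with theta_AL at the centre of the control extent the transition
        # midpoint coincides with theta_AL
        sym = DeformationSpec(theta_AS=0.0, theta_AL=90.0, theta_LE=180.0,
                              m_A=20.0, m_L=8.0, h_min=0.0, h_max=200.0)
        assert blend_coefficient(sym.theta_AL, sym.h_max, sym) == pytest.approx(
            (sym.m_A + sym.m_L) / 2.0
        )

    def test_height_scaling_linear(self):
        full = blend_coefficient(WIDE.theta_AL, WIDE.h_max, WIDE)
        half = blend_coefficient(WIDE.theta_AL, WIDE.h_max / 2.0, WIDE)
        assert half == pytest.approx(full / 2.0)

    def test_matches_naive_oracle(self, rng):
        thetas = rng.uniform(0, 360, 500)
        hs = rng.uniform(-10, 250, 500)
        for spec in (WIDE, dataclasses.replace(WIDE, m_A=5.0, m_L=25.0),
                     default_template()):
            spec = dataclasses.replace(spec, m_A=max(spec.m_A, 7.0), m_L=max(spec.m_L, 3.0))
            vec = blend_coefficient(thetas, hs, spec)
            oracle = np.array([naive_blend(t, h, spec) for t, h in zip(thetas, hs)])
            assert np.allclose(vec, oracle, atol=1e-9)

    def test_bounded_by_max_magnitude(self, rng):
        thetas = rng.uniform(0, 360, 1000)
        hs = rng.uniform(0, 200, 1000)
        c = blend_coefficient(thetas, hs, WIDE)
        assert np.all(c >= 0.0)
        assert np.all(c <= max(WIDE.m_A, WIDE.m_L) + 1e-12)

    def test_continuity_on_dense_grid(self):
        u = np.linspace(0.0, WIDE.delta_theta_max - 1e-9, 40000)
        c = blend_coefficient(WIDE.theta_AS + u, WIDE.h_max, WIDE)
        jumps = np.abs(np.diff(c))
        # residual at segment joins is ~1% of the bridged level by design
        assert jumps.max() < 0.011 * max(WIDE.m_A, WIDE.m_L)

    def test_edge_zones_span_ten_percent(self):
        spec = dataclasses.replace(WIDE, m_A=10.0, m_L=10.0)
        d = spec.delta_theta_max
        u = np.linspace(0, d * (1 - 1e-12), 20001)
        c = blend_coefficient(spec.theta_AS + u, spec.h_max, spec)
        inside = (u >= 0.1 * d) & (u <= 0.9 * d)
        assert np.allclose(c[inside], 10.0, atol=1e-12)  # plateau exact
        rising = u < 0.1 * d
        assert np.all(np.diff(c[rising]) > 0)
        assert c[rising].max() < 10.0
        falling = u > 0.9 * d
        assert np.all(np.diff(c[falling]) < 0)


class TestRectifyAnterolateral:
    def test_zero_magnitudes_identity(self, coarse_socket):
        spec = dataclasses.replace(WIDE, m_A=0.0, m_L=0.0)
        out = rectify_anterolateral(coarse_socket, spec)
        assert np.allclose(out.vertices, coarse_socket.vertices)

    def test_fixed_region_displacement_exactly_zero(self, coarse_socket):
        part = partition_vertices(coarse_socket, WIDE)
        out = rectify_anterolateral(coarse_socket, WIDE)
        moved = np.linalg.norm(out.vertices - coarse_socket.vertices, axis=1)
        assert moved[part.F].max() == 0.0

    def test_topology_preserved(self, coarse_socket):
        out = rectify_anterolateral(coarse_socket, WIDE)
        assert np.array_equal(out.faces, coarse_socket.faces)

    def test_displacements_bounded_by_magnitudes(self, coarse_socket):
        out = rectify_anterolateral(coarse_socket, WIDE)
        moved = np.linalg.norm(out.vertices - coarse_socket.vertices, axis=1)
        assert moved.max() <= max(WIDE.m_A, WIDE.m_L) + 1e-9

    def test_equals_constant_displacement_when_smoothing_off(self, cylinder_socket):
        C = 5.0
        spec = DeformationSpec(theta_AS=30.0, theta_AL=75.0, theta_LE=120.0,
                               m_A=C, m_L=C, h_min=0.0, h_max=300.0,
                               smooth_edges=False, height_scale=False)
        a = rectify_anterolateral(cylinder_socket, spec)
        b = displace_constant(cylinder_socket, C, 30.0, 120.0)
        assert np.allclose(a.vertices, b.vertices, atol=1e-12)

    def test_volume_monotone_in_each_magnitude(self, coarse_socket):
        vols_a = [
            enclosed_volume(rectify_anterolateral(
                coarse_socket, dataclasses.replace(WIDE, m_A=m, m_L=4.0)))
            for m in (0.0, 5.0, 12.0, 20.0)
        ]
        assert all(v1 > v2 for v1, v2 in zip(vols_a, vols_a[1:]))
        vols_l = [
            enclosed_volume(rectify_anterolateral(
                coarse_socket, dataclasses.replace(WIDE, m_A=4.0, m_L=m)))
            for m in (0.0, 5.0, 12.0, 20.0)
        ]
        assert all(v1 > v2 for v1, v2 in zip(vols_l, vols_l[1:]))


class TestApplyActions:
    def _actions(self, fis_config, thresholds, distal, scarpa):
        from socketfit.defaults import DEFAULT_BASELINES

        vals = dict(DEFAULT_BASELINES)
        vals.update({DISTAL: distal, SCARPA: scarpa})
        return infer([RegionPressure(r, p) for r, p in vals.items()],
                     fis_config, thresholds)

    def test_empty_actions_identity(self, coarse_socket, fis_config, thresholds):
        out = self._actions(fis_config, thresholds, 40.0, 48.0)
        assert out.actions == []
        rectified = apply_actions(coarse_socket, out, default_template())
        assert np.allclose(rectified.vertices, coarse_socket.vertices)

    def test_19mm_action_reaches_plateau_displacement(self, coarse_socket,
                                                      fis_config, thresholds):
        template = dataclasses.replace(WIDE, m_A=0.0, m_L=0.0)
        out = self._actions(fis_config, thresholds, 35.2, 9.6)  # "medium" pattern
        mags = [a.magnitude_mm for a in out.actions if a.zone == "anterior_scarpa"]
        assert mags and mags[0] == pytest.approx(19.0, abs=0.05)
        rectified = apply_actions(coarse_socket, out, template)
        cyl = coarse_socket.cylindrical()
        b1, b2, _, _ = template.breakpoints()
        u = (cyl[:, 1] - template.theta_AS) % 360.0
        h_H = cyl[partition_vertices(coarse_socket, template).H, 0].max()
        plateau = (u > b1) & (u < b2) & (cyl[:, 0] > 0.97 * h_H) & (cyl[:, 0] <= h_H)
        assert plateau.any()
        moved = np.linalg.norm(rectified.vertices - coarse_socket.vertices, axis=1)
        assert moved[plateau].max() == pytest.approx(mags[0], rel=0.05)

    def test_volume_decreases_across_9_19_29_variants(self, coarse_socket):
        template = default_template()
        vols = []
        for m in (9.0, 19.0, 29.0):
            spec = dataclasses.replace(template, m_A=m, m_L=0.0)
            vols.append(enclosed_volume(rectify_anterolateral(coarse_socket, spec)))
        v0 = enclosed_volume(coarse_socket)
        assert v0 > vols[0] > vols[1] > vols[2]

    def test_unknown_zone_rejected(self, coarse_socket, fis_config, thresholds):
        out = self._actions(fis_config, thresholds, 88.0, 9.6)
        with pytest.raises(DeformationError, match="zone"):
            apply_actions(coarse_socket, out, default_template(), zone_roles={})
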