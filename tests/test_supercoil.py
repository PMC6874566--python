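"""Supercoil parameter estimation: discrete estimators, helix fits,
extension."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hookjoint import (
    DegenerateInputError,
    InsufficientDataError,
    centerline_curvature_torsion,
    extend_assembly,
    fit_helix_lsq,
)
from hookjoint import (
    generate_supercoiled,
    helix_from_kappa_tau,
    index_lattice,
    native_spec,
)
from hookjoint.synthetic import _helix_frame

# the native supercoil: P = 1290 Å, 2R = 330 Å, left-handed
P_NATIVE, R_NATIVE = 1290.0, 165.0
H_NATIVE = P_NATIVE / (2 * np.pi)
KAPPA_NATIVE = R_NATIVE / (R_NATIVE ** 2 + H_NATIVE ** 2)
TAU_NATIVE = -H_NATIVE / (R_NATIVE ** 2 + H_NATIVE ** 2)


def _helix_points(R, h, sigma, arc, n):
    return _helix_frame(np.linspace(0, arc, n), R, h, sigma)[0]


class TestDiscreteEstimators:
    def test_native_helix_curvature_torsion(self):
        pts = _helix_points(R_NATIVE, H_NATIVE, -1.0, 800.0, 41)
        kappa, tau, _, _ = centerline_curvature_torsion(pts)
        assert kappa == pytest.approx(KAPPA_NATIVE, rel=5e-3)
        assert tau == pytest.approx(TAU_NATIVE, rel=5e-3)

    def test_collinear_points(self):
        line = np.outer(np.linspace(0, 100, 12), [0.4, 0.5, 0.7])
        kappa, tau, _, _ = centerline_curvature_torsion(line)
        assert kappa == pytest.approx(0.0, abs=1e-12)
        assert tau == pytest.approx(0.0, abs=1e-12)

    def test_planar_circle(self):
        theta = np.linspace(0, 1.2, 25)
        circle = np.column_stack([420 * np.cos(theta), 420 * np.sin(theta),
                                  np.zeros_like(theta)])
        kappa, tau, _, _ = centerline_curvature_torsion(circle)
        assert kappa == pytest.approx(1.0 / 420.0, rel=1e-9)
        assert tau == pytest.approx(0.0, abs=1e-9)

    def test_too_few_or_degenerate(self):
        with pytest.raises(InsufficientDataError):
            centerline_curvature_torsion(np.zeros((4, 3)))
        bad = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0],
                        [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateInputError):
            centerline_curvature_torsion(bad)


class TestInverseFrenet:
    def test_native_parameters(self):
        p = helix_from_kappa_tau(2.378e-3, -2.959e-3)
        assert p.pitch == pytest.approx(1290.0, rel=2e-3)
        assert p.radius == pytest.approx(165.0, rel=2e-3)
        assert p.handedness == "left"

    def test_circle_and_straight_limits(self):
        circle = helix_from_kappa_tau(1e-3, 0.0)
        assert circle.pitch == 0.0
        assert circle.handedness is None
        straight = helix_from_kappa_tau(0.0, 0.0)
        assert straight.radius == 0.0
        assert np.isinf(straight.pitch)

    @given(kappa=st.floats(1e-5, 1e-2), tau=st.floats(-1e-2, 1e-2))
    @settings(max_examples=60, deadline=None)
    def test_inverse_relations_hold(self, kappa, tau):
        p = helix_from_kappa_tau(kappa, tau)
        q = kappa ** 2 + tau ** 2
        assert p.radius == pytest.approx(kappa / q, rel=1e-9)
        assert p.reduced_pitch == pytest.approx(abs(tau) / q, rel=1e-9)


class TestHelixFit:
    def test_noiseless_recovery(self):
        pts = _helix_points(R_NATIVE, H_NATIVE, -1.0, 800.0, 41)
        init = helix_from_kappa_tau(*centerline_curvature_torsion(pts)[:2])
        fit = fit_helix_lsq(pts, init)
        assert fit.pitch == pytest.approx(P_NATIVE, rel=5e-3)
        assert fit.radius == pytest.approx(R_NATIVE, rel=5e-3)
        assert fit.handedness == "left"

    def test_noisy_recovery_within_three_percent(self):
        rng = np.random.default_rng(20191122)
        pts = _helix_points(R_NATIVE, H_NATIVE, -1.0, 800.0, 41)
        noisy = pts + rng.normal(0, 1.0, pts.shape)
        init = helix_from_kappa_tau(*centerline_curvature_torsion(noisy)[:2])
        fit = fit_helix_lsq(noisy, init, n_bootstrap=30)
        assert fit.pitch == pytest.approx(P_NATIVE, rel=0.03)
        assert fit.radius == pytest.approx(R_NATIVE, rel=0.03)
        lo, hi = fit.pitch_ci
        assert lo < hi

    def test_straight_input_flagged(self):
        line = np.outer(np.linspace(0, 100, 12), [0.0, 0.0, 1.0])
        init = helix_from_kappa_tau(*centerline_curvature_torsion(line)[:2])
        fit = fit_helix_lsq(line, init)
        assert not fit.converged
        assert fit.radius == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("P,R", [(600.0, 50.0), (1290.0, 165.0),
                                     (2000.0, 300.0), (800.0, 250.0)])
    def test_discrete_and_lsq_agree_noiseless(self, P, R):
        h = P / (2 * np.pi)
        pts = _helix_points(R, h, 1.0, 0.4 * 2 * np.pi * np.hypot(R, h), 25)
        kappa, tau, _, _ = centerline_curvature_torsion(pts)
        discrete = helix_from_kappa_tau(kappa, tau)
        fit = fit_helix_lsq(pts, discrete)
        assert discrete.pitch == pytest.approx(fit.pitch, rel=0.01)
        assert discrete.radius == pytest.approx(fit.radius, rel=0.01)
        assert fit.pitch == pytest.approx(P, rel=0.005)
        assert fit.radius == pytest.approx(R, rel=0.005)

    def test_mirror_image_flips_handedness_keeps_geometry(self, native26):
        subunits, _ = native26
        mirrored = [s.map_coords(lambda xyz: xyz * np.array([-1.0, 1.0, 1.0]))
                    for s in subunits]
        def estimate(subs):
            lat = index_lattice(subs)
            k, t, _, _ = centerline_curvature_torsion(lat.axis)
            return fit_helix_lsq(lat.axis, helix_from_kappa_tau(k, t))
        a = estimate(subunits)
        b = estimate(mirrored)
        assert a.handedness == "left" and b.handedness == "right"
        assert b.pitch == pytest.approx(a.pitch, rel=0.01)
        assert b.radius == pytest.approx(a.radius, rel=0.01)


class TestExtension:
    def test_zero_length_is_identity(self, native26, native26_lattice):
        subunits, _ = native26
        p = helix_from_kappa_tau(KAPPA_NATIVE, TAU_NATIVE)
        out = extend_assembly(subunits, native26_lattice, p, length=0.0)
        assert all(a is b for a, b in zip(out, subunits))

    def test_one_pitch_extension_geometry(self, native26, native26_lattice):
        """Extending to one pitch spans ~1290 Å axially at superhelix
        diameter ~330 Å, and the extension reproduces the input supercoil."""
        subunits, truth = native26
        k, t, _, _ = centerline_curvature_torsion(native26_lattice.axis)
        fit = fit_helix_lsq(native26_lattice.axis, helix_from_kappa_tau(k, t))
        extended = extend_assembly(subunits, native26_lattice, fit, length=1.0)
        u, a = fit.axis_direction, fit.axis_point
        centroids = np.array([s.centroid() for s in extended])
        z = (centroids - a) @ u
        radial = np.linalg.norm((centroids - a) - np.outer(z, u), axis=1)
        assert z.max() - z.min() >= 0.98 * fit.pitch
        # subunit centroids ring the superhelix at radius R ± tube radius
        assert 140.0 < radial.mean() < 190.0
        assert radial.max() > 190.0 and radial.min() < 140.0
        # self-consistency: the centerline rebuilt from each screw copy's
        # own window means (the copies are the bookkeeping of the
        # extension) reproduces the input parameters within 1%
        n0 = len(subunits)
        kernel = np.ones(11) / 11.0
        vertices = []
        for j in range(len(extended) // n0):
            cents = np.array([s.centroid()
                              for s in extended[j * n0:(j + 1) * n0]])
            vertices.append(np.column_stack(
                [np.convolve(cents[:, i], kernel, mode="valid")
                 for i in range(3)]))
        vertices = np.vstack(vertices)
        k2, t2, _, _ = centerline_curvature_torsion(vertices)
        refit = fit_helix_lsq(vertices, helix_from_kappa_tau(k2, t2))
        assert refit.pitch == pytest.approx(fit.pitch, rel=0.01)
        assert refit.radius == pytest.approx(fit.radius, rel=0.01)
        assert refit.handedness == fit.handedness

    def test_straight_cannot_extend(self, straight26, straight26_lattice):
        subunits, _ = straight26
        with pytest.raises(DegenerateInputError):
            extend_assembly(subunits, straight26_lattice,
                            helix_from_kappa_tau(0.0, 0.0), length=1.0)
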