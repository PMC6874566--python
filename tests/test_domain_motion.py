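"""Kabsch superposition, conformation classes and domain-motion recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hookjoint import (
    DegenerateInputError,
    Hinge,
    Layer,
    apply_hinge,
    conformation_classes,
    extension,
    generate_straight,
    kabsch_superpose,
    relative_domain_motion,
    subunit_length,
)
from hookjoint.domain_motion import domain_axis_tilt, pairwise_rmsd
from hookjoint.synthetic import SyntheticSpec, straight_spec

Z = np.array([0.0, 0.0, 1.0])


def _brute_force_rmsd(moving, fixed):
    """Independent oracle: direct minimization over rotation vector and
    translation."""
    def cost(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return np.sqrt(np.mean(np.sum((moving @ R.T + x[3:] - fixed) ** 2,
                                      axis=1)))
    best = np.inf
    for seed_rv in [np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 0, 2.0])]:
        res = minimize(cost, np.concatenate([seed_rv, np.zeros(3)]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12,
                                "maxiter": 20000, "maxfev": 20000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(0, 10, (30, 3))
        tf, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-9
        assert tf.angle_deg < 1e-6

    def test_known_rotation_recovered(self, rng):
        pts = rng.normal(0, 10, (40, 3))
        axis = np.array([0.0, 0.0, 1.0])
        R = Rotation.from_rotvec(np.deg2rad(24) * axis).as_matrix()
        tf, rmsd = kabsch_superpose(pts, pts @ R.T + np.array([3, -1, 7.0]))
        assert tf.angle_deg == pytest.approx(24.0, abs=1e-6)
        assert abs(abs(np.dot(tf.axis, axis)) - 1.0) < 1e-9
        assert rmsd < 1e-9

    def test_matches_brute_force_on_noisy_cloud(self, rng):
        pts = rng.normal(0, 8, (25, 3))
        R = Rotation.from_euler("xyz", [40, -25, 65], degrees=True).as_matrix()
        noisy = pts @ R.T + np.array([5, 5, -2.0]) + rng.normal(0, 0.2, (25, 3))
        _, rmsd = kabsch_superpose(pts, noisy)
        oracle = _brute_force_rmsd(pts, noisy)
        assert rmsd == pytest.approx(oracle, abs=1e-4)
        assert rmsd <= oracle + 1e-9   # least squares is optimal

    def test_matches_biopython_superimposer(self, rng):
        from Bio.SVDSuperimposer import SVDSuperimposer

        pts = rng.normal(0, 6, (20, 3))
        R = Rotation.from_euler("zxz", [10, 30, -50], degrees=True).as_matrix()
        target = pts @ R.T + 4.0 + rng.normal(0, 0.3, (20, 3))
        _, rmsd = kabsch_superpose(pts, target)
        sup = SVDSuperimposer()
        sup.set(target, pts)
        sup.run()
        assert rmsd == pytest.approx(sup.get_rms(), abs=1e-8)

    def test_idempotent(self, rng):
        pts = rng.normal(0, 10, (15, 3))
        R = Rotation.from_euler("xyz", [5, 10, 15], degrees=True).as_matrix()
        tf, _ = kabsch_superpose(pts @ R.T, pts)
        aligned = tf.apply(pts @ R.T)
        tf2, _ = kabsch_superpose(aligned, pts)
        assert tf2.angle_deg < 1e-6
        assert np.linalg.norm(tf2.translation) < 1e-8

    def test_global_motion_invariance(self, rng):
        a = rng.normal(0, 10, (20, 3))
        b = a @ Rotation.from_euler("x", 12, degrees=True).as_matrix().T + 2.0
        tf_ref, rmsd_ref = kabsch_superpose(a, b)
        G = Rotation.from_euler("zyx", [70, 33, -15], degrees=True).as_matrix()
        g = np.array([100.0, -40.0, 9.0])
        tf2, rmsd2 = kabsch_superpose(a @ G.T + g, b @ G.T + g)
        assert tf2.angle_deg == pytest.approx(tf_ref.angle_deg, abs=1e-6)
        assert rmsd2 == pytest.approx(rmsd_ref, abs=1e-5)

    def test_degenerate_input(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestConformationClasses:
    def test_straight_is_conformationally_uniform(self, straight26,
                                                  straight26_lattice):
        subunits, _ = straight26
        classes = conformation_classes(subunits, straight26_lattice)
        assert classes.n_classes == 11
        assert classes.conformationally_uniform
        assert max(v for v in classes.between_rmsd.values()) < 0.1

    def test_supercoiled_has_eleven_distinct_classes(self, native26,
                                                     native26_lattice):
        subunits, _ = native26
        classes = conformation_classes(subunits, native26_lattice)
        assert classes.n_classes == 11
        assert not classes.conformationally_uniform
        # subunits within one protofilament stay nearly identical
        assert max(classes.within_rmsd.values()) < 0.8

    def test_class_order_follows_stretch_ordering(self, native26,
                                                  native26_lattice,
                                                  native26_profile):
        """Walking around the circumference, class representatives order
        like the generator's per-protofilament stretch."""
        subunits, _ = native26
        classes = conformation_classes(subunits, native26_lattice)
        by_chain = {s.chain_id: s for s in subunits}
        means = native26_profile.per_protofilament_mean()
        ref = by_chain[classes.representative[7]]  # most compressed side
        rmsd_to_ref = {p: pairwise_rmsd(ref, by_chain[c])
                       for p, c in classes.representative.items()}
        # dissimilarity from the compressed representative should rank
        # like spacing difference from the compressed protofilament
        spacing_diff = {p: abs(means[p] - means[7]) for p in means}
        order_a = sorted(rmsd_to_ref, key=rmsd_to_ref.get)
        order_b = sorted(spacing_diff, key=spacing_diff.get)
        from scipy.stats import spearmanr
        rho = spearmanr([order_a.index(p) for p in sorted(means)],
                        [order_b.index(p) for p in sorted(means)]).statistic
        assert rho > 0.8


class TestDomainMotionRecovery:
    def test_self_comparison_is_identity(self, straight26):
        subunits, truth = straight26
        dm = relative_domain_motion(subunits[0], subunits[0],
                                    truth.spec.domain_definitions(), Z)
        for name in ("D0c", "D1", "D2"):
            assert dm.tilt(name) < 0.1
            assert abs(dm.shift(name)) < 0.05

    def test_hinge_tilt_recovered(self):
        spec = straight_spec()
        subunits, truth = generate_straight(spec)
        hinged = apply_hinge(subunits, truth, Hinge("D2", 24.0),
                             target_protofilaments=[1])
        dm = relative_domain_motion(hinged[1], hinged[0],
                                    spec.domain_definitions(), Z)
        assert dm.tilt("D2") == pytest.approx(24.0, abs=0.2)
        assert dm.tilt("D1") < 0.1
        assert dm.d0c_residual_angle_deg < 0.1

    def test_hinge_tilt_plus_shift_recovered(self):
        layers = (Layer("D0c", 25.0, 30, 6.0),
                  Layer("D1", 45.0, 40, 8.0, z_offset=12.0),
                  Layer("D2", 70.0, 35, 8.0))
        spec = SyntheticSpec(layers=layers)
        subunits, truth = generate_straight(spec)
        hinged = apply_hinge(subunits, truth, Hinge("D1", 4.0, axial_shift=5.0),
                             target_protofilaments=[1])
        dm = relative_domain_motion(hinged[1], hinged[0],
                                    spec.domain_definitions(), Z)
        assert dm.tilt("D1") == pytest.approx(4.0, abs=0.2)
        assert dm.shift("D1") == pytest.approx(5.0, abs=0.1)

    def test_subunit_length_extension_equals_imposed_stretch(self):
        layers = (Layer("D0c", 25.0, 30, 6.0),
                  Layer("D1", 45.0, 40, 8.0, z_offset=12.0),
                  Layer("D2", 70.0, 35, 8.0))
        spec = SyntheticSpec(layers=layers)
        subunits, truth = generate_straight(spec)
        shifted = apply_hinge(subunits, truth, Hinge("D1", 0.0, axial_shift=5.0),
                              target_protofilaments=[1])
        # brute-force expectation from coordinates
        expected = ((shifted[0].ca @ Z).max() - (shifted[0].ca @ Z).min()
                    - ((subunits[0].ca @ Z).max() - (subunits[0].ca @ Z).min()))
        dl = extension(subunits[0], shifted[0], Z)
        assert dl == pytest.approx(expected, abs=1e-9)
        assert dl == pytest.approx(5.0, abs=0.1)
        assert extension(subunits[0], subunits[0], Z) == 0.0

    def test_domain_axis_tilt_on_constructed_rod(self):
        # an elongated domain at a known 17° tilt from the axis
        n = 40
        t = np.linspace(-20, 20, n)
        direction = np.array([np.sin(np.deg2rad(17)), 0, np.cos(np.deg2rad(17))])
        coords = np.outer(t, direction)
        from hookjoint import DomainDefinition, SubunitModel
        jitter = np.random.default_rng(2).normal(0, 0.1, (n, 3))
        sub = SubunitModel("A", np.arange(1, n + 1), ["ALA"] * n,
                           [{"CA": c + jitter[i]}
                            for i, c in enumerate(coords)])
        tilt = domain_axis_tilt(sub, [DomainDefinition("rod", ((1, n),))],
                                "rod", Z)
        assert tilt == pytest.approx(17.0, abs=0.5)
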