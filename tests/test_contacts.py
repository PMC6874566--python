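"""Inter-subunit contacts, residue variability, D1 triangle gap."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hookjoint import (
    InsufficientDataError,
    d1_triangle_gap,
    find_contacts,
    generate_straight,
    residue_variability,
    straight_spec,
)
from hookjoint.contacts import _representative_pairs
from hookjoint.lattice import index_lattice
from hookjoint.synthetic import _rot_z


class TestFindContacts:
    def test_zero_cutoff_gives_empty_table(self, native26, native26_lattice):
        subunits, _ = native26
        table = find_contacts(subunits, native26_lattice, 5, cutoff=0.0)
        assert len(table.table) == 0
        assert table.n_constant == 0

    def test_invalid_direction(self, native26, native26_lattice):
        subunits, _ = native26
        with pytest.raises(ValueError):
            find_contacts(subunits, native26_lattice, 7)

    def test_straight_contacts_are_all_constant(self, straight26,
                                                straight26_lattice):
        """Identical contexts: every observed interface is constant."""
        subunits, _ = straight26
        table = find_contacts(subunits, straight26_lattice, 5, cutoff=17.0)
        assert len(table.table) > 0
        assert (table.table["class"] == "constant").all()

    def test_supercoiled_axial_contacts_switch_with_compression(
            self, native26, native26_lattice):
        """Along the protofilament, interfaces present on the compressed
        side open on the extended side."""
        subunits, _ = native26
        table = find_contacts(subunits, native26_lattice, 11, cutoff=27.0)
        switching = table.of_class("switching")
        assert len(switching) > 0
        # switching interfaces are present in the compressed contexts
        # (ids 6, 7) more often than in the extended context (id 1)
        present_comp = switching[["present_6", "present_7"]].to_numpy().mean()
        present_ext = switching["present_1"].to_numpy().mean()
        assert present_comp > present_ext

    def test_classification_stable_to_cutoff_perturbation(self, native26,
                                                          native26_lattice):
        subunits, _ = native26
        base = find_contacts(subunits, native26_lattice, 5, cutoff=17.0)
        constant_pairs = set(map(tuple, base.of_class("constant")
                                 [["residue_0", "residue_neighbor"]].to_numpy()))
        assert constant_pairs
        # pairs whose distances clear the cutoff by the perturbation margin
        # must keep their class at ±0.2 Å
        ctx_cols = [c for c in base.table.columns if c.startswith("context_")]
        robust = {
            tuple(r[["residue_0", "residue_neighbor"]])
            for _, r in base.of_class("constant").iterrows()
            if r[ctx_cols].max() <= 17.0 - 0.2
        }
        assert robust
        for cutoff in (16.8, 17.2):
            t = find_contacts(subunits, native26_lattice, 5, cutoff=cutoff)
            still = set(map(tuple, t.of_class("constant")
                            [["residue_0", "residue_neighbor"]].to_numpy()))
            assert robust <= still

    def test_direction_inversion_symmetry(self, native26, native26_lattice):
        """Contacts of 0→+5 equal contacts of −5→0 with roles swapped."""
        subunits, _ = native26
        by_chain = {s.chain_id: s for s in subunits}
        chain_of_k = native26_lattice.chain_of_k
        ctx = _representative_pairs(native26_lattice, 5)
        p, (k, k5) = next(iter(sorted(ctx.items())))
        a, b = by_chain[chain_of_k[k]], by_chain[chain_of_k[k5]]
        from hookjoint.contacts import _min_residue_distances
        fwd = _min_residue_distances(a, b, {(10, 40)})
        rev = _min_residue_distances(b, a, {(40, 10)})
        assert fwd[(10, 40)] == pytest.approx(rev[(40, 10)], abs=1e-12)


class TestResidueVariability:
    def test_straight_variability_is_zero(self, straight26,
                                          straight26_lattice):
        subunits, _ = straight26
        rv = residue_variability(subunits, straight26_lattice, 11)
        assert rv.complete
        assert rv.sd.max() < 1e-9

    def test_variability_grows_with_layer_radius(self, native26,
                                                 native26_lattice):
        """Bending disperses axial distances in proportion to radius, so
        the outer layer shows the largest SD and the inner the smallest."""
        subunits, truth = native26
        rv = residue_variability(subunits, native26_lattice, 11)
        summary = rv.domain_summary(truth.spec.domain_definitions(),
                                    subunits[0])
        sds = summary["mean_sd"]
        assert sds["D0c"] < sds["D1"] < sds["D2"]
        # dispersion of d0·κ·r·cos over 11 slots approaches d0κr/√2
        for layer in ("D0c", "D1", "D2"):
            r_eff = np.hypot(*truth.layer_xy_mean[layer])
            predicted = truth.spec.d0 * truth.kappa * r_eff / np.sqrt(2)
            assert sds[layer] == pytest.approx(predicted, rel=0.15)

    def test_rigid_motion_invariance(self, native26):
        subunits, _ = native26
        R = Rotation.from_euler("xyz", [25, 35, 45], degrees=True).as_matrix()
        moved = [s.transformed(R, np.array([10.0, -5.0, 60.0]))
                 for s in subunits]
        rv_a = residue_variability(subunits, index_lattice(subunits), 11)
        rv_b = residue_variability(moved, index_lattice(moved), 11)
        np.testing.assert_allclose(rv_a.sd.to_numpy(), rv_b.sd.to_numpy(),
                                   atol=1e-8)


class TestTriangleGap:
    def test_compressed_gap_smaller_than_extended(self, native26,
                                                  native26_lattice):
        subunits, truth = native26
        defs = truth.spec.domain_definitions()
        extended = d1_triangle_gap(subunits, native26_lattice, 1, defs)
        compressed = d1_triangle_gap(subunits, native26_lattice, 7, defs)
        assert (compressed["centroid_triangle_area"]
                < extended["centroid_triangle_area"])
        for key in ("min_dist_0_6", "min_dist_6_11", "min_dist_0_11"):
            assert compressed[key] < extended[key]

    def test_straight_area_matches_analytic_placement(self, straight26,
                                                      straight26_lattice):
        subunits, truth = straight26
        defs = truth.spec.domain_definitions()
        got = d1_triangle_gap(subunits, straight26_lattice, 1, defs)
        # analytic: D1 template centroid rotated/raised to k, k+6, k+11
        spec = truth.spec
        c_t = truth.template[30:70].mean(axis=0)
        k0 = _representative_pairs(straight26_lattice, 6)[1][0]
        def place(k):
            return (_rot_z(np.deg2rad(spec.twist_deg) * k) @ c_t
                    + np.array([0.0, 0.0, k * spec.rise]))
        c0, c6, c11 = place(k0), place(k0 + 6), place(k0 + 11)
        area = 0.5 * np.linalg.norm(np.cross(c6 - c0, c11 - c0))
        assert got["centroid_triangle_area"] == pytest.approx(area, rel=1e-9)

    def test_missing_neighbors_error(self, straight26, straight26_lattice):
        subunits, truth = straight26
        defs = truth.spec.domain_definitions()
        short = subunits[:11]
        lattice = index_lattice(short)
        with pytest.raises(InsufficientDataError):
            d1_triangle_gap(short, lattice, 1, defs)
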