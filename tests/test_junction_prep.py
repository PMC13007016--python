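"""Junction-prep geometry: dihedral setting, ring piercing, exclusions and
restraint potentials with analytic forces."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from peptoidbj._geometry import measure_angle, random_rotation
from peptoidbj.junction_prep import (RestraintSpec,
                                     detect_ring_piercing, field_from_bias,
                                     mitigation_exclusions,
                                     randomize_backbone_dihedrals,
                                     restraint_energy_forces, set_dihedral)
from peptoidbj.synthetic_data import build_peptoid_conformer


@pytest.fixture()
def conformer():
    return build_peptoid_conformer(4, {})


class TestDihedrals:
    def test_setting_current_value_is_identity(self, conformer):
        quad = conformer.dihedrals[1]["phi"]
        current = conformer.measure(quad)
        out = set_dihedral(conformer, quad, current)
        np.testing.assert_allclose(out.coords, conformer.coords, atol=1e-9)

    def test_set_measure_roundtrip(self, conformer):
        rng = np.random.default_rng(3)
        conf = conformer
        for res in conf.dihedrals:
            for name, quad in conf.dihedrals[res].items():
                target = float(rng.uniform(-179.9, 179.9))
                conf = set_dihedral(conf, quad, target)
                assert abs(conf.measure(quad) - target) < 1e-6

    def test_randomization_omega_convention(self, conformer):
        out = randomize_backbone_dihedrals(conformer, seed=11)
        for res, defs in conformer.dihedrals.items():
            if "omega" in defs:
                w = out.measure(defs["omega"])
                assert min(abs(w), abs(abs(w) - 180.0)) < 1e-6

    def test_randomization_preserves_bonds_and_angles(self, conformer):
        out = randomize_backbone_dihedrals(conformer, seed=5)
        for i, j in conformer.bonds:
            before = np.linalg.norm(conformer.position(i) - conformer.position(j))
            after = np.linalg.norm(out.position(i) - out.position(j))
            assert after == pytest.approx(before, abs=1e-9)
        # bond angles at every atom with two bonded neighbours
        adj = {}
        for i, j in conformer.bonds:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        for center, nbrs in adj.items():
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    before = measure_angle(conformer.position(nbrs[a]),
                                           conformer.position(center),
                                           conformer.position(nbrs[b]))
                    after = measure_angle(out.position(nbrs[a]),
                                          out.position(center),
                                          out.position(nbrs[b]))
                    assert after == pytest.approx(before, abs=1e-7)

    def test_randomization_deterministic(self, conformer):
        a = randomize_backbone_dihedrals(conformer, seed=2)
        b = randomize_backbone_dihedrals(conformer, seed=2)
        np.testing.assert_array_equal(a.coords, b.coords)


from conftest import make_hexagon as _hexagon
from conftest import make_ring_conformer as _ring_conformer


class TestRingPiercing:
    def test_distant_bond_no_piercing(self):
        conf = _ring_conformer(_hexagon(), [10.0, 0.0, -1.0], [10.0, 0.0, 1.0])
        assert detect_ring_piercing(conf) == []

    def test_perpendicular_through_centroid(self):
        conf = _ring_conformer(_hexagon(), [0.0, 0.0, -1.0], [0.0, 0.0, 1.0])
        hits = detect_ring_piercing(conf)
        assert len(hits) == 1
        np.testing.assert_allclose(hits[0][2], [0.0, 0.0, 0.0], atol=1e-9)

    def test_agrees_with_plane_polygon_oracle(self):
        rng = np.random.default_rng(17)
        n_checked = 0
        for _ in range(1000):
            rot = random_rotation(rng)
            shift = rng.uniform(-2, 2, 3)
            ring = _hexagon() @ rot.T + shift
            a = rng.uniform(-3, 3, 3)
            b = rng.uniform(-3, 3, 3)
            conf = _ring_conformer(ring, a, b)
            detected = len(detect_ring_piercing(conf)) > 0
            # oracle: segment-plane intersection + 2D point-in-polygon
            normal = rot @ np.array([0.0, 0.0, 1.0])
            denom = np.dot(normal, b - a)
            if abs(denom) < 1e-9:
                continue
            t = np.dot(normal, shift - a) / denom
            if not (0.0 <= t <= 1.0):
                expected = False
                margin = 1.0
            else:
                p = a + t * (b - a)
                local = rot.T @ (p - shift)
                poly = Polygon(_hexagon()[:, :2])
                expected = poly.contains(Point(local[0], local[1]))
                margin = poly.exterior.distance(Point(local[0], local[1]))
            if margin < 1e-6:
                continue  # boundary-degenerate configuration
            assert detected == expected
            n_checked += 1
        assert n_checked > 900

    def test_invariant_under_rigid_transform_and_endpoint_swap(self):
        rng = np.random.default_rng(23)
        ring = _hexagon()
        a, b = np.array([0.3, -0.2, -1.0]), np.array([-0.1, 0.4, 1.2])
        base = len(detect_ring_piercing(_ring_conformer(ring, a, b)))
        assert len(detect_ring_piercing(_ring_conformer(ring, b, a))) == base
        rot = random_rotation(rng)
        shift = rng.uniform(-5, 5, 3)
        conf = _ring_conformer(ring @ rot.T + shift, rot @ a + shift,
                               rot @ b + shift)
        assert len(detect_ring_piercing(conf)) == base

    def test_exclusion_pairs(self):
        conf = _ring_conformer(_hexagon(), [0.0, 0.0, -1.0], [0.0, 0.0, 1.0])
        hits = detect_ring_piercing(conf)
        excl = mitigation_exclusions(conf, hits)
        assert len(excl) == 6  # 2 bond atoms x 3 nearest ring atoms
        assert mitigation_exclusions(conf, []).pairs == set()
        # duplicated piercing entries collapse to the same pair set
        excl2 = mitigation_exclusions(conf, hits + hits)
        assert excl2.pairs == excl.pairs


class TestRestraints:
    def _spec(self, conf, **kw):
        s_ids = [a.id for a in conf.atoms if a.element == "S"]
        adj = {}
        for i, j in conf.bonds:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        lp = {s: tuple(sorted(adj[s])) for s in s_ids}
        return RestraintSpec(anchor_atom_ids=tuple(s_ids),
                             lone_pair_reference_atoms=lp, **kw)

    def test_zero_at_rest(self, conformer):
        s_ids = [a.id for a in conformer.atoms if a.element == "S"]
        sep = abs(conformer.position(s_ids[1])[2]
                  - conformer.position(s_ids[0])[2])
        # pick the axis along the actual S-S vector so the restraint is at rest
        v = conformer.position(s_ids[1]) - conformer.position(s_ids[0])
        spec = RestraintSpec(anchor_atom_ids=tuple(s_ids),
                             stage_target_A=float(np.linalg.norm(v)),
                             pulling_axis=v, k_anchor=10.0)
        e, f = restraint_energy_forces(conformer, None, spec)
        assert e == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_forces_match_finite_differences(self, conformer):
        rng = np.random.default_rng(31)
        charges = rng.uniform(-0.5, 0.5, len(conformer.atoms))
        spec = self._spec(conformer, stage_target_A=9.0, k_anchor=8.0,
                          field_V_per_m=field_from_bias(250.0, 1.0),
                          k_orient=3.0)
        h = 1e-5
        for trial in range(25):
            conf = conformer.copy()
            conf.coords = conf.coords + 0.2 * rng.standard_normal(conf.coords.shape)
            _, forces = restraint_energy_forces(conf, charges, spec)
            for ia in rng.choice(len(conf.atoms), 6, replace=False):
                for d in range(3):
                    cp = conf.copy()
                    cp.coords[ia, d] += h
                    cm = conf.copy()
                    cm.coords[ia, d] -= h
                    ep, _ = restraint_energy_forces(cp, charges, spec)
                    em, _ = restraint_energy_forces(cm, charges, spec)
                    fd = -(ep - em) / (2 * h)
                    scale = max(abs(fd), 1e-6)
                    assert abs(fd - forces[ia, d]) / scale < 1e-5

    def test_field_force_sum_is_total_charge_times_field(self, conformer):
        rng = np.random.default_rng(5)
        charges = rng.uniform(-0.4, 0.4, len(conformer.atoms))
        spec = self._spec(conformer, field_V_per_m=2.5e8, k_anchor=0.0)
        _, forces = restraint_energy_forces(conformer, charges, spec)
        from peptoidbj.junction_prep import _EV_PER_M_ANG_TO_KCAL
        expected = charges.sum() * 2.5e8 * _EV_PER_M_ANG_TO_KCAL
        assert forces[:, 2].sum() == pytest.approx(expected, rel=1e-9)
        # neutral molecule: zero net force
        neutral = charges - charges.mean()
        _, f2 = restraint_energy_forces(conformer, neutral, spec)
        assert abs(f2.sum(axis=0)).max() < 1e-12

    def test_anchor_term_invariant_to_axial_rotation(self, conformer):
        from peptoidbj._geometry import rotation_about_axis
        spec = self._spec(conformer, stage_target_A=6.0, k_anchor=5.0)
        e1, _ = restraint_energy_forces(conformer, None, spec)
        rot = rotation_about_axis([0, 0, 1], 73.0)
        conf = conformer.copy()
        conf.coords = conformer.coords @ rot.T
        e2, _ = restraint_energy_forces(conf, None, spec)
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_field_invariant_to_perpendicular_translation(self, conformer):
        rng = np.random.default_rng(9)
        charges = rng.uniform(-0.3, 0.3, len(conformer.atoms))
        spec = self._spec(conformer, field_V_per_m=1e8, k_anchor=0.0)
        e1, _ = restraint_energy_forces(conformer, charges, spec)
        conf = conformer.copy()
        conf.coords = conformer.coords + np.array([3.0, -2.0, 0.0])
        e2, _ = restraint_energy_forces(conf, charges, spec)
        assert e2 == pytest.approx(e1, rel=1e-9)

    def test_missing_charges_rejected(self, conformer):
        spec = self._spec(conformer, field_V_per_m=1e8)
        with pytest.raises(ValueError):
            restraint_energy_forces(conformer, None, spec)

    def test_bias_across_nm_gap_is_1e8_order(self):
        field = field_from_bias(250.0, 1.0)
        assert field == pytest.approx(2.5e8)
        assert np.floor(np.log10(field)) == 8
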