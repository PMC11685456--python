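"""Rotation/bend/displacement geometry, SASA and interface mapping."""

import numpy as np
import pytest

from hspdyn import (Atom, ContactCutoffs, DegenerateGeometryError,
                    DomainDefinition, SASAParams, Structure, angle_between,
                    buried_surface_area, centroid_displacement, contact_map,
                    make_bent_stalk, make_ideal_helix, make_rotated_pair,
                    make_two_domain_complex, principal_axis, sasa,
                    sasa_of_coords, select_atoms, stalk_bend_angle,
                    subdomain_rotation)
from conftest import random_rotation


def two_sphere_sasa_analytic(r1, r2, d, probe):
    """Closed-form accessible area of two intersecting expanded spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * (R1 ** 2 + R2 ** 2)
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    x2 = d - x1
    h1 = R1 - x1
    h2 = R2 - x2
    return (4 * np.pi * R1 ** 2 - 2 * np.pi * R1 * h1
            + 4 * np.pi * R2 ** 2 - 2 * np.pi * R2 * h2)


class TestPrincipalAxis:
    def test_collinear_points_along_z(self):
        pts = np.outer(np.arange(5.0), [0, 0, 1.0]) + [[0.01, 0, 0]] * 5
        pts[2, 0] = -0.01  # break exact collinearity, keep z dominant
        axis = principal_axis(pts)
        assert abs(axis[2]) > 0.9999

    def test_ideal_helix_axis_within_one_degree(self, helix30, helix_ca_domain):
        ca = select_atoms(helix30, helix_ca_domain).coords()
        axis = principal_axis(ca)
        assert angle_between(axis, [0, 0, 1]) < 1.0

    def test_orientation_follows_first_to_last(self, helix30, helix_ca_domain):
        ca = select_atoms(helix30, helix_ca_domain).coords()
        assert principal_axis(ca)[2] > 0
        assert principal_axis(ca[::-1])[2] < 0

    def test_matches_dense_direction_search(self, rng):
        # noisy rod along a random direction
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = np.linspace(0, 20, 60)
        pts = np.outer(t, direction) + rng.normal(0, 0.4, (60, 3))
        axis = principal_axis(pts)
        # brute force: maximise projected variance over a dense sphere lattice
        from hspdyn.geometry import _golden_spiral_points
        dirs = _golden_spiral_points(200_000)
        centered = pts - pts.mean(axis=0)
        var = np.einsum("nd,kd->kn", centered, dirs)
        best = dirs[np.argmax((var ** 2).sum(axis=1))]
        assert min(angle_between(axis, best),
                   angle_between(axis, -best)) < 0.5

    def test_isotropic_set_raises(self, rng):
        from hspdyn.geometry import _golden_spiral_points
        with pytest.raises(DegenerateGeometryError):
            principal_axis(_golden_spiral_points(500))


@pytest.fixture(scope="module")
def base():
    return make_ideal_helix(40)


class TestSubdomainRotation:
    ALIGN = DomainDefinition("align", "A", ((1, 19),))
    PROBE = DomainDefinition("probe", "A", ((20, 40),))

    def _pair_selections(self, a, b):
        return ((select_atoms(a, self.ALIGN), select_atoms(b, self.ALIGN)),
                (select_atoms(a, self.PROBE), select_atoms(b, self.PROBE)))

    def test_identical_structures_zero(self, base):
        align, probe = self._pair_selections(base, base)
        assert subdomain_rotation(base, base, align, probe) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("angle", [1.0, 20.0, 90.0, 179.0])
    def test_recovers_constructed_rotation(self, base, angle):
        a, b = make_rotated_pair(base, self.PROBE, angle, seed=17)
        align, probe = self._pair_selections(a, b)
        got = subdomain_rotation(a, b, align, probe, method="axis-angle")
        assert got == pytest.approx(angle, abs=0.1)

    def test_helix_axis_method_on_bent_probe(self, base):
        # rotate the probe helix about an axis perpendicular to its own axis:
        # the principal-axis angle then equals the rotation angle
        sel = select_atoms(base, self.PROBE)
        coords = base.coords.copy()
        centroid = sel.coords().mean(axis=0)
        theta = np.radians(20.0)
        Ry = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                       [-np.sin(theta), 0, np.cos(theta)]])
        coords[0, sel.indices] = (coords[0, sel.indices] - centroid) @ Ry.T + centroid
        b = base.with_coords(coords)
        align, probe = self._pair_selections(base, b)
        got = subdomain_rotation(base, b, align, probe, method="helix-axis")
        assert got == pytest.approx(20.0, abs=1.0)

    def test_pairing_mismatch_raises(self, base):
        a, b = make_rotated_pair(base, self.PROBE, 10.0, seed=1)
        align = (select_atoms(a, self.ALIGN),
                 select_atoms(b, DomainDefinition("x", "A", ((1, 10),))))
        probe = (select_atoms(a, self.PROBE), select_atoms(b, self.PROBE))
        with pytest.raises(ValueError):
            subdomain_rotation(a, b, align, probe)


class TestStalkBend:
    STALK = DomainDefinition("stalk", "A", ((1, 40),))

    def test_straight_helix_is_straight(self):
        s = make_ideal_helix(40)
        assert stalk_bend_angle(s, self.STALK, 20) == pytest.approx(0.0, abs=1.0)

    @pytest.mark.parametrize("bend", [5.0, 13.0, 25.0, 26.0, 40.0])
    def test_recovers_constructed_bend(self, bend):
        s = make_bent_stalk(40, bend, 20)
        assert stalk_bend_angle(s, self.STALK, 20) == pytest.approx(bend, abs=1.0)

    def test_external_straight_reference(self):
        bent = make_bent_stalk(40, 25.0, 20)
        straight = make_ideal_helix(40)
        got = stalk_bend_angle(bent, self.STALK, 20, reference=straight)
        assert got == pytest.approx(25.0, abs=1.0)

    def test_too_short_segment_raises(self):
        s = make_ideal_helix(40)
        with pytest.raises(ValueError):
            stalk_bend_angle(s, self.STALK, 4)


class TestCentroidDisplacement:
    def test_identical_structures_zero(self, helix30):
        d = DomainDefinition("d", "A", ((1, 15),))
        p = DomainDefinition("p", "A", ((16, 30),))
        pair = lambda dom: (select_atoms(helix30, dom), select_atoms(helix30, dom))
        assert centroid_displacement(helix30, helix30, pair(d), pair(p)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_three_four_translation_gives_five(self, helix30):
        d = DomainDefinition("d", "A", ((1, 15),))
        p = DomainDefinition("p", "A", ((16, 30),))
        coords = helix30.coords.copy()
        sel = select_atoms(helix30, p)
        coords[0, sel.indices] += np.array([3.0, 4.0, 0.0])
        moved = helix30.with_coords(coords)
        align = (select_atoms(helix30, d), select_atoms(moved, d))
        probe = (select_atoms(helix30, p), select_atoms(moved, p))
        assert centroid_displacement(helix30, moved, align, probe) == \
            pytest.approx(5.0, abs=1e-6)


class TestSasa:
    def test_single_carbon_analytic_sphere(self):
        areas = sasa_of_coords(np.zeros((1, 3)), np.array([1.7]), SASAParams())
        assert areas[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-12)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_spheres_match_spherical_cap_formula(self, d):
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = sasa_of_coords(coords, np.array([1.7, 1.7]), SASAParams())
        expected = two_sphere_sasa_analytic(1.7, 1.7, d, 1.4)
        assert areas.sum() == pytest.approx(expected, rel=0.02)

    def test_point_count_convergence(self, rng):
        coords = rng.normal(0, 3.0, (50, 3))
        radii = np.full(50, 1.7)
        a1 = sasa_of_coords(coords, radii, SASAParams(points_per_atom=960))
        a2 = sasa_of_coords(coords, radii, SASAParams(points_per_atom=10000))
        scale = 4 * np.pi * 3.1 ** 2
        assert np.max(np.abs(a1 - a2)) / scale < 0.02

    def test_rigid_transform_invariance(self, rng):
        # fine sampling so lattice-orientation noise sits below the 0.5% band
        params = SASAParams(points_per_atom=10000)
        coords = rng.normal(0, 3.0, (20, 3))
        radii = np.full(20, 1.6)
        base = sasa_of_coords(coords, radii, params)
        R = random_rotation(rng)
        moved = sasa_of_coords(coords @ R.T + 7.0, radii, params)
        assert np.abs(moved - base).max() / (4 * np.pi * 3.0 ** 2) < 0.005

    def test_unknown_element_policy(self, helix30):
        strict = SASAParams(fallback_radius=None, radii={"XX": 1.0})
        with pytest.raises(KeyError):
            sasa(helix30, strict)
        lenient = SASAParams(radii={})
        areas = sasa(helix30, lenient)  # falls back with a warning
        assert np.all(areas >= 0)


class TestBuriedSurfaceArea:
    def _chain_selections(self, struct):
        a = select_atoms(struct, DomainDefinition("A", "A", ((1, 12),), None))
        b = select_atoms(struct, DomainDefinition("B", "B", ((1, 12),), None))
        return a, b

    def test_far_partners_bury_nothing(self):
        c = make_two_domain_complex(12, 12, 100.0, seed=4)
        a, b = self._chain_selections(c)
        assert buried_surface_area(c, a, b) == pytest.approx(0.0, abs=1e-6)

    def test_two_atom_toy_matches_analytic(self):
        atoms = [Atom(1, "C1", "C", "LIG", 1, "", "A", is_hetero=True),
                 Atom(2, "C1", "C", "LIG", 1, "", "B", is_hetero=True)]
        d = 3.0
        s = Structure(atoms, np.array([[[0.0, 0, 0], [d, 0, 0]]]))
        from hspdyn import AtomSelection
        sel_a = AtomSelection(s, np.array([0]))
        sel_b = AtomSelection(s, np.array([1]))
        total = buried_surface_area(s, sel_a, sel_b, convention="total")
        isolated = 2 * 4 * np.pi * 3.1 ** 2
        expected = isolated - two_sphere_sasa_analytic(1.7, 1.7, d, 1.4)
        assert total == pytest.approx(expected, rel=0.02)
        half = buried_surface_area(s, sel_a, sel_b, convention="per-interface")
        assert half == pytest.approx(total / 2)

    def test_symmetric_and_monotone_under_approach(self):
        areas = []
        for sep in [30.0, 14.0, 10.0, 7.0]:
            c = make_two_domain_complex(12, 12, sep, seed=4)
            a, b = self._chain_selections(c)
            ab = buried_surface_area(c, a, b)
            assert ab == pytest.approx(buried_surface_area(c, b, a), abs=1e-9)
            areas.append(ab)
        assert all(x <= y + 1e-9 for x, y in zip(areas, areas[1:]))

    def test_overlapping_selections_raise(self, helix30):
        from hspdyn import select_all
        sel = select_all(helix30)
        with pytest.raises(ValueError):
            buried_surface_area(helix30, sel, sel)


class TestContactMap:
    def _arg_asp_pair(self, separation):
        """Minimal Arg guanidinium / Asp carboxylate pair."""
        atoms = [Atom(1, "NH1", "N", "ARG", 574, "", "A"),
                 Atom(2, "CZ", "C", "ARG", 574, "", "A"),
                 Atom(3, "OD1", "O", "ASP", 171, "", "B"),
                 Atom(4, "CG", "C", "ASP", 171, "", "B")]
        coords = np.array([[[0.0, 0, 0], [-1.3, 0, 0],
                            [separation, 0, 0], [separation + 1.3, 0, 0]]])
        s = Structure(atoms, coords)
        from hspdyn import AtomSelection
        return s, AtomSelection(s, np.array([0, 1]), "arg"), \
            AtomSelection(s, np.array([2, 3]), "asp")

    def test_distant_partners_give_empty_list(self):
        s, a, b = self._arg_asp_pair(50.0)
        report = contact_map(s, a, b)
        assert report.contacts == []

    def test_constructed_salt_bridge(self):
        s, a, b = self._arg_asp_pair(3.0)
        report = contact_map(s, a, b)
        assert len(report.contacts) == 1
        contact = report.contacts[0]
        assert contact.contact_class == "salt-bridge"
        assert contact.min_distance == pytest.approx(3.0)
        assert contact.residue_a[1] == 574 and contact.residue_b[1] == 171

    def test_classification_downgrades_with_distance(self):
        s, a, b = self._arg_asp_pair(4.2)  # beyond salt-bridge/hbond cutoffs
        report = contact_map(s, a, b)
        assert report.contacts[0].contact_class == "vdw"

    def test_interface_of_synthetic_complex_has_contacts_and_bsa(self, complex_close):
        a = select_atoms(complex_close, DomainDefinition("A", "A", ((1, 12),), None))
        b = select_atoms(complex_close, DomainDefinition("B", "B", ((1, 12),), None))
        report = contact_map(complex_close, a, b, sasa_params=SASAParams())
        assert len(report.contacts) > 0
        assert report.buried_area > 0
        assert report.buried_area_convention == "per-interface"
        payload = report.to_dict()
        assert payload["n_contacts"] == len(report.contacts)
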