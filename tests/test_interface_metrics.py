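import numpy as np
import pytest

from mcwound.interface_metrics import (
    buried_interface_area,
    catalytic_geometry,
    compute_sasa,
    count_clashes,
    sphere_points,
)
from mcwound.structure_io import Atom, CatalyticSiteSpec, StructureModel
from mcwound.synthetic_data import brute_force_clash_count


def carbon(serial, chain, coord, res_seq=None):
    return Atom(serial, "CA", "C", "ALA", res_seq or serial, chain, tuple(coord))


def pair_model(distance):
    """Two single-carbon chains separated along x."""
    return StructureModel(
        [carbon(1, "A", (0.0, 0.0, 0.0)), carbon(2, "B", (distance, 0.0, 0.0))],
        "A",
        "B",
    )


def cloud_model(rng, n_a=50, n_b=50, spread=6.0, offset=3.0):
    """Two random interpenetrating carbon clouds."""
    atoms = [
        carbon(i + 1, "A", c) for i, c in enumerate(rng.normal(0, spread, (n_a, 3)))
    ]
    atoms += [
        carbon(n_a + i + 1, "B", c + [offset, 0, 0])
        for i, c in enumerate(rng.normal(0, spread, (n_b, 3)))
    ]
    return StructureModel(atoms, "A", "B")


# Analytic two-sphere SASA: equal radii R, centre distance d < 2R.
# Each sphere loses one spherical cap of height h = R - d/2, area 2*pi*R*h.
def two_sphere_exposed_total(R, d):
    cap = 2.0 * np.pi * R * (R - d / 2.0)
    return 2.0 * (4.0 * np.pi * R * R - cap)


class TestSpherePoints:
    def test_single_point_is_unit(self):
        pts = sphere_points(1)
        assert pts.shape == (1, 3)
        assert np.linalg.norm(pts[0]) == pytest.approx(1.0, abs=1e-12)

    def test_norms_are_one(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_points_are_balanced(self):
        # Near-uniform coverage => centroid close to the origin.
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 0.05

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sphere_points(0)


class TestSasa:
    def test_single_atom_matches_closed_form(self, radii):
        res = compute_sasa([carbon(1, "A", (0, 0, 0))], radii)
        exact = 4.0 * np.pi * 3.1**2
        assert res.total_area == pytest.approx(exact, rel=0.01)
        assert res.per_atom_area[1] == pytest.approx(res.total_area)

    def test_disjoint_atoms_are_additive(self, radii):
        model = pair_model(100.0)
        res = compute_sasa(model.atoms, radii)
        assert res.total_area == pytest.approx(2 * 4.0 * np.pi * 3.1**2, rel=0.01)

    def test_two_overlapping_spheres_match_cap_formula(self, radii):
        model = pair_model(3.1)
        res = compute_sasa(model.atoms, radii)
        assert res.total_area == pytest.approx(two_sphere_exposed_total(3.1, 3.1), rel=0.01)

    def test_quadrature_error_shrinks_with_density(self, radii):
        exact = two_sphere_exposed_total(3.1, 3.1)
        axis = np.array([1.0, 2.0, 3.0])
        axis /= np.linalg.norm(axis)
        atoms = [carbon(1, "A", (0, 0, 0)), carbon(2, "B", 3.1 * axis)]
        errors = [
            abs(compute_sasa(atoms, radii, n_points=n).total_area - exact) / exact
            for n in (240, 960, 3840)
        ]
        assert errors[2] < errors[1] < errors[0]
        assert errors[1] < 0.01

    def test_per_atom_bounded_by_full_sphere(self, radii):
        rng = np.random.default_rng(5)
        model = cloud_model(rng, 20, 20, spread=3.0)
        res = compute_sasa(model.atoms, radii)
        full = 4.0 * np.pi * 3.1**2
        for area in res.per_atom_area.values():
            assert 0.0 <= area <= full + 1e-9
        assert res.total_area == pytest.approx(sum(res.per_atom_area.values()))

    def test_matches_independent_library_estimate(self, radii):
        # Cross-check against biotite's Shrake-Rupley on a random cloud.
        biotite_struct = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(17)
        model = cloud_model(rng, 30, 30, spread=4.0)
        ours = compute_sasa(model.atoms, radii, n_points=3840).total_area
        arr = biotite_struct.AtomArray(len(model.atoms))
        arr.coord = model.coords().astype(np.float32)
        arr.element = np.array([a.element for a in model.atoms])
        theirs = biotite_struct.sasa(
            arr,
            probe_radius=1.4,
            point_number=3840,
            vdw_radii=np.full(len(model.atoms), 1.70),
        ).sum()
        assert ours == pytest.approx(theirs, rel=0.02)


class TestBuriedInterfaceArea:
    def test_far_separated_chains_bury_nothing(self, radii):
        assert buried_interface_area(pair_model(100.0), radii) == 0.0

    def test_two_carbon_contact_matches_cap_oracle(self, radii):
        # Each chain alone: full sphere; complex: cap formula.
        full = 4.0 * np.pi * 3.1**2
        expected = (2 * full - two_sphere_exposed_total(3.1, 3.1)) / 2.0
        bsa = buried_interface_area(pair_model(3.1), radii)
        assert bsa == pytest.approx(expected, rel=0.02)

    def test_role_swap_is_symmetric(self, radii):
        rng = np.random.default_rng(9)
        model = cloud_model(rng, 15, 15, spread=3.0)
        swapped = StructureModel(model.atoms, "B", "A")
        assert buried_interface_area(model, radii) == pytest.approx(
            buried_interface_area(swapped, radii)
        )

    def test_halving_switch(self, radii):
        model = pair_model(3.1)
        half = buried_interface_area(model, radii, halve_bsa=True)
        whole = buried_interface_area(model, radii, halve_bsa=False)
        assert whole == pytest.approx(2 * half)

    def test_rigid_motion_invariance(self, radii):
        rng = np.random.default_rng(23)
        model = cloud_model(rng, 15, 15, spread=3.0)
        base = buried_interface_area(model, radii)
        # Rotate the whole complex by an arbitrary rotation + translation.
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = StructureModel(
            [
                Atom(a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                     tuple(rot @ np.asarray(a.coord) + [10.0, -5.0, 2.0]))
                for a in model.atoms
            ],
            "A",
            "B",
        )
        assert buried_interface_area(moved, radii) == pytest.approx(base, rel=0.02)


class TestClashes:
    @pytest.mark.parametrize(
        "distance,expected",
        [(3.5, 0), (3.0, 1), (2.9, 1), (3.01, 0)],  # C+C overlap = 3.4 - d
    )
    def test_threshold_arithmetic(self, radii, distance, expected):
        report = count_clashes(pair_model(distance), radii)
        assert report.clash_count == expected
        if expected:
            assert report.pairs[0][2] == pytest.approx(3.4 - distance)

    def test_matches_brute_force_on_random_clouds(self, radii):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            model = cloud_model(rng)
            report = count_clashes(model, radii)
            assert report.clash_count == brute_force_clash_count(model, radii)
            assert report.clash_count == len(report.pairs)
            assert all(ov >= report.overlap_threshold for *_, ov in report.pairs)

    def test_intra_chain_contacts_not_counted(self, radii):
        atoms = [
            carbon(1, "A", (0, 0, 0)),
            carbon(2, "A", (1.0, 0, 0)),  # heavy intra-chain overlap
            carbon(3, "B", (50, 0, 0)),
        ]
        model = StructureModel(atoms, "A", "B")
        assert count_clashes(model, radii).clash_count == 0


class TestCatalyticGeometry:
    def make_model(self, substrate_atoms):
        enzyme = [
            Atom(1, "SG", "S", "CYS", 139, "A", (0.0, 0.0, 0.0)),
            carbon(2, "A", (-3.0, 0, 0)),
        ]
        return StructureModel(enzyme + substrate_atoms, "A", "B")

    def test_min_distance_is_euclidean_min(self):
        model = self.make_model(
            [carbon(10, "B", (5.0, 0, 0), 1), carbon(11, "B", (0, 4.4, 0), 2)]
        )
        geom = catalytic_geometry(model, CatalyticSiteSpec("A", 139, "SG"))
        assert geom.min_distance == pytest.approx(4.4)
        assert geom.nearest_atom == 11

    def test_candidates_ranked_by_sg_to_carbonyl_distance(self):
        substrate = [
            Atom(10, "O", "O", "LYS", 1, "B", (3.0, 0, 0)),
            Atom(11, "O", "O", "ARG", 2, "B", (6.0, 0, 0)),
            Atom(12, "CA", "C", "LYS", 1, "B", (3.5, 1, 0)),
        ]
        geom = catalytic_geometry(
            self.make_model(substrate), CatalyticSiteSpec("A", 139, "SG")
        )
        assert [(c[0], c[1]) for c in geom.site_candidates] == [(1, "LYS"), (2, "ARG")]
        assert geom.site_candidates[0][2] == pytest.approx(3.0)

    def test_tied_distances_break_by_residue_number(self):
        substrate = [
            Atom(10, "O", "O", "ARG", 7, "B", (0, 3.0, 0)),
            Atom(11, "O", "O", "LYS", 2, "B", (0, -3.0, 0)),
        ]
        geom = catalytic_geometry(
            self.make_model(substrate), CatalyticSiteSpec("A", 139, "SG")
        )
        assert [c[0] for c in geom.site_candidates] == [2, 7]

    def test_no_arg_lys_gives_empty_candidates(self):
        substrate = [
            Atom(10, "O", "O", "GLY", 1, "B", (3.0, 0, 0)),
            carbon(11, "B", (4.0, 0, 0), 2),
        ]
        geom = catalytic_geometry(
            self.make_model(substrate), CatalyticSiteSpec("A", 139, "SG")
        )
        assert geom.site_candidates == []
        assert np.isfinite(geom.min_distance)
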