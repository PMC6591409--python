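"""Ring radii, asymmetry, hydrogen inference, permeant sizing, RMSD."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bestgate.exceptions import GeometryError, InsufficientOverlapError
from bestgate.pore_geometry import (
    ConstrictionRing,
    GeometryConstants,
    IonTable,
    aromatic_hydrogens,
    classify_permeants,
    pentagon_edges,
    place_aromatic_hydrogens,
    pore_profile,
    ring_asymmetry,
    ring_radius,
    superpose_rmsd,
)
from bestgate.structure_io import Atom, StructureModel
from bestgate.synthetic_data import (
    PentamerSpec,
    RingSpec,
    expected_fixture_radius,
    make_pentamer_fixture,
)
from conftest import random_ring_points

SIN36 = math.sin(math.radians(36.0))


def regular_pentagon(circumradius, z=0.0, phase=0.0):
    ang = phase + 2 * np.pi * np.arange(5) / 5
    return np.column_stack(
        [circumradius * np.cos(ang), circumradius * np.sin(ang),
         np.full(5, z)]
    )


def make_ring(points, probe=2.0, resnum=180, resname="ILE", atom="CD1"):
    return ConstrictionRing(resnum, resname, atom, np.asarray(points), probe)


def oracle_radius(points, probe, factor=1.17):
    """Brute-force oracle: all 10 pairwise distances, adjacent 5 selected
    by angular order about the centroid in the dominant-variance plane."""
    pts = np.asarray(points, float)
    dist = {}
    for i in range(5):
        for j in range(i + 1, 5):
            dist[(i, j)] = dist[(j, i)] = np.linalg.norm(pts[i] - pts[j])
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    w, v = np.linalg.eigh(cov)
    e1, e2 = v[:, -1], v[:, -2]  # two largest-variance directions
    ang = [math.atan2((p - centroid) @ e2, (p - centroid) @ e1) for p in pts]
    order = sorted(range(5), key=lambda i: ang[i])
    edges = [dist[(order[k], order[(k + 1) % 5])] for k in range(5)]
    return sum(edges) / (5 * factor) - probe


class TestRingRadius:
    def test_regular_pentagon_closed_form(self):
        # circumradius 3.0, methyl probe: edges 2*3*sin36 = 3.5267 A,
        # radius = 3.5267/1.17 - 2.00 = 1.014 A
        ring = make_ring(regular_pentagon(3.0))
        r = ring_radius(ring)
        assert r == pytest.approx(2 * 3.0 * SIN36 / 1.17 - 2.0, abs=1e-12)
        assert r == pytest.approx(1.014, abs=5e-4)

    def test_exact_constants_return_circumradius_minus_probe(self):
        ring = make_ring(regular_pentagon(3.0))
        r = ring_radius(ring, GeometryConstants.exact())
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_rings(self, rng):
        for _ in range(1000):
            pts = random_ring_points(rng)
            ring = make_ring(pts)
            assert ring_radius(ring) == pytest.approx(
                oracle_radius(pts, 2.0), abs=1e-9
            )

    def test_invariant_to_rigid_motion_and_point_order(self, rng):
        for _ in range(50):
            pts = random_ring_points(rng)
            base = ring_radius(make_ring(pts))
            rot = Rotation.random(random_state=np.random.RandomState(11))
            moved = rot.apply(pts) + rng.normal(0, 10, 3)
            perm = rng.permutation(5)
            assert ring_radius(make_ring(moved[perm])) == pytest.approx(
                base, abs=1e-9
            )

    def test_strictly_increasing_in_circumradius(self):
        radii = [ring_radius(make_ring(regular_pentagon(r)))
                 for r in np.linspace(1.0, 6.0, 12)]
        assert np.all(np.diff(radii) > 0)

    def test_overclosed_ring_reports_negative_radius(self):
        r = ring_radius(make_ring(regular_pentagon(1.0)))
        assert r < 0

    def test_coincident_points_raise(self):
        pts = regular_pentagon(3.0)
        pts[1] = pts[0]
        with pytest.raises(GeometryError, match="coincident"):
            ring_radius(make_ring(pts))

    def test_pentagon_edges_recovers_adjacency_from_shuffled_points(self, rng):
        pts = regular_pentagon(4.2, phase=0.3)
        edges = pentagon_edges(pts[rng.permutation(5)])
        assert np.allclose(edges, 2 * 4.2 * SIN36, atol=1e-9)


class TestRingAsymmetry:
    def test_c5_symmetric_ring_has_zero_spread_and_cv(self):
        asym = ring_asymmetry(make_ring(regular_pentagon(3.394)))
        assert asym.spread == pytest.approx(0.0, abs=1e-9)
        assert asym.cv == pytest.approx(0.0, abs=1e-9)

    def test_radial_displacement_appears_as_spread(self):
        spec = PentamerSpec(
            rings=(RingSpec(180, "ILE", circumradius=3.394,
                            displaced_point=2, displacement=0.7),),
        )
        model = make_pentamer_fixture(spec)
        from bestgate.structure_io import select_ring

        asym = ring_asymmetry(select_ring(model, 180))
        # one point moved 0.7 A radially outward also drags the centroid,
        # so compare against the constructed geometry, not just 0.7
        pts = select_ring(model, 180).points
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        assert asym.spread == pytest.approx(d.max() - d.min(), abs=1e-9)
        assert asym.spread == pytest.approx(0.7, abs=0.15)
        assert asym.spread > 0.5

    def test_zero_spread_iff_equal_centroid_distances(self, rng):
        pts = random_ring_points(rng)
        asym = ring_asymmetry(make_ring(pts))
        d = asym.per_point_centroid_distances
        assert (asym.spread < 1e-9) == bool(np.allclose(d, d[0], atol=1e-9))


class TestAromaticHydrogens:
    def test_ideal_benzene_hydrogens_coplanar_at_bond_length(self):
        ang = np.pi / 3 * np.arange(6)
        carbons = np.column_stack(
            [1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)]
        )
        hs = aromatic_hydrogens(carbons)
        assert np.allclose(hs[:, 2], 0.0, atol=1e-6)  # coplanar
        assert np.allclose(
            np.linalg.norm(hs - carbons, axis=1), 1.08, atol=1e-9
        )
        # hydrogens extend radially outward
        assert np.allclose(np.linalg.norm(hs[:, :2], axis=1), 2.47, atol=1e-9)

    def test_rotated_ring_gives_rotated_hydrogens(self, rng):
        ang = np.pi / 3 * np.arange(6)
        carbons = np.column_stack(
            [1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)]
        )
        rot = Rotation.random(random_state=np.random.RandomState(3))
        shift = rng.normal(0, 5, 3)
        hs_moved = aromatic_hydrogens(rot.apply(carbons) + shift)
        assert np.allclose(
            hs_moved, rot.apply(aromatic_hydrogens(carbons)) + shift,
            atol=1e-9,
        )

    def test_per_chain_choice_is_nearest_the_pore_axis(self, multi_ring_model):
        carbons = {}
        for cid in "ABCDE":
            res = multi_ring_model.residue_atoms(cid, 70)
            carbons[cid] = np.array(
                [res[n].position
                 for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
            )
        chosen = place_aromatic_hydrogens(carbons)
        axis_xy = np.mean(
            [c.mean(axis=0)[:2] for c in carbons.values()], axis=0
        )
        for cid, h in chosen.items():
            others = aromatic_hydrogens(carbons[cid])
            d_chosen = np.linalg.norm(h[:2] - axis_xy)
            assert all(
                d_chosen <= np.linalg.norm(o[:2] - axis_xy) + 1e-9
                for o in others
            )

    def test_missing_ring_carbon_raises(self):
        from bestgate.exceptions import MissingAtomError

        with pytest.raises(MissingAtomError):
            aromatic_hydrogens(np.zeros((5, 3)))


class TestClassifyPermeants:
    @pytest.mark.parametrize(
        "radius,dehydrated,hydrated",
        [
            (0.9, (), ()),                      # closed aperture: nothing fits
            (1.9, ("Cl-",), ()),                # only dehydrated Cl-
            (2.0, ("Cl-", "Br-"), ()),
            (2.6, ("Cl-", "Br-", "I-", "SCN-", "CH3SO3-"), ()),  # open gate
            (3.3, ("Cl-", "Br-", "I-", "SCN-", "CH3SO3-"),
             ("Cl-", "Br-", "I-")),
            (-0.5, (), ()),                     # overclosed
        ],
    )
    def test_size_filter(self, radius, dehydrated, hydrated):
        cls = classify_permeants(radius)
        assert set(cls.passes_dehydrated) == set(dehydrated)
        assert set(cls.passes_hydrated) == set(hydrated)

    def test_inclusive_boundary(self):
        table = IonTable()
        cls = classify_permeants(table.dehydrated["CH3SO3-"])
        assert "CH3SO3-" in cls.passes_dehydrated


class TestSuperposeRmsd:
    def test_self_rmsd_is_zero(self, multi_ring_model):
        assert superpose_rmsd(multi_ring_model, multi_ring_model) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_rigidly_moved_copy_has_zero_rmsd(self, multi_ring_model, rng):
        rot = Rotation.random(random_state=np.random.RandomState(5))
        shift = rng.normal(0, 20, 3)
        moved = StructureModel(
            "moved",
            [
                Atom(a.chain_id, a.residue_number, a.residue_name,
                     a.atom_name, a.alt_loc, a.element,
                     rot.apply(a.position) + shift, a.occupancy)
                for a in multi_ring_model.atoms
            ],
        )
        assert superpose_rmsd(multi_ring_model, moved) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_symmetric_in_arguments(self, multi_ring_model, rng):
        perturbed = StructureModel(
            "pert",
            [
                Atom(a.chain_id, a.residue_number, a.residue_name,
                     a.atom_name, a.alt_loc, a.element,
                     a.position + rng.normal(0, 0.5, 3), a.occupancy)
                for a in multi_ring_model.atoms
            ],
        )
        ab = superpose_rmsd(multi_ring_model, perturbed)
        ba = superpose_rmsd(perturbed, multi_ring_model)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab > 0

    def test_agrees_with_biotite_superimposition(self, multi_ring_model, rng):
        biotite_struc = pytest.importorskip("biotite.structure")
        ca = [a for a in multi_ring_model.atoms if a.atom_name == "CA"]
        fixed = np.array([a.position for a in ca])
        rot = Rotation.random(random_state=np.random.RandomState(9))
        mobile = rot.apply(fixed + rng.normal(0, 0.4, fixed.shape)) + 3.0

        def to_biotite(coords):
            arr = biotite_struc.AtomArray(len(coords))
            arr.coord = coords.astype(np.float32)
            return arr

        fitted, _ = biotite_struc.superimpose(
            to_biotite(fixed), to_biotite(mobile)
        )
        expected = float(biotite_struc.rmsd(to_biotite(fixed), fitted))

        moved = StructureModel(
            "m",
            [
                Atom(a.chain_id, a.residue_number, a.residue_name,
                     a.atom_name, a.alt_loc, a.element, pos, a.occupancy)
                for a, pos in zip(ca, mobile)
            ],
        )
        ref = StructureModel("r", list(ca))
        assert superpose_rmsd(ref, moved) == pytest.approx(expected, abs=1e-4)

    def test_insufficient_overlap_raises(self):
        a = StructureModel(
            "a", [Atom("A", 1, "ALA", "CA", "", "C", np.zeros(3))]
        )
        b = StructureModel(
            "b", [Atom("A", 1, "ALA", "CA", "", "C", np.ones(3))]
        )
        with pytest.raises(InsufficientOverlapError):
            superpose_rmsd(a, b)


class TestPoreProfile:
    def test_aperture_is_the_narrowest_ring(self, multi_ring_model):
        report = pore_profile(multi_ring_model, [62, 66, 70, 180])
        assert [r.residue_number for r in report.records] == [62, 66, 70, 180]
        radii = {r.residue_number: r.radius for r in report.records}
        assert min(radii, key=radii.get) == 180

    def test_known_circumradii_order_the_radii(self):
        spec = PentamerSpec(
            rings=(
                RingSpec(10, "ILE", circumradius=3.0),
                RingSpec(20, "ILE", circumradius=4.5, z=10.0),
            ),
        )
        report = pore_profile(make_pentamer_fixture(spec), [10, 20])
        r10, r20 = (rec.radius for rec in report.records)
        assert r10 == pytest.approx(expected_fixture_radius(3.0, 2.0), abs=1e-9)
        assert r20 == pytest.approx(expected_fixture_radius(4.5, 2.0), abs=1e-9)
        assert r10 < r20

    def test_empty_residue_list_gives_empty_report(self, multi_ring_model):
        report = pore_profile(multi_ring_model, [])
        assert report.records == []

    def test_per_residue_failure_recorded_not_raised(self, multi_ring_model):
        report = pore_profile(multi_ring_model, [180, 999])
        by_res = {r.residue_number: r for r in report.records}
        assert by_res[180].error is None and by_res[180].radius is not None
        assert by_res[999].error is not None and by_res[999].radius is None

    def test_reference_rmsd_included(self, multi_ring_model):
        report = pore_profile(
            multi_ring_model, [180], reference=multi_ring_model
        )
        assert report.rmsd_vs_reference == pytest.approx(0.0, abs=1e-9)
        assert report.to_dict()["rmsd_vs_reference_A"] == pytest.approx(
            0.0, abs=1e-9
        )
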