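"""SASA, buried interface areas, hydrogen bonds, cation-pi contacts."""

import numpy as np
import pytest
from conftest import random_rotation

from slc26kit.interfaces import (
    SASAParams,
    buried_area,
    find_cation_pi,
    find_hbonds,
    sasa,
    spiral_points,
)
from slc26kit.io import Atom, Structure


def atom(pos, name="C1", element="C", resname="ALA", resseq=1, chain="A",
         vdw=1.7, serial=1):
    return Atom(serial=serial, name=name, element=element, residue_name=resname,
                residue_seq=resseq, chain_id=chain,
                position=np.asarray(pos, float), vdw_radius=vdw)


class TestSASA:
    def test_single_atom_closed_form(self, make_structure):
        st = make_structure([[0, 0, 0]])
        area = sasa(st)[0]
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_distant_atoms_unoccluded(self, make_structure):
        st = make_structure([[0, 0, 0], [100, 0, 0]])
        areas = sasa(st)
        exact = 4 * np.pi * 3.1 ** 2
        np.testing.assert_allclose(areas, exact, rtol=1e-6)

    def test_caged_atom_zero(self):
        # octahedral + cubic cage of large neighbours fully encloses the center
        cage = []
        serial = 1
        for d in (2.0,):
            for v in ([d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0],
                      [0, 0, d], [0, 0, -d]):
                serial += 1
                cage.append(atom(v, name=f"C{serial}", resseq=serial,
                                 vdw=2.5, serial=serial))
        for sx in (-1.6, 1.6):
            for sy in (-1.6, 1.6):
                for sz in (-1.6, 1.6):
                    serial += 1
                    cage.append(atom([sx, sy, sz], name=f"C{serial}",
                                     resseq=serial, vdw=2.5, serial=serial))
        st = Structure([atom([0, 0, 0], vdw=1.0)] + cage)
        assert sasa(st)[0] == 0.0

    def test_point_count_convergence(self):
        rng = np.random.default_rng(2)
        st = Structure([atom(p, name=f"C{i}", resseq=i + 1, serial=i + 1)
                        for i, p in enumerate(rng.uniform(-4, 4, (15, 3)))])
        a1 = sasa(st, SASAParams(n_sphere_points=960))
        a2 = sasa(st, SASAParams(n_sphere_points=1920))
        exact0 = 4 * np.pi * 3.1 ** 2
        # doubling the point count moves any atom's area by < 2% of the
        # free-atom area
        assert np.max(np.abs(a1 - a2)) / exact0 < 0.02

    def test_spiral_points_unit_norm(self):
        pts = spiral_points(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestBuriedArea:
    def two_atom_structure(self, d):
        return Structure([atom([0, 0, 0], resseq=1),
                          atom([d, 0, 0], name="C2", resseq=2, serial=2)])

    def test_distant_groups_zero(self):
        st = self.two_atom_structure(100.0)
        rep = buried_area(st, st.select(resseq=1), st.select(resseq=2))
        assert rep.buried_area == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d", [2.5, 3.0, 4.0, 5.0])
    def test_two_sphere_analytic_cap(self, d):
        """Equal spheres at distance d < 2(r+p): each loses a spherical cap
        2*pi*R*(R - d/2), so the buried area equals that cap area."""
        R = 1.7 + 1.4
        st = self.two_atom_structure(d)
        rep = buried_area(st, st.select(resseq=1), st.select(resseq=2))
        analytic = 2 * np.pi * R * (R - d / 2)
        assert abs(rep.buried_area - analytic) / analytic < 0.02

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(10)
        atoms = [atom(p, name=f"C{i}", resseq=i + 1, serial=i + 1)
                 for i, p in enumerate(rng.uniform(-5, 5, (14, 3)))]
        st = Structure(atoms)
        ga = st.select(resseq=range(1, 8))
        gb = st.select(resseq=range(8, 15))
        ab = buried_area(st, ga, gb).buried_area
        ba = buried_area(st, gb, ga).buried_area
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_monotone_decrease_with_separation(self):
        prev = np.inf
        for d in (2.5, 3.5, 4.5, 5.5, 6.5, 100.0):
            st = self.two_atom_structure(d)
            rep = buried_area(st, st.select(resseq=1), st.select(resseq=2))
            assert rep.buried_area <= prev + 1e-9
            prev = rep.buried_area

    def test_contributions_sum_and_overlap_rejected(self):
        st = self.two_atom_structure(3.0)
        ga = st.select(resseq=1)
        rep = buried_area(st, ga, st.select(resseq=2))
        assert sum(rep.per_residue_contributions.values()) == pytest.approx(
            rep.buried_area, abs=1e-6)
        with pytest.raises(ValueError, match="overlap"):
            buried_area(st, ga, ga)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        st = self.two_atom_structure(3.0)
        rep0 = buried_area(st, st.select(resseq=1), st.select(resseq=2))
        moved = st.transformed(random_rotation(rng), np.array([5.0, 6.0, -7.0]))
        rep1 = buried_area(moved, moved.select(resseq=1), moved.select(resseq=2))
        # fixed sphere-point sampling rotates with neither structure, so
        # invariance holds only to the sampling resolution
        assert rep1.buried_area == pytest.approx(rep0.buried_area, rel=0.01)

    def test_against_independent_shrake_rupley(self):
        """Cross-check total SASA against biotite's Shrake-Rupley."""
        biotite_struct = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(42)
        pos = rng.uniform(-5, 5, (20, 3))
        st = Structure([atom(p, name=f"C{i}", resseq=i + 1, serial=i + 1)
                        for i, p in enumerate(pos)])
        ours = sasa(st, SASAParams(n_sphere_points=960)).sum()
        arr = biotite_struct.AtomArray(20)
        arr.coord = pos.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, 21)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        theirs = biotite_struct.sasa(arr, probe_radius=1.4,
                                     vdw_radii=np.full(20, 1.7),
                                     point_number=960).sum()
        assert abs(ours - theirs) / theirs < 0.01


class TestHBonds:
    def pair(self, d, donor_res="SER", acc_res="ASP"):
        return Structure([
            atom([0, 0, 0], name="OG", element="O", resname=donor_res, resseq=1),
            atom([d, 0, 0], name="OD1", element="O", resname=acc_res, resseq=2,
                 serial=2),
        ])

    def test_detected_at_2p8(self):
        bonds = find_hbonds(self.pair(2.8))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8)
        assert bonds[0].distance_only

    def test_not_detected_at_4(self):
        assert find_hbonds(self.pair(4.0)) == []

    def test_bad_angle_with_explicit_hydrogen_rejected(self):
        st = Structure([
            atom([0, 0, 0], name="OG", element="O", resname="SER", resseq=1),
            atom([0, 1.0, 0], name="HG", element="H", resname="SER", resseq=1,
                 serial=2, vdw=1.2),
            atom([2.8, 0, 0], name="OD1", element="O", resname="ASP", resseq=2,
                 serial=3),
        ])
        # donor-H perpendicular to the acceptor direction: ~90 deg < 120
        assert find_hbonds(st) == []

    def test_good_angle_with_explicit_hydrogen_kept(self):
        st = Structure([
            atom([0, 0, 0], name="OG", element="O", resname="SER", resseq=1),
            atom([1.0, 0, 0], name="HG", element="H", resname="SER", resseq=1,
                 serial=2, vdw=1.2),
            atom([2.8, 0, 0], name="OD1", element="O", resname="ASP", resseq=2,
                 serial=3),
        ])
        bonds = find_hbonds(st)
        assert len(bonds) == 1
        assert not bonds[0].distance_only
        assert bonds[0].angle == pytest.approx(180.0, abs=1e-6)


class TestCationPi:
    def phe_ring(self, center, resseq=10):
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring = []
        for i, nm in enumerate(ring_names):
            ang = np.deg2rad(60 * i)
            pos = np.asarray(center, float) + 1.39 * np.array(
                [np.cos(ang), np.sin(ang), 0.0])
            ring.append(atom(pos, name=nm, resname="PHE", resseq=resseq,
                             serial=100 + i))
        return ring

    def arg_head(self, center, resseq=20):
        return [atom(center, name="CZ", resname="ARG", resseq=resseq, serial=200)]

    def test_detected_at_4p5(self):
        st = Structure(self.phe_ring([0, 0, 0]) + self.arg_head([0, 0, 4.5]))
        hits = find_cation_pi(st)
        assert len(hits) == 1
        assert hits[0]["distance"] == pytest.approx(4.5, abs=1e-6)

    def test_not_detected_at_7(self):
        st = Structure(self.phe_ring([0, 0, 0]) + self.arg_head([0, 0, 7.0]))
        assert find_cation_pi(st) == []

    def test_no_aromatics_empty(self, make_structure):
        st = make_structure([[0, 0, 0], [3, 0, 0]])
        assert find_cation_pi(st) == []
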