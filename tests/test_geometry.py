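"""Pore profiling, open/closed classification, superpositions, censuses."""

import numpy as np
import pytest
from conftest import random_rotation

from slc26kit.geometry import (
    CleftPairSpec,
    DomainSelection,
    PorePath,
    PoreProfile,
    PoreThreshold,
    classify_pore,
    cleft_widths,
    elevator_shift,
    ligand_site_displacement,
    neighbor_census,
    pore_profile,
    structure_rmsd,
    superpose,
)
from slc26kit.io import Atom, Structure
from slc26kit.synthetic import BundleSpec, build_toy_bundle


def ca_structure(positions, chain="A", start=1, resname="ALA"):
    return Structure([
        Atom(serial=i + 1, name="CA", element="C", residue_name=resname,
             residue_seq=start + i, chain_id=chain,
             position=np.asarray(p, float), vdw_radius=1.7)
        for i, p in enumerate(positions)
    ])


class TestPoreProfile:
    def test_single_atom_arithmetic(self, make_structure):
        st = make_structure([[5.0, 0.0, 0.0]])
        path = PorePath(points=np.array([[0, 0, 0], [0, 0, 0.5]]), spacing=0.5)
        prof = pore_profile(st, path, method="brute")
        assert prof.radii[0] == pytest.approx(5.0 - 1.7)

    def test_point_inside_atom_clamps_to_zero(self, make_structure):
        st = make_structure([[0.2, 0.0, 0.0]])
        path = PorePath(points=np.array([[0, 0, 0], [0.5, 0, 0]]), spacing=0.5)
        prof = pore_profile(st, path, method="brute")
        assert prof.radii[0] == 0.0

    def test_grid_matches_brute_force_exactly(self):
        rng = np.random.default_rng(12)
        st = ca_structure(rng.uniform(-10, 10, (200, 3)))
        path = PorePath.axis([-8, 0.3, -0.2], [8, -0.4, 0.5])
        brute = pore_profile(st, path, method="brute")
        grid = pore_profile(st, path, method="grid")
        np.testing.assert_array_equal(brute.radii, grid.radii)

    def test_adding_atoms_never_increases_radii(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(-8, 8, (50, 3))
        extra = rng.uniform(-8, 8, (20, 3))
        path = PorePath.axis([-6, 0, 0], [6, 0, 0])
        r1 = pore_profile(ca_structure(base), path).radii
        r2 = pore_profile(ca_structure(np.vstack([base, extra])), path).radii
        assert np.all(r2 <= r1 + 1e-12)

    def test_toy_bundle_min_radius(self):
        bundle = build_toy_bundle(BundleSpec(cleft_radius=2.5, seed=1))
        z = bundle.coords()[:, 2]
        path = PorePath.axis([0, 0, z.min()], [0, 0, z.max()])
        prof = pore_profile(bundle, path)
        assert abs(prof.min_radius - 2.5) < 0.3

    def test_path_spacing_validated(self):
        with pytest.raises(ValueError, match="spacing"):
            PorePath(points=np.array([[0, 0, 0], [0, 0, 2.0]]), spacing=2.0)


class TestClassifyPore:
    def make_profile(self, radii):
        pts = np.column_stack([np.zeros(len(radii)), np.zeros(len(radii)),
                               np.arange(len(radii)) * 0.5])
        return PoreProfile(path=PorePath(points=pts, spacing=0.5),
                           radii=np.asarray(radii, float))

    def test_one_open_one_closed(self):
        prof = self.make_profile([2.0, 2.0, 2.0, 1.5, 2.0])
        cls = classify_pore(prof, pocket_index=2)
        assert cls == {"cytosolic": "open", "extracellular": "closed"}

    def test_exactly_threshold_is_closed(self):
        prof = self.make_profile([2.0, 1.8, 2.0])
        cls = classify_pore(prof, pocket_index=2)
        assert cls["cytosolic"] == "closed"

    def test_all_above_threshold_both_open(self):
        prof = self.make_profile([2.0, 2.5, 3.0])
        assert classify_pore(prof, 1) == {"cytosolic": "open",
                                          "extracellular": "open"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        prof = self.make_profile(rng.uniform(0.5, 4.0, 21))
        order = {"open": 1, "closed": 0}
        prev = classify_pore(prof, 10, PoreThreshold(0.6))
        for thr in np.arange(0.8, 4.0, 0.2):
            cur = classify_pore(prof, 10, PoreThreshold(float(thr)))
            for side in ("cytosolic", "extracellular"):
                assert order[cur[side]] <= order[prev[side]]
            prev = cur


class TestCleftWidths:
    def test_constructed_distance(self):
        st = ca_structure([[0, 0, 0], [7.25, 0, 0]], start=165)
        w = cleft_widths(st, CleftPairSpec(pairs=((165, 166),), chain="A"))
        assert w["165/166"] == pytest.approx(7.25)

    def test_identical_structure_zero_deltas(self):
        st = ca_structure(np.random.default_rng(1).uniform(-9, 9, (6, 3)), start=165)
        pairs = CleftPairSpec(pairs=((165, 168), (166, 169), (167, 170)))
        w1 = cleft_widths(st, pairs)
        w2 = cleft_widths(st, pairs)
        assert all(w1[k] == w2[k] for k in w1)

    def test_missing_pair_named_in_error(self):
        st = ca_structure([[0, 0, 0]], start=165)
        with pytest.raises(KeyError, match="165/442"):
            cleft_widths(st, CleftPairSpec(pairs=((165, 442),)))


class TestElevatorShift:
    def setup_method(self):
        rng = np.random.default_rng(21)
        self.gate_pos = rng.uniform(-10, 10, (30, 3))
        self.core_pos = rng.uniform(-10, 10, (15, 3))
        atoms = []
        for i, p in enumerate(self.gate_pos):
            atoms.append(Atom(serial=i + 1, name="CA", element="C",
                              residue_name="ALA", residue_seq=100 + i,
                              chain_id="A", position=p, vdw_radius=1.7))
        for i, p in enumerate(self.core_pos):
            atoms.append(Atom(serial=100 + i, name="CA", element="C",
                              residue_name="ALA", residue_seq=200 + i,
                              chain_id="A", position=p, vdw_radius=1.7))
        self.st = Structure(atoms)
        self.domains = DomainSelection(core=((200, 214),), gate=((100, 129),))
        self.probe = list(range(200, 215))

    def test_self_shift_zero(self):
        assert elevator_shift(self.st, self.st, self.domains, self.probe) == \
            pytest.approx(0.0, abs=1e-9)

    def test_translated_core_measured(self):
        from dataclasses import replace
        atoms = [replace(a, position=a.position + np.array([0, 0, 5.0]))
                 if a.residue_seq >= 200 else a for a in self.st.atoms]
        moved = Structure(atoms)
        shift = elevator_shift(moved, self.st, self.domains, self.probe)
        assert shift == pytest.approx(5.0, abs=1e-9)

    def test_global_rotation_removed_by_gate_alignment(self):
        rng = np.random.default_rng(2)
        R = random_rotation(rng)
        rotated = self.st.transformed(R, np.array([1.0, 2.0, 3.0]))
        shift = elevator_shift(rotated, self.st, self.domains, self.probe)
        assert shift == pytest.approx(0.0, abs=1e-6)

    def test_too_few_gate_atoms(self):
        small = self.st.subset(self.st.select(resseq=range(100, 110)))
        with pytest.raises(ValueError, match="need >= 20"):
            elevator_shift(small, small, self.domains, self.probe)


class TestNeighborCensus:
    def test_cutoff_boundary(self, make_atom):
        lig = make_atom([0, 0, 0], name="CL", element="CL", resname="CL",
                        resseq=900, hetero=True)
        near = make_atom([4.9, 0, 0], name="CA", resname="TYR", resseq=129)
        far = make_atom([5.1, 0, 0], name="CA", resname="VAL", resseq=167)
        st = Structure([lig, near, far])
        census = neighbor_census(st, [lig], cutoff=5.0)
        assert ("A", 129, "TYR") in census
        assert ("A", 167, "VAL") not in census
        assert census[("A", 129, "TYR")] == pytest.approx(4.9)

    def test_zero_cutoff_empty(self, make_atom):
        lig = make_atom([0, 0, 0], resseq=900, hetero=True)
        other = make_atom([1, 0, 0], resseq=1)
        assert neighbor_census(Structure([lig, other]), [lig], cutoff=0.0) == {}


class TestLigandDisplacement:
    def base(self):
        rng = np.random.default_rng(6)
        prot = ca_structure(rng.uniform(-10, 10, (12, 3)))
        lig = Atom(serial=99, name="S", element="S", residue_name="SO4",
                   residue_seq=901, chain_id="L",
                   position=np.array([1.0, 2.0, 3.0]), vdw_radius=1.8,
                   is_hetero=True)
        return Structure(prot.atoms + [lig]), lig

    def test_identical_zero(self):
        st, lig = self.base()
        d = ligand_site_displacement(st, [lig], st, [lig])
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_displaced_ligand_measured(self):
        from dataclasses import replace
        st, lig = self.base()
        lig2 = replace(lig, position=lig.position + np.array([0, 2.5, 0]))
        st2 = Structure(st.atoms[:-1] + [lig2])
        d = ligand_site_displacement(st, [lig], st2, [lig2])
        assert d == pytest.approx(2.5, abs=1e-9)

    def test_rigid_transform_of_second_structure_removed(self):
        st, lig = self.base()
        rng = np.random.default_rng(9)
        R = random_rotation(rng)
        st2 = st.transformed(R, np.array([4.0, -1.0, 6.0]))
        lig2 = st2.atoms[-1]
        d = ligand_site_displacement(st, [lig], st2, [lig2])
        assert d == pytest.approx(0.0, abs=1e-6)


class TestStructureRMSD:
    def test_identical_and_translated_zero(self):
        st = ca_structure(np.random.default_rng(4).uniform(-10, 10, (20, 3)))
        assert structure_rmsd(st, st) == pytest.approx(0.0, abs=1e-9)
        moved = st.transformed(np.eye(3), np.array([3.0, 3.0, 3.0]))
        assert structure_rmsd(moved, st) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_noise_rmsd_scaling(self):
        """Isotropic per-coordinate noise of sd s gives RMSD ~ s*sqrt(3)."""
        rng = np.random.default_rng(17)
        st = ca_structure(rng.uniform(-30, 30, (2000, 3)))
        s = 0.05
        from dataclasses import replace
        noisy = Structure([replace(a, position=a.position + rng.normal(0, s, 3))
                           for a in st.atoms])
        rmsd = structure_rmsd(noisy, st)
        assert abs(rmsd - s * np.sqrt(3)) / (s * np.sqrt(3)) < 0.10

    def test_insufficient_atoms(self):
        st = ca_structure([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="shared Calpha"):
            superpose(st, st)
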