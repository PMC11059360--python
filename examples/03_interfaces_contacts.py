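"""Buried interface area and contact detection.

Shows the Shrake-Rupley SASA primitive on closed-form cases, then the
buried-area convention (SASA_A + SASA_B - SASA_AB)/2 used to quantify
dimer interfaces, and the geometric hydrogen-bond / cation-pi detectors.
"""

import numpy as np

from slc26kit.interfaces import SASAParams, buried_area, find_cation_pi, find_hbonds, sasa
from slc26kit.io import Atom, Structure


def atom(pos, name, resname="ALA", resseq=1, element="C", serial=1):
    return Atom(serial=serial, name=name, element=element, residue_name=resname,
                residue_seq=resseq, chain_id="A",
                position=np.asarray(pos, float), vdw_radius=1.7)


single = Structure([atom([0, 0, 0], "C1")])
area = sasa(single)[0]
print(f"single carbon SASA: {area:.2f} A^2 "
      f"(closed form 4*pi*(1.7+1.4)^2 = {4 * np.pi * 3.1 ** 2:.2f})")

pair = Structure([atom([0, 0, 0], "C1", resseq=1),
                  atom([3.0, 0, 0], "C2", resseq=2, serial=2)])
rep = buried_area(pair, pair.select(resseq=1), pair.select(resseq=2))
cap = 2 * np.pi * 3.1 * (3.1 - 1.5)
print(f"two-sphere buried area at 3.0 A separation: {rep.buried_area:.2f} A^2 "
      f"(analytic spherical cap {cap:.2f})")

# hydrogen bond between a serine hydroxyl and an aspartate carboxylate
hb = Structure([atom([0, 0, 0], "OG", "SER", 1, "O"),
                atom([2.8, 0, 0], "OD1", "ASP", 2, "O", serial=2)])
bonds = find_hbonds(hb)
print(f"H-bond detected at {bonds[0].distance:.1f} A "
      f"(heavy-atom distance mode: {bonds[0].distance_only})")

# cation-pi pair: phenylalanine ring centroid vs arginine guanidinium
ring = [atom(1.39 * np.array([np.cos(np.deg2rad(60 * i)),
                              np.sin(np.deg2rad(60 * i)), 0.0]),
             n, "PHE", 10, serial=10 + i)
        for i, n in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"))]
cation = [atom([0, 0, 4.5], "CZ", "ARG", 20, serial=30)]
hits = find_cation_pi(Structure(ring + cation))
print(f"cation-pi contact at {hits[0]['distance']:.1f} A between "
      f"{hits[0]['aromatic']} and {hits[0]['cation']}")
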