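"""Solvent accessibility, buried interface areas and contact detection.

SASA follows Shrake & Rupley: each atom's sphere of radius
(vdW + probe) is covered with deterministic generalized-spiral points
and the accessible fraction is the share of points not inside any
neighbour's expanded sphere.  Buried interface area between two atom
groups uses the ChimeraX convention (SASA_A + SASA_B - SASA_AB) / 2,
with each isolated-group SASA computed with only that group's atoms
present.

Hydrogen bonds are detected geometrically on heavy atoms (deposited
cryo-EM models carry no hydrogens): donor/acceptor-typed N/O pairs at
2.0-3.5 A.  When explicit hydrogens exist an angular criterion applies.
Cation-pi contacts pair aromatic ring centroids (PHE/TYR/TRP) with
lysine/arginine cation centers within 6 A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import Atom, RadiiTable, Structure

__all__ = [
    "SASAParams",
    "InterfaceReport",
    "HBond",
    "sasa",
    "buried_area",
    "find_hbonds",
    "find_cation_pi",
    "spiral_points",
]


@dataclass(frozen=True)
class SASAParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_sphere_points < 92:
            raise ValueError("need at least 92 sphere points")


def spiral_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden angle) points on the unit
    sphere; quasi-uniform, no RNG, exactly reproducible."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(structure: Structure, params: SASAParams = SASAParams()) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Angstrom^2 (Shrake-Rupley)."""
    coords = structure.coords()
    radii = structure.radii() + params.probe_radius
    n = len(coords)
    unit = spiral_points(params.n_sphere_points)
    tree = cKDTree(coords)
    # neighbours possibly occluding atom i lie within r_i + max(r_j)
    rmax = radii.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        cand = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        if cand:
            nb = np.asarray(cand)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried_pts = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried_pts.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas


@dataclass
class InterfaceReport:
    """Buried interface between two residue groups with per-residue split."""

    buried_area: float
    per_residue_contributions: dict[tuple[str, int], float]
    n_atoms_a: int
    n_atoms_b: int

    def __post_init__(self) -> None:
        total = sum(self.per_residue_contributions.values())
        if abs(total - self.buried_area) > 1e-6:
            raise ValueError("per-residue contributions must sum to buried_area")


def buried_area(
    structure: Structure,
    group_a: Sequence[Atom],
    group_b: Sequence[Atom],
    params: SASAParams = SASAParams(),
) -> InterfaceReport:
    """Buried interface area (SASA_A + SASA_B - SASA_AB) / 2.

    Isolated-group SASA is computed with only that group's atoms present
    (the standard buried-area definition); atoms outside the two groups
    do not participate at all.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ids_a = {(a.chain_id, a.residue_seq, a.name) for a in group_a}
    ids_b = {(b.chain_id, b.residue_seq, b.name) for b in group_b}
    if ids_a & ids_b:
        raise ValueError("groups overlap; buried area needs disjoint selections")
    sub_a = structure.subset(list(group_a))
    sub_b = structure.subset(list(group_b))
    sub_ab = structure.subset(list(group_a) + list(group_b))
    a_alone = sasa(sub_a, params)
    b_alone = sasa(sub_b, params)
    ab = sasa(sub_ab, params)
    alone = np.concatenate([a_alone, b_alone])
    delta = (alone - ab) / 2.0
    buried = float(delta.sum())
    contrib: dict[tuple[str, int], float] = {}
    for atom, d in zip(sub_ab.atoms, delta):
        contrib[atom.residue_key] = contrib.get(atom.residue_key, 0.0) + float(d)
    # compensate accumulated float error so the invariant holds exactly
    err = buried - sum(contrib.values())
    if contrib and err != 0.0:
        first = next(iter(contrib))
        contrib[first] += err
    return InterfaceReport(buried_area=buried, per_residue_contributions=contrib,
                           n_atoms_a=len(group_a), n_atoms_b=len(group_b))


# ---------------------------------------------------------------------------
# hydrogen bonds

# side-chain donor/acceptor typing on heavy atoms; backbone N donates,
# backbone O accepts.  HIS ring nitrogens are treated as both.
_SC_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SC_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"}, "CYS": {"SG"},
}


def _is_donor(a: Atom) -> bool:
    if a.name == "N" and a.element == "N":
        return True
    return a.name in _SC_DONORS.get(a.residue_name, set())


def _is_acceptor(a: Atom) -> bool:
    if a.name in {"O", "OXT"} and a.element == "O":
        return True
    return a.name in _SC_ACCEPTORS.get(a.residue_name, set())


@dataclass
class HBond:
    donor: Atom
    acceptor: Atom
    distance: float
    angle: float | None = None     # D-H...A angle, only with explicit H
    distance_only: bool = True


def find_hbonds(
    structure: Structure,
    d_max: float = 3.5,
    d_min: float = 2.0,
    angle_min: float = 120.0,
) -> list[HBond]:
    """Geometric hydrogen bonds between typed donor/acceptor heavy atoms.

    Pairs within the same residue are excluded.  If the donor has an
    attached hydrogen (same residue, name starting 'H', within 1.3 A)
    the D-H...A angle must exceed *angle_min*; otherwise the detection
    is distance-only and flagged as such.
    """
    donors = [a for a in structure.atoms if _is_donor(a)]
    acceptors = [a for a in structure.atoms if _is_acceptor(a)]
    if not donors or not acceptors:
        return []
    acc_pos = np.array([a.position for a in acceptors])
    tree = cKDTree(acc_pos)
    hydrogens = [a for a in structure.atoms if a.element == "H"]
    out: list[HBond] = []
    for don in donors:
        for j in tree.query_ball_point(don.position, d_max):
            acc = acceptors[j]
            if acc.residue_key == don.residue_key:
                continue
            d = float(np.linalg.norm(don.position - acc.position))
            if not d_min <= d <= d_max:
                continue
            h = _attached_hydrogen(don, hydrogens)
            if h is not None:
                dh = don.position - h.position
                ah = acc.position - h.position
                cosang = np.dot(dh, ah) / (np.linalg.norm(dh) * np.linalg.norm(ah))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if angle < angle_min:
                    continue
                out.append(HBond(don, acc, d, angle=angle, distance_only=False))
            else:
                out.append(HBond(don, acc, d, distance_only=True))
    return out


def _attached_hydrogen(donor: Atom, hydrogens: list[Atom]) -> Atom | None:
    best = None
    best_d = 1.3
    for h in hydrogens:
        if h.residue_key != donor.residue_key:
            continue
        d = float(np.linalg.norm(h.position - donor.position))
        if d < best_d:
            best, best_d = h, d
    return best


# ---------------------------------------------------------------------------
# cation-pi

_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
_CATION_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("CZ", "NE", "NH1", "NH2"),
}


def find_cation_pi(structure: Structure, d_max: float = 6.0) -> list[dict]:
    """Aromatic-ring-centroid to cation-center pairs within *d_max*.

    Returns dicts with the aromatic residue, the cationic residue, and
    the centroid distance.
    """
    residues = structure.residues()
    rings = []
    cations = []
    for key, atoms in residues.items():
        resname = atoms[0].residue_name
        if resname in _RING_ATOMS:
            names = {a.name: a for a in atoms}
            ring = [names[n].position for n in _RING_ATOMS[resname] if n in names]
            if len(ring) >= 5:
                rings.append(((key[0], key[1], resname), np.mean(ring, axis=0)))
        if resname in _CATION_ATOMS:
            names = {a.name: a for a in atoms}
            cat = [names[n].position for n in _CATION_ATOMS[resname] if n in names]
            if cat:
                cations.append(((key[0], key[1], resname), np.mean(cat, axis=0)))
    out = []
    for (rkey, rpos) in rings:
        for (ckey, cpos) in cations:
            d = float(np.linalg.norm(rpos - cpos))
            if d <= d_max:
                out.append({"aromatic": rkey, "cation": ckey, "distance": d})
    return out
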