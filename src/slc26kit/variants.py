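"""Structure-based annotation of pathogenic missense variants.

A missense change is assigned to one of four explanatory categories by
ordered structural rules, mirroring how pathogenic substitutions in an
elevator-type anion transporter are rationalized:

1. ``substrate_site`` — the residue lines the substrate-binding cleft
   (within ``pocket_cutoff`` of the pocket center, or in a curated
   cleft-lining set).
2. ``lipid_interface`` — the residue faces the lipids in or at the edge
   of the membrane slab and the substitution changes its polarity,
   charge, or introduces a helix-breaking proline.
3. ``fold_destabilizing`` — the residue is buried and the substitution
   is sterically or chemically disruptive (large volume gain, proline,
   glycine inside regular secondary structure, strong hydrophilic shift,
   or loss of a multiply hydrogen-bonded side chain).
4. ``unexplained`` — nothing above fires.

The membrane slab itself is placed by maximizing the hydropathy contrast
between solvent-exposed residues inside and outside a slab normal to the
principal axis of the Calpha cloud — a deterministic, desk-scale
stand-in for full membrane-positioning servers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .interfaces import SASAParams, find_hbonds, sasa
from .io import Atom, Structure, VariantRecord

__all__ = [
    "KYTE_DOOLITTLE",
    "FORMAL_CHARGE",
    "RESIDUE_VOLUME",
    "MembraneSlab",
    "ResidueEnvironment",
    "SubstitutionDeltas",
    "CategoryRuleSet",
    "place_membrane_slab",
    "residue_environment",
    "substitution_deltas",
    "classify_variant",
    "entry_charge_census",
    "count_sidechain_hbonds",
]

# Kyte & Doolittle hydropathy, one-letter codes
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# formal side-chain charge at pH 7 (His neutral)
FORMAL_CHARGE: dict[str, int] = {
    "D": -1, "E": -1, "K": 1, "R": 1,
}

# mean residue volumes (A^3), Zamyatnin-style
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class MembraneSlab:
    """A hydrophobic slab: plane family |dot(x, normal) - center_offset| <= half_thickness."""

    normal: np.ndarray
    center_offset: float
    half_thickness: float
    fit_score: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            self.normal = self.normal / n
        if not 10.0 <= self.half_thickness <= 25.0:
            raise ValueError("half_thickness must be in [10, 25] A")

    @property
    def confident(self) -> bool:
        """False when the hydropathy contrast never became positive."""
        return self.fit_score > 0.0

    def depth_of(self, point: np.ndarray) -> float:
        return float(np.dot(point, self.normal) - self.center_offset)


@dataclass
class ResidueEnvironment:
    """Structural features of one residue driving variant classification."""

    depth: float                   # signed A from slab center along normal
    boundary_distance: float       # A to the nearer slab face
    in_slab: bool
    relative_burial: float         # residue SASA / isolated-residue SASA
    pocket_distance: float         # A from residue centroid to pocket center
    lipid_facing: bool
    helix_context: bool = False
    strand_context: bool = False
    interface_member: bool = False
    sidechain_hbonds: int = 0
    sidechain_fallback_ca: bool = False  # glycine: centroid fell back to CA

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_burial <= 1.2:
            raise ValueError("relative_burial must be in [0, 1.2]")
        if self.boundary_distance < 0 or self.pocket_distance < 0:
            raise ValueError("distances must be >= 0")


@dataclass(frozen=True)
class SubstitutionDeltas:
    """alt-minus-ref property changes for a missense substitution."""

    hydropathy_delta: float
    charge_delta: int
    volume_delta: float
    to_pro: bool
    to_gly: bool
    from_gly: bool


@dataclass(frozen=True)
class CategoryRuleSet:
    """Ordered classification rules and their calibration thresholds."""

    pocket_cutoff: float = 8.0
    boundary_cutoff: float = 5.0
    burial_cutoff: float = 0.2
    hydropathy_cutoff: float = -3.0
    volume_cutoff: float = 25.0
    min_sidechain_hbonds: int = 2
    cleft_lining: frozenset[int] = frozenset()

    CATEGORIES = ("substrate_site", "lipid_interface", "fold_destabilizing",
                  "unexplained")


DEFAULT_RULES = CategoryRuleSet()


# ---------------------------------------------------------------------------
# slab placement


def place_membrane_slab(
    structure: Structure,
    hydropathy: dict[str, float] | None = None,
    normal: Sequence[float] | None = None,
    sasa_params: SASAParams = SASAParams(n_sphere_points=240),
) -> MembraneSlab:
    """Fit a hydrophobic membrane slab to a structure.

    The slab normal is the first principal axis of the Calpha cloud
    (override with *normal*); center offset (0.5 A grid) and half
    thickness (10-25 A, 0.5 A grid) maximize the exposure-weighted
    hydropathy summed over residues inside the slab (each residue's
    hydropathy counts in proportion to its solvent exposure, so buried
    residues carry little membrane signal; because the total over all
    residues is fixed, this argmax coincides with the inside-minus-
    outside contrast).  ``fit_score`` is the maximized inside sum; a
    non-positive score flags an unreliable placement (e.g. a soluble
    protein).
    """
    hydropathy = hydropathy or KYTE_DOOLITTLE
    residues = structure.residues()
    if len(residues) < 50:
        raise ValueError(f"need >= 50 residues to place a slab, got {len(residues)}")
    ca = np.array([a.position for a in structure.atoms if a.name == "CA"])
    if len(ca) < 3:
        raise ValueError("structure has too few Calpha atoms")
    if normal is None:
        centered = ca - ca.mean(axis=0)
        cov = centered.T @ centered / len(ca)
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] < 1e-8 and evals[1] < 1e-8:
            raise ValueError("degenerate (linear) Calpha cloud; supply a normal")
        axis = evecs[:, -1]
    else:
        axis = np.asarray(normal, float)
        axis = axis / np.linalg.norm(axis)
    burial = relative_burial_per_residue(structure, sasa_params)
    feats = []
    for key, atoms in residues.items():
        one = THREE_TO_ONE.get(atoms[0].residue_name)
        if one is None:
            continue
        centroid = np.mean([a.position for a in atoms], axis=0)
        feats.append((float(np.dot(centroid, axis)),
                      burial[key] * hydropathy[one]))
    if not feats:
        raise ValueError("no standard residues; cannot place a slab")
    proj = np.array([f[0] for f in feats])
    hyd = np.array([f[1] for f in feats])
    offsets = np.arange(proj.min(), proj.max() + 0.25, 0.5)
    halves = np.arange(10.0, 25.0 + 0.25, 0.5)
    best = (-np.inf, 0.0, 15.0)
    for c in offsets:
        d = np.abs(proj - c)
        for h in halves:
            score = hyd[d <= h].sum()
            if score > best[0]:
                best = (score, float(c), float(h))
    return MembraneSlab(normal=axis, center_offset=best[1],
                        half_thickness=best[2], fit_score=best[0])


def relative_burial_per_residue(
    structure: Structure,
    params: SASAParams = SASAParams(n_sphere_points=240),
) -> dict[tuple[str, int], float]:
    """SASA in context / SASA of the residue's own atoms in isolation.

    Using the residue's actual atoms as its own reference keeps the
    ratio meaningful for reduced representations (e.g. Calpha+CB toys)
    as well as full-atom models.  Clamped to [0, 1.2].
    """
    areas = sasa(structure, params)
    per_res_context: dict[tuple[str, int], float] = {}
    for atom, a in zip(structure.atoms, areas):
        per_res_context[atom.residue_key] = per_res_context.get(atom.residue_key, 0.0) + a
    out: dict[tuple[str, int], float] = {}
    for key, atoms in structure.residues().items():
        alone = sasa(structure.subset(atoms), params).sum()
        ratio = per_res_context[key] / alone if alone > 0 else 0.0
        out[key] = float(np.clip(ratio, 0.0, 1.2))
    return out


# ---------------------------------------------------------------------------
# residue environments


def residue_environment(
    structure: Structure,
    residue: tuple[str, int],
    slab: MembraneSlab,
    pocket_center: Sequence[float],
    burial: dict[tuple[str, int], float] | None = None,
    burial_cutoff: float = 0.2,
    sidechain_hbonds: int | None = None,
) -> ResidueEnvironment:
    """Compute the structural feature vector of one residue.

    *burial* may carry precomputed :func:`relative_burial_per_residue`
    output to avoid repeated SASA runs when annotating many variants.
    A residue is lipid-facing when its Calpha-to-side-chain vector has a
    positive radial component (away from the bundle axis through the
    structure centroid along the slab normal) and it is exposed.
    """
    atoms = structure.residues().get(residue)
    if not atoms:
        raise KeyError(f"residue {residue} not in structure")
    if burial is None:
        burial = relative_burial_per_residue(structure)
    rel_burial = burial[residue]
    centroid = np.mean([a.position for a in atoms], axis=0)
    depth = slab.depth_of(centroid)
    in_slab = abs(depth) <= slab.half_thickness
    boundary = abs(slab.half_thickness - abs(depth))
    pocket_distance = float(np.linalg.norm(centroid - np.asarray(pocket_center, float)))

    ca = next((a for a in atoms if a.name == "CA"), atoms[0])
    sc_atoms = [a for a in atoms if a.name not in _BACKBONE]
    fallback = not sc_atoms
    sc_centroid = ca.position if fallback else np.mean([a.position for a in sc_atoms], axis=0)
    struct_centroid = structure.coords().mean(axis=0)
    rel = ca.position - struct_centroid
    radial = rel - np.dot(rel, slab.normal) * slab.normal
    nrm = np.linalg.norm(radial)
    outward = nrm > 0 and float(np.dot(sc_centroid - ca.position, radial / nrm)) > 0
    lipid_facing = bool(outward and rel_burial > burial_cutoff)

    helix = _helix_context(structure, residue)
    if sidechain_hbonds is None:
        sidechain_hbonds = 0
    return ResidueEnvironment(
        depth=depth,
        boundary_distance=boundary,
        in_slab=in_slab,
        relative_burial=rel_burial,
        pocket_distance=pocket_distance,
        lipid_facing=lipid_facing,
        helix_context=helix,
        sidechain_hbonds=sidechain_hbonds,
        sidechain_fallback_ca=fallback,
    )


def _helix_context(structure: Structure, residue: tuple[str, int]) -> bool:
    """Local alpha-helix check: Calpha(i)-Calpha(i+-4) distance < 6.5 A."""
    chain, seq = residue
    try:
        ca = structure.atom(chain, seq, "CA")
    except KeyError:
        return False
    for off in (4, -4):
        try:
            other = structure.atom(chain, seq + off, "CA")
        except KeyError:
            continue
        if np.linalg.norm(ca.position - other.position) < 6.5:
            return True
    return False


def count_sidechain_hbonds(structure: Structure, residue: tuple[str, int]) -> int:
    """Hydrogen bonds involving this residue's side-chain atoms."""
    bonds = find_hbonds(structure)
    n = 0
    for b in bonds:
        for atom in (b.donor, b.acceptor):
            if atom.residue_key == residue and atom.name not in _BACKBONE:
                n += 1
                break
    return n


# ---------------------------------------------------------------------------
# substitution properties


def substitution_deltas(
    record: VariantRecord,
    hydropathy: dict[str, float] | None = None,
) -> SubstitutionDeltas:
    """alt-minus-ref hydropathy, formal charge and volume changes."""
    hydropathy = hydropathy or KYTE_DOOLITTLE
    for aa in (record.ref_aa, record.alt_aa):
        if aa not in hydropathy or aa not in RESIDUE_VOLUME:
            raise ValueError(f"nonstandard amino-acid code {aa!r} in {record.label}")
    return SubstitutionDeltas(
        hydropathy_delta=hydropathy[record.alt_aa] - hydropathy[record.ref_aa],
        charge_delta=FORMAL_CHARGE.get(record.alt_aa, 0) - FORMAL_CHARGE.get(record.ref_aa, 0),
        volume_delta=RESIDUE_VOLUME[record.alt_aa] - RESIDUE_VOLUME[record.ref_aa],
        to_pro=record.alt_aa == "P",
        to_gly=record.alt_aa == "G",
        from_gly=record.ref_aa == "G",
    )


# ---------------------------------------------------------------------------
# classification


def classify_variant(
    record: VariantRecord,
    env: ResidueEnvironment,
    deltas: SubstitutionDeltas | None = None,
    rules: CategoryRuleSet = DEFAULT_RULES,
) -> tuple[str, str]:
    """Assign a category and a rationale citing the firing rule.

    Rules fire in order substrate_site -> lipid_interface ->
    fold_destabilizing -> unexplained; the first match wins.
    """
    if deltas is None:
        deltas = substitution_deltas(record)
    lbl = record.label

    if env.pocket_distance <= rules.pocket_cutoff or record.position in rules.cleft_lining:
        why = (f"{lbl}: residue lines the substrate-binding cleft "
               f"(pocket distance {env.pocket_distance:.1f} A"
               + (", curated cleft-lining residue" if record.position in rules.cleft_lining else "")
               + ")")
        return "substrate_site", why

    polarity_hit = (deltas.hydropathy_delta < rules.hydropathy_cutoff
                    or deltas.charge_delta != 0
                    or deltas.to_pro)
    if env.lipid_facing and (env.boundary_distance <= rules.boundary_cutoff or env.in_slab) \
            and polarity_hit:
        why = (f"{lbl}: lipid-facing at membrane depth {env.depth:.1f} A "
               f"(boundary {env.boundary_distance:.1f} A) with "
               f"hydropathy delta {deltas.hydropathy_delta:+.1f}, "
               f"charge delta {deltas.charge_delta:+d}"
               + (", proline introduced" if deltas.to_pro else ""))
        return "lipid_interface", why

    buried = env.relative_burial < rules.burial_cutoff
    steric = deltas.volume_delta > rules.volume_cutoff
    gly_in_ss = deltas.to_gly and (env.helix_context or env.strand_context)
    hydro = deltas.hydropathy_delta < rules.hydropathy_cutoff
    hbond_loss = (env.sidechain_hbonds >= rules.min_sidechain_hbonds
                  and deltas.charge_delta != 0)
    if buried and (steric or deltas.to_pro or gly_in_ss or hydro or hbond_loss):
        reasons = []
        if steric:
            reasons.append(f"volume gain {deltas.volume_delta:+.0f} A^3")
        if deltas.to_pro:
            reasons.append("helix-breaking proline")
        if gly_in_ss:
            reasons.append("glycine inside regular secondary structure")
        if hydro:
            reasons.append(f"hydrophilic shift {deltas.hydropathy_delta:+.1f}")
        if hbond_loss:
            reasons.append(f"loss of {env.sidechain_hbonds} side-chain H-bonds")
        why = (f"{lbl}: buried (relative burial {env.relative_burial:.2f}) with "
               + "; ".join(reasons))
        return "fold_destabilizing", why

    return "unexplained", (f"{lbl}: no structural rule fired (burial "
                           f"{env.relative_burial:.2f}, pocket {env.pocket_distance:.1f} A, "
                           f"lipid-facing {env.lipid_facing})")


# ---------------------------------------------------------------------------
# charge census


def entry_charge_census(
    structure: Structure,
    region_center: Sequence[float],
    radius: float = 12.0,
) -> dict:
    """Count charged residues around a point (e.g. the cytosolic entry).

    ARG/LYS/HIS count as positive, ASP/GLU as negative, judged by
    side-chain centroid distance to *region_center*.
    """
    center = np.asarray(region_center, float)
    pos: list[tuple[str, int, str]] = []
    neg: list[tuple[str, int, str]] = []
    for key, atoms in structure.residues().items():
        resname = atoms[0].residue_name
        if resname not in {"ARG", "LYS", "HIS", "ASP", "GLU"}:
            continue
        sc = [a for a in atoms if a.name not in _BACKBONE]
        ref = sc if sc else atoms
        centroid = np.mean([a.position for a in ref], axis=0)
        if np.linalg.norm(centroid - center) <= radius:
            entry = (key[0], key[1], resname)
            (pos if resname in {"ARG", "LYS", "HIS"} else neg).append(entry)
    return {"n_positive": len(pos), "n_negative": len(neg),
            "positive": sorted(pos, key=lambda e: (e[0], e[1])),
            "negative": sorted(neg, key=lambda e: (e[0], e[1]))}
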