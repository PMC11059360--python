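"""Translocation-pore geometry and conformational comparisons.

Covers the geometric measurements used to diagnose the inward-facing
state of an elevator transporter:

* pore-radius profile along a translocation path, with the open/closed
  rule (open where every radius beyond the pocket strictly exceeds the
  1.8 A radius of an unhydrated chloride ion);
* TM3/TM10 cleft widths from Calpha pairs;
* gate-aligned elevator displacement of the core domain;
* ligand neighbor census and inter-structure ligand displacement;
* Calpha RMSD after optimal superposition.

The pore path is a straight sampled axis between two anchors; curved
channel finding is deliberately out of scope (adequate for axial toy
bundles and the open/closed rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .io import Atom, RadiiTable, Structure

__all__ = [
    "PorePath",
    "PoreProfile",
    "PoreThreshold",
    "CleftPairSpec",
    "DomainSelection",
    "DEFAULT_CLEFT_PAIRS",
    "pore_profile",
    "classify_pore",
    "cleft_widths",
    "elevator_shift",
    "neighbor_census",
    "ligand_site_displacement",
    "structure_rmsd",
    "superpose",
]


@dataclass
class PorePath:
    """Ordered sample points along a (straight or waypoint) pore path."""

    points: np.ndarray
    spacing: float
    definition: str = "axis"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("a path needs >= 2 sample points of dimension 3")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps > 1.0 + 1e-9):
            raise ValueError("consecutive path spacing must be <= 1 A")

    @classmethod
    def axis(cls, start: Sequence[float], end: Sequence[float], spacing: float = 0.5) -> "PorePath":
        """Straight line from *start* to *end* sampled every *spacing* A."""
        start = np.asarray(start, float)
        end = np.asarray(end, float)
        length = float(np.linalg.norm(end - start))
        if length == 0:
            raise ValueError("start and end anchors coincide")
        n = max(2, int(np.ceil(length / spacing)) + 1)
        t = np.linspace(0.0, 1.0, n)
        return cls(points=start + t[:, None] * (end - start),
                   spacing=length / (n - 1), definition="axis")

    def arc_lengths(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class PoreProfile:
    """Largest non-clashing sphere radius at each path point."""

    path: PorePath
    radii: np.ndarray
    side_classification: dict | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, float)
        if self.radii.shape[0] != self.path.points.shape[0]:
            raise ValueError("one radius per path point required")
        if np.any(self.radii < 0):
            raise ValueError("radii are clamped at 0; negatives are invalid")

    @property
    def min_radius(self) -> float:
        return float(self.radii.min())

    @property
    def min_location(self) -> np.ndarray:
        return self.path.points[int(np.argmin(self.radii))]


@dataclass(frozen=True)
class PoreThreshold:
    """Open/closed radius threshold; default = unhydrated Cl- radius."""

    radius: float = 1.8

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("threshold radius must be positive")


@dataclass(frozen=True)
class CleftPairSpec:
    """Calpha residue pairs spanning the TM3/TM10 substrate cleft."""

    pairs: tuple[tuple[int, int], ...] = ((165, 442), (166, 441), (167, 440))
    chain: str = "A"


DEFAULT_CLEFT_PAIRS = CleftPairSpec()


@dataclass(frozen=True)
class DomainSelection:
    """Residue ranges of the core and gate sub-domains (author numbering).

    Ranges are inclusive (start, end) tuples.  The defaults must be
    curated per structure; core = TMs 1-4 and 8-11, gate = TMs 5-7 and
    12-14 in the transporter fold.
    """

    core: tuple[tuple[int, int], ...]
    gate: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        core = set(self.residues("core"))
        gate = set(self.residues("gate"))
        if core & gate:
            raise ValueError("core and gate selections must be disjoint")

    def residues(self, which: str) -> list[int]:
        ranges = self.core if which == "core" else self.gate
        out: list[int] = []
        for lo, hi in ranges:
            out.extend(range(lo, hi + 1))
        return out


# ---------------------------------------------------------------------------
# pore profiling


def _pore_radii_brute(points: np.ndarray, coords: np.ndarray, vdw: np.ndarray) -> np.ndarray:
    d = cdist(points, coords)
    return np.maximum(0.0, (d - vdw[None, :]).min(axis=1))


def _pore_radii_grid(points: np.ndarray, coords: np.ndarray, vdw: np.ndarray) -> np.ndarray:
    """KD-tree accelerated exact evaluation of min_a(||p-a|| - vdw_a).

    The nearest atom center gives an upper bound r0 = d_nn - w_nn; any
    atom beating it must lie within r0 + max(vdw) of the point, so a
    ball query suffices for exactness.
    """
    tree = cKDTree(coords)
    wmax = float(vdw.max())
    d_nn, i_nn = tree.query(points, k=1)
    upper = d_nn - vdw[i_nn]
    radii = np.empty(len(points))
    for i, p in enumerate(points):
        cand = tree.query_ball_point(p, r=max(upper[i], 0.0) + wmax + 1e-9)
        dd = np.linalg.norm(coords[cand] - p, axis=1) - vdw[cand]
        radii[i] = max(0.0, float(dd.min()))
    return radii


def pore_profile(
    structure: Structure,
    path: PorePath,
    radii: RadiiTable | None = None,
    method: str = "grid",
) -> PoreProfile:
    """Largest sphere at each path point not penetrating any vdW sphere.

    radius(p) = max(0, min over atoms a of ||p - pos(a)|| - vdw(a)).
    ``method='brute'`` is the O(points x atoms) reference; ``'grid'`` is
    the KD-tree accelerated version that matches it exactly.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords = structure.coords()
    vdw = structure.radii()
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if np.any(path.points < lo - 5) or np.any(path.points > hi + 5):
        import warnings
        warnings.warn("pore path extends well beyond the structure's bounding box",
                      stacklevel=2)
    if method == "brute":
        r = _pore_radii_brute(path.points, coords, vdw)
    elif method == "grid":
        r = _pore_radii_grid(path.points, coords, vdw)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PoreProfile(path=path, radii=r)


def classify_pore(
    profile: PoreProfile,
    pocket_index: int,
    threshold: PoreThreshold = PoreThreshold(),
) -> dict[str, str]:
    """Open/closed call for each side of the pocket.

    The path is ordered cytosolic terminus -> extracellular terminus.  A
    side is open iff every radius on the contiguous segment from the
    pocket to that terminus (pocket point included) is strictly greater
    than the threshold.
    """
    n = len(profile.radii)
    if not 0 <= pocket_index < n:
        raise IndexError(f"pocket_index {pocket_index} outside path of {n} points")
    cyt = profile.radii[: pocket_index + 1]
    ext = profile.radii[pocket_index:]
    return {
        "cytosolic": "open" if np.all(cyt > threshold.radius) else "closed",
        "extracellular": "open" if np.all(ext > threshold.radius) else "closed",
    }


# ---------------------------------------------------------------------------
# cleft widths


def cleft_widths(
    structure: Structure,
    pairs: CleftPairSpec = DEFAULT_CLEFT_PAIRS,
) -> dict[str, float]:
    """Calpha-Calpha distance for each cleft-spanning residue pair."""
    out: dict[str, float] = {}
    for r1, r2 in pairs.pairs:
        try:
            a1 = structure.atom(pairs.chain, r1, "CA")
            a2 = structure.atom(pairs.chain, r2, "CA")
        except KeyError as exc:
            raise KeyError(f"cleft pair {r1}/{r2} (chain {pairs.chain}): {exc}") from exc
        out[f"{r1}/{r2}"] = float(np.linalg.norm(a1.position - a2.position))
    return out


# ---------------------------------------------------------------------------
# superposition machinery


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ||R x + t - y||."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def _paired_ca(mobile: Structure, reference: Structure,
               resseq: set[int] | None = None, chain: str | None = None
               ) -> tuple[np.ndarray, np.ndarray, int]:
    """Coordinates of Calpha atoms shared by (chain, resseq, name)."""
    def keyed(s: Structure) -> dict:
        return {(a.chain_id, a.residue_seq): a for a in s.atoms
                if a.name == "CA"
                and (chain is None or a.chain_id == chain)
                and (resseq is None or a.residue_seq in resseq)}
    m = keyed(mobile)
    r = keyed(reference)
    shared = sorted(set(m) & set(r))
    dropped = len(set(m) | set(r)) - len(shared)
    xm = np.array([m[k].position for k in shared]) if shared else np.empty((0, 3))
    xr = np.array([r[k].position for k in shared]) if shared else np.empty((0, 3))
    return xm, xr, dropped


def superpose(
    mobile: Structure,
    reference: Structure,
    resseq: set[int] | None = None,
    chain: str | None = None,
    min_atoms: int = 3,
) -> tuple[Structure, np.ndarray, np.ndarray, float]:
    """Least-squares superposition of *mobile* onto *reference* over
    shared Calpha atoms; returns (transformed mobile, R, t, rmsd over the
    alignment selection)."""
    xm, xr, _ = _paired_ca(mobile, reference, resseq, chain)
    if len(xm) < min_atoms:
        raise ValueError(f"only {len(xm)} shared Calpha atoms; need >= {min_atoms}")
    R, t = _kabsch(xm, xr)
    moved = mobile.transformed(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((xm @ R.T + t - xr) ** 2, axis=1))))
    return moved, R, t, rmsd


def elevator_shift(
    mobile: Structure,
    reference: Structure,
    domains: DomainSelection,
    probe_resseq: Sequence[int],
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    chain: str | None = None,
) -> float:
    """Signed displacement of the core-domain probe along the membrane
    normal after aligning the gate domains.

    The gate Calpha atoms shared by both structures define the
    superposition; the probe (e.g. TM3/TM10 residues) centroid of the
    transformed mobile is compared with the reference's along *axis*.
    """
    gate = set(domains.residues("gate"))
    xm, xr, _ = _paired_ca(mobile, reference, gate, chain)
    if len(xm) < 20:
        raise ValueError(f"gate selections share only {len(xm)} Calpha atoms; need >= 20")
    R, t = _kabsch(xm, xr)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    probe = set(probe_resseq)
    pm, pr, _ = _paired_ca(mobile, reference, probe, chain)
    if len(pm) == 0:
        raise ValueError("probe selection shares no Calpha atoms")
    moved = pm @ R.T + t
    return float(np.dot(moved.mean(axis=0) - pr.mean(axis=0), axis))


# ---------------------------------------------------------------------------
# ligand environment


def neighbor_census(
    structure: Structure,
    ligand: Sequence[Atom],
    cutoff: float = 5.0,
) -> dict[tuple[str, int, str], float]:
    """Residues with any heavy atom within *cutoff* of any ligand atom.

    Returns {(chain, resseq, resname): minimum heavy-atom distance}.
    The ligand's own residues are excluded.
    """
    if not ligand:
        raise KeyError("ligand selection resolves to no atoms")
    lig_pos = np.array([a.position for a in ligand])
    lig_keys = {a.residue_key for a in ligand}
    census: dict[tuple[str, int, str], float] = {}
    if cutoff <= 0:
        return census
    for key, atoms in structure.residues().items():
        if key in lig_keys:
            continue
        pos = np.array([a.position for a in atoms])
        dmin = float(cdist(pos, lig_pos).min())
        if dmin <= cutoff:
            census[(key[0], key[1], atoms[0].residue_name)] = dmin
    return census


def ligand_site_displacement(
    structure_a: Structure,
    ligand_a: Sequence[Atom],
    structure_b: Structure,
    ligand_b: Sequence[Atom],
    align_resseq: set[int] | None = None,
    chain: str | None = None,
) -> float:
    """Distance between ligand centroids after superposing b onto a."""
    if not ligand_a or not ligand_b:
        raise KeyError("ligand selection resolves to no atoms")
    xb, xa, _ = _paired_ca(structure_b, structure_a, align_resseq, chain)
    if len(xb) < 3:
        raise ValueError("alignment selection shares fewer than 3 Calpha atoms")
    R, t = _kabsch(xb, xa)
    ca = np.mean([a.position for a in ligand_a], axis=0)
    cb = np.mean([a.position for a in ligand_b], axis=0)
    return float(np.linalg.norm((R @ cb + t) - ca))


def structure_rmsd(
    mobile: Structure,
    reference: Structure,
    resseq: set[int] | None = None,
    chain: str | None = None,
) -> float:
    """Calpha RMSD after optimal superposition over shared residues."""
    _, _, _, rmsd = superpose(mobile, reference, resseq, chain)
    return rmsd
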