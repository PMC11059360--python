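"""Synthetic structures, binding traces, density maps and variant tables.

Desk-scale stand-ins for the study inputs:

* :func:`build_toy_bundle` — an idealized alpha-helical bundle with an
  axial substrate cleft and a hydrophobic membrane belt, emulating the
  transmembrane domain of an elevator transporter.
* :func:`simulate_binding_trace` — a two-state (bound/unbound) Markov
  chain emitting substrate-to-reference distances, the desk-scale
  analogue of 1-microsecond MD replicates.  The built-in presets encode
  the stationary occupancies of the three substrates (chloride ~82%,
  sulfate 100%, oxalate ~65%).
* :func:`render_density` — Gaussian-rendered maps for Q-score oracles.
* :func:`make_variant_fixture` — small missense tables on the toy bundle.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Atom, DensityMap, RadiiTable, Structure, VariantRecord, Significance
from .residency import TrajectoryTrace

__all__ = [
    "BundleSpec",
    "KineticPreset",
    "PRESET_CL",
    "PRESET_SO4",
    "PRESET_OX",
    "PRESETS",
    "build_toy_bundle",
    "simulate_binding_trace",
    "render_density",
    "make_variant_fixture",
]

# ideal alpha-helix geometry (Calpha trace)
HELIX_RISE = 1.5          # A per residue along the helix axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_CA_RADIUS = 2.3     # A, Calpha distance from the helix axis

HYDROPHOBIC_SET = ("LEU", "ILE", "VAL", "PHE")
POLAR_SET = ("SER", "ASN", "GLU", "LYS")


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of the toy transmembrane helix bundle.

    ``ring_radius`` is the envelope margin between the axial cleft and
    each helix axis (Calpha radius 2.3 + side-chain extension 1.5 + a
    carbon vdW radius 1.7 = 5.5 A by default), so helix axes sit at
    ``ring_radius + cleft_radius`` from the bundle axis and the open
    axial pore has radius ~``cleft_radius``.
    """

    n_helices: int = 6
    helix_length: int = 24
    ring_radius: float = HELIX_CA_RADIUS + 1.5 + 1.7
    cleft_radius: float = 2.5
    belt_half_thickness: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 3:
            raise ValueError("need at least 3 helices")
        if self.cleft_radius < 0:
            raise ValueError("cleft_radius must be >= 0")
        if self.belt_half_thickness <= 0:
            raise ValueError("belt_half_thickness must be positive")


def build_toy_bundle(spec: BundleSpec, radii: RadiiTable | None = None) -> Structure:
    """Build an idealized helical bundle around the z axis.

    Each helix is a Calpha trace (1.5 A rise, 100 deg twist per residue,
    2.3 A Calpha radius) plus a pseudo side-chain atom (CB) placed 1.5 A
    radially outward from the local helix axis, so side chains facing the
    bundle exterior are lipid-facing and those facing the axis line the
    cleft.  Residues inside the membrane belt (|z| <= belt_half_thickness)
    get hydrophobic identities, the rest polar, drawn deterministically
    from the seed.
    """
    radii = radii or RadiiTable()
    axis_dist = spec.ring_radius + spec.cleft_radius
    if axis_dist < HELIX_CA_RADIUS + 0.5:
        raise ValueError(
            f"helices at {axis_dist:.2f} A from the bundle axis would overlap it")
    rng = np.random.default_rng(spec.seed)
    c_r = radii.lookup("C")
    atoms: list[Atom] = []
    serial = 0
    resseq = 0
    z0 = -(spec.helix_length - 1) * HELIX_RISE / 2.0
    for h in range(spec.n_helices):
        ring_angle = 2 * np.pi * h / spec.n_helices
        center = axis_dist * np.array([np.cos(ring_angle), np.sin(ring_angle), 0.0])
        chain = chr(ord("A") + h)
        for i in range(spec.helix_length):
            resseq += 1
            z = z0 + i * HELIX_RISE
            phase = np.deg2rad(HELIX_TWIST * i) + ring_angle + np.pi
            # phase offset points residue 0 toward the bundle axis
            radial = np.array([np.cos(phase), np.sin(phase), 0.0])
            ca = center + HELIX_CA_RADIUS * radial + np.array([0.0, 0.0, z])
            cb = center + (HELIX_CA_RADIUS + 1.5) * radial + np.array([0.0, 0.0, z])
            pool = HYDROPHOBIC_SET if abs(z) <= spec.belt_half_thickness else POLAR_SET
            resname = pool[rng.integers(len(pool))]
            for name, pos in (("CA", ca), ("CB", cb)):
                serial += 1
                atoms.append(Atom(serial=serial, name=name, element="C",
                                  residue_name=resname, residue_seq=resseq,
                                  chain_id=chain, position=pos,
                                  vdw_radius=c_r, is_hetero=False))
    return Structure(atoms, title=f"toy_bundle_seed{spec.seed}")


# ---------------------------------------------------------------------------
# two-state binding kinetics


@dataclass(frozen=True)
class KineticPreset:
    """Two-state Markov kinetics with state-conditional distance emissions.

    Emission supports are kept strictly inside (bound) / outside
    (unbound) the default 3.5-8.0 A binding window so the hidden state is
    exactly recoverable from the emitted distance.
    """

    name: str
    p_on: float                      # per-frame P(unbound -> bound)
    p_off: float                     # per-frame P(bound -> unbound)
    bound_emission: tuple[float, float] = (4.0, 7.5)
    unbound_emission: tuple[float, float] = (9.0, 30.0)
    start_state: str = "unbound"     # 'bound' | 'unbound' | 'stationary'

    def __post_init__(self) -> None:
        for p in (self.p_on, self.p_off):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must be in [0, 1]")
        lo, hi = self.bound_emission
        if not 3.5 < lo < hi < 8.0:
            raise ValueError("bound emission support must lie strictly inside (3.5, 8)")
        lo, hi = self.unbound_emission
        if not (hi > lo and (hi < 3.5 or lo > 8.0)):
            raise ValueError("unbound emission support must lie strictly outside [3.5, 8]")

    @property
    def stationary_bound(self) -> float:
        """Long-run bound probability p_on / (p_on + p_off)."""
        if self.p_on + self.p_off == 0:
            return 1.0 if self.start_state == "bound" else 0.0
        return self.p_on / (self.p_on + self.p_off)


#: chloride-like kinetics: stationary occupancy 0.82
PRESET_CL = KineticPreset("preset_cl", p_on=0.0041, p_off=0.0009,
                          start_state="stationary")
#: sulfate-like kinetics: starts bound, never unbinds (occupancy 1.0)
PRESET_SO4 = KineticPreset("preset_so4", p_on=0.0041, p_off=0.0,
                           start_state="bound")
#: oxalate-like kinetics: stationary occupancy 0.65
PRESET_OX = KineticPreset("preset_ox", p_on=0.00325, p_off=0.00175,
                          start_state="stationary")

PRESETS = {p.name: p for p in (PRESET_CL, PRESET_SO4, PRESET_OX)}


def simulate_binding_trace(preset: KineticPreset, n_frames: int, seed: int) -> TrajectoryTrace:
    """Sample a two-state binding trajectory and emit per-frame distances.

    The hidden state sequence follows the preset's Markov chain; each
    frame's distance is drawn uniformly from the current state's emission
    support.  Only distances are kept, as for a real trajectory analysis.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if preset.start_state == "bound":
        state = True
    elif preset.start_state == "unbound":
        state = False
    else:
        state = bool(rng.random() < preset.stationary_bound)
    states = np.empty(n_frames, dtype=bool)
    flips = rng.random(n_frames)
    for i in range(n_frames):
        states[i] = state
        state = (flips[i] >= preset.p_off) if state else (flips[i] < preset.p_on)
    u = rng.random(n_frames)
    blo, bhi = preset.bound_emission
    ulo, uhi = preset.unbound_emission
    distances = np.where(states, blo + u * (bhi - blo), ulo + u * (uhi - ulo))
    return TrajectoryTrace(replicate_id=f"{preset.name}_seed{seed}",
                           distances=distances, source="synthetic", seed=seed)


# ---------------------------------------------------------------------------
# density rendering


def render_density(
    structure: Structure,
    sigma: float = 0.6,
    voxel: float = 0.4,
    padding: float = 4.0,
) -> DensityMap:
    """Render a model as a sum of unit-amplitude isotropic Gaussians.

    Each atom contributes exp(-r^2 / (2 sigma^2)); the grid covers the
    structure's bounding box plus *padding* on every side.
    """
    if sigma <= 0 or voxel <= 0:
        raise ValueError("sigma and voxel must be positive")
    if voxel > 2 * sigma:
        import warnings
        warnings.warn(f"voxel {voxel} A > 2*sigma {2 * sigma} A: "
                      "the rendered map will be aliased", stacklevel=2)
    coords = structure.coords()
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    values = np.zeros(shape, dtype=np.float64)
    cutoff = 4.0 * sigma
    axes = [lo[d] + voxel * np.arange(shape[d]) for d in range(3)]
    for pos in coords:
        idx_lo = np.maximum(np.floor((pos - cutoff - lo) / voxel).astype(int), 0)
        idx_hi = np.minimum(np.ceil((pos + cutoff - lo) / voxel).astype(int) + 1, shape)
        gx = axes[0][idx_lo[0]:idx_hi[0]] - pos[0]
        gy = axes[1][idx_lo[1]:idx_hi[1]] - pos[1]
        gz = axes[2][idx_lo[2]:idx_hi[2]] - pos[2]
        r2 = (gx[:, None, None] ** 2 + gy[None, :, None] ** 2 + gz[None, None, :] ** 2)
        values[idx_lo[0]:idx_hi[0], idx_lo[1]:idx_hi[1], idx_lo[2]:idx_hi[2]] += \
            np.exp(-r2 / (2.0 * sigma ** 2))
    return DensityMap(values=values.astype(np.float32),
                      voxel_size=np.full(3, voxel), origin=lo)


# ---------------------------------------------------------------------------
# variant fixtures

# hydrophilic / charged substitutions used when perturbing belt residues
_CHARGED = ("K", "D", "R", "E")
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def make_variant_fixture(
    structure: Structure,
    n: int,
    seed: int,
    gene: str = "TOY1",
) -> list[VariantRecord]:
    """Sample *n* missense records at residues of *structure*.

    Substitutions are chosen by structural context so the fixture spans
    the downstream categories: belt-exposed hydrophobics get charged
    substitutions (lipid-interface candidates), cleft-facing residues get
    arginine (substrate-site candidates), everything else gets proline
    (fold candidates).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    residues = structure.residues()
    if n > len(residues):
        raise ValueError(f"n={n} exceeds residue count {len(residues)}")
    rng = np.random.default_rng(seed)
    keys = sorted(residues, key=lambda k: (k[0], k[1]))
    picks = rng.choice(len(keys), size=n, replace=False)
    axis_center = structure.coords().mean(axis=0)
    records: list[VariantRecord] = []
    for pi in sorted(picks):
        chain, resseq = keys[pi]
        atoms = residues[(chain, resseq)]
        resname = atoms[0].residue_name
        ref = _THREE_TO_ONE.get(resname, "A")
        ca = next((a for a in atoms if a.name == "CA"), atoms[0])
        cb = next((a for a in atoms if a.name == "CB"), None)
        in_belt = resname in HYDROPHOBIC_SET
        outward = False
        if cb is not None:
            radial = ca.position - axis_center
            radial[2] = 0.0
            nrm = np.linalg.norm(radial)
            if nrm > 0:
                outward = float(np.dot(cb.position - ca.position, radial / nrm)) > 0
        if in_belt and outward:
            alt = _CHARGED[rng.integers(len(_CHARGED))]
        elif not outward:
            alt = "R"
        else:
            alt = "P"
        if alt == ref:
            alt = "W"
        records.append(VariantRecord(gene=gene, ref_aa=ref, position=resseq,
                                     alt_aa=alt,
                                     significance=Significance.PATHOGENIC))
    return records
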