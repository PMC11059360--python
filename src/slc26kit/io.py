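"""Structure, density-map and variant-table input/output.

Every other module works on the lightweight :class:`Structure` /
:class:`DensityMap` containers defined here.  Parsing of PDB, mmCIF and
CCP4/MRC files is delegated to :mod:`gemmi`; this module flattens the
hierarchy into plain arrays, resolves alternate locations, and attaches
van der Waals radii from a configurable element table.

Conventions
-----------
* Author (PDB) residue numbering is preserved everywhere, so residue
  labels match the literature (G166 means author residue 166).
* Coordinates and radii are in Angstrom.
* Only the first model of multi-model files is read.
* Deposited cryo-EM models carry no hydrogens; all downstream geometry
  works on heavy atoms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "DensityMap",
    "VariantRecord",
    "RadiiTable",
    "BONDI_RADII",
    "read_structure",
    "write_structure",
    "read_density_map",
    "write_density_map",
    "read_variant_table",
    "write_variant_table",
]


# Bondi (1964) element radii, Angstrom; the conventional hard-sphere set
# used for surface and pore calculations.  Elements missing from the table
# fall back to RadiiTable.default (carbon-like 1.7 A) with a logged note.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
}


@dataclass(frozen=True)
class RadiiTable:
    """Element -> van der Waals radius map with a fallback default."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    name: str = "bondi"
    default: float = 1.70

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius for {el} out of the (0.5, 3.0) A range: {r}")

    def lookup(self, element: str) -> float:
        r = self.radii.get(element.upper())
        if r is None:
            logger.info("element %r not in radii table %r; using default %.2f A",
                        element, self.name, self.default)
            return self.default
        return r


@dataclass
class Atom:
    """One heavy (or explicit hydrogen) atom of a structural model."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol is empty")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)


class Structure:
    """An ordered collection of atoms with simple selection helpers.

    Atom identity is (chain_id, residue_seq, name) after altloc
    resolution; duplicates are rejected.
    """

    def __init__(self, atoms: Sequence[Atom], title: str = "", assembly_id: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        seen: set[tuple[str, int, str]] = set()
        for a in atoms:
            key = (a.chain_id, a.residue_seq, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} after altloc resolution")
            seen.add(key)
        self.atoms: list[Atom] = atoms
        self.title = title
        self.assembly_id = assembly_id

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy: x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return Structure(new, title=self.title, assembly_id=self.assembly_id)

    # -- selections ---------------------------------------------------

    def select(
        self,
        chain: str | None = None,
        resseq: int | Iterable[int] | None = None,
        names: str | Iterable[str] | None = None,
        resname: str | Iterable[str] | None = None,
        hetero: bool | None = None,
        predicate: Callable[[Atom], bool] | None = None,
    ) -> list[Atom]:
        """Atoms matching all given filters (None means 'any')."""
        if isinstance(resseq, int):
            resseq = {resseq}
        elif resseq is not None:
            resseq = set(resseq)
        if isinstance(names, str):
            names = {names}
        elif names is not None:
            names = set(names)
        if isinstance(resname, str):
            resname = {resname}
        elif resname is not None:
            resname = set(resname)
        out = []
        for a in self.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            if resseq is not None and a.residue_seq not in resseq:
                continue
            if names is not None and a.name not in names:
                continue
            if resname is not None and a.residue_name not in resname:
                continue
            if hetero is not None and a.is_hetero != hetero:
                continue
            if predicate is not None and not predicate(a):
                continue
            out.append(a)
        return out

    def subset(self, atoms: Sequence[Atom], title: str | None = None) -> "Structure":
        return Structure(list(atoms), title=self.title if title is None else title,
                         assembly_id=self.assembly_id)

    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Atoms grouped by (chain_id, residue_seq), in file order."""
        groups: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return groups

    def atom(self, chain: str, resseq: int, name: str) -> Atom:
        """The unique atom at (chain, residue, name); KeyError if absent."""
        hits = self.select(chain=chain, resseq=resseq, names=name)
        if not hits:
            raise KeyError(f"no atom ({chain}, {resseq}, {name})")
        return hits[0]


@dataclass
class DensityMap:
    """A 3D scalar grid on an orthogonal lattice.

    ``values[i, j, k]`` sits at ``origin + (i, j, k) * voxel_size`` in
    Angstrom (x, y, z axis order after header normalization).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.voxel_size = np.broadcast_to(np.asarray(self.voxel_size, float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3D array")
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the sampled lattice, Angstrom."""
        upper = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return self.origin.copy(), upper

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points (n, 3).

        Points outside the lattice raise ValueError; callers decide how
        to treat out-of-bounds atoms.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        frac = (pts - self.origin) / self.voxel_size
        if np.any(frac < 0) or np.any(frac > np.array(self.shape) - 1):
            raise ValueError("interpolation point outside map bounds")
        i0 = np.floor(frac).astype(int)
        i0 = np.minimum(i0, np.array(self.shape) - 2)
        f = frac - i0
        v = self.values
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        c = (
            v[ix, iy, iz] * (1 - fx) * (1 - fy) * (1 - fz)
            + v[ix + 1, iy, iz] * fx * (1 - fy) * (1 - fz)
            + v[ix, iy + 1, iz] * (1 - fx) * fy * (1 - fz)
            + v[ix, iy, iz + 1] * (1 - fx) * (1 - fy) * fz
            + v[ix + 1, iy + 1, iz] * fx * fy * (1 - fz)
            + v[ix + 1, iy, iz + 1] * fx * (1 - fy) * fz
            + v[ix, iy + 1, iz + 1] * (1 - fx) * fy * fz
            + v[ix + 1, iy + 1, iz + 1] * fx * fy * fz
        )
        return c if np.asarray(points).ndim == 2 else float(c[0])


class Significance:
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    OTHER = "other"


@dataclass(frozen=True)
class VariantRecord:
    """A missense protein change in <ref><pos><alt> notation."""

    gene: str
    ref_aa: str
    position: int
    alt_aa: str
    significance: str = Significance.OTHER

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self}: reference and alternate residues are identical")
        if self.position < 1:
            raise ValueError(f"{self}: position must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


# ---------------------------------------------------------------------------
# structure I/O


class ParseError(ValueError):
    pass


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name.

    Occupancy ties go to the alphabetically first altloc id (blank beats
    any letter, matching the single-conformer case).
    """
    best: dict[str, gemmi.Atom] = {}
    for at in residue:
        prev = best.get(at.name)
        if prev is None:
            best[at.name] = at
            continue
        if at.occ > prev.occ or (at.occ == prev.occ and at.altloc < prev.altloc):
            best[at.name] = at
    return list(best.values())


def read_structure(
    path: str | Path,
    format: str = "auto",
    radii: RadiiTable | None = None,
) -> Structure:
    """Read a PDB or mmCIF coordinate file into a :class:`Structure`.

    Altlocs are resolved to the highest-occupancy conformer and only the
    first model is used.  Every atom gets a vdW radius from *radii*.
    """
    path = Path(path)
    radii = radii or RadiiTable()
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown coordinate format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models present")
    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in _resolve_altlocs(res):
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        vdw_radius=radii.lookup(at.element.name),
                        is_hetero=het,
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: model contains no atoms")
    return Structure(atoms, title=st.name or path.stem)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.title or "model"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for a in structure.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chains[a.chain_id] = ch
        key = a.residue_key
        res = residues.get(key)
        if res is None:
            r = gemmi.Residue()
            r.name = a.residue_name
            r.seqid = gemmi.SeqId(a.residue_seq, " ")
            r.het_flag = "H" if a.is_hetero else "A"
            ch.add_residue(r)
            res = ch[len(ch) - 1]
            residues[key] = res
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = 1.0
        at.b_iso = 0.0
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a Structure as PDB or mmCIF (format inferred from suffix on 'auto')."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = _to_gemmi(structure)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown coordinate format {format!r}")


# ---------------------------------------------------------------------------
# density map I/O


class MapFormatError(ValueError):
    pass


def read_density_map(path: str | Path) -> DensityMap:
    """Read a CCP4/MRC map; axis order is normalized to x, y, z."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read CCP4/MRC map {path}: {exc}") from exc
    m.setup(0.0)  # reorders axes to x,y,z and fills unset voxels
    grid = m.grid
    values = np.array(grid.array, dtype=np.float32)
    voxel = np.array([grid.spacing[0], grid.spacing[1], grid.spacing[2]], float)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], float)
    # grids written with NCSTART-style offsets instead of ORIGIN records
    if np.allclose(origin, 0.0):
        start = np.array([m.header_i32(w) for w in (5, 6, 7)], float)
        origin = start * voxel
    return DensityMap(values=values, voxel_size=voxel, origin=origin)


def write_density_map(density: DensityMap, path: str | Path) -> None:
    """Write a DensityMap as a CCP4/MRC file (orthogonal cell, ORIGIN header)."""
    nx, ny, nz = density.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    cell = gemmi.UnitCell(
        nx * density.voxel_size[0],
        ny * density.voxel_size[1],
        nz * density.voxel_size[2],
        90.0, 90.0, 90.0,
    )
    grid.set_unit_cell(cell)
    np.asarray(grid.array)[:] = density.values
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), density.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# variant tables

_CHANGE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

_SIGNIFICANCE_MAP = {
    "pathogenic": Significance.PATHOGENIC,
    "likely pathogenic": Significance.LIKELY_PATHOGENIC,
    "likely_pathogenic": Significance.LIKELY_PATHOGENIC,
}

REQUIRED_VARIANT_COLUMNS = ("gene", "protein_change", "clinical_significance")


class VariantTable(list):
    """List of VariantRecord with a count of skipped (unparseable) rows."""

    n_skipped: int = 0


def read_variant_table(path: str | Path) -> VariantTable:
    """Read a variant TSV with gene / protein_change / clinical_significance columns.

    Rows whose protein_change is not single-letter ``<ref><pos><alt>``
    notation (e.g. nucleotide changes like ``c.532C>T``) are skipped with
    a warning and counted in the returned table's ``n_skipped``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks required columns: {missing}")
    out = VariantTable()
    for _, row in df.iterrows():
        change = str(row["protein_change"]).strip()
        mt = _CHANGE_RE.match(change)
        if mt is None:
            logger.warning("skipping unparseable protein change %r in %s", change, path)
            out.n_skipped += 1
            continue
        sig = _SIGNIFICANCE_MAP.get(str(row["clinical_significance"]).strip().lower(),
                                    Significance.OTHER)
        ref, pos, alt = mt.group(1), int(mt.group(2)), mt.group(3)
        if ref == alt:
            logger.warning("skipping synonymous change %r in %s", change, path)
            out.n_skipped += 1
            continue
        out.append(VariantRecord(gene=str(row["gene"]).strip(), ref_aa=ref,
                                 position=pos, alt_aa=alt, significance=sig))
    return out


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [
        {"gene": r.gene, "protein_change": r.label,
         "clinical_significance": r.significance}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_VARIANT_COLUMNS)).to_csv(
        path, sep="\t", index=False)
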