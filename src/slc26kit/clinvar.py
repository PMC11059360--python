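"""Curated ClinVar missense set for the SLC26A2 sulfate transporter.

The 25 pathogenic / likely-pathogenic missense changes (21 distinct
residues) documented for SLC26A2, each paired with a synthetic
:class:`~slc26kit.variants.ResidueEnvironment` transcribed by hand from
the structural context of the deposited models (PDB 8TNW/8TNX/8TNY):
membrane depth, burial, pocket proximity and secondary-structure
context.  These environments are curated stand-ins, not computed from
coordinates, so the classifier can be exercised and validated without
downloading the deposited structures.

``expected_category`` records the structure-based mechanistic
explanation for each change: destabilized fold, perturbed lipid
interaction, altered substrate site, or unexplained.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Significance, VariantRecord
from .variants import ResidueEnvironment

__all__ = ["CuratedVariant", "CURATED_VARIANTS", "curated_records",
           "CLEFT_LINING_RESIDUES"]

#: residues lining the TM3/TM10 substrate cleft (author numbering);
#: Q125 stabilizes the cleft-inserting K442 side chain, G166 borders the
#: pocket at the N-terminal end of TM3
CLEFT_LINING_RESIDUES = frozenset({125, 166})


@dataclass(frozen=True)
class CuratedVariant:
    record: VariantRecord
    env: ResidueEnvironment
    expected_category: str


def _env(**kw) -> ResidueEnvironment:
    base = dict(depth=0.0, boundary_distance=15.0, in_slab=True,
                relative_burial=0.05, pocket_distance=25.0,
                lipid_facing=False, helix_context=True)
    base.update(kw)
    return ResidueEnvironment(**base)


def _rec(label: str) -> VariantRecord:
    return VariantRecord(gene="SLC26A2", ref_aa=label[0],
                         position=int(label[1:-1]), alt_aa=label[-1],
                         significance=Significance.PATHOGENIC)


# buried transmembrane-core context (mid-membrane, helical, far from pocket)
_TM_BURIED = dict()
# buried cytosolic STAS-domain context (outside the slab)
_STAS_BURIED = dict(depth=35.0, boundary_distance=20.0, in_slab=False,
                    relative_burial=0.05, helix_context=False)
# lipid-facing residue near a membrane boundary
_BOUNDARY_LIPID = dict(depth=13.5, boundary_distance=1.5, in_slab=True,
                       relative_burial=0.80, lipid_facing=True)
# lipid-facing residue at the membrane midpoint
_MID_LIPID = dict(depth=0.5, boundary_distance=14.5, in_slab=True,
                  relative_burial=0.70, lipid_facing=True)

CURATED_VARIANTS: tuple[CuratedVariant, ...] = (
    # --- fold stability, transmembrane domain -------------------------
    CuratedVariant(_rec("A133V"), _env(**_TM_BURIED), "fold_destabilizing"),
    CuratedVariant(_rec("C311R"), _env(**_TM_BURIED), "fold_destabilizing"),
    CuratedVariant(_rec("A386V"), _env(**_TM_BURIED), "fold_destabilizing"),
    CuratedVariant(_rec("A386G"), _env(**_TM_BURIED), "fold_destabilizing"),
    CuratedVariant(_rec("N425D"), _env(sidechain_hbonds=3), "fold_destabilizing"),
    CuratedVariant(_rec("A461V"), _env(**_TM_BURIED), "fold_destabilizing"),
    CuratedVariant(_rec("L483P"), _env(**_TM_BURIED), "fold_destabilizing"),
    CuratedVariant(_rec("G484D"), _env(**_TM_BURIED), "fold_destabilizing"),
    CuratedVariant(_rec("S522F"), _env(**_TM_BURIED), "fold_destabilizing"),
    # --- fold stability, STAS domain ----------------------------------
    CuratedVariant(_rec("C653S"), _env(**_STAS_BURIED, strand_context=True),
                   "fold_destabilizing"),
    CuratedVariant(_rec("C653Y"), _env(**_STAS_BURIED, strand_context=True),
                   "fold_destabilizing"),
    CuratedVariant(_rec("C653G"), _env(**_STAS_BURIED, strand_context=True),
                   "fold_destabilizing"),
    CuratedVariant(_rec("G678V"), _env(**_STAS_BURIED), "fold_destabilizing"),
    CuratedVariant(_rec("A715T"), _env(**_STAS_BURIED), "fold_destabilizing"),
    # --- lipid interaction --------------------------------------------
    CuratedVariant(_rec("D111Y"), _env(**_BOUNDARY_LIPID), "lipid_interface"),
    CuratedVariant(_rec("S157P"), _env(**_BOUNDARY_LIPID), "lipid_interface"),
    CuratedVariant(_rec("R279W"), _env(**_BOUNDARY_LIPID), "lipid_interface"),
    CuratedVariant(_rec("I426T"), _env(**_MID_LIPID), "lipid_interface"),
    CuratedVariant(_rec("I426N"), _env(**_MID_LIPID), "lipid_interface"),
    CuratedVariant(_rec("Q454P"), _env(**_BOUNDARY_LIPID), "lipid_interface"),
    CuratedVariant(_rec("W505R"), _env(**_BOUNDARY_LIPID), "lipid_interface"),
    CuratedVariant(_rec("T512K"), _env(**_BOUNDARY_LIPID), "lipid_interface"),
    # --- substrate site -----------------------------------------------
    CuratedVariant(_rec("Q125L"), _env(pocket_distance=7.0, relative_burial=0.30),
                   "substrate_site"),
    CuratedVariant(_rec("G166R"), _env(pocket_distance=4.0, relative_burial=0.30,
                                       sidechain_fallback_ca=True),
                   "substrate_site"),
    # --- unexplained: exposed at the cytosolic entry, not pocket-lining
    CuratedVariant(_rec("D250V"), _env(depth=-18.0, boundary_distance=3.0,
                                       in_slab=False, relative_burial=0.90,
                                       pocket_distance=12.0, helix_context=False),
                   "unexplained"),
)


def curated_records() -> list[VariantRecord]:
    """The 25 missense records alone (e.g. for writing a variant TSV)."""
    return [cv.record for cv in CURATED_VARIANTS]
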