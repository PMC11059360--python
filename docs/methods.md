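# Methods

This note records the models and procedures behind each analysis, the
parameters that matter, and the choices made where the design was
genuinely open.

## Structural data model

Structures are flat, ordered atom lists keyed by
(chain, author residue number, atom name); author (PDB) numbering is
kept everywhere so residue labels match the literature (G166 is author
residue 166). Alternate locations resolve to the highest-occupancy
conformer, ties to the alphabetically first altloc id; only the first
model of multi-model files is read. Every atom carries a van der Waals
radius from a Bondi-style element table (carbon 1.70 Å, nitrogen 1.55,
oxygen 1.52, sulfur 1.80, chloride 1.75, …); unknown elements fall back
to 1.70 Å with a logged note, and the table is selectable wherever radii
enter a calculation. Deposited cryo-EM models carry no hydrogens, so
every geometric operation is defined on heavy atoms. CCP4/MRC maps are
normalized to x,y,z axis order on read; the origin is taken from the
header (ORIGIN words, else NCSTART × voxel) and never re-centered.

## Two-state binding kinetics and the residency statistic

The trajectory observable is a scalar per-frame distance from the
substrate (centroid, for multi-atom ligands) to a reference atom — by
default the Cα of the glycine at the N-terminal end of TM3 that borders
the substrate pocket. A frame is *bound* when the distance lies in the
closed interval [3.5, 8.0] Å. Including both edges is a choice (a
"between 3.5 and 8 Å" criterion does not fix it); it is exposed in the
window object, and the synthetic emission supports (bound U(4.0, 7.5) Å,
unbound U(9.0, 30.0) Å) deliberately avoid the edges so no synthetic
result can depend on that choice.

The generator is a two-state Markov chain with per-frame transition
probabilities p_on (unbound→bound) and p_off (bound→unbound), stationary
bound probability p_on/(p_on+p_off). Presets:

| preset | p_on | p_off | stationary | start |
|---|---|---|---|---|
| preset_cl | 0.0041 | 0.0009 | 0.82 | stationary draw |
| preset_so4 | 0.0041 | 0 | 1.00 (absorbing) | bound |
| preset_ox | 0.00325 | 0.00175 | 0.65 | stationary draw |

Frame time is abstract: all statistics are per-frame fractions, and the
microsecond timescale of the real replicate design is not reproduced.
The replicate statistic is the arithmetic mean of per-replicate bound
fractions with sample (n−1) standard deviation (sd reported as 0 and
flagged for a single replicate). Reports round to whole percentage
points in the "82 ± 4%" style while full precision is kept internally.
With correlation time τ = 1/(p_on+p_off) ≈ 200 frames, a 100,000-frame
replicate has a Monte-Carlo standard error of ≈ 2.4 percentage points on
the chloride preset, so three replicates recover the stationary value
within ~1.5 points typically; the generator reproduces the target means
by construction, not the inter-replicate spread of real simulations.
No autocorrelation-corrected error bars and no k_on/k_off estimation are
attempted. Scalar traces carry no periodic-boundary information; any PBC
unwrapping belongs to the upstream coordinate adapter.

## Toy bundle

The synthetic transmembrane domain is a ring of ideal α-helical Cα
traces (rise 1.5 Å/residue, twist 100°/residue, Cα helix radius 2.3 Å)
with one pseudo side-chain atom per residue placed 1.5 Å radially
outward from the local helix axis. Helix axes sit at
ring_radius + cleft_radius from the bundle axis, where the default
ring_radius 5.5 Å is the helix envelope (2.3 Å Cα radius + 1.5 Å
side-chain extension + 1.7 Å carbon vdW), so the open axial pore has
radius ≈ cleft_radius. Residues with |z(Cα)| ≤ belt_half_thickness
(default 15 Å) draw hydrophobic identities (LEU/ILE/VAL/PHE), the rest
polar (SER/ASN/GLU/LYS), deterministically from the seed. The bundle
captures what the analyses need — an axial cleft, a hydrophobic belt,
inward- and outward-facing side chains — and nothing else: no backbone
beyond Cα, no lipids, no energetics. Passing tests on it demonstrate
estimator and geometry correctness, not fidelity to any real fold.

## Pore profile and the open/closed rule

The pore radius at a path point p is max(0, min over atoms of
(‖p − x_a‖ − r_a)): the largest sphere at p that penetrates no vdW
sphere. The default path is a straight axis between two user anchors
sampled every 0.5 Å; curved-channel optimization (as dedicated channel
finders perform) is deliberately out of scope, which is adequate for
axial toy systems and for the open/closed rule but cannot be assumed to
reproduce curved-channel radii on deposited structures (the testable
claim there is qualitative open/closed agreement). Both an O(points ×
atoms) reference implementation and a KD-tree-accelerated version exist;
the accelerated version is exact (the nearest atom center bounds the
search ball by d_nn − r_nn + max(r)) and the tests assert bitwise
equality. A side of the pocket is open iff every radius on the
contiguous segment from the pocket index to that terminus is strictly
greater than the 1.8 Å threshold (the unhydrated Cl⁻ radius); exact
equality is closed.

## Superpositions

All alignments are least-squares Kabsch superpositions over Cα atoms
paired by (chain, residue number); unmatched residues are dropped.
Elevator displacement aligns the gate-domain selections (≥ 20 shared Cα
required) and reports the probe (TM3/TM10) centroid displacement
projected on the membrane normal — by default the slab normal, z for
the toy systems. Which residue ranges constitute each TM is a curated,
editable input, not something the code infers.

## SASA and buried interfaces

Shrake–Rupley with n = 960 deterministic golden-angle spiral points per
atom (no RNG, exactly reproducible) and probe radius 1.4 Å: an atom's
accessible area is the fraction of points on its expanded sphere
(r_vdW + probe) lying inside no neighbor's expanded sphere, times
4π(r_vdW + probe)². Buried interface area between groups A and B is
(SASA_A + SASA_B − SASA_AB)/2, each term computed **with only that
group's (or the union's) atoms present** — the standard buried-area
convention; computing isolated-group SASA in the context of the full
assembly would change the values, which is why the convention is stated
here and recorded in reports. Per-residue contributions are the halved
per-atom losses, summed per residue. Because the point set does not
rotate with the structure, SASA is rotation-invariant only to the
sampling resolution (≲ 1% at 960 points; doubling the count moves any
atom by < 2%).

Hydrogen bonds are geometric: typed N/O/S donor–acceptor heavy-atom
pairs (backbone N donates, backbone O accepts, plus a side-chain typing
table) at 2.0–3.5 Å, different residues only. With explicit hydrogens a
D–H···A angle ≥ 120° is additionally required; without (the deposited
cryo-EM case) detection is distance-only and flagged, and reported bond
lengths are heavy-atom distances. Cation-π contacts pair PHE/TYR/TRP
ring centroids with LYS NZ or the ARG guanidinium centroid within 6 Å.
No energy scoring is attempted.

## Q-score

Per atom, the map is sampled by trilinear interpolation at the atom
center and on concentric shells of radius 0.1–2.0 Å (0.1 Å steps,
8–32 spiral points per shell growing with radius). Points lying closer
to any other model atom than to the probe atom are discarded, so each
atom is scored against its own density; occlusion is judged against all
model atoms, not just the selection. The score is the Pearson
correlation between sampled values and a reference Gaussian
v_min + (v_max − v_min)·exp(−r²/2σ²) with σ = 0.6 Å by default (the
published convention for high-resolution reference profiles; the value
is configurable and always logged). Per-residue and selection scores
are plain means. Flat samples (range within float interpolation noise)
score 0 with a flag instead of raising. Q is invariant under positive
affine transforms of the map values (correlation property) and degrades
monotonically with added map noise.

A model scored against its own rendered map reaches Q ≈ 1 only when
atoms are spaced widely enough that their Gaussians do not overlap;
with realistic 1.3–1.5 Å bonds the mutual density caps self-agreement
near 0.97 at matching σ. The self-agreement tests therefore use a
cluster with ≥ 2.5 Å spacing, where overlap is negligible. No B-factor
weighting, map sharpening, FSC or half-map handling is included.

## Membrane slab and variant classification

The slab normal is the first principal axis of the Cα cloud (override
available); a grid search over center offset (0.5 Å steps across the
projection range) and half thickness (10–25 Å, 0.5 Å steps) maximizes
the exposure-weighted hydropathy (Kyte–Doolittle) summed over residues
inside the slab. Weighting each residue by its solvent exposure rather
than hard-filtering at a burial cutoff keeps the objective smooth and
the optimum unique up to the grid; because the total over all residues
is fixed, this argmax equals the inside-minus-outside contrast. The
reported fit score is the inside sum; a non-positive score flags an
unreliable placement (soluble or all-polar input). This is a
deterministic desk-scale stand-in for full membrane-positioning
servers: it recovers a constructed belt to within the grid step but
claims no parity with PPM/OPM on real structures.

Relative burial is residue SASA in context divided by the SASA of the
residue's own atoms in isolation (clamped to [0, 1.2]); using the
residue's actual atoms as the reference keeps the ratio meaningful for
reduced representations as well as full-atom models. A residue is
lipid-facing when its Cα→side-chain-centroid vector has a positive
radial component (away from the bundle axis along the slab normal) and
the residue is exposed (> 0.2 relative burial); glycine falls back to
Cα with a flag. Helix context is a local Cα(i)–Cα(i±4) < 6.5 Å check;
strand context is supplied (curated) where needed.

Substitution deltas come from fixed published tables: Kyte–Doolittle
hydropathy, formal side-chain charge at pH 7 (His neutral), and
standard residue volumes. Classification rules fire in order, first
match wins:

1. **substrate_site** — pocket distance ≤ 8 Å, or the residue is in the
   curated cleft-lining set.
2. **lipid_interface** — lipid-facing, in the slab or within 5 Å of a
   face, and the substitution shifts hydropathy below −3, changes formal
   charge, or introduces proline.
3. **fold_destabilizing** — buried (< 0.2 relative burial) and the
   substitution gains > 25 Å³ volume, introduces proline, introduces
   glycine inside regular secondary structure (helix or strand), shifts
   hydropathy below −3, or removes a side chain engaged in ≥ 2 hydrogen
   bonds while changing charge.
4. **unexplained** — otherwise.

The thresholds (8 Å, 5 Å, 0.2, −3, 25 Å³, 2 H-bonds) are calibration
knobs of this package, fixed once against the curated 25-change set and
exposed in the rule-set object; they are not measured constants. Two
rule details were set by the biology of the curated set: proline counts
as a polarity-class trigger at the lipid boundary (helix-breaking
substitutions there disrupt anchoring even without a charge change),
and the glycine rule covers strands as well as helices (glycine is
destabilizing in β-sheets). The curated environments in
`slc26kit.clinvar` are hand-transcribed structural contexts
(synthetic stand-ins, marked as such), not values computed from the
deposited coordinates; the classifier itself computes every feature
from coordinates when a structure is supplied. The charge census counts
ARG/LYS/HIS as positive and ASP/GLU as negative by side-chain-centroid
distance to a supplied center (default 12 Å); it replaces full
electrostatic surface computation, which is out of scope along with
ΔΔG prediction and conservation features.

## Pipeline and problem sizes

The pipeline stages are deterministic given (config, seed): replicate
seeds are seed, seed+1, …; every output file is hashed into a manifest
with the config hash. Default problem sizes — 3 × 20,000-frame traces in
the demo pipeline, 3 × 100,000 frames in the acceptance script, a
6-helix × 24-residue bundle, 960 SASA points, 0.3–0.4 Å rendering
voxels — were chosen so each stage completes in seconds on one CPU
while keeping Monte-Carlo error well inside the tolerances quoted above.

## Known limitations

- Straight-axis pore paths only; no curved channel search or cavity
  detection, no water analysis.
- The slab objective has a 0.5 Å grid resolution and a principal-axis
  normal; oblique membranes in real assemblies need the normal override.
- The toy bundle's reduced representation (Cα + pseudo-CB) means
  absolute SASA values on it are not comparable to full-atom models —
  only ratios and interfaces are used.
- Q-score internals of other implementations (exact sampling counts,
  occlusion policy) vary; deposited-data scores are soft targets with
  stated tolerances, while synthetic self-agreement is the hard test.
- The curated variant environments encode the documented structural
  context for the changes named in the source material; classifications
  of other variants depend on the supplied structure and thresholds.
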