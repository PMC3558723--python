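# Methods

This note records what the package computes, the choices that shape each
verdict, and what the synthetic fixtures do and do not establish about
real crystal structures.

## Lattice expansion

A crystal entry is reduced to the heavy atoms of model 1 (hydrogens and
waters removed; alternate locations collapsed to the highest-occupancy
conformer, ties broken by altloc label order). Space-group operators are
resolved from the Hermann–Mauguin symbol via gemmi; a missing or
placeholder cell leaves the structure without crystal context (sequence
analyses still run; lattice operations raise), and an unknown symbol is a
hard error naming the symbol.

Symmetry mates are generated as (operator, integer lattice shift) pairs.
The shift window is derived per operator: with fractionalization matrix F,
a Cartesian margin r maps to per-axis fractional margins r·‖Fᵢ·‖, and the
window is the interval of integer shifts for which the shifted fractional
bounding box of the transformed molecule can approach the asymmetric
unit's box within that margin. This makes the window adaptive — large
molecules in small cells reach ±2 and beyond — rather than the customary
fixed ±1. A mate is emitted only if an actual atom pair falls within the
radius (k-d tree check), and the identity operation with zero shift is
never emitted. The default mate radius is 5.0 Å, strictly larger than the
4.5 Å contact cutoff so no contact-bearing mate can be missed.

Coordinates are Cartesian ångströms everywhere; fractional coordinates
appear only inside symmetry application. Whether the inspection should
extend past the first shell of neighbours is not something the survey's
subject matter fixes; the adaptive window is this package's own choice and
is recorded in the report provenance.

## Domain annotation

Annotation is deliberately manifest-driven: a curated TSV per entry lists
each chain's molecule and its domain segments in author numbering
(residues are keyed by chain, author number and insertion code, and are
never renumbered). Reproducibility of partner classification must not
depend on an automatic Ig-domain segmentation heuristic, so none exists
here. Residues of annotated chains outside all segments become domain
"other"; unannotated chains become molecule "other". A declared chain
absent from the structure is a hard error; a declared segment with no
resolved residues is a recorded warning, not an error.

Cα residues are mapped to Ig-fold elements (strands A–G; loops AB, BC, CD,
DE, EF, FG — loops are the complements of strands, so the tiling is
exhaustive) by aligning the entry's resolved Cα sequence to a bundled
species reference (global alignment, BLOSUM62, gap open 11 / extend 1).
Element names transfer through aligned non-gap columns; below 30 %
identity the transfer is refused and flagged rather than guessed.

The bundled references are the mature human and mouse TCR α constant-domain
sequences with author-numbering offsets chosen to match the reference
crystal entries' numbering. The curation is internally validated: a single
offset (+107 for human, +117 for mouse) places every literature-cited site
(human N141/N175/N186; mouse N185/N199) on the expected residue, and the
strand boundaries place them on the expected elements (C strand start, EF
loop, F strand for human; EF and FG loops for mouse). The mouse FG-loop
site is sometimes printed as 189 and sometimes 199 in the literature; the
consistent-offset argument supports 199, and no test depends on the label,
only on the count.

## Contact detection and classification

A contact is any heavy-atom pair within 4.5 Å — the standard
crystal-contact criterion — between a Cα-domain atom and a *different
molecule instance*: a different complex in the ASU, any symmetry mate, or,
within the same complex, any molecule other than the TCR α chain itself.
Within-complex β-chain and MHC contacts are included because the survey's
partner classification treats them on the same footing as lattice
neighbours; every record carries mate provenance (`ASU` or
`op{i}+({u},{v},{w})`), so either reading — lattice-only or
lattice-plus-ASU — can be recovered by filtering. Waters, ions, glycans
and other non-protein HETATM groups are never partners. No minimum
interface size is applied at detection (a single atom pair registers);
interfaces are judged at the assessment stage, so "barely touching" pairs
are kept and visible.

Verdicts rank partners by heavy-atom pair count. "Cα forms dimer" is
reserved for the case where the top partner is another Cα *and* the pair
passed the symmetry assessment; otherwise the verdict lists the contacted
partner domains; a contact-free complex reports "no contact".

## Dimer assessment

**Symmetry.** The two Cα copies are superposed by least-squares (Kabsch)
over backbone atoms shared by residue number, with the mate-side copy
placed at its lattice position. The relating transformation x → Rx + t is
reduced to rotation angle, rotation axis, and screw = |axis·t| (the
translation component along the axis, which is invariant to the choice of
axis point). A pair counts as 2-fold symmetric at angle ≥ 160° and screw
≤ 3 Å — tolerant of lattice distortion, while a 90°-rotated touching pair
fails by a wide margin. Fewer than 80 % of the manifest-declared Cα
residues resolved on either side makes the pair "insufficient-coordinates".

**Membrane orientation.** Each complex's membrane axis is the unit vector
from its V-module (Vα+Vβ) backbone centroid to its C-module (Cα+Cβ)
centroid — centroids rather than C-terminal residues, because the
connecting peptides are frequently disordered in these entries; either
module under 50 % resolved makes the orientation "undetermined". For a
symmetric pair, the axis tilt is the average of the 2-fold axis's angles
to the two membrane axes, each folded into [0°, 90°] (the rotation maps
one membrane axis onto the other, so the two angles agree for an exact
2-fold; whenever the mean membrane axis is nonzero this equals the angle
to the mean, and it remains defined in the exactly-flat case where the
mean vanishes). Tilt ≤ 45° classifies the pair upright-side-by-side, above
45° flat-on-membrane; 45° is the midpoint between the two ideal
geometries, is exposed in the configuration, and is reported alongside
every result. Non-symmetric pairs are "asymmetric-touch" and report the
angle between the two membrane axes instead.

**Interface composition.** Per side, each Cα contact atom counts once for
its residue's element regardless of how many partner atoms it touches
(avoiding double-weighting atoms in multiple pairs); per-element fractions
are averaged over the two sides and normalized over elements plus
"unassigned". A pair is model-consistent only when symmetric, upright,
and C+F fraction ≥ 0.5.

## Sequon analysis

The scanner reports every N-X-S/T with X ≠ P, overlapping sites included;
ambiguity letters never match. X = Pro is excluded as part of the standard
sequon definition (proline at X blocks transfer), a deliberately stricter
reading than "X is any amino acid". The efficiency rule — N-X-S sites are
efficient unless X ∈ {W, D, E, L} — is stated in the literature for the
serine sequon only; N-X-T defaults to efficient here, and the rule lives
in a swappable table so alternative published rules can be substituted.
An efficient sequon whose Asn maps to the C or F strand (or to an
observed interface's element set, when one is supplied) occludes that
interface; one such site suffices for the "dimer-interface-occluded"
verdict. Hits that cannot be mapped onto structure residues are flagged
unmapped and excluded from the verdict. The notion of the Cα "outer face"
is reported through strand location only; no solvent-accessibility
calculation enters the verdict.

## Synthetic fixtures

The toy domain is a rigid backbone-only (N, CA, C, O) point cloud: two
stacked sheets (A-B-E-D and C-G-F) of straight antiparallel strands 3.4 Å
per residue, loops bridging strand ends with an outward bulge in the
strand direction and pulled inward in the sheet plane, and the F strand
bowed 2 Å proud of its sheet so that it alone forms one face of the
domain. Element labels tile the sequence (strands weighted 3:1 over
loops), and the emitted strand map is the ground truth for transfer tests.
Sequences are drawn from the 17 letters without N/S/T so planted sequons
are the only sequons.

Four toy domains (Vα, Vβ above; Cα, Cβ below) form a TCR-like complex
whose membrane axis points down −z and whose Cα F face is the +x face of
the whole complex. Scenario geometry exploits that face: a 180° rotation
about an axis perpendicular to the face normal, through a point half a
gap beyond the face, maps the face plane onto a parallel plane at the
chosen gap for *every* axis tilt — so upright (tilt 0°), flat (tilt 90°)
and the whole 0–90° sweep all present touching F faces with an exact
2-fold, with a 4.0 Å gap placing only F-strand atoms within the 4.5 Å
cutoff. The lattice-contact scenario parks a 180°-rotated partner far
inside a P1 cell whose a-axis length makes the two F faces meet across
the cell boundary, exercising the symmetry-mate code path with
identity ±(1,0,0) mates. The asymmetric touch rotates the partner 90°
about z and advances it by bisection until overall clearance reaches
3.6 Å, which lands Cα-on-Cα by construction. Cells are otherwise three
times the molecular extent so nothing else touches.

What the fixtures do *not* emulate: real side chains (contacts are
backbone-only, so interface fractions are cleaner than in real lattices),
realistic Ig geometry or energetics, disorder, alternate conformations,
glycan HETATM groups, or non-orthorhombic cells with oblique angles
(the parser and symmetry algebra handle them; the fixtures simply do not
generate them). Passing the fixture suite therefore establishes the
correctness of the geometry, bookkeeping and classification logic — not
that any particular real lattice contains or lacks a dimer; the
survey-reproduction checks on deposited structures do that, and they
require a one-time fetch plus manifest curation (see README).

## Numerical notes

- Superposition uses SVD with a reflection guard; the rotation angle
  comes from the rotation-vector norm, so an exact planted 180° rotation
  is recovered to < 10⁻³ degrees from full-precision coordinates. PDB
  serialization rounds coordinates to 10⁻³ Å, which limits angles
  recovered from re-read files to ~10⁻² degrees; tests acknowledge the
  two regimes explicitly.
- Candidate pairs are canonicalized through the inverse symmetry
  operation, so the same interface seen from either molecule is assessed
  once; swapping the two complexes leaves every assessment field
  unchanged.
- All tabular outputs are sorted on full key columns; reruns on identical
  inputs are byte-identical, and survey results are independent of
  manifest row order and directory listing order.
- Angles are reported at 0.1° precision in tables (3 decimals
  internally); distances at 10⁻⁴ Å.
- The tilt classification at exactly 45.0° is knife-edge by construction;
  the sweep tests assert a single boundary crossing rather than the label
  of the boundary point itself.

## Problem sizes

The bundled verification suite runs entirely on synthetic inputs sized
for exactness rather than realism: toy domains of 50–60 residues (four
atoms per residue), complexes of ~1 900 atoms, five scenarios across ten
seeds in the acceptance script, brute-force oracle windows of ±2 lattice
shifts, and 10 000 random sequences for the scanner oracle. These sizes
make every oracle exhaustive while keeping the whole suite interactive.
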