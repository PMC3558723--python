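# tcrsurvey

Crystal-packing analysis of T-cell receptor (TCR) constant-α domains.

## The problem

Two views of early αβ TCR triggering differ on whether TCR heterodimers
dimerize in *cis* on the T-cell surface. One proposal places the dimer
interface on the **C and F β-strands of the Cα domain** (the
membrane-proximal constant Ig domain of the TCR α chain). If such a dimer
were physiological, it should appear as a crystal contact in at least some
TCR/pMHC complex crystal lattices, because crystal packing and biological
assembly obey the same energetics.

`tcrsurvey` makes that test computable. For each crystal structure it:

1. **Expands the lattice** — resolves the space-group operators from the
   Hermann–Mauguin symbol and generates exactly the symmetry mates with any
   atom within a chosen radius of the asymmetric unit (lattice-shift window
   derived per entry from the cell and molecular extent, never a fixed ±1);
2. **Annotates domains** — a curated manifest maps chains and author-numbered
   residue ranges to Vα/Cα/Vβ/Cβ, MHC subdomains, peptide and CD4; Cα
   residues are assigned to Ig-fold elements (strands A–G, loops AB–FG) by
   global alignment (BLOSUM62, gap 11/1) to a bundled species reference;
3. **Detects Cα contacts** — every heavy-atom pair ≤ 4.5 Å between a Cα atom
   and a different molecule instance (another complex in the ASU, a
   symmetry mate, or the same complex's β chain / MHC), classified by
   partner domain;
4. **Assesses candidate Cα–Cα dimers** — least-squares superposition of the
   two copies yields the relating rigid transformation; a genuine 2-fold has
   rotation ≈ 180° with near-zero screw (translation along the axis). The
   membrane axis of each complex (V-module → C-module centroid vector)
   orients the dimer: axis tilt ≤ 45° means the pair could stand upright
   side by side, larger tilt means it could only lie flat on the membrane.
   Interface composition counts Cα-side contact atoms per Ig element. A pair
   is **model-consistent** only if it is symmetric, upright, and the C+F
   strands carry ≥ 50 % of the interface;
5. **Scans for N-glycosylation sequons** — N-X-S/T with X ≠ P; for N-X-S the
   site is efficiently glycosylated unless X ∈ {W, D, E, L}. An efficient
   sequon on the C or F strand occludes the putative dimer interface, since
   a branched glycan there is incompatible with a protein–protein dimer on
   the same face.

A first-class synthetic-fixture generator builds toy crystals (pseudo-Ig
domains assembled into TCR-like complexes, planted 2-fold dimers at chosen
axis tilts, planted lattice contacts, planted sequons) whose ground truth
the pipeline must recover exactly, so every stage is verifiable offline.

## Worked example

Simulate a planted upright 2-fold dimer and survey it:

```sh
tcrsurvey simulate --scenario upright-2fold-dimer --seed 1 --out demo
tcrsurvey survey --manifest demo/TOY-UPRIGHT-2FOLD-DIMER_manifest.tsv \
    --structures demo --strandmaps demo --out demo/report
```

`demo/report/survey.tsv`:

```
entry_id                 mhc_class species n_complexes status verdict         ...
TOY-UPRIGHT-2FOLD-DIMER            toy     2           ok     Cα forms dimer
```

`demo/report/assessments.tsv` (the geometric verdict for the one candidate
pair):

```
pair_label     is_symmetric two_fold_rotation_angle screw_translation orientation_class    two_fold_axis_tilt interface_elements model2_consistent
1|ASU<->2|ASU  True         180.0                   0.0               upright-side-by-side 0.0                F:1.000            True
```

Read: the two Cα copies are related by an exact 180° rotation with zero
screw, the 2-fold axis is parallel to the membrane axes (tilt 0°), and the
interface is pure F strand — exactly the planted geometry, and the only
configuration the dimerization model would accept.

Sequon analysis of the bundled Cα references prints the conserved sites:

```python
>>> from tcrsurvey import scan_reference, load_strand_map
>>> from tcrsurvey.glyco import occlusion_check
>>> hits = scan_reference(load_strand_map("human"))
>>> [(h.author_number, h.sequon_string, h.element_name, h.efficient) for h in hits]
[(141, 'NVS', 'C', True), (175, 'NKS', 'EF', True), (186, 'NNS', 'F', True)]
>>> occlusion_check(hits).verdict
'dimer-interface-occluded'
```

The human Cα carries three efficient sequons — at the start of the C strand
(N141), on the EF loop (N175) and on the F strand (N186) — so the proposed
C/F-strand dimer face is glycan-occluded. The mouse reference carries two
sequons, both on loops (EF: N185, FG: N199), leaving the C/F face open by
that criterion:

```python
>>> [(h.author_number, h.sequon_string, h.element_name) for h in
...  scan_reference(load_strand_map("mouse"))]
[(185, 'NQT', 'EF'), (199, 'NAT', 'FG')]
```

## Command-line interface

- `tcrsurvey survey --manifest M.tsv --structures DIR [--config C] [--strandmaps DIR] --out OUT`
  — full survey; writes `survey.tsv`, `contacts.tsv`, `assessments.tsv`,
  `provenance.json` (config + SHA-256 checksums) and `survey.log`.
- `tcrsurvey glyco --fasta F.fasta [--structure S.pdb --manifest M.tsv]`
  — sequon table for sequences or a structure's Cα domains.
- `tcrsurvey simulate --scenario NAME --seed K --out DIR` — synthetic
  scenario with its ground-truth JSON (`isolated`,
  `lattice-contact-F-strand`, `upright-2fold-dimer`, `flat-2fold-dimer`,
  `asymmetric-touch`).
- `tcrsurvey fetch --out DIR` — optional, network-only helper that
  downloads the survey set; the analysis pipeline itself is strictly
  offline.

Every threshold (contact cutoff 4.5 Å, mate radius 5.0 Å, symmetry angle
≥ 160° / screw ≤ 3 Å, upright/flat boundary 45°, alignment identity 30 %,
model C+F fraction 0.5) lives in a config file (`key = value`) and is
recorded in the report provenance. See `docs/methods.md` for the rationale
behind each choice and the package's known limitations.
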