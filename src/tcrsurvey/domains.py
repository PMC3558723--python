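"""Residue-level domain annotation and Ig-fold strand mapping.

Annotation is manifest-driven: a curated TSV assigns each chain of each
entry to a molecule (TCR alpha/beta, MHC chains, peptide, CD4, ...) and
lists its domain segments in author numbering. Automatic domain
segmentation is deliberately avoided so that survey verdicts never depend
on a parsing heuristic.

Strand elements of the C-alpha immunoglobulin fold (strands A-G and the
connecting loops) are transferred onto each entry by global pairwise
alignment against a bundled species reference sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ManifestError
from .structure_io import CrystalStructure

CA_DOMAIN = "Cα"

MANIFEST_COLUMNS = [
    "entry_id", "complex_index", "chain_id", "molecule",
    "domain_name", "start", "end", "species",
]

STRAND_ELEMENTS = ["A", "B", "C", "D", "E", "F", "G"]
LOOP_ELEMENTS = ["AB", "BC", "CD", "DE", "EF", "FG"]


def one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


@dataclass
class AnnotationManifest:
    """Curated chain/domain assignments for one or more entries."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        t = self.table
        if len(t) and (t["start"] > t["end"]).any():
            bad = t[t["start"] > t["end"]].iloc[0]
            raise ManifestError(
                f"segment start > end for {bad['entry_id']}/{bad['chain_id']}"
            )
        # segments within one chain must not overlap
        for (entry, chain), grp in t.groupby(["entry_id", "chain_id"]):
            seg = grp.sort_values("start")
            prev_end = None
            for _, row in seg.iterrows():
                if prev_end is not None and row["start"] <= prev_end:
                    raise ManifestError(
                        f"overlapping segments on {entry}/{chain} at {row['start']}"
                    )
                prev_end = row["end"]
        # exactly one C-alpha segment per complex for annotated entries
        for (entry, cx), grp in t.groupby(["entry_id", "complex_index"]):
            n_ca = (grp["domain_name"] == CA_DOMAIN).sum()
            if n_ca != 1:
                raise ManifestError(
                    f"{entry} complex {cx}: expected exactly one {CA_DOMAIN} "
                    f"segment, found {n_ca}"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationManifest":
        table = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "icode": str})
        return cls(table)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "AnnotationManifest":
        return cls(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def entries(self) -> list[str]:
        return sorted(self.table["entry_id"].unique())

    def for_entry(self, entry_id: str) -> pd.DataFrame:
        sub = self.table[self.table["entry_id"] == entry_id]
        if sub.empty:
            raise ManifestError(f"manifest has no rows for entry {entry_id!r}")
        return sub

    def species_of(self, entry_id: str) -> str:
        return str(self.for_entry(entry_id)["species"].iloc[0])


@dataclass
class StrandMap:
    """Ig-fold element tiling of a reference C-alpha sequence.

    ``elements`` holds (element_name, start_offset, end_offset) with 1-based
    inclusive offsets into ``reference_sequence``; ``author_start`` is the
    author residue number of offset 1 in the reference entry, so sequon and
    strand positions can be reported in the numbering the field uses.
    """

    species: str
    elements: list[tuple[str, int, int]]
    reference_sequence: str
    author_start: int = 1

    def __post_init__(self):
        covered = []
        names = [e[0] for e in self.elements]
        if len(set(names)) != len(names):
            raise ManifestError("strand map element names must be unique")
        for name, s, e in sorted(self.elements, key=lambda x: x[1]):
            covered.extend(range(s, e + 1))
        if covered != list(range(1, len(self.reference_sequence) + 1)):
            raise ManifestError("strand map elements must tile the reference")
        for required in ("C", "F"):
            if required not in names:
                raise ManifestError(f"strand map lacks the {required} strand")

    def element_at(self, offset: int) -> str:
        """Element name at a 1-based reference offset ('' outside)."""
        for name, s, e in self.elements:
            if s <= offset <= e:
                return name
        return ""

    def element_at_author(self, author_number: int) -> str:
        return self.element_at(author_number - self.author_start + 1)


def _read_author_start(description: str) -> int:
    for token in description.split():
        if token.startswith("author_start="):
            return int(token.split("=", 1)[1])
    return 1


def load_strand_map(species: str, data_dir: str | Path | None = None) -> StrandMap:
    """Load a bundled (or external) strand map + reference sequence.

    Expects ``strandmap_<species>.tsv`` with columns (species, element,
    start_offset, end_offset) and ``ca_reference_<species>.fasta`` whose
    header may carry ``author_start=<n>``.
    """
    if data_dir is None:
        root = resources.files("tcrsurvey").joinpath("data")
    else:
        root = Path(data_dir)
    tsv = root.joinpath(f"strandmap_{species}.tsv")
    fasta = root.joinpath(f"ca_reference_{species}.fasta")
    table = pd.read_csv(str(tsv), sep="\t")
    with open(str(fasta)) as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    elements = [
        (str(r["element"]), int(r["start_offset"]), int(r["end_offset"]))
        for _, r in table.iterrows()
    ]
    return StrandMap(
        species=species,
        elements=elements,
        reference_sequence=str(record.seq),
        author_start=_read_author_start(record.description),
    )


@dataclass
class DomainAnnotation:
    """Per-residue molecule/domain/element assignment for one entry.

    ``residues`` columns: chain, resnum, icode, aa, complex_index, molecule,
    domain_name, element_name. ``expected_counts`` maps
    (complex_index, domain_name) to the residue count the manifest declares,
    for resolved-fraction checks downstream.
    """

    entry_id: str
    species: str
    residues: pd.DataFrame
    expected_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def lookup(self) -> dict:
        """(chain, resnum, icode) -> row dict, for fast joins."""
        return {
            (r.chain, r.resnum, r.icode): r
            for r in self.residues.itertuples(index=False)
        }

    def ca_complexes(self) -> list[int]:
        mask = self.residues["domain_name"] == CA_DOMAIN
        return sorted(self.residues.loc[mask, "complex_index"].unique())

    def ca_sequence(self, complex_index: int) -> tuple[str, pd.DataFrame]:
        """C-alpha sequence (file order) and its residue rows for one complex."""
        mask = (self.residues["domain_name"] == CA_DOMAIN) & (
            self.residues["complex_index"] == complex_index
        )
        rows = self.residues[mask]
        return "".join(rows["aa"]), rows


def annotate(structure: CrystalStructure, manifest: AnnotationManifest) -> DomainAnnotation:
    """Label every residue of ``structure`` from the curated manifest.

    Residues inside declared segments take the segment's molecule/domain;
    residues of annotated chains outside every segment become domain
    "other"; chains without manifest rows become molecule "other"
    (complex_index 0). A declared chain absent from the structure is a hard
    error; a declared segment with zero resolved residues is a recorded
    warning.
    """
    rows = manifest.for_entry(structure.entry_id)
    species = str(rows["species"].iloc[0])
    present_chains = set(structure.atoms["chain"].unique())
    declared_chains = set(rows["chain_id"].astype(str))
    missing = declared_chains - present_chains
    if missing:
        raise ManifestError(
            f"{structure.entry_id}: manifest declares absent chains {sorted(missing)}"
        )

    chain_info = {}  # chain -> (complex_index, molecule)
    segments = []  # (chain, start, end, complex_index, molecule, domain)
    for _, r in rows.iterrows():
        chain = str(r["chain_id"])
        chain_info.setdefault(chain, (int(r["complex_index"]), str(r["molecule"])))
        segments.append(
            (chain, int(r["start"]), int(r["end"]),
             int(r["complex_index"]), str(r["molecule"]), str(r["domain_name"]))
        )

    res_keys = structure.atoms[
        structure.atoms["is_protein"]
    ][["chain", "resnum", "icode", "resname"]].drop_duplicates()

    out = []
    seg_hits = {i: 0 for i in range(len(segments))}
    for r in res_keys.itertuples(index=False):
        molecule, domain, cx = "other", "other", 0
        if r.chain in chain_info:
            cx, molecule = chain_info[r.chain]
            for i, (chain, start, end, s_cx, s_mol, s_dom) in enumerate(segments):
                if chain == r.chain and start <= r.resnum <= end:
                    cx, molecule, domain = s_cx, s_mol, s_dom
                    seg_hits[i] += 1
                    break
        out.append(
            (r.chain, r.resnum, r.icode, one_letter(r.resname),
             cx, molecule, domain, "")
        )

    notes = []
    expected = {}
    for i, (chain, start, end, cx, mol, dom) in enumerate(segments):
        expected[(cx, dom)] = expected.get((cx, dom), 0) + (end - start + 1)
        if seg_hits[i] == 0:
            msg = (
                f"{structure.entry_id}: segment {dom} {chain}:{start}-{end} "
                "has zero resolved residues"
            )
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)

    residues = pd.DataFrame(
        out,
        columns=["chain", "resnum", "icode", "aa", "complex_index",
                 "molecule", "domain_name", "element_name"],
    )
    return DomainAnnotation(
        entry_id=structure.entry_id,
        species=species,
        residues=residues,
        expected_counts=expected,
        warnings=notes,
    )


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def map_strands(
    annotation: DomainAnnotation,
    strand_map: StrandMap,
    min_identity: float = 0.30,
) -> DomainAnnotation:
    """Transfer Ig-fold element names onto each complex's C-alpha residues.

    Each C-alpha sequence is globally aligned (BLOSUM62, gap open 11 /
    extend 1) to the species reference; element names flow through aligned
    non-gap columns. An alignment below ``min_identity`` leaves elements
    empty and records a strand-transfer-unreliable warning.
    """
    if strand_map.species != annotation.species:
        raise ManifestError(
            f"strand map species {strand_map.species!r} does not match "
            f"annotation species {annotation.species!r}"
        )
    aligner = _make_aligner()
    residues = annotation.residues.copy()
    notes = list(annotation.warnings)
    ref = strand_map.reference_sequence

    for cx in annotation.ca_complexes():
        seq, rows = annotation.ca_sequence(cx)
        if not seq:
            continue
        aln = aligner.align(ref, seq)[0]
        blocks = aln.aligned
        n_aligned = 0
        n_ident = 0
        assignments = {}  # positional index within seq -> element
        for (rs, re), (qs, qe) in zip(blocks[0], blocks[1]):
            for k in range(re - rs):
                ref_pos = rs + k  # 0-based
                q_pos = qs + k
                n_aligned += 1
                if ref[ref_pos] == seq[q_pos]:
                    n_ident += 1
                assignments[q_pos] = strand_map.element_at(ref_pos + 1)
        identity = n_ident / n_aligned if n_aligned else 0.0
        if identity < min_identity:
            msg = (
                f"{annotation.entry_id} complex {cx}: strand-transfer-unreliable "
                f"(identity {identity:.2f} < {min_identity:.2f})"
            )
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        idx = rows.index.to_list()
        for q_pos, element in assignments.items():
            residues.at[idx[q_pos], "element_name"] = element

    return DomainAnnotation(
        entry_id=annotation.entry_id,
        species=annotation.species,
        residues=residues,
        expected_counts=dict(annotation.expected_counts),
        warnings=notes,
    )
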