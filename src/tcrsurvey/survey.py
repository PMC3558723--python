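"""Whole-survey orchestration: structures in, Table-style report out.

For every entry in the annotation manifest the pipeline reads the
structure, annotates domains, transfers Ig strand elements, generates
symmetry mates, detects C-alpha contacts, assesses every candidate
C-alpha/C-alpha pair, scans the C-alpha sequence for glycosylation
sequons, and writes three TSV tables (survey, contacts, assessments) plus
a JSON sidecar with the configuration and input checksums. Outputs are
deterministic: identical inputs and configuration give byte-identical
tables regardless of directory listing or manifest row order.

The pipeline itself never touches the network; a separate fetch script may
populate the structures directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import SurveyConfig
from .contacts import CONTACT_COLUMNS, find_ca_contacts, summarize
from .dimers import assess_all_pairs
from .domains import (
    AnnotationManifest,
    DomainAnnotation,
    StrandMap,
    annotate,
    load_strand_map,
    map_strands,
)
from .errors import InsufficientCoordinatesError, ManifestError, TcrSurveyError
from .glyco import find_sequons, map_hits_to_structure, occlusion_check
from .structure_io import expand_symmetry, read_structure

logger = logging.getLogger("tcrsurvey")

SURVEY_COLUMNS = [
    "entry_id", "species", "n_complexes", "status", "verdict",
    "n_contact_records", "n_ca_ca_pairs", "n_symmetric_pairs",
    "n_model2_consistent", "glyco_verdict",
]
ASSESSMENT_COLUMNS = [
    "entry_id", "pair_label", "is_symmetric", "two_fold_rotation_angle",
    "screw_translation", "orientation_class", "axis_angle",
    "two_fold_axis_tilt", "interface_elements", "model2_consistent",
    "n_contact_atoms",
]


@dataclass
class EntryResult:
    """Everything computed for one entry."""

    entry_id: str
    status: str  # ok | skipped | failed
    annotation: DomainAnnotation | None = None
    contacts: pd.DataFrame | None = None
    assessments: list = field(default_factory=list)
    verdict: str = ""
    glyco_verdict: str = ""
    detail: str = ""


def _entry_metadata() -> dict[str, str]:
    """entry_id -> MHC class for the bundled survey set ('' elsewhere)."""
    from importlib import resources

    path = resources.files("tcrsurvey").joinpath("data/table1_entries.tsv")
    table = pd.read_csv(str(path), sep="\t")
    return dict(zip(table["entry_id"], table["mhc_class"]))


def _find_structure_file(structures_dir: Path, entry_id: str) -> Path | None:
    for stem in (entry_id, entry_id.lower(), entry_id.upper()):
        for ext in (".pdb", ".ent", ".cif", ".mmcif"):
            p = structures_dir / f"{stem}{ext}"
            if p.exists():
                return p
    return None


def _strand_map_for(
    species: str, strandmap_dir: Path | None, cache: dict
) -> StrandMap | None:
    if species in cache:
        return cache[species]
    sm = None
    if strandmap_dir is not None:
        try:
            sm = load_strand_map(species, strandmap_dir)
        except FileNotFoundError:
            sm = None
    if sm is None:
        try:
            sm = load_strand_map(species)
        except FileNotFoundError:
            sm = None
    cache[species] = sm
    return sm


def _format_fractions(fractions: dict[str, float]) -> str:
    return ";".join(f"{k}:{v:.3f}" for k, v in sorted(fractions.items()))


def run_entry(
    path: Path,
    manifest: AnnotationManifest,
    entry_id: str,
    config: SurveyConfig,
    strandmap_dir: Path | None = None,
    _sm_cache: dict | None = None,
) -> EntryResult:
    """Run the full pipeline on one structure file."""
    structure = read_structure(path)
    structure.entry_id = entry_id
    annotation = annotate(structure, manifest)
    sm = _strand_map_for(annotation.species, strandmap_dir, _sm_cache or {})
    if sm is not None:
        annotation = map_strands(annotation, sm, config.alignment_min_identity)
    else:
        logger.warning("%s: no strand map for species %r", entry_id, annotation.species)

    mates = expand_symmetry(structure, config.mate_radius) if structure.has_crystal_context else []
    records = find_ca_contacts(structure, annotation, mates, config.contact_cutoff)

    assessments = []
    try:
        assessments = assess_all_pairs(structure, annotation, records, config)
    except InsufficientCoordinatesError as exc:
        logger.warning("%s: %s", entry_id, exc)
    symmetric = {
        cx for a in assessments if a.is_symmetric for cx in a.complex_indices
    }
    summary = summarize(records, annotation, symmetric)

    glyco_parts = []
    for cx in annotation.ca_complexes():
        seq, _ = annotation.ca_sequence(cx)
        hits = map_hits_to_structure(find_sequons(seq, f"{entry_id}/{cx}"), annotation, cx)
        report = occlusion_check(hits)
        glyco_parts.append(f"{len(hits)} sequons, {report.verdict}")
        break  # complexes are copies; the first suffices for the entry verdict
    result = EntryResult(
        entry_id=entry_id,
        status="ok",
        annotation=annotation,
        contacts=records,
        assessments=assessments,
        verdict=summary.verdict_string(),
        glyco_verdict="; ".join(glyco_parts) if glyco_parts else "no Cα",
    )
    logger.info(
        "%s: %d contacts, %d pairs, verdict %r",
        entry_id, len(records), len(assessments), result.verdict,
    )
    return result


def run_survey(
    manifest_path: str | Path,
    structures_dir: str | Path,
    config: SurveyConfig | None = None,
    out_dir: str | Path | None = None,
    strandmap_dir: str | Path | None = None,
) -> dict[str, Path | pd.DataFrame]:
    """Survey every manifest entry; write survey/contacts/assessments TSVs.

    Entries whose structure file is absent are reported as "skipped", never
    silently dropped. Returns the output paths and in-memory tables.
    """
    config = config or SurveyConfig()
    manifest = AnnotationManifest.from_tsv(manifest_path)
    if manifest.table.empty:
        raise ManifestError(f"manifest {manifest_path} is empty")
    structures_dir = Path(structures_dir)
    strandmap_dir = Path(strandmap_dir) if strandmap_dir else None
    sm_cache: dict = {}

    survey_rows = []
    contact_tables = []
    assessment_rows = []
    checksums = {}
    for entry_id in manifest.entries():
        rows = manifest.for_entry(entry_id)
        species = str(rows["species"].iloc[0])
        n_complexes = int(rows["complex_index"].nunique())
        path = _find_structure_file(structures_dir, entry_id)
        if path is None:
            logger.warning("%s: structure file not found, skipped", entry_id)
            survey_rows.append(
                (entry_id, species, n_complexes, "skipped", "skipped",
                 0, 0, 0, 0, "")
            )
            continue
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        res = run_entry(path, manifest, entry_id, config, strandmap_dir, sm_cache)
        n_sym = sum(a.is_symmetric for a in res.assessments)
        n_m2 = sum(a.model2_consistent for a in res.assessments)
        survey_rows.append(
            (entry_id, species, n_complexes, res.status, res.verdict,
             len(res.contacts), len(res.assessments), n_sym, n_m2,
             res.glyco_verdict)
        )
        contact_tables.append(res.contacts)
        for a in res.assessments:
            assessment_rows.append(
                (a.entry_id, a.pair_label, a.is_symmetric,
                 a.two_fold_rotation_angle, a.screw_translation,
                 a.orientation_class,
                 "" if a.axis_angle is None else a.axis_angle,
                 "" if a.two_fold_axis_tilt is None else a.two_fold_axis_tilt,
                 _format_fractions(a.interface_element_fractions),
                 a.model2_consistent, a.n_contact_atoms)
            )

    survey = pd.DataFrame(survey_rows, columns=SURVEY_COLUMNS)
    survey.insert(1, "mhc_class", survey["entry_id"].map(_entry_metadata()).fillna(""))
    non_empty = [t for t in contact_tables if len(t)]
    contacts = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else pd.DataFrame(columns=CONTACT_COLUMNS)
    )
    assessments = pd.DataFrame(assessment_rows, columns=ASSESSMENT_COLUMNS)

    out: dict[str, Path | pd.DataFrame] = {
        "survey": survey, "contacts": contacts, "assessments": assessments,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        survey.to_csv(out_dir / "survey.tsv", sep="\t", index=False)
        contacts.to_csv(out_dir / "contacts.tsv", sep="\t", index=False)
        assessments.to_csv(out_dir / "assessments.tsv", sep="\t", index=False)
        sidecar = {
            "package_version": __version__,
            "config": config.to_dict(),
            "structure_checksums_sha256": checksums,
            "manifest": str(manifest_path),
        }
        (out_dir / "provenance.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )
        out.update(
            survey_path=out_dir / "survey.tsv",
            contacts_path=out_dir / "contacts.tsv",
            assessments_path=out_dir / "assessments.tsv",
            provenance_path=out_dir / "provenance.json",
        )
    return out
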