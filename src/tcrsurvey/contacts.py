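"""Inter-molecular contacts of the TCR C-alpha domain.

A contact is a heavy-atom pair within ``contact_cutoff`` between a C-alpha
domain atom and any protein atom of a *different molecule instance*: a
different complex in the asymmetric unit, a symmetry mate, or — within the
same complex — any chain other than the TCR alpha chain itself (the beta
chain and MHC sit next to C-alpha in the same complex and are classified as
partners just like lattice neighbours). Waters, ions, glycans and other
non-protein HETATM groups never count as partners.

No minimum interface size is imposed at detection: a single qualifying atom
pair registers, so near-threshold interfaces ("barely touch") are kept and
filtering happens at assessment/reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .domains import CA_DOMAIN, DomainAnnotation
from .structure_io import CrystalStructure, SymmetryMate

MOL_TCR_ALPHA = "TCRα"

CONTACT_COLUMNS = [
    "entry_id", "ca_complex_index", "ca_chain", "ca_resnum", "ca_icode",
    "ca_element", "ca_atom", "partner_mate", "partner_chain",
    "partner_resnum", "partner_icode", "partner_complex_index",
    "partner_molecule", "partner_domain", "partner_atom", "distance",
]

_PARTNER_PREFIX = {
    "TCRα": "TCR", "TCRβ": "TCR",
    "MHCI-heavy": "MHCI", "MHCII-α": "MHCII", "MHCII-β": "MHCII",
    "β2m": "β2m", "peptide": "peptide", "CD4": "CD4", "other": "other",
}


def partner_label(molecule: str, domain: str) -> str:
    """Human-readable partner class, e.g. 'TCR Vβ', 'MHCII β2', 'CD4 D1'."""
    prefix = _PARTNER_PREFIX.get(molecule, molecule)
    if domain in ("other", "") or prefix in ("β2m", "peptide", "other"):
        return prefix
    return f"{prefix} {domain}"


def _atom_annotation(structure: CrystalStructure, annotation: DomainAnnotation):
    """Per-atom complex/molecule/domain/element arrays aligned with atoms rows."""
    lut = annotation.lookup()
    n = len(structure.atoms)
    cx = np.zeros(n, int)
    mol = np.full(n, "other", object)
    dom = np.full(n, "other", object)
    elem = np.full(n, "", object)
    protein = structure.atoms["is_protein"].to_numpy()
    keys = list(
        zip(structure.atoms["chain"], structure.atoms["resnum"], structure.atoms["icode"])
    )
    for i, key in enumerate(keys):
        if not protein[i]:
            continue
        row = lut.get(key)
        if row is None:
            continue
        cx[i] = row.complex_index
        mol[i] = row.molecule
        dom[i] = row.domain_name
        elem[i] = row.element_name
    return cx, mol, dom, elem, protein


def find_ca_contacts(
    structure: CrystalStructure,
    annotation: DomainAnnotation,
    mates: list[SymmetryMate],
    contact_cutoff: float = 4.5,
) -> pd.DataFrame:
    """All qualifying C-alpha contacts, one row per heavy-atom pair.

    ``mates`` must come from ``expand_symmetry`` with a radius larger than
    ``contact_cutoff``. An empty result is a valid outcome ("no contact").
    """
    cx, mol, dom, elem, protein = _atom_annotation(structure, annotation)
    xyz = structure.xyz
    atoms = structure.atoms
    is_ca = (dom == CA_DOMAIN) & protein

    records: list[tuple] = []

    def emit(ca_idx: np.ndarray, partner_idx: np.ndarray, partner_xyz: np.ndarray,
             mate_label: str):
        if len(ca_idx) == 0 or len(partner_idx) == 0:
            return
        tree = cKDTree(partner_xyz[partner_idx])
        pairs = cKDTree(xyz[ca_idx]).query_ball_tree(tree, r=contact_cutoff)
        for a_local, plist in enumerate(pairs):
            i = ca_idx[a_local]
            for p_local in plist:
                j = partner_idx[p_local]
                d = float(np.linalg.norm(xyz[i] - partner_xyz[j]))
                records.append(
                    (
                        structure.entry_id, int(cx[i]),
                        atoms.at[i, "chain"], int(atoms.at[i, "resnum"]),
                        atoms.at[i, "icode"], elem[i], atoms.at[i, "name"],
                        mate_label, atoms.at[j, "chain"],
                        int(atoms.at[j, "resnum"]), atoms.at[j, "icode"],
                        int(cx[j]), mol[j], dom[j], atoms.at[j, "name"],
                        round(d, 4),
                    )
                )

    protein_idx = np.flatnonzero(protein)
    for complex_index in annotation.ca_complexes():
        ca_idx = np.flatnonzero(is_ca & (cx == complex_index))
        # within-ASU partners: everything except this complex's own alpha chain
        own_alpha = (cx == complex_index) & (mol == MOL_TCR_ALPHA)
        asu_partner_idx = np.flatnonzero(protein & ~own_alpha)
        emit(ca_idx, asu_partner_idx, xyz, "ASU")
        # every symmetry mate is a different molecule instance by definition
        for mate in mates:
            emit(ca_idx, protein_idx, mate.transformed_xyz, mate.mate_label)

    df = pd.DataFrame(records, columns=CONTACT_COLUMNS)
    return df.sort_values(CONTACT_COLUMNS, kind="mergesort").reset_index(drop=True)


@dataclass
class CaContactSummary:
    """Per-complex partner ranking and Table-style verdict for one entry."""

    entry_id: str
    partner_counts: dict  # complex_index -> list[(label, n_atom_pairs)]
    verdicts: dict  # complex_index -> verdict string

    def verdict_string(self) -> str:
        """One line for the whole entry, complexes joined in index order."""
        parts = [self.verdicts[cxi] for cxi in sorted(self.verdicts)]
        uniq = sorted(set(parts))
        if len(uniq) == 1:
            return uniq[0]
        return "; ".join(f"complex {cxi}: {self.verdicts[cxi]}" for cxi in sorted(self.verdicts))


def summarize(
    records: pd.DataFrame,
    annotation: DomainAnnotation,
    symmetric_dimer_complexes: set[int] | frozenset[int] = frozenset(),
) -> CaContactSummary:
    """Rank contact partners per complex and phrase a survey verdict.

    Partners are ordered by descending heavy-atom pair count. The verdict is
    "no contact" for a contact-free complex, "Cα forms dimer" when the top
    partner is another C-alpha and the pair passed the symmetry assessment
    (``symmetric_dimer_complexes``), otherwise "Cα contacts <partners>".
    """
    counts: dict[int, list] = {}
    verdicts: dict[int, str] = {}
    for cxi in annotation.ca_complexes():
        sub = records[records["ca_complex_index"] == cxi] if len(records) else records
        if len(sub) == 0:
            counts[cxi] = []
            verdicts[cxi] = "no contact"
            continue
        labels = [
            partner_label(m, d)
            for m, d in zip(sub["partner_molecule"], sub["partner_domain"])
        ]
        tally = pd.Series(labels).value_counts()
        ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        counts[cxi] = ranked
        top = ranked[0][0]
        if top == f"TCR {CA_DOMAIN}" and cxi in symmetric_dimer_complexes:
            verdicts[cxi] = "Cα forms dimer"
        else:
            verdicts[cxi] = "Cα contacts " + " and ".join(lbl for lbl, _ in ranked)
    return CaContactSummary(annotation.entry_id, counts, verdicts)
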