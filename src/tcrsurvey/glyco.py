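"""N-linked glycosylation sequon scanning and interface-occlusion logic.

The sequon is the tripeptide N-X-S/T with X any residue except proline
(X = Pro blocks transfer and is excluded from the motif itself, the
standard definition). For N-X-S sequons an efficiency rule applies: the
site is expected to be efficiently glycosylated unless X is Trp, Asp, Glu
or Leu. The published rule covers only the serine sequon; N-X-T sites
default to efficient, and the rule table is swappable for alternative
published rules.

An efficient sequon whose asparagine sits on an interface strand (by
default the C and F strands of the C-alpha Ig fold) occludes that
interface: a bulky glycan there is incompatible with a protein-protein
dimer through the same face.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .domains import DomainAnnotation, StrandMap, CA_DOMAIN

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

# third residue -> set of X residues that make the site inefficient
DEFAULT_EFFICIENCY_RULES: dict[str, frozenset[str]] = {
    "S": frozenset("WDEL"),
    "T": frozenset(),
}

DEFAULT_INTERFACE_ELEMENTS = frozenset({"C", "F"})

OCCLUDED = "dimer-interface-occluded"
NOT_OCCLUDED = "not-occluded"


@dataclass(frozen=True)
class SequonHit:
    """One N-X-S/T site.

    ``position`` is the 1-based index of the Asn in the scanned sequence;
    ``author_number`` is filled when the hit maps onto structure residues,
    ``element_name`` when the Asn lies in an annotated C-alpha domain.
    """

    sequence_id: str
    position: int
    sequon_string: str
    efficient: bool
    author_number: int | None = None
    element_name: str = ""
    on_outer_face: bool | None = None

    @property
    def x_residue(self) -> str:
        return self.sequon_string[1]

    @property
    def third_residue(self) -> str:
        return self.sequon_string[2]


def efficiency_flag(
    sequon: str, rules: dict[str, frozenset[str]] = DEFAULT_EFFICIENCY_RULES
) -> bool:
    """Apply the efficiency rule to one 3-letter sequon."""
    return sequon[1] not in rules[sequon[2]]


def find_sequons(
    sequence: str,
    sequence_id: str = "",
    rules: dict[str, frozenset[str]] = DEFAULT_EFFICIENCY_RULES,
) -> list[SequonHit]:
    """Every N-X-S/T site (X != P) in the sequence, overlapping hits included.

    Ambiguity codes (X/B/Z...) are tolerated in the input and never match
    as N, S or T. Sequences shorter than 3 yield no hits.
    """
    seq = sequence.upper()
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] != "N" or seq[i + 1] == "P" or seq[i + 2] not in ("S", "T"):
            continue
        sequon = seq[i : i + 3]
        hits.append(
            SequonHit(
                sequence_id=sequence_id,
                position=i + 1,
                sequon_string=sequon,
                efficient=efficiency_flag(sequon, rules),
            )
        )
    return hits


def map_hits_to_structure(
    hits: list[SequonHit],
    annotation: DomainAnnotation,
    complex_index: int,
) -> list[SequonHit]:
    """Attach author residue numbers and Ig elements to C-alpha sequence hits.

    The hits must come from scanning ``annotation.ca_sequence(complex_index)``:
    position *k* in that sequence is the *k*-th resolved C-alpha residue.
    """
    _, rows = annotation.ca_sequence(complex_index)
    numbered = list(rows.itertuples(index=False))
    out = []
    for hit in hits:
        if 1 <= hit.position <= len(numbered):
            row = numbered[hit.position - 1]
            out.append(
                replace(hit, author_number=int(row.resnum), element_name=row.element_name)
            )
        else:
            out.append(hit)
    return out


def scan_reference(strand_map: StrandMap, sequence_id: str | None = None) -> list[SequonHit]:
    """Scan a species C-alpha reference sequence with author numbering and elements."""
    sid = sequence_id or f"{strand_map.species}_ca_reference"
    hits = find_sequons(strand_map.reference_sequence, sid)
    return [
        replace(
            h,
            author_number=strand_map.author_start + h.position - 1,
            element_name=strand_map.element_at(h.position),
        )
        for h in hits
    ]


@dataclass
class OcclusionReport:
    """Per-hit occlusion flags and the domain-level verdict."""

    hits: list[SequonHit]
    occludes: list[bool]
    unmapped: list[bool]
    verdict: str


def occlusion_check(
    hits: list[SequonHit],
    interface_elements: frozenset[str] | set[str] = DEFAULT_INTERFACE_ELEMENTS,
) -> OcclusionReport:
    """Test whether efficient sequons sit on the putative dimer interface.

    A hit occludes when it is efficient and its Asn lies on one of
    ``interface_elements`` (default: the C and F strands, the proposed
    dimer interface; pass an observed interface element set instead to test
    a specific crystal dimer). Hits without a structural mapping are
    flagged unmapped and excluded from the verdict.
    """
    occludes, unmapped = [], []
    for hit in hits:
        has_mapping = hit.author_number is not None
        unmapped.append(not has_mapping)
        occludes.append(
            bool(has_mapping and hit.efficient and hit.element_name in interface_elements)
        )
    verdict = OCCLUDED if any(occludes) else NOT_OCCLUDED
    return OcclusionReport(list(hits), occludes, unmapped, verdict)
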