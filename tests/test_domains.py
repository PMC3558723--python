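"""Manifest-driven annotation and Ig strand-element transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tcrsurvey as ts
from tcrsurvey.domains import AnnotationManifest, StrandMap, load_strand_map
from tcrsurvey.errors import ManifestError


def test_annotate_labels_planted_domains(scenario_cache):
    data = scenario_cache("upright-2fold-dimer")
    ann = data["annotation"]
    counts = ann.residues.groupby(["complex_index", "domain_name"]).size()
    for cx in (1, 2):
        for dom, n in (("Vα", 50), ("Cα", 60), ("Vβ", 50), ("Cβ", 60)):
            assert counts[(cx, dom)] == n


def test_single_segment_manifest_covers_every_residue(scenario_cache):
    data = scenario_cache("isolated")
    structure = data["structure"]
    rows = [
        dict(entry_id=structure.entry_id, complex_index=1, chain_id=c,
             molecule="TCRα" if c == "A" else "TCRβ", domain_name=d,
             start=-10_000, end=10_000, species="toy")
        for c, d in (("A", "Cα"), ("B", "Cβ"))
    ]
    ann = ts.annotate(structure, AnnotationManifest.from_rows(rows))
    assert set(ann.residues["domain_name"]) == {"Cα", "Cβ"}


def test_annotation_independent_of_manifest_row_order(scenario_cache):
    data = scenario_cache("flat-2fold-dimer")
    structure, bundle = data["structure"], data["bundle"]
    shuffled = AnnotationManifest(
        bundle.manifest.table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    )
    a = ts.annotate(structure, bundle.manifest).residues
    b = ts.annotate(structure, shuffled).residues
    assert a.equals(b)


def test_annotate_is_idempotent(scenario_cache):
    data = scenario_cache("isolated")
    a = ts.annotate(data["structure"], data["bundle"].manifest).residues
    b = ts.annotate(data["structure"], data["bundle"].manifest).residues
    assert a.equals(b)


def test_absent_declared_chain_is_hard_error(scenario_cache):
    data = scenario_cache("isolated")
    table = data["bundle"].manifest.table.copy()
    table.loc[table.index[0], "chain_id"] = "Z"
    with pytest.raises(ManifestError, match="Z"):
        ts.annotate(data["structure"], AnnotationManifest(table))


def test_empty_segment_recorded_as_warning(scenario_cache):
    data = scenario_cache("isolated")
    table = data["bundle"].manifest.table.copy()
    extra = table.iloc[[0]].copy()
    extra["domain_name"] = "other"
    extra["start"], extra["end"] = 9000, 9100
    manifest = AnnotationManifest(
        __import__("pandas").concat([table, extra], ignore_index=True)
    )
    with pytest.warns(UserWarning, match="zero resolved"):
        ann = ts.annotate(data["structure"], manifest)
    assert any("zero resolved" in w for w in ann.warnings)


def test_manifest_rejects_overlapping_segments(scenario_cache):
    table = scenario_cache("isolated")["bundle"].manifest.table.copy()
    table.loc[table.index[1], "start"] = 1  # collides with the V segment
    with pytest.raises(ManifestError, match="overlap"):
        AnnotationManifest(table)


def test_strand_transfer_identity_alignment(scenario_cache):
    """Aligning the toy reference to itself reproduces the planted tiling."""
    data = scenario_cache("isolated")
    ann = data["annotation"]
    sm = data["bundle"].strand_maps["toy"]
    ca = ann.residues[ann.residues["domain_name"] == "Cα"].reset_index(drop=True)
    expected = [sm.element_at(i + 1) for i in range(len(ca))]
    assert list(ca["element_name"]) == expected


def test_strand_transfer_survives_two_point_substitutions():
    """Oracle: gap-free alignment of a doubly mutated copy keeps all elements."""
    sm = load_strand_map("human")
    seq = list(sm.reference_sequence)
    # two interior substitutions away from element boundaries
    seq[5], seq[30] = "A", "G"
    mutated = "".join(seq)
    ref_ann = _transfer(sm, sm.reference_sequence)
    mut_ann = _transfer(sm, mutated)
    assert ref_ann == mut_ann


def _transfer(strand_map: StrandMap, query: str) -> list[str]:
    """Run map_strands on a synthetic single-chain annotation carrying ``query``."""
    import pandas as pd

    from tcrsurvey.domains import DomainAnnotation, map_strands

    residues = pd.DataFrame(
        {
            "chain": "A", "resnum": np.arange(1, len(query) + 1), "icode": "",
            "aa": list(query), "complex_index": 1, "molecule": "TCRα",
            "domain_name": "Cα", "element_name": "",
        }
    )
    ann = DomainAnnotation("TOY", strand_map.species, residues, {(1, "Cα"): len(query)})
    out = map_strands(ann, strand_map)
    return list(out.residues["element_name"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.data())
def test_strand_transfer_stable_under_sparse_substitutions(data):
    """<=5% substitutions never change any element assignment."""
    sm = load_strand_map("human")
    n = len(sm.reference_sequence)
    k = data.draw(st.integers(min_value=0, max_value=max(1, n // 20)))
    positions = data.draw(
        st.lists(st.integers(0, n - 1), min_size=k, max_size=k, unique=True)
    )
    letters = data.draw(
        st.lists(st.sampled_from("ARNDQGHIKMFWYV"), min_size=k, max_size=k)
    )
    seq = list(sm.reference_sequence)
    for p, c in zip(positions, letters):
        seq[p] = c
    assert _transfer(sm, "".join(seq)) == _transfer(sm, sm.reference_sequence)


def test_low_identity_leaves_elements_empty():
    sm = load_strand_map("human")
    rng = np.random.default_rng(11)
    junk = "".join(rng.choice(list("GPGPGP"), size=len(sm.reference_sequence)))
    with pytest.warns(UserWarning, match="strand-transfer-unreliable"):
        elements = _transfer(sm, junk)
    assert set(elements) == {""}


@pytest.mark.parametrize(
    "species,author,element",
    [
        ("human", 141, "C"), ("human", 175, "EF"), ("human", 186, "F"),
        ("mouse", 185, "EF"), ("mouse", 199, "FG"),
    ],
)
def test_bundled_strand_maps_place_known_glycan_sites(species, author, element):
    sm = load_strand_map(species)
    assert sm.element_at_author(author) == element


def test_strand_map_requires_c_and_f_strands():
    with pytest.raises(ManifestError, match="F strand"):
        StrandMap("x", [("A", 1, 5), ("C", 6, 10)], "A" * 10)
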