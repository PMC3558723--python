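"""Shared fixtures: cached synthetic scenarios and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

import tcrsurvey as ts
from tcrsurvey import fixtures as fx


@pytest.fixture(scope="session")
def scenario_cache(tmp_path_factory):
    """Build each (scenario, seed) once per session; returns a factory.

    The factory yields a dict with the bundle, the structure re-read from
    the written PDB, the strand-mapped annotation, mates, contact records,
    assessments and the survey-style verdict.
    """
    cache: dict = {}
    root = tmp_path_factory.mktemp("scenarios")

    def build(name: str, seed: int = 1):
        key = (name, seed)
        if key in cache:
            return cache[key]
        if name.startswith("tilt:"):
            bundle = fx.make_tilted_dimer_scenario(float(name.split(":")[1]), seed)
        else:
            bundle = fx.make_crystal_scenario(name, seed)
        out = root / f"{bundle.entry_id}-s{seed}"
        structure = fx.load_scenario_structure(bundle, out)
        annotation = ts.map_strands(
            ts.annotate(structure, bundle.manifest), bundle.strand_maps["toy"]
        )
        mates = ts.expand_symmetry(structure, 5.0)
        records = ts.find_ca_contacts(structure, annotation, mates, 4.5)
        assessments = ts.assess_all_pairs(structure, annotation, records)
        symmetric = {c for a in assessments if a.is_symmetric for c in a.complex_indices}
        summary = ts.summarize(records, annotation, symmetric)
        cache[key] = dict(
            bundle=bundle, structure=structure, annotation=annotation,
            mates=mates, records=records, assessments=assessments,
            summary=summary, out_dir=out,
        )
        return cache[key]

    return build


def brute_force_mates(structure, radius: float, window: int = 2) -> list[tuple]:
    """Oracle: exhaustive operator x lattice-shift enumeration in a fixed window."""
    xyz = structure.xyz
    F, O = structure.frac_matrix, structure.orth_matrix
    frac = xyz @ F.T
    tree = cKDTree(xyz)
    found = []
    for i, op in enumerate(structure.spacegroup_ops):
        moved = frac @ op.rot.T + op.tran
        for shift in itertools.product(range(-window, window + 1), repeat=3):
            if i == 0 and shift == (0, 0, 0) and op.is_identity():
                continue
            cart = (moved + np.asarray(shift, float)) @ O.T
            d, _ = tree.query(cart, k=1, distance_upper_bound=radius)
            if np.isfinite(d.min()) and d.min() <= radius:
                found.append((i, shift))
    return sorted(found)


def brute_force_ca_contacts(structure, annotation, cutoff: float, window: int = 2) -> set:
    """Oracle: all-pairs contact enumeration over every instance in the window.

    Returns {(ca_atom_row, mate_label, partner_atom_row)} using the same
    labelling scheme as the pipeline so the sets are directly comparable.
    """
    from scipy.spatial.distance import cdist

    atoms = structure.atoms
    lut = annotation.lookup()
    n = len(atoms)
    cx = np.zeros(n, int)
    mol = np.full(n, "other", object)
    dom = np.full(n, "other", object)
    protein = atoms["is_protein"].to_numpy()
    for k, key in enumerate(zip(atoms["chain"], atoms["resnum"], atoms["icode"])):
        row = lut.get(key)
        if row is not None and protein[k]:
            cx[k], mol[k], dom[k] = row.complex_index, row.molecule, row.domain_name
    xyz = structure.xyz
    out = set()
    for complex_index in sorted(set(cx[dom == "Cα"])):
        ca_idx = np.flatnonzero((dom == "Cα") & (cx == complex_index))
        # ASU partners
        ok = protein & ~((cx == complex_index) & (mol == "TCRα"))
        pd_idx = np.flatnonzero(ok)
        d = cdist(xyz[ca_idx], xyz[pd_idx])
        for a, b in zip(*np.nonzero(d <= cutoff)):
            out.add((int(ca_idx[a]), "ASU", int(pd_idx[b])))
        # every (op, shift) instance in the window
        if not structure.has_crystal_context:
            continue
        F, O = structure.frac_matrix, structure.orth_matrix
        frac = xyz @ F.T
        prot_idx = np.flatnonzero(protein)
        for i, op in enumerate(structure.spacegroup_ops):
            moved = frac @ op.rot.T + op.tran
            for shift in itertools.product(range(-window, window + 1), repeat=3):
                if i == 0 and shift == (0, 0, 0) and op.is_identity():
                    continue
                cart = (moved[prot_idx] + np.asarray(shift, float)) @ O.T
                d = cdist(xyz[ca_idx], cart)
                hit_a, hit_b = np.nonzero(d <= cutoff)
                label = f"op{i}+({shift[0]},{shift[1]},{shift[2]})"
                for a, b in zip(hit_a, hit_b):
                    out.add((int(ca_idx[a]), label, int(prot_idx[b])))
    return out


def contact_key_set(structure, records) -> set:
    """Pipeline records as {(ca_atom_row, mate_label, partner_atom_row)}."""
    atoms = structure.atoms
    index = {
        (r.chain, r.resnum, r.icode, r.name): i
        for i, r in enumerate(atoms.itertuples(index=False))
    }
    out = set()
    for r in records.itertuples(index=False):
        a = index[(r.ca_chain, r.ca_resnum, r.ca_icode, r.ca_atom)]
        b = index[(r.partner_chain, r.partner_resnum, r.partner_icode, r.partner_atom)]
        out.add((a, r.partner_mate, b))
    return out
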