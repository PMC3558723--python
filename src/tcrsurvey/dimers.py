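"""Geometric assessment of candidate C-alpha/C-alpha pairs.

Three questions decide whether a crystal contact could realize the proposed
C/F-strand dimerization of two TCRs:

1. *Symmetry* — superposing one C-alpha copy onto the other yields a rigid
   transformation; a genuine 2-fold dimer has a rotation angle near 180
   degrees with a near-zero screw (translation along the rotation axis).
2. *Membrane orientation* — each complex's membrane axis is the unit vector
   from its variable-module (Valpha+Vbeta) backbone centroid to its
   constant-module (Calpha+Cbeta) centroid, pointing toward the membrane.
   A physiological side-by-side dimer has its 2-fold axis roughly parallel
   to the membrane axes (tilt below the configured 45-degree boundary); a
   tilt beyond it means the pair could only sit flat on the membrane.
3. *Interface composition* — which Ig-fold elements of C-alpha carry the
   contact atoms; the dimerization model under test requires the C and F
   strands to dominate.

A pair is model-consistent only if all three verdicts line up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial.transform import Rotation

from .config import SurveyConfig
from .domains import CA_DOMAIN, DomainAnnotation
from .errors import InsufficientCoordinatesError
from .structure_io import CrystalStructure, SymmetryMate, invert_mate, transform_xyz

BACKBONE = ("N", "CA", "C", "O")
V_DOMAINS = ("Vα", "Vβ")
C_DOMAINS = ("Cα", "Cβ")

UPRIGHT = "upright-side-by-side"
FLAT = "flat-on-membrane"
ASYMMETRIC = "asymmetric-touch"
UNDETERMINED = "undetermined"


@dataclass
class SymmetryResult:
    is_symmetric: bool
    rotation_angle: float  # degrees in [0, 180]
    screw_translation: float  # angstrom
    axis: np.ndarray | None  # unit vector when angle > 0
    rmsd: float


@dataclass
class OrientationResult:
    orientation_class: str
    membrane_axis_1: np.ndarray | None
    membrane_axis_2: np.ndarray | None
    axis_angle: float | None  # degrees between the two membrane axes
    two_fold_axis_tilt: float | None  # degrees, [0, 90]


@dataclass
class DimerAssessment:
    """Full verdict for one candidate C-alpha pair."""

    entry_id: str
    pair_label: str
    complex_indices: tuple[int, int]
    mate_label: str
    is_symmetric: bool
    two_fold_rotation_angle: float
    screw_translation: float
    orientation_class: str
    axis_angle: float | None
    two_fold_axis_tilt: float | None
    interface_element_fractions: dict[str, float] = field(default_factory=dict)
    model2_consistent: bool = False
    n_contact_atoms: int = 0


def _domain_backbone(
    structure: CrystalStructure,
    annotation: DomainAnnotation,
    complex_index: int,
    domains: tuple[str, ...],
    transform: tuple[int, tuple[int, int, int]] | None = None,
) -> dict[tuple, np.ndarray]:
    """Backbone atom coordinates keyed by (chain, resnum, icode, atom_name).

    ``transform`` optionally applies a symmetry operation (op index, shift)
    so a mate-side instance can be assessed in its lattice position.
    """
    res = annotation.residues
    keys = res[
        (res["complex_index"] == complex_index) & (res["domain_name"].isin(domains))
    ][["chain", "resnum", "icode"]]
    wanted = set(map(tuple, keys.to_numpy()))
    atoms = structure.atoms
    mask = atoms["name"].isin(BACKBONE).to_numpy() & np.array(
        [
            (c, n, i) in wanted
            for c, n, i in zip(atoms["chain"], atoms["resnum"], atoms["icode"])
        ],
        dtype=bool,
    )
    sel = atoms[mask]
    xyz = sel[["x", "y", "z"]].to_numpy(float)
    if transform is not None and len(xyz):
        xyz = transform_xyz(structure, transform[0], transform[1], xyz)
    return {
        (r.chain, r.resnum, r.icode, r.name): xyz[k]
        for k, r in enumerate(sel.itertuples(index=False))
    }


def _chain_free(instance: dict[tuple, np.ndarray]) -> dict[tuple, np.ndarray]:
    """Drop the chain from instance keys so two complexes can be paired.

    Valid for single-chain selections (a C-alpha domain); residue numbers
    identify atoms across copies of the same complex.
    """
    return {k[1:]: v for k, v in instance.items()}


def _resolved_fraction(
    annotation: DomainAnnotation, complex_index: int, domains: tuple[str, ...]
) -> float:
    res = annotation.residues
    present = len(
        res[(res["complex_index"] == complex_index) & (res["domain_name"].isin(domains))]
    )
    expected = sum(
        annotation.expected_counts.get((complex_index, d), 0) for d in domains
    )
    return present / expected if expected else 0.0


def assess_symmetry(
    inst1: dict[tuple, np.ndarray],
    inst2: dict[tuple, np.ndarray],
    config: SurveyConfig = SurveyConfig(),
) -> SymmetryResult:
    """Rigid transformation relating two C-alpha copies, as angle/axis/screw.

    Least-squares superposition (Kabsch) over backbone atoms shared by
    residue number; the rotation angle and the translation component along
    the rotation axis decide 2-fold symmetry.
    """
    common = sorted(set(inst1) & set(inst2))
    if len(common) < 12:
        raise InsufficientCoordinatesError(
            f"only {len(common)} shared backbone atoms between the two copies"
        )
    x = np.array([inst1[k] for k in common])
    y = np.array([inst2[k] for k in common])
    sup = SVDSuperimposer()
    sup.set(y, x)  # maps x (copy 1) onto y (copy 2)
    sup.run()
    rot, tran = sup.get_rotran()
    R = rot.T  # column-vector convention
    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle > 1e-9:
        axis = rotvec / np.linalg.norm(rotvec)
        screw = float(abs(np.dot(axis, tran)))
    else:
        axis = None
        screw = float(np.linalg.norm(tran))
    return SymmetryResult(
        is_symmetric=(
            angle >= config.symmetry_min_angle and screw <= config.symmetry_max_screw
        ),
        rotation_angle=angle,
        screw_translation=screw,
        axis=axis,
        rmsd=float(sup.get_rms()),
    )


def _membrane_axis(
    structure: CrystalStructure,
    annotation: DomainAnnotation,
    complex_index: int,
    transform=None,
) -> np.ndarray | None:
    """Unit vector V-module centroid -> C-module centroid (toward membrane)."""
    if _resolved_fraction(annotation, complex_index, V_DOMAINS) < 0.5:
        return None
    if _resolved_fraction(annotation, complex_index, C_DOMAINS) < 0.5:
        return None
    v = _domain_backbone(structure, annotation, complex_index, V_DOMAINS, transform)
    c = _domain_backbone(structure, annotation, complex_index, C_DOMAINS, transform)
    if not v or not c:
        return None
    vec = np.mean(list(c.values()), axis=0) - np.mean(list(v.values()), axis=0)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else None


def _folded_angle(axis: np.ndarray, u: np.ndarray) -> float:
    """Angle between an undirected axis and a vector, folded into [0, 90]."""
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(axis, u)), 0.0, 1.0))))


def assess_orientation(
    structure: CrystalStructure,
    annotation: DomainAnnotation,
    complex_pair: tuple[int, int],
    transforms: tuple,
    symmetry: SymmetryResult,
    config: SurveyConfig = SurveyConfig(),
) -> OrientationResult:
    """Classify the pair's geometry relative to the cell membrane.

    For a symmetric pair the tilt of the 2-fold axis is the average of its
    folded angles to the two membrane axes (for an exact 2-fold the two
    angles are equal, and whenever the mean membrane axis is nonzero this
    equals the angle to it); upright at or below the configured boundary,
    flat above it. A non-symmetric pair is an asymmetric touch and only the
    angle between the two membrane axes is reported.
    """
    u1 = _membrane_axis(structure, annotation, complex_pair[0], transforms[0])
    u2 = _membrane_axis(structure, annotation, complex_pair[1], transforms[1])
    if u1 is None or u2 is None:
        return OrientationResult(UNDETERMINED, u1, u2, None, None)
    axis_angle = float(np.degrees(np.arccos(np.clip(np.dot(u1, u2), -1.0, 1.0))))
    if symmetry.is_symmetric and symmetry.axis is not None:
        tilt = 0.5 * (_folded_angle(symmetry.axis, u1) + _folded_angle(symmetry.axis, u2))
        cls = UPRIGHT if tilt <= config.orientation_tilt_boundary else FLAT
        return OrientationResult(cls, u1, u2, axis_angle, tilt)
    return OrientationResult(ASYMMETRIC, u1, u2, axis_angle, None)


def interface_element_fractions(
    side_records: list[pd.DataFrame],
) -> tuple[dict[str, float], int]:
    """Per-element share of C-alpha-side contact atoms, averaged over sides.

    Each side contributes each contact *atom* once regardless of how many
    partner atoms it touches; fractions sum to 1 over elements plus
    "unassigned". Returns the fractions and the total unique contact atoms.
    """
    side_fracs = []
    n_atoms = 0
    for side in side_records:
        if side is None or len(side) == 0:
            continue
        atoms = side.drop_duplicates(
            subset=["ca_chain", "ca_resnum", "ca_icode", "ca_atom"]
        )
        n_atoms += len(atoms)
        labels = atoms["ca_element"].replace("", "unassigned")
        side_fracs.append(labels.value_counts(normalize=True))
    if not side_fracs:
        return {}, 0
    combined = pd.concat(side_fracs, axis=1).fillna(0.0).mean(axis=1)
    combined = combined / combined.sum()
    return {str(k): float(v) for k, v in combined.sort_index().items()}, n_atoms


def _canonical_pair(
    structure: CrystalStructure, cx_i: int, cx_j: int, mate_label: str
) -> tuple[int, int, str]:
    """Canonical representation of a pair, identifying mirror duplicates."""
    if mate_label == "ASU":
        return (min(cx_i, cx_j), max(cx_i, cx_j), "ASU")
    op_index, shift = _parse_mate_label(mate_label)
    inv_op, inv_shift = invert_mate(structure, op_index, shift)
    alt = (cx_j, cx_i, SymmetryMate.label_for(inv_op, inv_shift))
    return min((cx_i, cx_j, mate_label), alt)


def _parse_mate_label(label: str) -> tuple[int, tuple[int, int, int]]:
    op_part, shift_part = label.split("+", 1)
    u, v, w = shift_part.strip("()").split(",")
    return int(op_part[2:]), (int(u), int(v), int(w))


def find_ca_ca_pairs(
    structure: CrystalStructure, records: pd.DataFrame
) -> list[tuple[int, int, str]]:
    """Unique candidate pairs (cx_i, cx_j, mate_label) from the contact table."""
    if len(records) == 0:
        return []
    caca = records[records["partner_domain"] == CA_DOMAIN]
    pairs = set()
    for r in caca.itertuples(index=False):
        pairs.add(
            _canonical_pair(
                structure, int(r.ca_complex_index), int(r.partner_complex_index),
                r.partner_mate,
            )
        )
    return sorted(pairs)


def _pair_side_records(
    structure: CrystalStructure,
    records: pd.DataFrame,
    pair: tuple[int, int, str],
) -> list[pd.DataFrame]:
    """Contact rows seen from each side of one interface."""
    cx_i, cx_j, label = pair
    caca = records[records["partner_domain"] == CA_DOMAIN]
    side1 = caca[
        (caca["ca_complex_index"] == cx_i)
        & (caca["partner_complex_index"] == cx_j)
        & (caca["partner_mate"] == label)
    ]
    if label == "ASU":
        mirror = "ASU"
    else:
        inv_op, inv_shift = invert_mate(structure, *_parse_mate_label(label))
        mirror = SymmetryMate.label_for(inv_op, inv_shift)
    side2 = caca[
        (caca["ca_complex_index"] == cx_j)
        & (caca["partner_complex_index"] == cx_i)
        & (caca["partner_mate"] == mirror)
    ]
    return [side1, side2]


def assess_pair(
    structure: CrystalStructure,
    annotation: DomainAnnotation,
    records: pd.DataFrame,
    pair: tuple[int, int, str],
    config: SurveyConfig = SurveyConfig(),
) -> DimerAssessment:
    """Run symmetry, orientation and interface analysis on one pair."""
    cx_i, cx_j, label = pair
    if _resolved_fraction(annotation, cx_i, (CA_DOMAIN,)) < 0.8 or (
        _resolved_fraction(annotation, cx_j, (CA_DOMAIN,)) < 0.8
    ):
        raise InsufficientCoordinatesError(
            f"{structure.entry_id} pair {pair}: <80% of the C-alpha segment resolved"
        )
    t2 = None if label == "ASU" else _parse_mate_label(label)
    inst1 = _chain_free(_domain_backbone(structure, annotation, cx_i, (CA_DOMAIN,)))
    inst2 = _chain_free(_domain_backbone(structure, annotation, cx_j, (CA_DOMAIN,), t2))
    symmetry = assess_symmetry(inst1, inst2, config)
    orientation = assess_orientation(
        structure, annotation, (cx_i, cx_j), (None, t2), symmetry, config
    )
    fractions, n_atoms = interface_element_fractions(
        _pair_side_records(structure, records, pair)
    )
    cf = fractions.get("C", 0.0) + fractions.get("F", 0.0)
    model2 = (
        symmetry.is_symmetric
        and orientation.orientation_class == UPRIGHT
        and cf >= config.model2_min_cf_fraction
    )
    return DimerAssessment(
        entry_id=structure.entry_id,
        pair_label=f"{cx_i}|ASU<->{cx_j}|{label}",
        complex_indices=(cx_i, cx_j),
        mate_label=label,
        is_symmetric=symmetry.is_symmetric,
        two_fold_rotation_angle=round(symmetry.rotation_angle, 3),
        screw_translation=round(symmetry.screw_translation, 3),
        orientation_class=orientation.orientation_class,
        axis_angle=None if orientation.axis_angle is None else round(orientation.axis_angle, 1),
        two_fold_axis_tilt=(
            None if orientation.two_fold_axis_tilt is None
            else round(orientation.two_fold_axis_tilt, 1)
        ),
        interface_element_fractions=fractions,
        model2_consistent=model2,
        n_contact_atoms=n_atoms,
    )


def assess_all_pairs(
    structure: CrystalStructure,
    annotation: DomainAnnotation,
    records: pd.DataFrame,
    config: SurveyConfig = SurveyConfig(),
) -> list[DimerAssessment]:
    """Assess every candidate C-alpha/C-alpha pair found in the contact table."""
    out = []
    for pair in find_ca_ca_pairs(structure, records):
        out.append(assess_pair(structure, annotation, records, pair, config))
    return out
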