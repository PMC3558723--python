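"""Crystal structure parsing and symmetry-mate generation.

gemmi does the heavy lifting for file formats (PDB and mmCIF), unit-cell
algebra and resolution of Hermann-Mauguin symbols into operator lists; this
module flattens one entry into array form convenient for contact analysis
and generates exactly the lattice neighbours that can touch the asymmetric
unit within a given radius.

Coordinates are Cartesian angstroms everywhere outside symmetry
application; fractional coordinates appear only inside
:func:`expand_symmetry` and the mate transforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import NoCrystalContextError, UnknownSpaceGroupError

_WATER_NAMES = {"HOH", "DOD", "WAT"}


@dataclass(frozen=True)
class SymOp:
    """One space-group operation in fractional coordinates."""

    rot: np.ndarray  # (3, 3)
    tran: np.ndarray  # (3,)

    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.rot, np.eye(3)) and np.allclose(self.tran % 1.0, 0.0)
        )


@dataclass
class CrystalStructure:
    """Heavy atoms, unit cell and space-group operators of one entry.

    ``atoms`` is a DataFrame with one row per heavy atom of model 1:
    ``name, element, resname, resnum, icode, chain, het, is_protein,
    x, y, z``. Author residue numbering is preserved.
    """

    entry_id: str
    atoms: pd.DataFrame
    cell: gemmi.UnitCell | None
    spacegroup_symbol: str
    spacegroup_ops: list[SymOp] = field(default_factory=list)

    @property
    def asu_chain_ids(self) -> list[str]:
        return sorted(self.atoms["chain"].unique())

    @property
    def xyz(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    @property
    def has_crystal_context(self) -> bool:
        return self.cell is not None and len(self.spacegroup_ops) > 0

    @property
    def frac_matrix(self) -> np.ndarray:
        self._require_cell()
        return np.array(self.cell.frac.mat.tolist())

    @property
    def orth_matrix(self) -> np.ndarray:
        self._require_cell()
        return np.array(self.cell.orth.mat.tolist())

    def _require_cell(self):
        if not self.has_crystal_context:
            raise NoCrystalContextError(
                f"{self.entry_id}: no unit cell / symmetry information"
            )

    def residue_keys(self) -> pd.DataFrame:
        """Unique (chain, resnum, icode) tuples in file order."""
        return self.atoms[["chain", "resnum", "icode"]].drop_duplicates()


@dataclass
class SymmetryMate:
    """One symmetry-related copy of the asymmetric unit near the ASU.

    ``transformed_xyz`` rows align with ``CrystalStructure.atoms`` rows.
    """

    source_op_index: int
    lattice_shift: tuple[int, int, int]
    transformed_xyz: np.ndarray
    mate_label: str
    min_distance: float

    @staticmethod
    def label_for(op_index: int, shift: tuple[int, int, int]) -> str:
        u, v, w = shift
        return f"op{op_index}+({u},{v},{w})"


def _resolve_ops(symbol: str) -> list[SymOp]:
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise UnknownSpaceGroupError(symbol)
    ops = []
    for op in sg.operations():
        den = float(op.DEN)
        ops.append(
            SymOp(rot=np.array(op.rot, float) / den, tran=np.array(op.tran, float) / den)
        )
    # gemmi lists the identity first; keep that invariant explicit.
    if not ops[0].is_identity():
        ops.sort(key=lambda o: not o.is_identity())
    return ops


def _coor_format(fmt: str) -> gemmi.CoorFormat:
    return {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }[fmt]


def read_structure(path: str | Path, fmt: str = "auto") -> CrystalStructure:
    """Read one entry: heavy atoms of model 1, cell and space-group operators.

    Hydrogens and waters are dropped. Alternate locations are reduced to the
    highest-occupancy conformer (ties broken by altloc label order). Missing
    or placeholder cell information yields a structure without crystal
    context; lattice operations on it raise :class:`NoCrystalContextError`.
    An unresolvable space-group symbol is a hard error.
    """
    path = Path(path)
    if fmt not in ("auto", "pdb", "mmcif"):
        raise ValueError(f"format must be pdb, mmcif or auto, not {fmt!r}")
    st = gemmi.read_structure(str(path), format=_coor_format(fmt))
    entry_id = (st.name or path.stem).strip() or path.stem

    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_water():
                continue
            is_protein = info.is_amino_acid() if info is not None else False
            # highest-occupancy altloc per atom name, ties by altloc order
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if (
                    prev is None
                    or atom.occ > prev.occ
                    or (atom.occ == prev.occ and atom.altloc < prev.altloc)
                ):
                    best[atom.name] = atom
            for atom in best.values():
                rows.append(
                    (
                        atom.name,
                        atom.element.name,
                        res.name,
                        res.seqid.num,
                        (res.seqid.icode or " ").strip(),
                        chain.name,
                        res.het_flag == "H",
                        is_protein,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                    )
                )
    atoms = pd.DataFrame(
        rows,
        columns=[
            "name", "element", "resname", "resnum", "icode", "chain",
            "het", "is_protein", "x", "y", "z",
        ],
    )

    cell = st.cell
    has_cell = cell.is_crystal() and cell.volume > 2.0
    symbol = (st.spacegroup_hm or "").strip()
    if not has_cell or not symbol:
        return CrystalStructure(entry_id, atoms, None, symbol, [])
    ops = _resolve_ops(symbol)
    return CrystalStructure(entry_id, atoms, cell, symbol, ops)


def transform_xyz(
    structure: CrystalStructure,
    op_index: int,
    lattice_shift: tuple[int, int, int],
    xyz: np.ndarray,
) -> np.ndarray:
    """Apply space-group operation ``op_index`` plus a lattice shift (Cartesian in/out)."""
    op = structure.spacegroup_ops[op_index]
    F = structure.frac_matrix
    O = structure.orth_matrix
    frac = xyz @ F.T
    moved = frac @ op.rot.T + op.tran + np.asarray(lattice_shift, float)
    return moved @ O.T


def _shift_window(
    frac_asu: np.ndarray,
    frac_moved: np.ndarray,
    margin_frac: np.ndarray,
) -> list[range]:
    """Integer shift ranges per axis that could bring ``frac_moved`` within margin."""
    lo = np.floor(frac_asu.min(0) - frac_moved.max(0) - margin_frac).astype(int)
    hi = np.ceil(frac_asu.max(0) - frac_moved.min(0) + margin_frac).astype(int)
    return [range(lo[i], hi[i] + 1) for i in range(3)]


def expand_symmetry(
    structure: CrystalStructure, contact_radius: float = 5.0
) -> list[SymmetryMate]:
    """Generate every symmetry mate with an atom within ``contact_radius`` of the ASU.

    The lattice-shift search window is derived per operator from the cell
    geometry and the molecule's fractional bounding box (never a fixed +-1),
    so large molecules in small cells still find all touching neighbours.
    The identity operation with zero shift is never emitted. Mates are
    ordered by (operator index, u, v, w).
    """
    if contact_radius <= 0:
        raise ValueError("contact_radius must be positive")
    structure._require_cell()
    xyz = structure.xyz
    if len(xyz) == 0:
        return []
    F = structure.frac_matrix
    O = structure.orth_matrix
    frac = xyz @ F.T
    # |delta_frac_i| <= ||row_i(F)|| * |delta_x| bounds the fractional margin
    margin = contact_radius * np.linalg.norm(F, axis=1)
    tree = cKDTree(xyz)

    mates: list[SymmetryMate] = []
    for i, op in enumerate(structure.spacegroup_ops):
        moved = frac @ op.rot.T + op.tran
        ranges = _shift_window(frac, moved, margin)
        for shift in itertools.product(*ranges):
            if i == 0 and shift == (0, 0, 0) and op.is_identity():
                continue
            cart = (moved + np.asarray(shift, float)) @ O.T
            d, _ = tree.query(cart, k=1, distance_upper_bound=contact_radius)
            dmin = d.min()
            if np.isfinite(dmin) and dmin <= contact_radius:
                mates.append(
                    SymmetryMate(
                        source_op_index=i,
                        lattice_shift=tuple(int(s) for s in shift),
                        transformed_xyz=cart,
                        mate_label=SymmetryMate.label_for(i, shift),
                        min_distance=float(dmin),
                    )
                )
    mates.sort(key=lambda m: (m.source_op_index, m.lattice_shift))
    return mates


def invert_mate(
    structure: CrystalStructure, op_index: int, lattice_shift: tuple[int, int, int]
) -> tuple[int, tuple[int, int, int]]:
    """Return (op_index, shift) of the inverse symmetry operation.

    If mate M maps the ASU onto a neighbour, the inverse maps that
    neighbour's frame back, i.e. the same interface seen from the other
    molecule. Needed to deduplicate candidate pairs.
    """
    op = structure.spacegroup_ops[op_index]
    rinv = np.linalg.inv(op.rot)
    tinv = -rinv @ (op.tran + np.asarray(lattice_shift, float))
    for j, other in enumerate(structure.spacegroup_ops):
        if not np.allclose(other.rot, rinv, atol=1e-9):
            continue
        diff = tinv - other.tran
        shift = np.round(diff)
        if np.allclose(diff, shift, atol=1e-9):
            return j, tuple(int(s) for s in shift)
    raise ValueError("operator inverse not found in space group (corrupt op list?)")


def write_mate_pdb(
    structure: CrystalStructure, mate: SymmetryMate, path: str | Path
) -> None:
    """Debug helper: write one transformed mate as a PDB file.

    The mate label goes into the TITLE record.
    """
    st = gemmi.Structure()
    st.name = f"{structure.entry_id} {mate.mate_label}"
    if structure.cell is not None:
        st.cell = structure.cell
        st.spacegroup_hm = structure.spacegroup_symbol
    model = gemmi.Model("1")
    xyz = mate.transformed_xyz
    for chain_id, chain_df in structure.atoms.groupby("chain", sort=False):
        chain = gemmi.Chain(str(chain_id))
        for (resnum, icode, resname), res_df in chain_df.groupby(
            ["resnum", "icode", "resname"], sort=False
        ):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(resnum), icode or " ")
            for idx, row in res_df.iterrows():
                atom = gemmi.Atom()
                atom.name = row["name"]
                atom.element = gemmi.Element(row["element"])
                atom.pos = gemmi.Position(*xyz[idx])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    doc_path = Path(path)
    st.raw_remarks = [f"TITLE     {st.name}"]
    st.write_pdb(str(doc_path))
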