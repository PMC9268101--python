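"""Molecule input/output and the in-memory molecular graph container.

Molecules enter as SMILES strings or V2000 SDF records and are normalized
into :class:`MolecularGraph` — a light, index-stable view of the hydrogen-
suppressed molecule (heavy atoms with attached-hydrogen counts, bonds with
orders 1/1.5/2/3, optional 3D coordinates and partial charges). RDKit does
the parsing and aromaticity perception; aromatic bonds always carry order
1.5 so that downstream descriptor arithmetic is Kekule-independent.

Activity tables (CSV with columns ``id,IC50_uM``) are joined onto graphs as
:class:`ActivityRecord` objects carrying the derived pIC50 and potency class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

from .activity import classify_activity, pic50_from_ic50

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "ActivityRecord",
    "ChemIOError",
    "parse_smiles",
    "read_smiles_file",
    "read_sdf",
    "write_sdf",
    "attach_activities",
]


class ChemIOError(ValueError):
    """Raised on malformed molecule or activity input."""


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    is_aromatic: bool = False
    attached_h: int = 0
    coords: Optional[tuple[float, float, float]] = None
    partial_charge: Optional[float] = None


@dataclass
class Bond:
    i: int
    j: int
    order: float  # 1, 1.5, 2 or 3; aromatic bonds are always 1.5


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph with 0-based atom indices."""

    atoms: list[Atom]
    bonds: list[Bond]
    id: str = ""
    rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ChemIOError(f"bond ({b.i},{b.j}) out of range for {n} atoms")
            if b.i == b.j:
                raise ChemIOError(f"self-bond on atom {b.i}")
            if b.order not in (1, 1.5, 2, 3):
                raise ChemIOError(f"unsupported bond order {b.order}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def total_h(self) -> int:
        return sum(a.attached_h for a in self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out

    def has_coords(self) -> bool:
        return all(a.coords is not None for a in self.atoms)


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    ic50_um: float
    pic50: float
    label: str


def _graph_from_rdmol(mol: Chem.Mol, mol_id: str) -> MolecularGraph:
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for a in mol.GetAtoms():
        xyz = None
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            xyz = (p.x, p.y, p.z)
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                is_aromatic=a.GetIsAromatic(),
                attached_h=a.GetTotalNumHs(),
                coords=xyz,
            )
        )
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, id=mol_id, rdmol=mol)


def parse_smiles(text: str, mol_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed MolecularGraph.

    Atom order follows the input SMILES. Multi-fragment inputs (salts,
    mixtures) are rejected: the modelled compounds are single molecules.
    """
    text = text.strip()
    if not text:
        raise ChemIOError("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        # best-effort localization: find the shortest prefix that also fails
        pos = next(
            (
                k
                for k in range(1, len(text) + 1)
                if Chem.MolFromSmiles(text[:k], sanitize=False) is None
            ),
            len(text),
        )
        raise ChemIOError(f"cannot parse SMILES {text!r} (near position {pos})")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ChemIOError(f"multi-fragment input rejected: {text!r}")
    return _graph_from_rdmol(mol, mol_id or text)


def read_smiles_file(path: str | Path) -> list[MolecularGraph]:
    """Read a SMILES file: one molecule per line, optional tab-separated id."""
    graphs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol{ln}"
        try:
            graphs.append(parse_smiles(smi, mol_id))
        except ChemIOError as exc:
            raise ChemIOError(f"line {ln}: {exc}") from exc
    return graphs


def read_sdf(path: str | Path) -> list[MolecularGraph]:
    """Read a V2000 SDF into graphs with 3D coordinates preserved in Angstrom.

    Explicit hydrogens are folded into attached-H counts; the record name
    (or its 1-based index when unnamed) becomes the graph id.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        return []
    graphs: list[MolecularGraph] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    for rec, mol in enumerate(supplier, start=1):
        if mol is None:
            raise ChemIOError(f"malformed SDF record {rec} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        graphs.append(_graph_from_rdmol(mol, name or f"record{rec}"))
    return graphs


def _rdmol_from_graph(graph: MolecularGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in graph.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.formal_charge)
        at.SetNoImplicit(True)
        at.SetNumExplicitHs(a.attached_h)
        rw.AddAtom(at)
    order_map = {
        1: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
    }
    for b in graph.bonds:
        rw.AddBond(b.i, b.j, order_map[b.order])
        if b.order == 1.5:
            rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    for idx, a in enumerate(graph.atoms):
        rw.GetAtomWithIdx(idx).SetIsAromatic(a.is_aromatic)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, catchErrors=True)
    if graph.has_coords():
        conf = Chem.Conformer(mol.GetNumAtoms())
        for idx, a in enumerate(graph.atoms):
            conf.SetAtomPosition(idx, a.coords)
        mol.AddConformer(conf)
    mol.SetProp("_Name", graph.id)
    return mol


def write_sdf(graphs: Sequence[MolecularGraph], path: str | Path) -> None:
    """Write graphs to a V2000 SDF (coordinates kept when present)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for g in graphs:
            mol = g.rdmol if g.rdmol is not None else _rdmol_from_graph(g)
            if g.rdmol is not None and g.has_coords() and not mol.GetNumConformers():
                mol = _rdmol_from_graph(g)
            mol.SetProp("_Name", g.id)
            writer.write(mol)
    finally:
        writer.close()


def attach_activities(
    graphs: Iterable[MolecularGraph], csv_table: str | Path | pd.DataFrame
) -> list[tuple[MolecularGraph, ActivityRecord]]:
    """Join an activity CSV (columns ``id,IC50_uM``) onto molecular graphs.

    Returns (graph, record) pairs in graph order; unmatched graph ids are
    silently left out of the result but reported via the returned pairs'
    coverage. Duplicate table ids and non-positive IC50 values are errors.
    """
    if isinstance(csv_table, pd.DataFrame):
        table = csv_table.copy()
    else:
        table = pd.read_csv(csv_table)
    required = {"id", "IC50_uM"}
    if not required.issubset(table.columns):
        raise ChemIOError(f"activity table needs columns {sorted(required)}")
    table["id"] = table["id"].astype(str)
    dupes = table["id"][table["id"].duplicated()].tolist()
    if dupes:
        raise ChemIOError(f"duplicate ids in activity table: {dupes}")
    bad = table[~(table["IC50_uM"] > 0)]
    if len(bad):
        raise ChemIOError(
            f"non-positive IC50 rejected for ids: {bad['id'].tolist()}"
        )
    by_id = {row.id: float(row.IC50_uM) for row in table.itertuples()}
    pairs = []
    for g in graphs:
        if g.id in by_id:
            ic50 = by_id[g.id]
            rec = ActivityRecord(
                compound_id=g.id,
                ic50_um=ic50,
                pic50=pic50_from_ic50(ic50),
                label=classify_activity(ic50),
            )
            pairs.append((g, rec))
    return pairs
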