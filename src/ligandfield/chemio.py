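"""Molecule, complex and activity I/O plus dataset bookkeeping.

Everything downstream works on two light containers: :class:`MoleculeRecord`
(an aligned 3D small molecule with per-atom partial charges and interaction
typing) and :class:`ComplexStructure` (a protein-ligand complex, optionally
with multiple coordinate frames).  Readers exist for SDF V2000, Tripos MOL2
and PDB (including multi-MODEL trajectories); activities come from a simple
CSV with ``id`` plus either ``ic50_nM`` or ``pic50`` columns.

Units: coordinates and radii in Angstrom, charges in elementary charges,
activities as pIC50 (-log10 of molar IC50).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import constants

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "MoleculeRecord",
    "ComplexStructure",
    "DatasetSplit",
    "ChemIOError",
    "ParseError",
    "read_structures",
    "write_structures",
    "to_pic50",
    "from_pic50",
    "partition_dataset",
    "load_activities",
    "assign_typing",
    "infer_bonds",
    "load_table3",
    "load_reference_split_ids",
]


class ChemIOError(ValueError):
    """Raised for malformed chemical input (bad element, bad values)."""


class ParseError(ChemIOError):
    """Raised when a file cannot be parsed under the named standard."""


@dataclass
class AtomRecord:
    """A single atom: element, position, charge and interaction typing."""

    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float = 0.0
    is_donor_h_parent: bool = False
    is_acceptor: bool = False
    hydrophobic_weight: float = 0.0
    # residue annotation, used for protein atoms only
    name: str = ""
    chain: str = ""
    res_name: str = ""
    res_number: int = 0
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ChemIOError(f"atom {self.element}: coordinates must be a finite 3-vector")
        if self.vdw_radius == 0.0:
            self.vdw_radius = constants.vdw_radius(self.element)
        if self.vdw_radius <= 0:
            raise ChemIOError(f"atom {self.element}: vdw radius must be positive")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """Residue identity as (chain, residue number, insertion code)."""
        return (self.chain, self.res_number, self.insertion_code)


@dataclass
class MoleculeRecord:
    """An aligned 3D molecule with optional activity (pIC50)."""

    id: str
    atoms: list[AtomRecord]
    activity: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ChemIOError(f"molecule {self.id!r} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]

    def translated(self, shift: Sequence[float]) -> "MoleculeRecord":
        shift = np.asarray(shift, dtype=float)
        atoms = []
        for a in self.atoms:
            b = AtomRecord(
                a.element, a.coords + shift, a.partial_charge, a.vdw_radius,
                a.is_donor_h_parent, a.is_acceptor, a.hydrophobic_weight,
                a.name, a.chain, a.res_name, a.res_number, a.insertion_code,
            )
            atoms.append(b)
        return MoleculeRecord(self.id, atoms, self.activity)


@dataclass
class ComplexStructure:
    """Protein-ligand complex; ``frames`` holds alternate coordinate sets.

    Each frame is an (n_protein + n_ligand, 3) array ordered protein atoms
    first, then ligand atoms, matching the reference coordinates.
    """

    protein_atoms: list[AtomRecord]
    ligand: MoleculeRecord
    frames: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.protein_atoms) + len(self.ligand.atoms)
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ChemIOError(f"frame {k} has {f.shape[0]} atoms, expected {n}")
            self.frames[k] = f

    @property
    def n_atoms(self) -> int:
        return len(self.protein_atoms) + len(self.ligand.atoms)

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Map residue id -> indices into ``protein_atoms`` (file order)."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.protein_atoms):
            out.setdefault(a.residue_id, []).append(i)
        return out

    def frame_coords(self, k: int | None = None) -> np.ndarray:
        """Coordinates of frame ``k`` (None -> reference coordinates)."""
        if k is None:
            return np.vstack([np.array([a.coords for a in self.protein_atoms]),
                              self.ligand.coords])
        return self.frames[k]


@dataclass
class DatasetSplit:
    train: list[MoleculeRecord]
    test: list[MoleculeRecord]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        train_ids = {m.id for m in self.train}
        test_ids = {m.id for m in self.test}
        if train_ids & test_ids:
            raise ChemIOError("train and test sets overlap")
        if set(self.excluded) & (train_ids | test_ids):
            raise ChemIOError("excluded ids appear in a partition")


# ---------------------------------------------------------------------------
# typing rules


def infer_bonds(mol: MoleculeRecord) -> list[tuple[int, int]]:
    """Distance-based covalent connectivity.

    X-H bonds are assigned below 1.25 A, heavy-heavy bonds below 1.85 A.
    Good enough for typing rules on idealised geometries; not a perception
    algorithm for strained real-world structures.
    """
    xyz = mol.coords
    elems = mol.elements
    bonds = []
    n = len(elems)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d < 1e-6:
                continue
            cutoff = (constants.H_BOND_LENGTH_CUTOFF
                      if "H" in (elems[i], elems[j])
                      else constants.HEAVY_BOND_CUTOFF)
            if d <= cutoff:
                bonds.append((i, j))
    return bonds


def assign_typing(mol: MoleculeRecord) -> MoleculeRecord:
    """Assign donor/acceptor/hydrophobic typing flags in place.

    Rules (deterministic, table-driven):

    * donor parent: N/O/S with at least one covalently attached hydrogen;
    * acceptor: N or O (lone-pair bearing);
    * hydrophobic weight 1: C, S or halogen with \\|partial charge\\| < 0.2 e,
      else 0.
    """
    bonds = infer_bonds(mol)
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(mol.atoms))}
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    for i, a in enumerate(mol.atoms):
        has_h = any(mol.atoms[j].element == "H" for j in neighbors[i])
        a.is_donor_h_parent = a.element in constants.DONOR_PARENT_ELEMENTS and has_h
        a.is_acceptor = a.element in constants.ACCEPTOR_ELEMENTS
        hydrophobic_elem = (a.element == "C" or a.element == "S"
                            or a.element in constants.HALOGENS)
        a.hydrophobic_weight = float(
            hydrophobic_elem
            and abs(a.partial_charge) < constants.HYDROPHOBIC_CHARGE_CUTOFF)
    return mol


# ---------------------------------------------------------------------------
# readers / writers

_CHARGE_PROP = "PARTIAL_CHARGES"


def _check_elements(elems: Iterable[str], where: str) -> None:
    for e in elems:
        if e not in constants.VDW_RADII:
            raise ChemIOError(f"{where}: unknown element {e!r}")


def _mol_from_rdkit(rdmol, index: int, default_id: str) -> MoleculeRecord:
    from rdkit import Chem  # local import keeps rdkit optional at import time

    if rdmol is None:
        raise ParseError(f"record {index}: malformed molecule block")
    if rdmol.GetNumConformers() == 0:
        raise ParseError(f"record {index}: no 3D coordinates")
    conf = rdmol.GetConformer()
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    mol_id = name.strip() or default_id

    charges: list[float] | None = None
    if rdmol.HasProp(_CHARGE_PROP):
        charges = [float(x) for x in rdmol.GetProp(_CHARGE_PROP).split()]
        if len(charges) != rdmol.GetNumAtoms():
            raise ParseError(f"record {index}: {_CHARGE_PROP} length mismatch")
    elif all(a.HasProp("_TriposPartialCharge") for a in rdmol.GetAtoms()):
        charges = [float(a.GetProp("_TriposPartialCharge")) for a in rdmol.GetAtoms()]
    if charges is None:
        logger.warning("record %s: no partial charges in file, defaulting to 0", mol_id)
        charges = [0.0] * rdmol.GetNumAtoms()

    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        elem = a.GetSymbol()
        if elem not in constants.VDW_RADII:
            raise ChemIOError(f"record {index}: unknown element {elem!r}")
        p = conf.GetAtomPosition(i)
        atoms.append(AtomRecord(elem, np.array([p.x, p.y, p.z]), charges[i]))
    activity = None
    if rdmol.HasProp("pIC50"):
        activity = float(rdmol.GetProp("pIC50"))
    rec = MoleculeRecord(mol_id, atoms, activity)
    assign_typing(rec)
    rec.rdmol = rdmol  # type: ignore[attr-defined]  # kept for descriptor filters
    return rec


def _read_sdf(path: Path) -> list[MoleculeRecord]:
    from rdkit import Chem

    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = []
    for i, rdmol in enumerate(supplier):
        mols.append(_mol_from_rdkit(rdmol, i, default_id=f"mol{i}"))
    if not mols:
        raise ParseError(f"{path}: no molecule records")
    return mols


def _read_mol2(path: Path) -> list[MoleculeRecord]:
    from rdkit import Chem

    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    blocks = []
    current: list[str] = []
    for line in text.splitlines(keepends=True):
        if line.startswith("@<TRIPOS>MOLECULE") and current:
            blocks.append("".join(current))
            current = []
        current.append(line)
    if current:
        blocks.append("".join(current))
    mols = []
    for i, block in enumerate(blocks):
        rdmol = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
        mols.append(_mol_from_rdkit(rdmol, i, default_id=f"mol{i}"))
    if not mols:
        raise ParseError(f"{path}: no molecule records")
    return mols


def _read_pdb(path: Path) -> ComplexStructure:
    from Bio.PDB import PDBParser

    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises bare exceptions on bad input
        raise ParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise ParseError(f"{path}: no MODEL records or atoms")

    def split_model(model):
        prot, lig = [], []
        for chain in model:
            for res in chain:
                het = res.id[0].strip()
                is_het = het not in ("",) and het != "W"
                for atom in res:
                    elem = (atom.element or "").strip().capitalize() or atom.get_name()[0]
                    if elem not in constants.VDW_RADII:
                        raise ChemIOError(f"{path}: unknown element {elem!r}")
                    rec = AtomRecord(
                        elem, np.array(atom.coord, dtype=float),
                        name=atom.get_name(), chain=chain.id,
                        res_name=res.get_resname(), res_number=res.id[1],
                        insertion_code=res.id[2].strip(),
                    )
                    (lig if is_het else prot).append(rec)
        return prot, lig

    prot0, lig0 = split_model(models[0])
    if not lig0:
        # no HETATM ligand: treat the whole structure as protein-only complex
        # with a one-atom placeholder ligand is wrong; instead raise
        raise ParseError(f"{path}: no HETATM ligand found in complex")
    logger.warning("%s: PDB carries no partial charges, defaulting to 0", path.name)
    ligand = MoleculeRecord(lig0[0].res_name or path.stem, lig0)
    assign_typing(ligand)
    frames = []
    n0 = len(prot0) + len(lig0)
    for model in models[1:] if len(models) > 1 else []:
        p, l = split_model(model)
        coords = np.vstack([[a.coords for a in p], [a.coords for a in l]])
        if coords.shape[0] != n0:
            raise ParseError(f"{path}: frame atom count mismatch")
        frames.append(coords)
    if len(models) > 1:
        first = np.vstack([[a.coords for a in prot0], [a.coords for a in lig0]])
        frames.insert(0, first)
    return ComplexStructure(prot0, ligand, frames)


def read_structures(path, format: str | None = None):
    """Read molecules or a complex from ``path``.

    ``format`` is one of ``sdf``, ``mol2``, ``pdb``; inferred from the file
    suffix when omitted.  SDF/MOL2 return a list of :class:`MoleculeRecord`;
    PDB returns a :class:`ComplexStructure` (multi-MODEL files map model
    records to frames in file order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "mol2":
        return _read_mol2(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unsupported format {fmt!r}")


def _rdkit_from_record(mol: MoleculeRecord):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    em = Chem.RWMol()
    for a in mol.atoms:
        em.AddAtom(Chem.Atom(a.element))
    for i, j in infer_bonds(mol):
        em.AddBond(i, j, Chem.BondType.SINGLE)
    m = em.GetMol()
    conf = Chem.Conformer(len(mol.atoms))
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
    m.AddConformer(conf)
    m.SetProp("_Name", mol.id)
    m.SetProp(_CHARGE_PROP, " ".join(f"{a.partial_charge:.6f}" for a in mol.atoms))
    if mol.activity is not None:
        m.SetProp("pIC50", f"{mol.activity:.6f}")
    return m


def _write_sdf(mols: Sequence[MoleculeRecord], path: Path) -> None:
    from rdkit import Chem

    with Chem.SDWriter(str(path)) as w:
        w.SetKekulize(False)
        for mol in mols:
            w.write(getattr(mol, "rdmol", None) or _rdkit_from_record(mol))


def _write_mol2(mols: Sequence[MoleculeRecord], path: Path) -> None:
    # RDKit has no Tripos writer; emit a minimal but standard-conforming file.
    lines: list[str] = []
    for mol in mols:
        bonds = infer_bonds(mol)
        lines.append("@<TRIPOS>MOLECULE")
        lines.append(mol.id)
        lines.append(f"{len(mol.atoms)} {len(bonds)} 0 0 0")
        lines.append("SMALL")
        lines.append("USER_CHARGES")
        lines.append("@<TRIPOS>ATOM")
        for i, a in enumerate(mol.atoms, start=1):
            x, y, z = a.coords
            lines.append(
                f"{i:>4} {a.element}{i:<4} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                f"{a.element:<5} 1 LIG {a.partial_charge:>9.4f}")
        lines.append("@<TRIPOS>BOND")
        for k, (i, j) in enumerate(bonds, start=1):
            lines.append(f"{k:>4} {i + 1:>4} {j + 1:>4} 1")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_atom_line(serial: int, a: AtomRecord, coords, hetatm: bool,
                   name: str | None = None) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name = (name or a.name or a.element)[:4]
    res = (a.res_name or ("LIG" if hetatm else "GLY"))[:3]
    chain = (a.chain or "A")[:1]
    x, y, z = coords
    return (f"{record}{serial:>5} {name:<4}{'':1}{res:>3} {chain}"
            f"{a.res_number or 1:>4}{a.insertion_code or '':1}   "
            f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}          "
            f"{a.element.upper():>2}")


def _write_pdb(cx: ComplexStructure, path: Path) -> None:
    atoms = list(cx.protein_atoms) + list(cx.ligand.atoms)
    het_flags = [False] * len(cx.protein_atoms) + [True] * len(cx.ligand.atoms)
    # atom names must be unique within a residue: standard parsers silently
    # drop duplicate-named atoms, so disambiguate with a per-residue counter
    names: list[str] = []
    counters: dict[tuple, dict[str, int]] = {}
    seen: dict[tuple, set[str]] = {}
    for a, het in zip(atoms, het_flags):
        key = ("LIG",) if het else a.residue_id
        used = seen.setdefault(key, set())
        name = (a.name or a.element)[:4]
        if name in used:
            cnt = counters.setdefault(key, {})
            while True:
                cnt[name] = cnt.get(name, 0) + 1
                cand = f"{name[:2]}{cnt[name]}"[:4]
                if cand not in used:
                    name = cand
                    break
        used.add(name)
        names.append(name)
    frames = cx.frames or [cx.frame_coords(None)]
    lines = []
    multi = len(frames) > 1
    for k, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {k:>4}")
        for s, (a, het, xyz, nm) in enumerate(
                zip(atoms, het_flags, frame, names), start=1):
            lines.append(_pdb_atom_line(s, a, xyz, het, nm))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_structures(obj, path, format: str | None = None) -> None:
    """Write molecules (SDF/MOL2) or a complex (PDB) to ``path``."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        if not isinstance(obj, ComplexStructure):
            raise TypeError("PDB output requires a ComplexStructure")
        _write_pdb(obj, path)
        return
    mols = [obj] if isinstance(obj, MoleculeRecord) else list(obj)
    if fmt == "sdf":
        _write_sdf(mols, path)
    elif fmt == "mol2":
        _write_mol2(mols, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# activities and dataset bookkeeping


def to_pic50(ic50_nM: float) -> float:
    """Convert an IC50 in nanomolar to pIC50 = -log10(IC50 in molar)."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return -math.log10(ic50_nM * 1e-9)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: pIC50 -> IC50 in nanomolar."""
    return 10.0 ** (9.0 - pic50)


def load_activities(path) -> dict[str, float]:
    """Read an activity CSV with columns ``id`` plus ``ic50_nM`` or ``pic50``."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ParseError(f"{path}: missing 'id' column")
    if "pic50" in df.columns:
        return dict(zip(df["id"].astype(str), df["pic50"].astype(float)))
    if "ic50_nM" in df.columns:
        return {str(i): to_pic50(v) for i, v in zip(df["id"], df["ic50_nM"].astype(float))}
    raise ParseError(f"{path}: need an 'ic50_nM' or 'pic50' column")


def partition_dataset(records: Sequence[MoleculeRecord],
                      test_ids: Sequence[str],
                      outlier_ids: Sequence[str] = ()) -> DatasetSplit:
    """Split a series into train/test and drop named outliers from both.

    Deterministic given the id lists; raises if any id is unknown or if the
    training partition would come out empty.
    """
    by_id = {m.id: m for m in records}
    if len(by_id) != len(records):
        raise ChemIOError("duplicate molecule ids in dataset")
    missing = [i for i in list(test_ids) + list(outlier_ids) if i not in by_id]
    if missing:
        raise KeyError(f"unknown ids: {missing}")
    out = set(outlier_ids)
    test_set = set(test_ids) - out
    train = [m for m in records if m.id not in test_set and m.id not in out]
    test = [m for m in records if m.id in test_set]
    if not train:
        raise ChemIOError("training partition is empty")
    logger.info("partition: %d train, %d test, %d excluded",
                len(train), len(test), len(out))
    return DatasetSplit(train, test, sorted(out))


# ---------------------------------------------------------------------------
# packaged reference fixtures


def load_table3() -> pd.DataFrame:
    """Published observed/predicted pIC50 table (43 train + 11 test rows)."""
    with resources.files("ligandfield.data").joinpath("table3.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_split_ids() -> dict:
    """Reference train/test/outlier id bookkeeping for the 57-compound series."""
    with resources.files("ligandfield.data").joinpath("dataset_ids.json").open() as fh:
        return json.load(fh)


def reference_all_ids() -> list[str]:
    """All 57 compound ids: the 54 tabulated plus the 3 named outliers."""
    table = load_table3()
    ids = list(table["compound"])
    ids += load_reference_split_ids()["outlier_ids"]
    return ids
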