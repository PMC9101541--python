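"""Readers for the external formats the screening pipeline consumes.

SDF and SMILES parsing is delegated to RDKit, PDB parsing to Biotite;
records are normalized into the pipeline's own domain types.  Compositions
always include hydrogens — sources with implicit hydrogens get
valence-based completion, because AQVN counts every atom.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .eiip import MolecularComposition
from .interactions import AtomRecord, ComplexStructure, assign_roles

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "PropertyRow",
    "ReadReport",
    "read_sdf",
    "read_smiles_table",
    "read_pdb_complex",
    "read_property_table",
    "write_pdb",
    "MANDATORY_PROPERTY_COLUMNS",
]


@dataclass
class MoleculeRecord:
    """A normalized small molecule: id, composition, optional 3D geometry."""

    id: str
    composition: MolecularComposition
    coords: Optional[list[tuple[str, float, float, float]]] = None
    formal_charges: Optional[list[int]] = None
    source: str = "formula"  # sdf | smiles | formula

    def __post_init__(self) -> None:
        if self.composition.n_atoms <= 0:
            raise ValueError("composition must contain at least one atom")
        if self.coords is not None:
            from collections import Counter

            coord_elements = Counter(el for el, *_ in self.coords)
            if dict(coord_elements) != dict(self.composition.counts):
                raise ValueError(
                    "coordinate element multiset does not match the composition"
                )


@dataclass
class ReadReport:
    """Bookkeeping for a batch read: parsed + skipped = seen."""

    n_read: int = 0
    n_skipped: int = 0
    skipped: list[str] = field(default_factory=list)


@dataclass
class PropertyRow:
    """One ADMET descriptor record (QikProp-style schema).

    DHB/AHB may be fractional (QikProp averages over tautomers/conformers);
    they are compared as real numbers, never rounded.
    """

    id: str
    MW: float
    DHB: float
    AHB: float
    logP: float
    PSA: float
    logS: float
    PCaco: float
    PM: float
    RB: Optional[float] = None
    DM: Optional[float] = None
    MV: Optional[float] = None
    HOA: Optional[float] = None
    QPlogBB: Optional[float] = None
    CNSMPO: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.MW > 0:
            raise ValueError(f"MW must be > 0, got {self.MW}")
        if self.PCaco < 0:
            raise ValueError(f"PCaco must be >= 0, got {self.PCaco}")
        if self.HOA is not None and not 0 <= self.HOA <= 100:
            raise ValueError(f"HOA must be in [0, 100], got {self.HOA}")


def _composition_from_rdkit(mol) -> MolecularComposition:
    from rdkit import Chem

    molh = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for atom in molh.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    return MolecularComposition(counts)


def _record_from_rdkit(mol, mol_id: str, source: str) -> MoleculeRecord:
    comp = _composition_from_rdkit(mol)
    coords = None
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    if mol.GetNumConformers() and source == "sdf":
        from rdkit import Chem

        molh = Chem.AddHs(mol, addCoords=True)
        conf = molh.GetConformer()
        coords = [
            (
                molh.GetAtomWithIdx(i).GetSymbol(),
                conf.GetAtomPosition(i).x,
                conf.GetAtomPosition(i).y,
                conf.GetAtomPosition(i).z,
            )
            for i in range(molh.GetNumAtoms())
        ]
        charges = [a.GetFormalCharge() for a in molh.GetAtoms()]
    return MoleculeRecord(
        id=mol_id, composition=comp, coords=coords, formal_charges=charges, source=source
    )


def read_sdf(path: str | Path) -> tuple[list[MoleculeRecord], ReadReport]:
    """Read a V2000 SDF file into molecule records.

    Hydrogens come from the explicit atom block plus implicit-H completion,
    so compositions always carry full hydrogen counts.  Malformed blocks
    are skipped with a warning and counted in the report.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SDF file not found: {path}")
    report = ReadReport()
    records: list[MoleculeRecord] = []
    if not path.read_text().strip():
        return records, report
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, mol in enumerate(supplier):
            if mol is None:
                report.n_skipped += 1
                report.skipped.append(f"block {i}")
                logger.warning("skipping malformed SDF block %d in %s", i, path)
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            records.append(_record_from_rdkit(mol, mol_id, "sdf"))
            report.n_read += 1
    return records, report


def read_smiles_table(path: str | Path) -> tuple[list[MoleculeRecord], ReadReport]:
    """Read a one-SMILES-per-line table (optional tab-separated id).

    Implicit hydrogens are completed before the composition is computed.
    Unparsable SMILES are skipped with a warning.
    """
    from rdkit import Chem
    from rdkit.rdBase import BlockLogs

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SMILES file not found: {path}")
    report = ReadReport()
    records: list[MoleculeRecord] = []
    with open(path) as fh, BlockLogs():
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                report.n_skipped += 1
                report.skipped.append(smiles)
                logger.warning("skipping unparsable SMILES %r (line %d)", smiles, i + 1)
                continue
            records.append(_record_from_rdkit(mol, mol_id, "smiles"))
            report.n_read += 1
    return records, report


def _element_from_atom_name(name: str) -> str:
    name = name.strip()
    if len(name) >= 2 and name[:2].capitalize() in ("Cl", "Br"):
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_pdb_complex(
    path: str | Path,
    ligand_selector: str,
    infer_roles: bool = True,
) -> ComplexStructure:
    """Read a PDB file and partition atoms into receptor and ligand.

    ``ligand_selector`` is a residue name (HETATM convention) or
    ``chain:X``.  Elements come from the element column; blank element
    fields fall back to the atom-name prefix with a warning.  With
    ``infer_roles`` the heuristic donor/acceptor/charge typing of
    :func:`eiipscreen.interactions.assign_roles` is applied.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    structure = pdb.PDBFile.read(str(path)).get_structure(model=1, extra_fields=["charge"])

    by_chain = ligand_selector.startswith("chain:")
    chain_id = ligand_selector.split(":", 1)[1] if by_chain else None

    atoms: list[AtomRecord] = []
    ligand_found = False
    for at in structure:
        element = str(at.element).strip().capitalize()
        if not element:
            element = _element_from_atom_name(str(at.atom_name))
            warnings.warn(
                f"blank element column for atom {at.atom_name!r}; "
                f"inferred {element} from the name prefix",
                stacklevel=2,
            )
        if by_chain:
            is_ligand = str(at.chain_id) == chain_id
        else:
            is_ligand = str(at.res_name).strip() == ligand_selector
        ligand_found = ligand_found or is_ligand
        atoms.append(
            AtomRecord(
                element=element,
                coords=(float(at.coord[0]), float(at.coord[1]), float(at.coord[2])),
                residue_number=int(at.res_id),
                residue_name=str(at.res_name).strip(),
                chain=str(at.chain_id).strip() or "A",
                atom_name=str(at.atom_name).strip(),
                is_ligand=is_ligand,
                formal_charge=int(getattr(at, "charge", 0) or 0),
            )
        )
    if not ligand_found:
        available = sorted({a.residue_name for a in atoms})
        raise ValueError(
            f"ligand selector {ligand_selector!r} matched no atoms; "
            f"available residues: {', '.join(available)}"
        )
    c = ComplexStructure(atoms=atoms)
    return assign_roles(c) if infer_roles else c


def write_pdb(c: ComplexStructure, path: str | Path) -> None:
    """Write a complex as a minimal PDB (ATOM for receptor, HETATM for ligand)."""
    lines = []
    for i, a in enumerate(c.atoms, start=1):
        record = "HETATM" if a.is_ligand else "ATOM  "
        x, y, z = a.coords
        name = (a.atom_name or a.element)[:4]
        if a.formal_charge > 0:
            charge = f"{a.formal_charge}+"
        elif a.formal_charge < 0:
            charge = f"{-a.formal_charge}-"
        else:
            charge = "  "
        lines.append(
            f"{record}{i:>5} {name:<4} {a.residue_name[:3]:<3} {a.chain[:1]}"
            f"{a.residue_number:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2}{charge}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


MANDATORY_PROPERTY_COLUMNS = ["MW", "DHB", "AHB", "logP", "PSA", "logS", "PCaco", "PM"]

_OPTIONAL_PROPERTY_COLUMNS = ["RB", "DM", "MV", "HOA", "QPlogBB", "CNSMPO"]

# Column-name aliases seen in published property tables.
_COLUMN_ALIASES = {
    "Compound": "id", "compound": "id", "ID": "id", "Name": "id",
    "%HOA": "HOA", "CNS MPO": "CNSMPO", "QP log BB": "QPlogBB",
    "log P": "logP", "log S": "logS",
}


def _to_float(value) -> float:
    """Parse a number, normalizing the unicode minus sign U+2212."""
    if isinstance(value, str):
        value = value.strip().replace("−", "-")
    return float(value)


def read_property_table(path: str | Path) -> list[PropertyRow]:
    """Read an ADMET property CSV into typed rows.

    The header must contain MW, DHB, AHB, logP, PSA, logS, PCaco and PM;
    optional columns are carried along when present.  Unicode minus signs
    in numeric cells are normalized, as published tables often use U+2212.
    """
    df = pd.read_csv(path, dtype=str)
    df = df.rename(columns=lambda c: _COLUMN_ALIASES.get(c.strip(), c.strip()))
    if "id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "id"})
    missing = [col for col in MANDATORY_PROPERTY_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"missing column {', '.join(missing)}")
    rows = []
    for _, r in df.iterrows():
        kwargs = {"id": str(r["id"])}
        for col in MANDATORY_PROPERTY_COLUMNS:
            kwargs[col] = _to_float(r[col])
        for col in _OPTIONAL_PROPERTY_COLUMNS:
            if col in df.columns and pd.notna(r[col]):
                kwargs[col] = _to_float(r[col])
        rows.append(PropertyRow(**kwargs))
    return rows
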