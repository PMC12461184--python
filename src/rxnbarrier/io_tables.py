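"""Readers and writers for the delimited-text dataset formats.

Reactions travel as CSV with columns ``id``, ``rxn_smiles`` (atom-mapped,
explicit H) and optional ``dE0`` (kcal/mol) plus an optional ``reverse``
flag column; conformers as standard XYZ whose comment line carries
``id=<reaction id> role=<r|ts|p> maps=<comma-separated atom maps>``.
Energies are kcal/mol and coordinates Angstrom throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors3d import AlignmentError, Conformer
from .reaction_graph import Reaction, parse_reaction
from .synthetic import FixtureRecord

__all__ = [
    "DatasetBundle",
    "FormatError",
    "read_reactions",
    "write_reactions",
    "read_xyz",
    "write_xyz",
    "read_conformer_dir",
    "write_fixture",
]


class FormatError(ValueError):
    pass


@dataclass
class DatasetBundle:
    reactions: list[Reaction]
    conformers: dict[str, dict[str, Conformer]] = field(default_factory=dict)
    extra_tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def targets(self) -> dict[str, float]:
        return {r.id: r.barrier for r in self.reactions if r.barrier is not None}


def read_reactions(path, forward_only: bool = False) -> DatasetBundle:
    """Parse and validate a reaction table.

    Row-level failures carry the 1-based data line number; ``forward_only``
    drops rows whose ``reverse`` column is truthy.
    """
    df = pd.read_csv(path)
    required = {"id", "rxn_smiles"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"{path}: duplicate reaction ids {dups}")
    dropped = 0
    if forward_only and "reverse" in df.columns:
        n0 = len(df)
        df = df[~df["reverse"].astype(bool)]
        dropped = n0 - len(df)
    reactions = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rxn = parse_reaction(str(row.rxn_smiles), rxn_id=str(row.id))
        except ValueError as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from exc
        if hasattr(row, "dE0") and not pd.isna(row.dE0):
            rxn.barrier = float(row.dE0)
        reactions.append(rxn)
    return DatasetBundle(
        reactions=reactions,
        provenance={
            "path": str(path),
            "forward_only": forward_only,
            "rows_dropped_reverse": dropped,
        },
    )


def write_reactions(reactions: list[Reaction], smiles: dict[str, str], path) -> None:
    """Write a reaction table; ``smiles`` maps id to the mapped SMILES."""
    rows = [
        {"id": r.id, "rxn_smiles": smiles[r.id], "dE0": r.barrier}
        for r in reactions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_xyz(path) -> Conformer:
    """Read one conformer from an annotated XYZ file."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise FormatError(f"{path}: first line must be the atom count") from exc
    meta = dict(
        item.split("=", 1) for item in lines[1].split() if "=" in item
    )
    for key in ("id", "role", "maps"):
        if key not in meta:
            raise FormatError(f"{path}: comment line missing {key}= metadata")
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n:
        raise FormatError(f"{path}: atom count says {n} but {len(body)} atom lines follow")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) != 4:
            raise FormatError(f"{path}: malformed atom line {ln!r}")
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:]])
    maps = [int(v) for v in meta["maps"].split(",")]
    if len(maps) != n or sorted(maps) != sorted(set(maps)):
        raise AlignmentError(f"{path}: maps metadata is not a permutation of {n} atom maps")
    return Conformer(
        elements=elements,
        coordinates=np.array(coords),
        map_order=maps,
        role=meta["role"],
    )


def write_xyz(conformer: Conformer, rxn_id: str, role: str, path) -> None:
    maps = ",".join(str(m) for m in conformer.map_order)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(conformer.elements)}\n")
        fh.write(f"id={rxn_id} role={role} maps={maps}\n")
        for el, (x, y, z) in zip(conformer.elements, conformer.coordinates):
            fh.write(f"{el} {x:.12f} {y:.12f} {z:.12f}\n")


def read_conformer_dir(directory) -> dict[str, dict[str, Conformer]]:
    """Load every ``<id>_<role>.xyz`` under a directory, keyed by id then role."""
    store: dict[str, dict[str, Conformer]] = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".xyz"):
            continue
        conf = read_xyz(Path(directory) / name)
        with open(Path(directory) / name, encoding="utf-8") as fh:
            fh.readline()
            meta = dict(item.split("=", 1) for item in fh.readline().split() if "=" in item)
        store.setdefault(meta["id"], {})[meta["role"]] = conf
    return store


def _record_smiles(record: FixtureRecord) -> str:
    """Reconstruct the mapped reaction SMILES from a fixture record."""
    from rdkit import Chem

    def side(atoms, bonds):
        mol = Chem.RWMol()
        idx = {}
        for m in sorted(atoms):
            a = Chem.Atom(atoms[m].element)
            a.SetAtomMapNum(m)
            a.SetNoImplicit(True)
            idx[m] = mol.AddAtom(a)
        from .splits import _ORDER_TO_RDKIT

        for (m1, m2), rec in bonds.items():
            mol.AddBond(idx[m1], idx[m2], _ORDER_TO_RDKIT[rec.order])
        return Chem.MolToSmiles(mol)

    r = record.reaction
    return side(r.reactant_atoms, r.reactant_bonds) + ">>" + side(r.product_atoms, r.product_bonds)


def write_fixture(records: list[FixtureRecord], directory) -> None:
    """Write a fixture population as reactions.csv plus per-role XYZ files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    xyz_dir = directory / "xyz"
    xyz_dir.mkdir(exist_ok=True)
    smiles = {rec.reaction.id: _record_smiles(rec) for rec in records}
    write_reactions([rec.reaction for rec in records], smiles, directory / "reactions.csv")
    for rec in records:
        for role, conf in rec.conformers.items():
            write_xyz(conf, rec.reaction.id, role, xyz_dir / f"{rec.reaction.id}_{role}.xyz")
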