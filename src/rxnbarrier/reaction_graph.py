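"""Condensed graph of reaction (CGR) construction.

A reaction written as an atom-mapped SMILES with explicit hydrogens is
parsed into per-side atom/bond records, and the two molecular graphs are
superimposed into a single reaction graph: every atom carries the
concatenation of its reactant-side and product-side feature vector, every
bond in the union of the two bond sets carries the concatenation of its
per-side bond features, with the half corresponding to a side where the
bond does not exist set to all zeros.  Bond formation and cleavage are
therefore explicit in the edge features, which is what lets a single graph
network regress a reaction-level property such as the barrier height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "AtomRecord",
    "BondRecord",
    "Reaction",
    "CondensedGraph",
    "FeatureConfig",
    "ReactionParseError",
    "AtomMappingError",
    "BalanceError",
    "UnsupportedElementError",
    "parse_reaction",
    "default_atom_features",
    "default_bond_features",
    "build_cgr",
    "directed_edge_features",
]

# Covers H/C/N/O plus S and the halogens seen across the barrier-height
# benchmark sets (hydrogen transfer, cycloaddition, E2/SN2 chemistry).
DEFAULT_ELEMENTS: tuple[str, ...] = ("H", "C", "N", "O", "F", "S", "Cl", "Br", "I")

HYBRIDIZATIONS: tuple[str, ...] = ("S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "other")
BOND_ORDERS: tuple[str, ...] = ("single", "double", "triple", "aromatic")
RING_SIZES: tuple[int, ...] = (3, 4, 5, 6, 7, 8)

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class ReactionParseError(ValueError):
    """The reaction SMILES could not be parsed."""


class AtomMappingError(ValueError):
    """Missing or duplicate atom-map numbers."""


class BalanceError(ValueError):
    """Reactant and product sides do not carry the same mapped atoms."""


class UnsupportedElementError(ValueError):
    """Element outside the configured supported-element list."""


@dataclass(frozen=True)
class AtomRecord:
    map_index: int
    element: str
    degree: int
    formal_charge: int
    hybridization: str
    n_hydrogens: int
    aromatic: bool
    mass: float


@dataclass(frozen=True)
class BondRecord:
    endpoints: tuple[int, int]  # unordered pair of map indices
    order: str
    conjugated: bool
    ring_size: int | None

    def __post_init__(self):
        a, b = self.endpoints
        if a == b:
            raise ValueError("bond endpoints must be distinct")
        if self.ring_size is not None and self.ring_size < 3:
            raise ValueError("ring_size must be >= 3")
        object.__setattr__(self, "endpoints", (min(a, b), max(a, b)))


@dataclass
class Reaction:
    id: str
    reactant_atoms: dict[int, AtomRecord]
    reactant_bonds: dict[tuple[int, int], BondRecord]
    product_atoms: dict[int, AtomRecord]
    product_bonds: dict[tuple[int, int], BondRecord]
    barrier: float | None = None

    @property
    def map_indices(self) -> list[int]:
        return sorted(self.reactant_atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.reactant_atoms)


@dataclass
class FeatureConfig:
    """Encoding widths for the default atom/bond feature scheme.

    One-hot blocks follow the chemprop-style convention: small-integer
    fields get a dedicated slot per value plus an overflow slot; the atomic
    mass is kept as a real number divided by 100 for scaling.
    """

    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    max_degree: int = 4
    max_hydrogens: int = 4
    charge_range: tuple[int, int] = (-2, 2)

    @property
    def atom_width(self) -> int:
        lo, hi = self.charge_range
        return (
            len(self.elements)
            + (self.max_degree + 2)
            + (hi - lo + 3)
            + len(HYBRIDIZATIONS)
            + (self.max_hydrogens + 2)
            + 1  # aromatic flag
            + 1  # mass / 100
        )

    @property
    def bond_width(self) -> int:
        return len(BOND_ORDERS) + 1 + 1 + len(RING_SIZES)  # order, conjugated, in-ring, ring sizes


def _atom_record(atom: Chem.Atom) -> AtomRecord:
    hyb = str(atom.GetHybridization())
    return AtomRecord(
        map_index=atom.GetAtomMapNum(),
        element=atom.GetSymbol(),
        degree=atom.GetDegree(),
        formal_charge=atom.GetFormalCharge(),
        hybridization=hyb if hyb in HYBRIDIZATIONS else "other",
        n_hydrogens=atom.GetTotalNumHs(includeNeighbors=True),
        aromatic=atom.GetIsAromatic(),
        mass=atom.GetMass(),
    )


def _parse_side(smiles: str, side: str, rxn_id: str):
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise ReactionParseError(f"reaction {rxn_id!r}: unparseable {side} SMILES {smiles!r}")

    atoms: dict[int, AtomRecord] = {}
    implicit_h: dict[int, int] = {}
    idx_to_map: dict[int, int] = {}
    for atom in mol.GetAtoms():
        m = atom.GetAtomMapNum()
        if m <= 0:
            raise AtomMappingError(
                f"reaction {rxn_id!r}: unmapped {atom.GetSymbol()} atom on {side} side"
            )
        if m in atoms:
            raise AtomMappingError(f"reaction {rxn_id!r}: duplicate atom map {m} on {side} side")
        atoms[m] = _atom_record(atom)
        # hydrogens not written as mapped atoms; zero for explicit-H input
        implicit_h[m] = atom.GetTotalNumHs(includeNeighbors=False)
        idx_to_map[atom.GetIdx()] = m

    ring_info = mol.GetRingInfo()
    bonds: dict[tuple[int, int], BondRecord] = {}
    for bond in mol.GetBonds():
        order = _RDKIT_ORDER.get(bond.GetBondType())
        if order is None:
            raise ReactionParseError(
                f"reaction {rxn_id!r}: unsupported bond type {bond.GetBondType()}"
            )
        ring_size: int | None = None
        if bond.IsInRing():
            sizes = [len(r) for r in ring_info.BondRings() if bond.GetIdx() in r]
            ring_size = min(sizes) if sizes else None
        rec = BondRecord(
            endpoints=(idx_to_map[bond.GetBeginAtomIdx()], idx_to_map[bond.GetEndAtomIdx()]),
            order=order,
            conjugated=bond.GetIsConjugated(),
            ring_size=ring_size,
        )
        bonds[rec.endpoints] = rec
    return atoms, bonds, implicit_h


def parse_reaction(rxn_smiles: str, rxn_id: str = "") -> Reaction:
    """Parse an atom-mapped, balanced, explicit-hydrogen reaction SMILES.

    Raises
    ------
    ReactionParseError, AtomMappingError, BalanceError
        For unparseable SMILES, missing/duplicate atom maps, or sides whose
        mapped-atom sets (or per-map elements) disagree.
    """
    if rxn_smiles.count(">>") != 1:
        raise ReactionParseError(f"reaction {rxn_id!r}: expected exactly one '>>' separator")
    left, right = rxn_smiles.split(">>")
    r_atoms, r_bonds, r_implicit = _parse_side(left, "reactant", rxn_id)
    p_atoms, p_bonds, p_implicit = _parse_side(right, "product", rxn_id)

    if set(r_atoms) != set(p_atoms):
        missing = sorted(set(r_atoms) ^ set(p_atoms))
        raise BalanceError(
            f"reaction {rxn_id!r}: unbalanced reaction, atom maps {missing} on one side only"
        )
    for m in r_atoms:
        if r_atoms[m].element != p_atoms[m].element:
            raise BalanceError(
                f"reaction {rxn_id!r}: atom map {m} is {r_atoms[m].element} in the reactant "
                f"but {p_atoms[m].element} in the product"
            )
        if r_implicit[m] != p_implicit[m]:
            # hydrogens not carried as mapped atoms cannot appear or vanish
            raise BalanceError(
                f"reaction {rxn_id!r}: atom map {m} carries {r_implicit[m]} unmapped "
                f"hydrogens in the reactant but {p_implicit[m]} in the product"
            )
    return Reaction(
        id=rxn_id,
        reactant_atoms=r_atoms,
        reactant_bonds=r_bonds,
        product_atoms=p_atoms,
        product_bonds=p_bonds,
    )


def _one_hot(value, choices, overflow: bool = False) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if overflow else 0))
    if value in choices:
        vec[choices.index(value)] = 1.0
    elif overflow:
        vec[-1] = 1.0
    return vec


def default_atom_features(atom: AtomRecord, config: FeatureConfig | None = None) -> np.ndarray:
    """Encode one atom: element, degree, charge, hybridization, H count,
    aromaticity as one-hots, atomic mass divided by 100."""
    config = config or FeatureConfig()
    if atom.element not in config.elements:
        raise UnsupportedElementError(
            f"element {atom.element!r} not in supported set {config.elements}"
        )
    lo, hi = config.charge_range
    vec = (
        _one_hot(atom.element, list(config.elements))
        + _one_hot(atom.degree, list(range(config.max_degree + 1)), overflow=True)
        + _one_hot(min(max(atom.formal_charge, lo - 1), hi + 1), list(range(lo - 1, hi + 2)))
        + _one_hot(atom.hybridization, list(HYBRIDIZATIONS))
        + _one_hot(atom.n_hydrogens, list(range(config.max_hydrogens + 1)), overflow=True)
        + [1.0 if atom.aromatic else 0.0]
        + [atom.mass / 100.0]
    )
    return np.asarray(vec, dtype=np.float64)


def default_bond_features(bond: BondRecord | None, config: FeatureConfig | None = None) -> np.ndarray:
    """Encode one bond; an absent bond (``None``) is the all-zero vector."""
    config = config or FeatureConfig()
    if bond is None:
        return np.zeros(config.bond_width, dtype=np.float64)
    in_ring = bond.ring_size is not None
    vec = (
        _one_hot(bond.order, list(BOND_ORDERS))
        + [1.0 if bond.conjugated else 0.0]
        + [1.0 if in_ring else 0.0]
        + _one_hot(bond.ring_size, list(RING_SIZES))
    )
    return np.asarray(vec, dtype=np.float64)


@dataclass
class CondensedGraph:
    """Superimposed reactant/product graph.

    Atoms are ordered by ascending atom-map index; ``edge_list`` holds
    0-based atom positions for the union of reactant and product bonds.
    Feature vectors are two-sided concatenations (reactant half first).
    """

    n_atoms: int
    map_indices: list[int]  # position -> map index, ascending
    atom_features: np.ndarray  # (n_atoms, 2 * atom_width)
    edge_list: list[tuple[int, int]]  # 0-based positions, i < j
    bond_features: np.ndarray  # (n_edges, 2 * bond_width)
    mol_extra: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)


def build_cgr(reaction: Reaction, config: FeatureConfig | None = None) -> CondensedGraph:
    """Superimpose the two sides of a balanced reaction into one graph."""
    config = config or FeatureConfig()
    maps = reaction.map_indices
    pos = {m: i for i, m in enumerate(maps)}

    atom_features = np.stack(
        [
            np.concatenate(
                [
                    default_atom_features(reaction.reactant_atoms[m], config),
                    default_atom_features(reaction.product_atoms[m], config),
                ]
            )
            for m in maps
        ]
    )

    edge_keys = sorted(set(reaction.reactant_bonds) | set(reaction.product_bonds))
    edge_list: list[tuple[int, int]] = []
    bond_rows: list[np.ndarray] = []
    for key in edge_keys:
        i, j = pos[key[0]], pos[key[1]]
        edge_list.append((min(i, j), max(i, j)))
        bond_rows.append(
            np.concatenate(
                [
                    default_bond_features(reaction.reactant_bonds.get(key), config),
                    default_bond_features(reaction.product_bonds.get(key), config),
                ]
            )
        )
    bond_features = (
        np.stack(bond_rows) if bond_rows else np.zeros((0, 2 * config.bond_width))
    )
    return CondensedGraph(
        n_atoms=len(maps),
        map_indices=list(maps),
        atom_features=atom_features,
        edge_list=edge_list,
        bond_features=bond_features,
    )


def directed_edge_features(cgr: CondensedGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Expand undirected edges into both directions with e_vw = cat(x_v, bond_vw).

    Returns ``(src, dst, rev, features)`` where edge ``2k`` runs i->j and
    edge ``2k+1`` runs j->i for undirected edge ``k``; ``rev[e]`` is the
    index of the opposite direction.
    """
    n_dir = 2 * cgr.n_edges
    src = np.empty(n_dir, dtype=np.intp)
    dst = np.empty(n_dir, dtype=np.intp)
    for k, (i, j) in enumerate(cgr.edge_list):
        src[2 * k], dst[2 * k] = i, j
        src[2 * k + 1], dst[2 * k + 1] = j, i
    rev = np.arange(n_dir, dtype=np.intp) ^ 1
    feats = (
        np.concatenate([cgr.atom_features[src], np.repeat(cgr.bond_features, 2, axis=0)], axis=1)
        if n_dir
        else np.zeros((0, cgr.atom_features.shape[1] + cgr.bond_features.shape[1]))
    )
    return src, dst, rev, feats
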