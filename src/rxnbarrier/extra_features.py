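"""Auxiliary feature attachment: ml-QM descriptor schema and extras.

Machine-learned surrogates of DFT descriptors (ml-QM features) come in
three levels — 13 atomic, 4 bond, 20 molecular, 37 in total.  Because the
descriptor models operate on single molecules, values are computed for the
reactant and product components separately and attached to the condensed
reaction graph as two-sided concatenations, mirroring the default feature
convention.  This module also provides the column bookkeeping needed by
permutation feature importance: shuffling a single column across a dataset
and restricting a dataset to a named column subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reaction_graph import CondensedGraph, Reaction

__all__ = [
    "FeatureSchema",
    "ExtraFeatureSet",
    "CoverageError",
    "SchemaError",
    "mlqm_schema",
    "attach_extra",
    "permute_feature_column",
    "select_feature_subset",
]

LEVELS = ("atom", "bond", "molecule")


class CoverageError(ValueError):
    """An extra-feature table is missing a row for a mapped atom or bond."""


class SchemaError(ValueError):
    """Column count or column id disagrees with the declared schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered registry of named feature columns with a level tag each."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        for _, level in self.entries:
            if level not in LEVELS:
                raise SchemaError(f"unknown level {level!r}")

    def names(self, level: str | None = None) -> list[str]:
        return [n for n, lv in self.entries if level is None or lv == level]

    def count(self, level: str) -> int:
        return len(self.names(level))

    def __len__(self) -> int:
        return len(self.entries)


# Named entries follow the published examples for each level; the rest of
# the 13/4/20 slots carry stable placeholder ids so that column selection
# and importance reports stay well-defined without the full name table.
_MLQM_ATOM = (
    "npa_charge",
    "parr_function",
    "nmr_shielding",
    "valence_occupancy_2s",
    "valence_occupancy_2p",
)
_MLQM_BOND = ("bond_order", "bond_length", "bonding_electrons", "natural_ionicity")
_MLQM_MOL = (
    "homo_lumo_gap",
    "ionization_potential",
    "electron_affinity",
    "dipole_moment",
    "quadrupole_moment",
)


def mlqm_schema() -> FeatureSchema:
    """The 37-descriptor ml-QM registry: 13 atom + 4 bond + 20 molecular."""
    atoms = list(_MLQM_ATOM) + [f"mlqm_atom_{i:02d}" for i in range(len(_MLQM_ATOM) + 1, 14)]
    bonds = list(_MLQM_BOND)
    mols = list(_MLQM_MOL) + [f"mlqm_mol_{i:02d}" for i in range(len(_MLQM_MOL) + 1, 21)]
    entries = tuple(
        [(n, "atom") for n in atoms] + [(n, "bond") for n in bonds] + [(n, "molecule") for n in mols]
    )
    return FeatureSchema(entries)


@dataclass
class ExtraFeatureSet:
    """Per-reaction extra features, keyed per side.

    ``atom_table[side][map_index]`` and ``bond_table[side][(m1, m2)]`` hold
    one vector per schema column at that level; ``molecule_table[side]`` is
    a single vector. A side where a fragment does not exist (e.g. a bond
    broken in the product) simply has no row; attachment fills zeros.
    """

    schema: FeatureSchema
    atom_table: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    bond_table: dict[str, dict[tuple[int, int], np.ndarray]] = field(default_factory=dict)
    molecule_table: dict[str, np.ndarray] = field(default_factory=dict)
    scaling_stats: dict[str, tuple[float, float]] | None = None

    def scaled(self, vec: np.ndarray, level: str) -> np.ndarray:
        if self.scaling_stats is None:
            return vec
        names = self.schema.names(level)
        out = np.array(vec, dtype=np.float64)
        for i, name in enumerate(names):
            mu, sd = self.scaling_stats.get(name, (0.0, 1.0))
            out[i] = (out[i] - mu) / (sd if sd > 0 else 1.0)
        return out


def _side_atom_vec(extra: ExtraFeatureSet, side: str, m: int, width: int, rxn_id: str) -> np.ndarray:
    table = extra.atom_table.get(side, {})
    if m not in table:
        raise CoverageError(f"reaction {rxn_id!r}: no {side}-side atom extras for map index {m}")
    vec = np.asarray(table[m], dtype=np.float64)
    if vec.shape != (width,):
        raise SchemaError(
            f"reaction {rxn_id!r}: atom extras for map {m} have width {vec.shape}, expected {width}"
        )
    return extra.scaled(vec, "atom")


def attach_extra(
    cgr: CondensedGraph,
    reaction: Reaction,
    extra: ExtraFeatureSet,
    level: str,
) -> CondensedGraph:
    """Concatenate per-side extra vectors onto the CGR features at ``level``.

    Reactant-side extras come first, mirroring the default two-sided
    layout; molecule-level extras are stored on the graph and appended to
    the pooled embedding downstream rather than to per-atom rows.
    """
    if level not in LEVELS:
        raise SchemaError(f"unknown level {level!r}")
    if level == "atom":
        w = extra.schema.count("atom")
        rows = [
            np.concatenate(
                [
                    _side_atom_vec(extra, "reactant", m, w, reaction.id),
                    _side_atom_vec(extra, "product", m, w, reaction.id),
                ]
            )
            for m in cgr.map_indices
        ]
        return replace(cgr, atom_features=np.concatenate([cgr.atom_features, np.stack(rows)], axis=1))
    if level == "bond":
        w = extra.schema.count("bond")
        pos_to_map = cgr.map_indices
        rows = []
        for (i, j) in cgr.edge_list:
            key = tuple(sorted((pos_to_map[i], pos_to_map[j])))
            halves = []
            for side, bonds in (("reactant", reaction.reactant_bonds), ("product", reaction.product_bonds)):
                if key in bonds:
                    table = extra.bond_table.get(side, {})
                    if key not in table:
                        raise CoverageError(
                            f"reaction {reaction.id!r}: no {side}-side bond extras for {key}"
                        )
                    vec = np.asarray(table[key], dtype=np.float64)
                    if vec.shape != (w,):
                        raise SchemaError(
                            f"reaction {reaction.id!r}: bond extras for {key} have width "
                            f"{vec.shape}, expected {w}"
                        )
                    halves.append(extra.scaled(vec, "bond"))
                else:
                    halves.append(np.zeros(w))
            rows.append(np.concatenate(halves))
        new_bonds = (
            np.concatenate([cgr.bond_features, np.stack(rows)], axis=1)
            if rows
            else cgr.bond_features
        )
        return replace(cgr, bond_features=new_bonds)
    # molecule level
    w = extra.schema.count("molecule")
    halves = []
    for side in ("reactant", "product"):
        if side not in extra.molecule_table:
            raise CoverageError(f"reaction {reaction.id!r}: no {side}-side molecule extras")
        vec = np.asarray(extra.molecule_table[side], dtype=np.float64)
        if vec.shape != (w,):
            raise SchemaError(
                f"reaction {reaction.id!r}: molecule extras have width {vec.shape}, expected {w}"
            )
        halves.append(extra.scaled(vec, "molecule"))
    return replace(cgr, mol_extra=np.concatenate([cgr.mol_extra, *halves]))


def permute_feature_column(dataset, column_id: str, seed: int):
    """Return a copy of ``dataset`` with one extra-feature column shuffled
    across records (atom-level columns shuffle across the pooled atom axis,
    molecule-level across reactions). The value multiset is preserved and
    every other column is untouched; identical seeds give identical shuffles.
    """
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    if column_id in out.atom_extra_columns:
        j = out.atom_extra_columns.index(column_id)
        pooled = np.concatenate([rec.atom_extras[:, j] for rec in out.records])
        perm = rng.permutation(len(pooled))
        shuffled = pooled[perm]
        k = 0
        for rec in out.records:
            n = rec.atom_extras.shape[0]
            rec.atom_extras = rec.atom_extras.copy()
            rec.atom_extras[:, j] = shuffled[k : k + n]
            k += n
        return out
    if column_id in out.mol_extra_columns:
        j = out.mol_extra_columns.index(column_id)
        vals = np.array([rec.mol_extras[j] for rec in out.records])
        perm = rng.permutation(len(vals))
        for rec, v in zip(out.records, vals[perm]):
            rec.mol_extras = rec.mol_extras.copy()
            rec.mol_extras[j] = v
        return out
    raise KeyError(f"unknown extra-feature column {column_id!r}")


def select_feature_subset(dataset, column_ids):
    """Restrict a dataset's extra features to ``column_ids`` (order kept as
    in the dataset); default CGR features are untouched."""
    unknown = [c for c in column_ids if c not in dataset.atom_extra_columns + dataset.mol_extra_columns]
    if unknown:
        raise KeyError(f"unknown extra-feature columns {unknown}")
    out = dataset.copy()
    atom_keep = [i for i, c in enumerate(out.atom_extra_columns) if c in column_ids]
    mol_keep = [i for i, c in enumerate(out.mol_extra_columns) if c in column_ids]
    for rec in out.records:
        rec.atom_extras = rec.atom_extras[:, atom_keep]
        rec.mol_extras = rec.mol_extras[mol_keep]
    out.atom_extra_columns = [out.atom_extra_columns[i] for i in atom_keep]
    out.mol_extra_columns = [out.mol_extra_columns[i] for i in mol_keep]
    return out
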