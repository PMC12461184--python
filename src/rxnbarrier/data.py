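"""In-memory dataset of featurized reactions ready for model training."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors3d import Conformer, DescriptorConfig, positional_features
from .extra_features import ExtraFeatureSet, attach_extra
from .reaction_graph import CondensedGraph, FeatureConfig, Reaction, build_cgr

__all__ = ["EncodedReaction", "ReactionDataset", "featurize_reactions"]


@dataclass
class EncodedReaction:
    id: str
    cgr: CondensedGraph
    atom_extras: np.ndarray  # (n_atoms, k) auxiliary per-atom block
    mol_extras: np.ndarray  # (km,)
    target: float | None = None


@dataclass
class ReactionDataset:
    records: list[EncodedReaction]
    atom_extra_columns: list[str] = field(default_factory=list)
    mol_extra_columns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def copy(self) -> "ReactionDataset":
        from copy import copy as shallow

        return ReactionDataset(
            records=[shallow(r) for r in self.records],
            atom_extra_columns=list(self.atom_extra_columns),
            mol_extra_columns=list(self.mol_extra_columns),
        )

    def subset(self, ids) -> "ReactionDataset":
        wanted = set(ids)
        return ReactionDataset(
            records=[r for r in self.records if r.id in wanted],
            atom_extra_columns=list(self.atom_extra_columns),
            mol_extra_columns=list(self.mol_extra_columns),
        )

    def targets(self) -> np.ndarray:
        return np.array([r.target for r in self.records], dtype=np.float64)

    @property
    def atom_extra_width(self) -> int:
        return len(self.atom_extra_columns)

    @property
    def mol_extra_width(self) -> int:
        return len(self.mol_extra_columns)


def featurize_reactions(
    reactions: list[Reaction],
    feature_config: FeatureConfig | None = None,
    extras: dict[str, ExtraFeatureSet] | None = None,
    extra_levels: tuple[str, ...] = ("atom", "bond", "molecule"),
    conformers: dict[str, dict[str, Conformer]] | None = None,
    roles_used=("ts",),
    descriptor_config: DescriptorConfig | None = None,
    targets: dict[str, float] | None = None,
) -> ReactionDataset:
    """Build CGRs plus optional ml-QM and positional blocks for a dataset.

    ``extras`` maps reaction id to its ExtraFeatureSet; ``conformers`` maps
    reaction id to role-keyed conformers.  Atom-level ml-QM columns appear
    as ``<name>:r`` / ``<name>:p`` (two-sided); positional columns follow
    the role-tagged names from the descriptor assembly.
    """
    feature_config = feature_config or FeatureConfig()
    records: list[EncodedReaction] = []
    atom_cols: list[str] | None = None
    mol_cols: list[str] | None = None

    for rxn in reactions:
        cgr = build_cgr(rxn, feature_config)
        extra_mats: list[np.ndarray] = []
        names: list[str] = []
        mnames: list[str] = []
        if extras is not None:
            efs = extras[rxn.id]
            if "bond" in extra_levels and efs.schema.count("bond"):
                cgr = attach_extra(cgr, rxn, efs, "bond")
            if "molecule" in extra_levels and efs.schema.count("molecule"):
                cgr = attach_extra(cgr, rxn, efs, "molecule")
                for side in ("r", "p"):
                    mnames += [f"{n}:{side}" for n in efs.schema.names("molecule")]
            if "atom" in extra_levels and efs.schema.count("atom"):
                base_width = cgr.atom_features.shape[1]
                aug = attach_extra(cgr, rxn, efs, "atom")
                extra_mats.append(aug.atom_features[:, base_width:])
                for side in ("r", "p"):
                    names += [f"{n}:{side}" for n in efs.schema.names("atom")]
        if conformers is not None:
            pf = positional_features(conformers[rxn.id], roles_used, descriptor_config)
            extra_mats.append(pf.matrix)
            names += pf.column_names
        atom_extras = (
            np.concatenate(extra_mats, axis=1) if extra_mats else np.zeros((cgr.n_atoms, 0))
        )
        if atom_cols is None:
            atom_cols, mol_cols = names, mnames
        target = rxn.barrier
        if targets is not None:
            target = targets.get(rxn.id, target)
        records.append(
            EncodedReaction(
                id=rxn.id,
                cgr=cgr,
                atom_extras=atom_extras,
                mol_extras=cgr.mol_extra,
                target=target,
            )
        )
    return ReactionDataset(
        records=records,
        atom_extra_columns=atom_cols or [],
        mol_extra_columns=mol_cols or [],
    )
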