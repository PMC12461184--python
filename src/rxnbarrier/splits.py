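"""Dataset splitting strategies for reaction barrier regression.

Three strategies are provided: a plain random 90/5/5 split, a
reaction-core split that clusters reactions by their changed-bond subgraph
so that no bond-change pattern leaks across partitions, and a
barrier-height split that holds out the lowest and highest 5% of barriers
to probe extrapolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .reaction_graph import Reaction

__all__ = [
    "SplitAssignment",
    "DegenerateCoreError",
    "random_split",
    "reaction_core_key",
    "core_split",
    "barrier_split",
]

_ORDER_TO_RDKIT = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}


class DegenerateCoreError(ValueError):
    """Identity reaction: no bond changes, no reaction core."""


@dataclass
class SplitAssignment:
    train: list[str]
    validation: list[str]
    test: list[str]
    strategy: str
    fractions: tuple[float, float, float]
    seed: int | None = None
    notes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "seed": self.seed,
            "fractions": list(self.fractions),
            "train": list(self.train),
            "validation": list(self.validation),
            "test": list(self.test),
            "notes": self.notes,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "SplitAssignment":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            train=d["train"],
            validation=d["validation"],
            test=d["test"],
            strategy=d["strategy"],
            fractions=tuple(d["fractions"]),
            seed=d.get("seed"),
            notes=d.get("notes", {}),
        )


def _check_fractions(fractions) -> tuple[float, float, float]:
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9 or min(fr) < 0:
        raise ValueError(f"fractions must be three non-negatives summing to 1, got {fractions}")
    return fr


def _sizes(n: int, fractions) -> tuple[int, int, int]:
    # floor for validation/test, remainder to train
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    return n - n_val - n_test, n_val, n_test


def random_split(ids, fractions=(0.90, 0.05, 0.05), seed: int = 0) -> SplitAssignment:
    """Shuffle ids with the seed and cut 90/5/5 (train gets the remainder)."""
    fr = _check_fractions(fractions)
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 ids to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_train, n_val, n_test = _sizes(len(ids), fr)
    return SplitAssignment(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        strategy="random",
        fractions=fr,
        seed=seed,
    )


def reaction_core_key(reaction: Reaction) -> str:
    """Canonical key for the changed-bond subgraph (environment radius 0).

    The core consists of every bond that is formed, broken, or changes
    order between the two sides, together with the endpoint atoms.  The
    key is the canonical SMILES of the reactant-side core subgraph joined
    to the product-side one with ``>>``, so it is stable under atom
    relabeling.
    """
    changed: list[tuple[int, int]] = []
    for key in set(reaction.reactant_bonds) | set(reaction.product_bonds):
        rb = reaction.reactant_bonds.get(key)
        pb = reaction.product_bonds.get(key)
        if rb is None or pb is None or rb.order != pb.order:
            changed.append(key)
    if not changed:
        raise DegenerateCoreError(
            f"reaction {reaction.id!r} has no bond changes (identity reaction)"
        )
    core_atoms = sorted({m for pair in changed for m in pair})

    def side_smiles(atoms: dict, bonds: dict) -> str:
        mol = Chem.RWMol()
        idx = {}
        for m in core_atoms:
            a = Chem.Atom(atoms[m].element)
            a.SetFormalCharge(atoms[m].formal_charge)
            a.SetNoImplicit(True)
            idx[m] = mol.AddAtom(a)
        for pair in changed:
            rec = bonds.get(pair)
            if rec is not None:
                mol.AddBond(idx[pair[0]], idx[pair[1]], _ORDER_TO_RDKIT[rec.order])
        return Chem.MolToSmiles(mol)

    return (
        side_smiles(reaction.reactant_atoms, reaction.reactant_bonds)
        + ">>"
        + side_smiles(reaction.product_atoms, reaction.product_bonds)
    )


def core_split(
    reactions, fractions=(0.90, 0.05, 0.05), seed: int = 0
) -> SplitAssignment:
    """Cluster reactions by reaction-core key and assign whole clusters.

    Clusters are visited largest-first (a seeded shuffle breaks size ties)
    and greedily routed to whichever partition minimises the squared
    deviation of partition sizes from their targets, so reactions sharing
    a core never straddle partitions and large clusters gravitate to train.
    Realised fractions can deviate from the targets when clusters are
    lopsided; they are recorded in ``notes``.
    """
    fr = _check_fractions(fractions)
    reactions = list(reactions)
    clusters: dict[str, list[str]] = {}
    for rxn in reactions:
        clusters.setdefault(reaction_core_key(rxn), []).append(rxn.id)

    rng = np.random.default_rng(seed)
    keys = sorted(clusters)
    shuffled = [keys[i] for i in rng.permutation(len(keys))]
    ordered = sorted(shuffled, key=lambda k: -len(clusters[k]))  # stable: ties stay shuffled
    n_total = len(reactions)
    targets = [f * n_total for f in fr]
    counts = [0, 0, 0]
    parts: list[list[str]] = [[], [], []]
    key_sets: list[set[str]] = [set(), set(), set()]
    for key in ordered:
        size = len(clusters[key])
        errors = []
        for p in range(3):
            trial = list(counts)
            trial[p] += size
            errors.append(sum((trial[q] - targets[q]) ** 2 for q in range(3)))
        p = int(np.argmin(errors))  # ties go to train
        parts[p].extend(clusters[key])
        key_sets[p].add(key)
        counts[p] += len(clusters[key])
    realized = [c / n_total for c in counts]
    return SplitAssignment(
        train=parts[0],
        validation=parts[1],
        test=parts[2],
        strategy="reaction_core",
        fractions=fr,
        seed=seed,
        notes={"realized_fractions": realized, "n_clusters": len(clusters)},
    )


def barrier_split(
    targets: dict[str, float],
    fractions=(0.90, 0.05, 0.05),
    low_to: str = "validation",
) -> SplitAssignment:
    """Hold out the barrier extremes: lowest 5% and highest 5%.

    By convention the low extreme goes to ``low_to`` (validation by
    default) and the high extreme to the other held-out partition; the
    middle 90% trains.  Ties are broken by id, so the split is
    deterministic without a seed.
    """
    fr = _check_fractions(fractions)
    if low_to not in ("validation", "test"):
        raise ValueError("low_to must be 'validation' or 'test'")
    for rid, v in targets.items():
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing or non-finite barrier for id {rid!r}")
    ordered = sorted(targets, key=lambda rid: (targets[rid], rid))
    n = len(ordered)
    _, n_val, n_test = _sizes(n, fr)
    n_low, n_high = (n_val, n_test) if low_to == "validation" else (n_test, n_val)
    low = ordered[:n_low]
    high = ordered[n - n_high :] if n_high else []
    train = ordered[n_low : n - n_high] if n_high else ordered[n_low:]
    val, test = (low, high) if low_to == "validation" else (high, low)
    return SplitAssignment(
        train=train,
        validation=val,
        test=test,
        strategy="barrier_height",
        fractions=fr,
        seed=None,
        notes={"low_extreme_assigned_to": low_to},
    )
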