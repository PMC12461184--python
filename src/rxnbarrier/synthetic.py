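"""Synthetic reaction fixtures with a known generative barrier formula.

The generator emits atom-mapped, balanced, explicit-hydrogen transfer
reactions of the form R1–H + R2 -> R1 + H–R2 over a small palette of
hydride fragments (methyl, ethyl, amino, hydroxyl, thiyl), together with
reactant / transition-state / product conformers and a barrier assembled
from two separable parts plus noise:

    barrier = beta . (bond-change counts) + gamma * d_TS + eps,

where ``d_TS`` is the forming-bond distance in the transition state, drawn
uniformly and independently of the molecular graph.  Because nothing in
the 2D reaction graph carries information about ``d_TS``, a graph-only
model's error is floored by the geometry term, while a model that sees TS
coordinates can remove it — the same separation the barrier-height models
are designed to exploit on real data, at desk scale.  Conformer file order
is deliberately shuffled per record so alignment code is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors3d import Conformer
from .reaction_graph import Reaction, parse_reaction

__all__ = ["FixtureConfig", "FixtureRecord", "generate", "barrier_oracle", "ConsistencyError"]


class ConsistencyError(ValueError):
    """Stored barrier disagrees with the generative formula."""


_TET = np.deg2rad(109.47)


@dataclass(frozen=True)
class _Fragment:
    name: str
    element: str
    xh_bond: float  # equilibrium X-H distance, Angstrom
    n_heavy: int


_FRAGMENTS = (
    _Fragment("methyl", "C", 1.09, 1),
    _Fragment("ethyl", "C", 1.09, 2),
    _Fragment("amino", "N", 1.01, 1),
    _Fragment("hydroxyl", "O", 0.96, 1),
    _Fragment("thiyl", "S", 1.34, 1),
)

# Fixed, arbitrary graph-term coefficients (kcal/mol) keyed by the element
# pair of each broken/formed bond, on a scale typical of hydrogen-transfer
# barriers.
DEFAULT_BETA = {
    "intercept": 20.0,
    "break:C-H": 8.0,
    "break:N-H": 3.0,
    "break:O-H": 5.0,
    "break:S-H": -2.0,
    "form:C-H": 4.0,
    "form:N-H": 1.0,
    "form:O-H": -3.0,
    "form:S-H": -1.0,
}


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic population.

    Defaults put the geometry term's standard deviation near 2 kcal/mol
    (gamma * width(d)/sqrt(12) = 7 * 1/sqrt(12) ~ 2.0) against 0.5 kcal/mol
    of Gaussian noise, so the with/without-coordinates error gap is
    resolvable from two thousand reactions.
    """

    n_reactions: int = 2000
    elements: tuple[str, ...] = ("C", "N", "O", "S")
    max_heavy_atoms: int = 2
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    gamma: float = 7.0  # kcal/mol per Angstrom of TS forming-bond distance
    noise_sigma: float = 0.5  # kcal/mol
    d_range: tuple[float, float] = (1.1, 2.1)  # TS forming-bond distance, Angstrom
    ts_stretch: float = 0.35  # breaking-bond elongation in the TS, Angstrom
    separation: float = 4.5  # non-bonded fragment distance, Angstrom
    seed: int = 0

    def palette(self) -> list[_Fragment]:
        pal = [
            f
            for f in _FRAGMENTS
            if f.element in self.elements and f.n_heavy <= self.max_heavy_atoms
        ]
        if not pal:
            raise ValueError(
                f"no fragment over elements {self.elements} fits max_heavy_atoms="
                f"{self.max_heavy_atoms}"
            )
        return pal


@dataclass
class FixtureRecord:
    reaction: Reaction
    conformers: dict[str, Conformer]  # keys r, ts, p
    true_barrier: float
    components: dict  # graph_term, geometry_term, noise, d_ts


def _tet_dir(phi: float, sign: float = 1.0) -> np.ndarray:
    """Unit vector at the tetrahedral angle from the (sign * +x) axis."""
    return np.array(
        [sign * np.cos(_TET), np.sin(_TET) * np.cos(phi), np.sin(_TET) * np.sin(phi)]
    )


def _fragment_atoms(frag: _Fragment, center: np.ndarray, sign: float):
    """Elements, coordinates and internal bonds (index pairs) of a fragment.

    Atom 0 is the attachment (central) atom; ``sign`` is +1 when the
    transferred hydrogen sits on the +x side of the centre.
    """
    els = [frag.element]
    coords = [center]
    bonds: list[tuple[int, int]] = []
    if frag.name == "methyl":
        for k in range(3):
            els.append("H")
            coords.append(center + 1.09 * _tet_dir(2 * np.pi * k / 3, sign))
            bonds.append((0, len(els) - 1))
    elif frag.name == "ethyl":
        for k in range(2):
            els.append("H")
            coords.append(center + 1.09 * _tet_dir(np.pi / 2 + np.pi * k, sign))
            bonds.append((0, len(els) - 1))
        c2 = center + 1.54 * _tet_dir(3 * np.pi / 2, sign)
        els.append("C")
        coords.append(c2)
        bonds.append((0, len(els) - 1))
        c2_idx = len(els) - 1
        axis = (c2 - center) / np.linalg.norm(c2 - center)
        # orthonormal frame around the C-C axis for the terminal hydrogens
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(axis @ tmp) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(axis, tmp)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        for k in range(3):
            phi = 2 * np.pi * k / 3
            d = np.cos(_TET) * (-axis) + np.sin(_TET) * (np.cos(phi) * e1 + np.sin(phi) * e2)
            els.append("H")
            coords.append(c2 - 1.09 * d)
            bonds.append((c2_idx, len(els) - 1))
    elif frag.name == "amino":
        for k in range(2):
            els.append("H")
            coords.append(center + 1.01 * _tet_dir(np.pi * k, sign))
            bonds.append((0, len(els) - 1))
    elif frag.name == "hydroxyl":
        els.append("H")
        coords.append(center + 0.96 * _tet_dir(0.0, sign))
        bonds.append((0, len(els) - 1))
    elif frag.name == "thiyl":
        els.append("H")
        coords.append(center + 1.34 * _tet_dir(0.0, sign))
        bonds.append((0, len(els) - 1))
    else:  # pragma: no cover
        raise ValueError(frag.name)
    return els, coords, bonds


def _fragment_smiles(frag: _Fragment, maps: list[int], extra_h: int | None = None) -> str:
    """Mapped SMILES for the fragment, optionally with the transferred H."""
    if frag.name == "ethyl":
        c1, h1, h2, c2, h3, h4, h5 = maps
        s = f"[C:{c1}]([H:{h1}])([H:{h2}])([C:{c2}]([H:{h3}])([H:{h4}])[H:{h5}])"
    else:
        central, *hs = maps
        s = f"[{frag.element}:{central}]" + "".join(f"([H:{h}])" for h in hs)
    if extra_h is not None:
        s += f"[H:{extra_h}]"
    return s if extra_h is not None else s.rstrip()


def _build_reaction_smiles(donor: _Fragment, acceptor: _Fragment, maps_d, h_map, maps_a) -> str:
    lhs = _fragment_smiles(donor, maps_d, extra_h=h_map) + "." + _fragment_smiles(acceptor, maps_a)
    rhs = _fragment_smiles(donor, maps_d) + "." + _fragment_smiles(acceptor, maps_a, extra_h=h_map)
    # a bare fragment with no substituent hydrogens parses fine; strip the
    # trailing () artefacts never occurs with this palette
    return lhs + ">>" + rhs


def _n_atoms(frag: _Fragment) -> int:
    return {"methyl": 4, "ethyl": 7, "amino": 3, "hydroxyl": 2, "thiyl": 2}[frag.name]


def generate(config: FixtureConfig) -> list[FixtureRecord]:
    """Generate the fixture population; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    palette = config.palette()
    records: list[FixtureRecord] = []
    for i in range(config.n_reactions):
        donor = palette[rng.integers(len(palette))]
        acceptor = palette[rng.integers(len(palette))]
        nd, na = _n_atoms(donor), _n_atoms(acceptor)
        maps_d = list(range(1, nd + 1))
        h_map = nd + 1
        maps_a = list(range(nd + 2, nd + 1 + na + 1))
        rxn_id = f"fx{i:05d}"
        smiles = _build_reaction_smiles(donor, acceptor, maps_d, h_map, maps_a)
        reaction = parse_reaction(smiles, rxn_id)

        d_ts = float(rng.uniform(*config.d_range))
        conformers = _make_conformers(config, donor, acceptor, maps_d, h_map, maps_a, d_ts, rng)

        graph_term = (
            config.beta["intercept"]
            + config.beta[f"break:{donor.element}-H"]
            + config.beta[f"form:{acceptor.element}-H"]
        )
        geometry_term = config.gamma * d_ts
        noise = float(rng.normal(0.0, config.noise_sigma)) if config.noise_sigma > 0 else 0.0
        reaction.barrier = graph_term + geometry_term + noise
        records.append(
            FixtureRecord(
                reaction=reaction,
                conformers=conformers,
                true_barrier=reaction.barrier,
                components={
                    "graph_term": graph_term,
                    "geometry_term": geometry_term,
                    "noise": noise,
                    "d_ts": d_ts,
                },
            )
        )
    return records


def _make_conformers(config, donor, acceptor, maps_d, h_map, maps_a, d_ts, rng):
    """r/ts/p geometries of the collinear X-H...Y complex, rigidly moved
    and with per-record shuffled file order."""
    out: dict[str, Conformer] = {}
    for role in ("r", "ts", "p"):
        if role == "r":
            hx = donor.xh_bond
            yx = donor.xh_bond + config.separation
        elif role == "ts":
            hx = donor.xh_bond + config.ts_stretch
            yx = hx + d_ts
        else:
            yx = config.separation + acceptor.xh_bond
            hx = yx - acceptor.xh_bond
        d_els, d_coords, _ = _fragment_atoms(donor, np.zeros(3), sign=1.0)
        a_els, a_coords, _ = _fragment_atoms(acceptor, np.array([yx, 0.0, 0.0]), sign=-1.0)
        els = d_els + ["H"] + a_els
        coords = np.array(d_coords + [np.array([hx, 0.0, 0.0])] + a_coords)
        map_order = maps_d + [h_map] + maps_a

        # random rigid motion: rotation from a normalised quaternion + shift
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        coords = coords @ rot.T + rng.normal(scale=3.0, size=3)

        perm = rng.permutation(len(els))
        out[role] = Conformer(
            elements=[els[j] for j in perm],
            coordinates=coords[perm],
            map_order=[map_order[j] for j in perm],
            role={"r": "reactant", "ts": "ts", "p": "product"}[role],
        )
    return out


def _pair_label(e1: str, e2: str) -> str:
    """Canonical element-pair label with hydrogen written last (X-H style)."""
    return "-".join(sorted((e1, e2), key=lambda s: (s == "H", s)))


def bond_change_counts(reaction: Reaction) -> dict[str, int]:
    """Counts of broken/formed/order-changed bonds keyed by element pair."""
    counts: dict[str, int] = {}
    keys = set(reaction.reactant_bonds) | set(reaction.product_bonds)
    for key in keys:
        rb = reaction.reactant_bonds.get(key)
        pb = reaction.product_bonds.get(key)
        pair = _pair_label(*(reaction.reactant_atoms[m].element for m in key))
        if rb is not None and pb is None:
            kind = f"break:{pair}"
        elif rb is None and pb is not None:
            kind = f"form:{pair}"
        elif rb is not None and pb is not None and rb.order != pb.order:
            kind = f"order:{pair}"
        else:
            continue
        counts[kind] = counts.get(kind, 0) + 1
    return counts


def barrier_oracle(record: FixtureRecord, config: FixtureConfig | None = None) -> float:
    """Recompute the generative formula from the stored reaction/conformers.

    Uses only the record's graph (bond-change counts), the TS conformer
    (forming-bond distance read back through the map alignment) and the
    stored noise draw; raises :class:`ConsistencyError` if the result does
    not round-trip to ``true_barrier``.
    """
    config = config or FixtureConfig()
    counts = bond_change_counts(record.reaction)
    graph_term = config.beta["intercept"] + sum(
        config.beta.get(kind, 0.0) * c for kind, c in counts.items()
    )
    formed = [
        key
        for key in record.reaction.product_bonds
        if key not in record.reaction.reactant_bonds
    ]
    if len(formed) != 1:
        raise ConsistencyError(f"expected exactly one formed bond, found {len(formed)}")
    ts = record.conformers["ts"]
    pos = {m: i for i, m in enumerate(ts.map_order)}
    a, b = formed[0]
    d = float(np.linalg.norm(ts.coordinates[pos[a]] - ts.coordinates[pos[b]]))
    value = graph_term + config.gamma * d + record.components["noise"]
    if abs(value - record.true_barrier) > 1e-6:
        raise ConsistencyError(
            f"recomputed barrier {value:.6f} != stored {record.true_barrier:.6f}"
        )
    return value
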