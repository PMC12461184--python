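import numpy as np
import pytest

from rxnbarrier.reaction_graph import (
    AtomRecord,
    BalanceError,
    FeatureConfig,
    ReactionParseError,
    UnsupportedElementError,
    build_cgr,
    default_atom_features,
    default_bond_features,
    directed_edge_features,
    parse_reaction,
)

from conftest import ETHANE_RXN

IDENTITY_RXN = "[C:1]([H:2])([H:3])([H:4])[H:5]>>[C:1]([H:2])([H:3])([H:4])[H:5]"


class TestParseReaction:
    def test_ethane_dehydrogenation_is_balanced(self):
        rxn = parse_reaction(ETHANE_RXN)
        assert rxn.n_atoms == 8
        assert set(rxn.reactant_atoms) == set(rxn.product_atoms) == set(range(1, 9))
        assert len(rxn.reactant_bonds) == 7
        assert len(rxn.product_bonds) == 6

    def test_identity_reaction_sides_compare_equal(self):
        rxn = parse_reaction(IDENTITY_RXN)
        assert rxn.reactant_atoms == rxn.product_atoms
        assert rxn.reactant_bonds == rxn.product_bonds

    @pytest.mark.parametrize(
        "smiles,err",
        [
            ("[CH4:1]>>[CH3:1]", BalanceError),  # H count differs
            ("not a smiles>>[H:1][H:2]", ReactionParseError),
            ("[C:1]([H:2])([H:2])[H:3][H:4]>>[C:1]", ReactionParseError),
            ("[H:1][H:1]>>[H:1][H:1]", ValueError),  # duplicate maps
            ("[O:1]([H:2])[H:3]>>[N:1]([H:2])[H:3]", BalanceError),  # element swap
        ],
    )
    def test_malformed_inputs_raise(self, smiles, err):
        with pytest.raises(err):
            parse_reaction(smiles)


class TestDefaultFeatures:
    def test_carbon_mass_slot_is_scaled_atomic_mass(self):
        rxn = parse_reaction(IDENTITY_RXN)
        vec = default_atom_features(rxn.reactant_atoms[1])
        assert vec[-1] == pytest.approx(0.12011, abs=1e-5)

    def test_nonaromatic_atom_has_zero_aromatic_slot(self):
        rxn = parse_reaction(IDENTITY_RXN)
        assert default_atom_features(rxn.reactant_atoms[1])[-2] == 0.0

    def test_formal_charge_changes_only_charge_block(self):
        base = AtomRecord(1, "N", 3, 0, "SP3", 2, False, 14.007)
        charged = AtomRecord(1, "N", 3, 1, "SP3", 2, False, 14.007)
        diff = default_atom_features(base) != default_atom_features(charged)
        cfg = FeatureConfig()
        lo = len(cfg.elements) + cfg.max_degree + 2
        hi = lo + (cfg.charge_range[1] - cfg.charge_range[0] + 3)
        assert diff.any()
        assert not diff[:lo].any() and not diff[hi:].any()

    def test_unsupported_element_errors(self):
        atom = AtomRecord(1, "Xe", 0, 0, "other", 0, False, 131.29)
        with pytest.raises(UnsupportedElementError):
            default_atom_features(atom)

    def test_absent_bond_is_zero_vector(self):
        assert not default_bond_features(None).any()

    def test_plain_single_bond_sets_only_order_slot(self):
        rxn = parse_reaction(IDENTITY_RXN)
        vec = default_bond_features(rxn.reactant_bonds[(1, 2)])
        assert vec[0] == 1.0 and vec.sum() == 1.0

    def test_aromatic_six_ring_bond_sets_aromatic_and_ring_slots(self):
        benzene = "c1ccccc1"
        mapped = "".join(
            f"[cH:{i}]" if i > 1 else f"[cH:{i}]1" for i in range(1, 7)
        ) + "1"
        rxn = parse_reaction(f"{mapped}>>{mapped}")
        bond = next(iter(rxn.reactant_bonds.values()))
        vec = default_bond_features(bond)
        # slots: orders(4), conjugated, in-ring, ring sizes 3..8
        assert vec[3] == 1.0  # aromatic order
        assert vec[5] == 1.0  # in-ring flag
        assert vec[6 + 3] == 1.0  # ring size 6


class TestCondensedGraph:
    def test_edge_list_is_union_of_both_sides(self):
        cgr = build_cgr(parse_reaction(ETHANE_RXN))
        # 5 unchanged bonds + C1-C2 (order change) + 2 reactant-only + 1 product-only
        assert cgr.n_edges == 8

    def test_changed_cc_bond_has_single_and_double_halves(self):
        rxn = parse_reaction(ETHANE_RXN)
        cgr = build_cgr(rxn)
        k = cgr.edge_list.index((0, 1))
        half = cgr.bond_features.shape[1] // 2
        r, p = cgr.bond_features[k][:half], cgr.bond_features[k][half:]
        assert r[0] == 1.0 and p[1] == 1.0  # single in reactant, double in product

    def test_reactant_only_bond_has_zero_product_half(self):
        rxn = parse_reaction(ETHANE_RXN)
        cgr = build_cgr(rxn)
        half = cgr.bond_features.shape[1] // 2
        changed = [
            k
            for k, key in enumerate(sorted(set(rxn.reactant_bonds) | set(rxn.product_bonds)))
            if (key in rxn.reactant_bonds) != (key in rxn.product_bonds)
        ]
        assert changed
        for k in changed:
            r, p = cgr.bond_features[k][:half], cgr.bond_features[k][half:]
            assert (not r.any()) != (not p.any())  # exactly one all-zero half

    def test_identity_reaction_halves_equal(self):
        cgr = build_cgr(parse_reaction(IDENTITY_RXN))
        ah = cgr.atom_features.shape[1] // 2
        bh = cgr.bond_features.shape[1] // 2
        assert np.array_equal(cgr.atom_features[:, :ah], cgr.atom_features[:, ah:])
        assert np.array_equal(cgr.bond_features[:, :bh], cgr.bond_features[:, bh:])

    def test_relabeling_permutes_rows_and_preserves_edge_multiset(self):
        rxn = parse_reaction(ETHANE_RXN)
        cgr = build_cgr(rxn)
        # relabel map m -> 9 - m (reverses atom order)
        relabeled = ETHANE_RXN
        for m in range(1, 9):
            relabeled = relabeled.replace(f":{m}]", f":tmp{9 - m}]")
        relabeled = relabeled.replace(":tmp", ":")
        cgr2 = build_cgr(parse_reaction(relabeled))
        assert np.allclose(cgr2.atom_features, cgr.atom_features[::-1])
        rows = {tuple(r) for r in cgr.bond_features}
        rows2 = {tuple(r) for r in cgr2.bond_features}
        assert rows == rows2

    def test_every_fixture_reaction_builds(self, fixture_population):
        for rec in fixture_population:
            cgr = build_cgr(rec.reaction)
            assert cgr.atom_features.shape[0] == cgr.n_atoms


class TestDirectedEdges:
    def test_directed_vectors_share_bond_block_and_swap_atom_block(self):
        cgr = build_cgr(parse_reaction(ETHANE_RXN))
        src, dst, rev, feats = directed_edge_features(cgr)
        na = cgr.atom_features.shape[1]
        for e in range(len(src)):
            assert np.array_equal(feats[e, :na], cgr.atom_features[src[e]])
            assert np.array_equal(feats[e, na:], feats[rev[e], na:])
            assert src[e] == dst[rev[e]] and dst[e] == src[rev[e]]

    def test_vector_length_is_atom_plus_bond_width(self):
        cgr = build_cgr(parse_reaction(ETHANE_RXN))
        _, _, _, feats = directed_edge_features(cgr)
        assert feats.shape == (
            2 * cgr.n_edges,
            cgr.atom_features.shape[1] + cgr.bond_features.shape[1],
        )
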