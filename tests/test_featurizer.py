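"""Atom/bond feature layouts and the dual-block reaction features."""

import numpy as np
import pytest
from rdkit import Chem

from cgrnet import (ATOM_FDIM, BOND_FDIM, RXN_ATOM_FDIM, RXN_BOND_FDIM,
                    atom_features, bond_features, build_cgr, featurize_cgr,
                    featurize_molecule, parse_reaction)
from cgrnet.featurizer import ATOMIC_NUMS, RXN_MODES, _tilde
from cgrnet.rxn_graph import AtomAttrs, BondAttrs

from conftest import WATER_BALANCED


def _atom_attrs(smiles, idx=0):
    return AtomAttrs.from_rdkit(Chem.MolFromSmiles(smiles).GetAtomWithIdx(idx))


class TestAtomFeatures:
    def test_vector_length_is_133(self):
        assert atom_features(_atom_attrs("CCO")).shape == (ATOM_FDIM,)

    def test_sp3_carbon_layout(self):
        """Neutral sp3 carbon, total degree 4: one slot per one-hot block
        (6 blocks), aromatic flag clear, mass scaled by 100."""
        x = atom_features(_atom_attrs("CC"))
        onehots, flags = x[:-2], x[-2:]
        assert set(np.unique(onehots)) == {0.0, 1.0}
        assert onehots.sum() == 6
        assert flags[0] == 0.0  # not aromatic
        assert flags[1] == pytest.approx(12.011 / 100, abs=1e-4)
        assert x[0] == 0.0 and x[5] == 1.0  # atomic number 6 -> slot index 5

    def test_out_of_range_atomic_number_hits_unknown_slot(self):
        attrs = AtomAttrs(atomic_num=118, degree=0, formal_charge=0,
                          chiral_tag=0, num_h=0, hybridization="S",
                          aromatic=False, mass=294.0)
        x = atom_features(attrs)
        assert x[len(ATOMIC_NUMS)] == 1.0  # catch-all slot of the Z block
        assert x[:len(ATOMIC_NUMS)].sum() == 0


class TestBondFeatures:
    def test_single_acyclic_bond_layout(self):
        mol = Chem.MolFromSmiles("CC")
        e = bond_features(BondAttrs.from_rdkit(mol.GetBondWithIdx(0)))
        assert e.shape == (BOND_FDIM,)
        assert e[0] == 0.0      # null flag clear
        assert e[1] == 1.0      # single
        assert e[2:5].sum() == 0

    def test_absent_bond_sets_only_null_flag(self):
        e = bond_features(None)
        assert e[0] == 1.0 and e[1:].sum() == 0

    def test_molecular_edge_init_input_is_147(self):
        mol = Chem.MolFromSmiles("CCO")
        g = featurize_molecule(mol)
        cat = np.concatenate([g.atom_matrix[g.edge_src[0]], g.edge_matrix[0]])
        assert cat.shape == (147,)


class TestFeaturizeCGR:
    def test_reaction_dimensions_165_and_28(self, water_records):
        g = featurize_cgr(build_cgr(water_records[0]))
        assert g.atom_matrix.shape == (3, RXN_ATOM_FDIM)
        assert g.edge_matrix.shape == (4, RXN_BOND_FDIM)

    def test_identity_reaction_diff_blocks_are_zero(self, identity_record):
        g = featurize_cgr(build_cgr(identity_record))
        assert np.all(g.atom_matrix[:, ATOM_FDIM:] == 0)
        assert np.all(g.edge_matrix[:, BOND_FDIM:] == 0)

    def test_reverse_reaction_negates_diff_blocks(self, toy_records):
        for rec in toy_records[:15]:
            fwd = featurize_cgr(build_cgr(rec))
            rev = featurize_cgr(build_cgr(rec.reversed()))
            np.testing.assert_allclose(fwd.atom_matrix[:, ATOM_FDIM:],
                                       -rev.atom_matrix[:, ATOM_FDIM:],
                                       atol=1e-12)
            np.testing.assert_allclose(fwd.edge_matrix[:, BOND_FDIM:],
                                       -rev.edge_matrix[:, BOND_FDIM:],
                                       atol=1e-12)

    def test_one_hot_diff_entries_lie_in_minus1_0_1(self, toy_records):
        for rec in toy_records:
            g = featurize_cgr(build_cgr(rec))
            onehot_diff = g.atom_matrix[:, ATOM_FDIM:-1]  # mass entry excluded
            assert set(np.unique(onehot_diff)) <= {-1.0, 0.0, 1.0}
            assert set(np.unique(g.edge_matrix[:, BOND_FDIM:])) \
                <= {-1.0, 0.0, 1.0}

    def test_all_modes_share_vector_lengths(self, water_records):
        cgr = build_cgr(water_records[1])
        for mode in RXN_MODES:
            g = featurize_cgr(cgr, mode=mode)
            assert g.atom_matrix.shape[1] == RXN_ATOM_FDIM
            assert g.edge_matrix.shape[1] == RXN_BOND_FDIM

    def test_balanced_reaction_ignores_imbalance_mode(self, balanced_records):
        for rec in balanced_records[:10]:
            cgr = build_cgr(rec)
            za = featurize_cgr(cgr, imbalance_mode="zero")
            zc = featurize_cgr(cgr, imbalance_mode="copy")
            np.testing.assert_array_equal(za.atom_matrix, zc.atom_matrix)
            np.testing.assert_array_equal(za.edge_matrix, zc.edge_matrix)

    def test_zero_mode_missing_atom_diff_is_minus_reactant(self, water_records):
        """A vanished atom's diff block equals minus its reactant block."""
        cgr = build_cgr(water_records[1])  # vertex 1 only in reactants
        g = featurize_cgr(cgr, mode="reac_diff", imbalance_mode="zero")
        row = g.atom_matrix[0]  # vertices sorted by map number
        np.testing.assert_allclose(row[ATOM_FDIM:], -_tilde(row[:ATOM_FDIM]))

    def test_copy_mode_missing_atom_diff_is_zero(self, water_records):
        cgr = build_cgr(water_records[1])
        g = featurize_cgr(cgr, mode="reac_diff", imbalance_mode="copy")
        assert np.all(g.atom_matrix[0, ATOM_FDIM:] == 0)

    def test_copy_mode_does_not_impute_broken_bonds(self, water_records):
        """Both endpoints of the broken O-H exist on the product side of the
        balanced reaction, so copy mode must not impute the bond there."""
        cgr = build_cgr(water_records[0])
        gz = featurize_cgr(cgr, imbalance_mode="zero")
        gc = featurize_cgr(cgr, imbalance_mode="copy")
        np.testing.assert_array_equal(gz.edge_matrix, gc.edge_matrix)

    def test_unknown_mode_is_a_configuration_error(self, identity_record):
        cgr = build_cgr(identity_record)
        with pytest.raises(ValueError, match="mode"):
            featurize_cgr(cgr, mode="bogus")
        with pytest.raises(ValueError, match="imbalance"):
            featurize_cgr(cgr, imbalance_mode="bogus")


def _remap(record, perm):
    """Relabel map numbers via perm (dict old->new) on copies of both sides."""
    import copy
    rec = copy.copy(record)
    rec.reactant = Chem.Mol(record.reactant)
    rec.product = Chem.Mol(record.product)
    for mol in (rec.reactant, rec.product):
        for a in mol.GetAtoms():
            a.SetAtomMapNum(perm[a.GetAtomMapNum()])
    return rec


class TestRelabelingEquivariance:
    def test_map_permutation_permutes_rows(self, toy_records):
        rng = np.random.default_rng(0)
        for rec in toy_records[:10]:
            cgr = build_cgr(rec)
            maps = sorted(cgr.vertices)
            new = list(rng.permutation(np.arange(1, len(maps) + 1)))
            perm = {old: int(new[i]) for i, old in enumerate(maps)}
            g1 = featurize_cgr(cgr)
            g2 = featurize_cgr(build_cgr(_remap(rec, perm)))
            # row of old map m sits at sorted position of perm[m]
            order = np.argsort([perm[m] for m in maps])
            np.testing.assert_allclose(g2.atom_matrix,
                                       g1.atom_matrix[order], atol=1e-12)
            assert g1.edge_matrix.shape == g2.edge_matrix.shape


class TestDirectedEdges:
    def test_every_bond_gives_two_mutual_reverses(self, toy_records):
        for rec in toy_records[:10]:
            g = featurize_cgr(build_cgr(rec))
            assert g.n_directed_edges % 2 == 0
            for e in range(g.n_directed_edges):
                r = g.rev_index[e]
                assert g.rev_index[r] == e
                assert g.edge_src[e] == g.edge_tgt[r]
                assert g.edge_tgt[e] == g.edge_src[r]
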