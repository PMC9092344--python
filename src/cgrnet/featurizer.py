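"""Numeric atom/bond features for molecules and for condensed reaction graphs.

Molecular atom vectors have length 133 (one-hot atomic number, degree,
formal charge, chirality, H count, hybridization, aromaticity flag, scaled
mass) and molecular bond vectors length 14 (null-bond flag, bond-type
one-hot, conjugation, ring membership, stereo one-hot), so the edge
initialization input cat(x_v, e_vw) has length 147.

Reaction graphs carry dual blocks: the atom vector concatenates one side's
full 133 features with a 32-wide difference block that drops the atomic
number one-hot (elements cannot change in a reaction) but keeps the scaled
mass, giving 165; bond vectors concatenate two 14-blocks, giving 28.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .rxn_graph import AtomAttrs, BondAttrs, CGRGraph

# one-hot block sizes; each block except the flags has a trailing
# catch-all slot for out-of-range values
ATOMIC_NUMS = list(range(1, 101))            # 100 + unknown = 101
DEGREES = list(range(6))                     # 0-5 + unknown = 7
FORMAL_CHARGES = [-2, -1, 0, 1, 2]           # + unknown = 6
CHIRAL_TAGS = [0, 1, 2, 3]                   # + unknown = 5
NUM_HS = list(range(5))                      # 0-4 + unknown = 6
HYBRIDIZATIONS = ["SP", "SP2", "SP3", "SP3D", "SP3D2"]  # + unknown = 6
BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
BOND_STEREOS = [0, 1, 2, 3, 4, 5]            # + unknown = 7

ATOM_FDIM = 133
ATOM_DIFF_FDIM = 32          # 133 minus the 101 atomic-number slots
RXN_ATOM_FDIM = ATOM_FDIM + ATOM_DIFF_FDIM   # 165
BOND_FDIM = 14
RXN_BOND_FDIM = 2 * BOND_FDIM                # 28

RXN_MODES = ("reac_diff", "reac_prod", "prod_diff")
IMBALANCE_MODES = ("zero", "copy")


def _one_hot(value, choices: Sequence) -> List[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # unknown slot
    return vec


def atom_features(attrs: Optional[AtomAttrs]) -> np.ndarray:
    """Length-133 feature vector for an atom; ``None`` gives the zero vector."""
    if attrs is None:
        return np.zeros(ATOM_FDIM)
    vec = (
        _one_hot(attrs.atomic_num, ATOMIC_NUMS)
        + _one_hot(attrs.degree, DEGREES)
        + _one_hot(attrs.formal_charge, FORMAL_CHARGES)
        + _one_hot(attrs.chiral_tag, CHIRAL_TAGS)
        + _one_hot(attrs.num_h, NUM_HS)
        + _one_hot(attrs.hybridization, HYBRIDIZATIONS)
        + [1.0 if attrs.aromatic else 0.0]
        + [attrs.mass / 100.0]
    )
    return np.asarray(vec)


def bond_features(attrs: Optional[BondAttrs]) -> np.ndarray:
    """Length-14 feature vector; an absent bond sets only the null flag."""
    if attrs is None:
        vec = [1.0] + [0.0] * (BOND_FDIM - 1)
        return np.asarray(vec)
    type_vec = [0.0] * len(BOND_TYPES)
    if attrs.bond_type in BOND_TYPES:
        type_vec[BOND_TYPES.index(attrs.bond_type)] = 1.0
    vec = (
        [0.0]
        + type_vec
        + [1.0 if attrs.conjugated else 0.0]
        + [1.0 if attrs.in_ring else 0.0]
        + _one_hot(attrs.stereo, BOND_STEREOS)
    )
    return np.asarray(vec)


def _tilde(x: np.ndarray) -> np.ndarray:
    """Drop the atomic-number one-hot; keeps degree..mass (length 32)."""
    return x[len(ATOMIC_NUMS) + 1:]


@dataclass
class FeaturizedGraph:
    """Numeric graph ready for the encoder.

    ``edge_src``/``edge_tgt`` index atoms for each directed edge; every
    undirected bond contributes the two mutually reverse directed edges
    ``2k`` and ``2k+1`` (``rev_index`` maps one onto the other).
    """

    atom_matrix: np.ndarray            # n_atoms x atom_dim
    edge_matrix: np.ndarray            # 2*n_bonds x bond_dim
    edge_src: np.ndarray               # int, source atom per directed edge
    edge_tgt: np.ndarray               # int, target atom per directed edge
    rev_index: np.ndarray              # int, index of the reverse edge
    extra_features: Optional[np.ndarray] = None

    @property
    def n_atoms(self) -> int:
        return self.atom_matrix.shape[0]

    @property
    def n_directed_edges(self) -> int:
        return self.edge_matrix.shape[0]


def _directed(n_bonds: int, ends: List[Tuple[int, int]]):
    src = np.empty(2 * n_bonds, dtype=np.int64)
    tgt = np.empty(2 * n_bonds, dtype=np.int64)
    rev = np.empty(2 * n_bonds, dtype=np.int64)
    for k, (i, j) in enumerate(ends):
        src[2 * k], tgt[2 * k] = i, j
        src[2 * k + 1], tgt[2 * k + 1] = j, i
        rev[2 * k], rev[2 * k + 1] = 2 * k + 1, 2 * k
    return src, tgt, rev


def featurize_cgr(cgr: CGRGraph, mode: str = "reac_diff",
                  imbalance_mode: str = "zero",
                  extra_features: Optional[np.ndarray] = None,
                  copy_all_bonds: bool = False) -> FeaturizedGraph:
    """Featurize a condensed reaction graph.

    ``mode`` selects how the two sides combine per atom/bond:

    * ``reac_diff`` (default, usually best): reactant block plus the
      product-minus-reactant difference block;
    * ``prod_diff``: product block plus reactant-minus-product difference;
    * ``reac_prod``: reactant block plus the product block directly
      (atomic-number slots dropped from the second block).

    ``imbalance_mode`` fills in atoms/bonds present on only one side:
    ``zero`` substitutes the zero vector, ``copy`` imputes the present
    side's features. Bonds are only imputed when they are missing because
    an endpoint atom is absent (imbalance), not when the bond itself is
    made or broken; set ``copy_all_bonds`` to impute those too.
    Differences are computed after substitution.
    """
    if mode not in RXN_MODES:
        raise ValueError(f"unknown reaction mode {mode!r}; choose from {RXN_MODES}")
    if imbalance_mode not in IMBALANCE_MODES:
        raise ValueError(
            f"unknown imbalance mode {imbalance_mode!r}; choose from {IMBALANCE_MODES}")
    copy = imbalance_mode == "copy"

    verts = cgr.sorted_vertices()
    index = {v.map_num: i for i, v in enumerate(verts)}

    atom_rows = []
    for v in verts:
        reac_attrs, prod_attrs = v.reac, v.prod
        if copy:
            reac_attrs = reac_attrs if v.in_reac else prod_attrs
            prod_attrs = prod_attrs if v.in_prod else v.reac
        xr = atom_features(reac_attrs)
        xp = atom_features(prod_attrs)
        if mode == "reac_diff":
            row = np.concatenate([xr, _tilde(xp) - _tilde(xr)])
        elif mode == "prod_diff":
            row = np.concatenate([xp, _tilde(xr) - _tilde(xp)])
        else:  # reac_prod
            row = np.concatenate([xr, _tilde(xp)])
        atom_rows.append(row)
    atom_matrix = (np.stack(atom_rows) if atom_rows
                   else np.zeros((0, RXN_ATOM_FDIM)))

    edges = cgr.sorted_edges()
    bond_rows = []
    ends = []
    for e in edges:
        i, j = e.key
        ends.append((index[i], index[j]))
        vi, vj = cgr.vertices[i], cgr.vertices[j]
        er = bond_features(e.reac) if e.in_reac else np.zeros(BOND_FDIM)
        ep = bond_features(e.prod) if e.in_prod else np.zeros(BOND_FDIM)
        if copy:
            # impute only if the bond is missing due to a missing endpoint
            if not e.in_reac and (copy_all_bonds
                                  or not (vi.in_reac and vj.in_reac)):
                er = ep
            if not e.in_prod and (copy_all_bonds
                                  or not (vi.in_prod and vj.in_prod)):
                ep = bond_features(e.reac)
        if mode == "reac_diff":
            row = np.concatenate([er, ep - er])
        elif mode == "prod_diff":
            row = np.concatenate([ep, er - ep])
        else:
            row = np.concatenate([er, ep])
        bond_rows.append(row)
    edge_matrix = (np.repeat(np.stack(bond_rows), 2, axis=0) if bond_rows
                   else np.zeros((0, RXN_BOND_FDIM)))
    src, tgt, rev = _directed(len(edges), ends)
    return FeaturizedGraph(atom_matrix=atom_matrix, edge_matrix=edge_matrix,
                           edge_src=src, edge_tgt=tgt, rev_index=rev,
                           extra_features=extra_features)


def featurize_molecule(mol, extra_features: Optional[np.ndarray] = None
                       ) -> FeaturizedGraph:
    """Featurize a plain molecular graph (atom dim 133, bond dim 14)."""
    from .rxn_graph import AtomAttrs as _A, BondAttrs as _B

    atom_matrix = (np.stack([atom_features(_A.from_rdkit(a))
                             for a in mol.GetAtoms()])
                   if mol.GetNumAtoms() else np.zeros((0, ATOM_FDIM)))
    bond_rows = []
    ends = []
    for b in mol.GetBonds():
        ends.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bond_rows.append(bond_features(_B.from_rdkit(b)))
    edge_matrix = (np.repeat(np.stack(bond_rows), 2, axis=0) if bond_rows
                   else np.zeros((0, BOND_FDIM)))
    src, tgt, rev = _directed(len(ends), ends)
    return FeaturizedGraph(atom_matrix=atom_matrix, edge_matrix=edge_matrix,
                           edge_src=src, edge_tgt=tgt, rev_index=rev,
                           extra_features=extra_features)
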