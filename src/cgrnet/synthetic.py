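"""Synthetic atom-mapped toy reactions with graph-derived targets.

Four explicit-hydrogen reaction templates over small C/H/O/N skeletons --
homolysis, SN2 substitution by amide ion, E2 elimination by hydroxide and
proton transfer to water -- each altering at most two bonds, so the linear
target rule

    y = alpha * (bonds broken) + beta * (bonds formed)
        + gamma * (product charge sum - reactant charge sum) + noise

is exactly computable from the condensed graph of reaction. Imbalanced
variants drop one product fragment, mimicking unreported leaving groups.
These fixtures emulate curated reaction datasets structurally (valid
mappings, balanced/imbalanced mixtures, regression or template-id class
targets); they make no claim to realistic thermochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol

from .rxn_graph import ReactionRecord, build_cgr, parse_reaction

SKELETONS = ["CCO", "CCCO", "CC(C)O", "CCOC", "COC", "OCCO",
             "CCN", "CCC", "CCCC", "CNC", "CCCN", "CC(C)C"]

TEMPLATES = ("homolysis", "substitution", "elimination", "proton_transfer")


@dataclass
class FixtureSpec:
    """Generation settings and the linear target rule coefficients."""

    n_reactions: int = 100
    seed: int = 0
    fraction_imbalanced: float = 0.0
    alpha: float = 10.0      # per bond broken
    beta: float = -4.0       # per bond formed
    gamma: float = 2.0       # per unit change of the formal-charge sum
    sigma: float = 0.0       # Gaussian noise on y
    task: str = "regression"  # or "multiclass" (label = template id)

    def __post_init__(self):
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        if not 0.0 <= self.fraction_imbalanced <= 1.0:
            raise ValueError("fraction_imbalanced must be in [0, 1]")


def _with_h(smiles: str) -> Chem.Mol:
    return Chem.AddHs(Chem.MolFromSmiles(smiles))


def _combine(*mols: Chem.Mol) -> RWMol:
    out = mols[0]
    for m in mols[1:]:
        out = Chem.CombineMols(out, m)
    rw = RWMol(out)
    for i, atom in enumerate(rw.GetAtoms()):
        atom.SetAtomMapNum(i + 1)
    return rw


def _finalize(rw: RWMol) -> Chem.Mol:
    for atom in rw.GetAtoms():
        atom.SetNoImplicit(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _heavy(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() > 1


def _h_neighbors(atom: Chem.Atom) -> List[int]:
    return [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]


# -- candidate site finders (indices into the skeleton molecule) ------------

def _sites_homolysis(mol: Chem.Mol) -> List[Tuple[int, ...]]:
    out = []
    for b in mol.GetBonds():
        a, c = b.GetBeginAtom(), b.GetEndAtom()
        if _heavy(a) and _heavy(c) and str(b.GetBondType()) == "SINGLE":
            out.append((a.GetIdx(), c.GetIdx()))
    return out


def _sites_substitution(mol: Chem.Mol) -> List[Tuple[int, ...]]:
    out = []
    for b in mol.GetBonds():
        a, c = b.GetBeginAtom(), b.GetEndAtom()
        pair = {a.GetAtomicNum(), c.GetAtomicNum()}
        if pair == {6, 8} and str(b.GetBondType()) == "SINGLE":
            carbon = a if a.GetAtomicNum() == 6 else c
            oxygen = c if carbon is a else a
            out.append((carbon.GetIdx(), oxygen.GetIdx()))
    return out


def _sites_elimination(mol: Chem.Mol) -> List[Tuple[int, ...]]:
    out = []
    for c_idx, o_idx in _sites_substitution(mol):
        alpha = mol.GetAtomWithIdx(c_idx)
        for nb in alpha.GetNeighbors():
            if nb.GetAtomicNum() != 6:
                continue
            hs = _h_neighbors(nb)
            if hs:
                out.append((hs[0], nb.GetIdx(), c_idx, o_idx))
    return out


def _sites_proton_transfer(mol: Chem.Mol) -> List[Tuple[int, ...]]:
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            hs = _h_neighbors(atom)
            if hs:
                out.append((atom.GetIdx(), hs[0]))
    return out


_FINDERS: dict = {
    "homolysis": _sites_homolysis,
    "substitution": _sites_substitution,
    "elimination": _sites_elimination,
    "proton_transfer": _sites_proton_transfer,
}

# partner molecule added to the reactant side, per template
_PARTNERS = {
    "homolysis": None,
    "substitution": "[NH2-]",
    "elimination": "[OH-]",
    "proton_transfer": "O",
}


def _partner_heteroatom(rw: RWMol, n_skel: int) -> int:
    for atom in rw.GetAtoms():
        if atom.GetIdx() >= n_skel and _heavy(atom):
            return atom.GetIdx()
    raise AssertionError("partner molecule has no heavy atom")


def _apply_template(template: str, reac: RWMol, site: Tuple[int, ...],
                    n_skel: int) -> RWMol:
    prod = RWMol(reac)
    single = Chem.BondType.SINGLE
    if template == "homolysis":
        i, j = site
        prod.RemoveBond(i, j)
        for idx in (i, j):
            a = prod.GetAtomWithIdx(idx)
            a.SetNumRadicalElectrons(a.GetNumRadicalElectrons() + 1)
    elif template == "substitution":
        c, o = site
        n = _partner_heteroatom(prod, n_skel)
        prod.RemoveBond(c, o)
        prod.GetAtomWithIdx(o).SetFormalCharge(-1)
        prod.AddBond(c, n, single)
        prod.GetAtomWithIdx(n).SetFormalCharge(0)
    elif template == "elimination":
        h, cb, ca, o = site
        b = _partner_heteroatom(prod, n_skel)
        prod.RemoveBond(cb, h)
        prod.RemoveBond(ca, o)
        prod.GetBondBetweenAtoms(cb, ca).SetBondType(Chem.BondType.DOUBLE)
        prod.AddBond(h, b, single)
        prod.GetAtomWithIdx(b).SetFormalCharge(0)
        prod.GetAtomWithIdx(o).SetFormalCharge(-1)
    elif template == "proton_transfer":
        het, h = site
        acc = _partner_heteroatom(prod, n_skel)
        prod.RemoveBond(het, h)
        prod.AddBond(h, acc, single)
        prod.GetAtomWithIdx(het).SetFormalCharge(
            prod.GetAtomWithIdx(het).GetFormalCharge() - 1)
        prod.GetAtomWithIdx(acc).SetFormalCharge(
            prod.GetAtomWithIdx(acc).GetFormalCharge() + 1)
    else:
        raise ValueError(f"unknown template {template!r}")
    return prod


def _drop_smallest_fragment(product: Chem.Mol) -> Optional[Chem.Mol]:
    """Remove the smallest product fragment; None if only one fragment."""
    frags = Chem.GetMolFrags(product)
    if len(frags) < 2:
        return None
    victim = min(frags, key=lambda f: (len(f), f))
    rw = RWMol(product)
    for idx in sorted(victim, reverse=True):
        rw.RemoveAtom(idx)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def generate_toy_reactions(spec: FixtureSpec) -> List[ReactionRecord]:
    """Seed-reproducible list of mapped toy reactions with targets.

    Regression targets follow the linear bond-change rule; multiclass
    targets are the template name. All records pass mapping validation,
    and with ``fraction_imbalanced`` zero both sides have equal atom
    multisets.
    """
    rng = np.random.default_rng(spec.seed)
    records: List[ReactionRecord] = []
    while len(records) < spec.n_reactions:
        template = TEMPLATES[rng.integers(len(TEMPLATES))]
        finder = _FINDERS[template]
        skel_order = rng.permutation(len(SKELETONS))
        chosen = None
        for si in skel_order:
            mol = _with_h(SKELETONS[si])
            sites = finder(mol)
            if sites:
                chosen = (mol, sites[rng.integers(len(sites))])
                break
        if chosen is None:
            continue
        skel, site = chosen
        partner = _PARTNERS[template]
        pieces = [skel] + ([_with_h(partner)] if partner else [])
        reac_rw = _combine(*pieces)
        prod_rw = _apply_template(template, reac_rw, site, skel.GetNumAtoms())
        reactant = _finalize(RWMol(reac_rw))
        product = _finalize(prod_rw)
        if rng.random() < spec.fraction_imbalanced:
            reduced = _drop_smallest_fragment(product)
            if reduced is not None:
                product = reduced
        smiles = f"{Chem.MolToSmiles(reactant)}>>{Chem.MolToSmiles(product)}"
        record = ReactionRecord(reactant=reactant, product=product,
                                smiles=smiles)
        cgr = build_cgr(record)
        if spec.task == "multiclass":
            record.targets = np.array([template], dtype=object)
        else:
            y = (spec.alpha * cgr.bonds_broken()
                 + spec.beta * cgr.bonds_formed()
                 + spec.gamma * cgr.charge_change())
            if spec.sigma > 0:
                y += spec.sigma * rng.standard_normal()
            record.targets = np.array([y])
        records.append(record)
    return records


def bond_change_features(records: List[ReactionRecord]) -> np.ndarray:
    """(broken, formed, charge change) per record -- the generative design
    matrix of the regression target rule."""
    rows = []
    for rec in records:
        cgr = build_cgr(rec)
        rows.append([cgr.bonds_broken(), cgr.bonds_formed(),
                     cgr.charge_change()])
    return np.array(rows, dtype=float)


def to_dataframe(records: List[ReactionRecord],
                 target_name: str = "y") -> pd.DataFrame:
    """Fixture records as the CSV dialect the readers consume."""
    return pd.DataFrame({
        "smiles": [r.smiles for r in records],
        target_name: [np.asarray(r.targets).ravel()[0] for r in records],
    })


def write_fixture_csv(records: List[ReactionRecord], path: str,
                      target_name: str = "y") -> None:
    to_dataframe(records, target_name).to_csv(path, index=False)


def fig1_water_example() -> Tuple[ReactionRecord, ReactionRecord]:
    """The water-dissociation toy reaction, balanced and imbalanced.

    The balanced variant breaks one O-H bond heterolytically and keeps the
    other; the imbalanced variant omits the proton fragment from the
    product side, leaving one vertex with no product presence.
    """
    balanced = parse_reaction("[H:1][O:2][H:3]>>[O-:2][H:3].[H+:1]",
                              keep_explicit_h=True)
    imbalanced = parse_reaction("[H:1][O:2][H:3]>>[O-:2][H:3]",
                                keep_explicit_h=True)
    return balanced, imbalanced
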