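"""Atom-mapped reaction SMILES parsing and condensed graph of reaction (CGR).

A reaction is written ``reactants>agents>products`` with an atom-map number on
every atom, e.g. ``[H:1][O:2][H:3]>>[O-:2][H:3].[H+:1]``. The CGR is the
superposition of the reactant and product graphs: one vertex per map number
present on either side, one edge per atom pair bonded on either side, each
carrying a *before* and an *after* attribute block. Imbalanced reactions
(unequal atom multisets, e.g. unreported leaving groups) are first-class:
vertices and edges simply lack one side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from rdkit import Chem


class ReactionParseError(ValueError):
    """Reaction SMILES is syntactically invalid."""


class AtomMappingError(ValueError):
    """Atom-map numbers are missing, duplicated or inconsistent."""


class CGRConsistencyError(ValueError):
    """Reactant and product disagree on atom identity at a map number."""


@dataclass(frozen=True)
class AtomAttrs:
    """Side-specific atom attributes extracted from an RDKit atom."""

    atomic_num: int
    degree: int
    formal_charge: int
    chiral_tag: int
    num_h: int
    hybridization: str
    aromatic: bool
    mass: float

    @classmethod
    def from_rdkit(cls, atom: Chem.Atom) -> "AtomAttrs":
        return cls(
            atomic_num=atom.GetAtomicNum(),
            degree=atom.GetTotalDegree(),
            formal_charge=atom.GetFormalCharge(),
            chiral_tag=int(atom.GetChiralTag()),
            num_h=atom.GetTotalNumHs(includeNeighbors=True),
            hybridization=str(atom.GetHybridization()),
            aromatic=atom.GetIsAromatic(),
            mass=atom.GetMass(),
        )


@dataclass(frozen=True)
class BondAttrs:
    """Side-specific bond attributes extracted from an RDKit bond."""

    bond_type: str
    conjugated: bool
    in_ring: bool
    stereo: int

    @classmethod
    def from_rdkit(cls, bond: Chem.Bond) -> "BondAttrs":
        return cls(
            bond_type=str(bond.GetBondType()),
            conjugated=bond.GetIsConjugated(),
            in_ring=bond.IsInRing(),
            stereo=int(bond.GetStereo()),
        )


@dataclass
class ReactionRecord:
    """A parsed atom-mapped reaction with optional targets and descriptors.

    ``reactant`` and ``product`` are RDKit molecules (possibly multi-fragment)
    whose atoms all carry map numbers; ``agents`` is the discarded middle
    field of the reaction SMILES, kept only as text tokens.
    """

    reactant: Chem.Mol
    product: Chem.Mol
    agents: List[str] = field(default_factory=list)
    targets: Optional[np.ndarray] = None
    extra_features: Optional[np.ndarray] = None
    weight: float = 1.0
    smiles: Optional[str] = None

    def reversed(self) -> "ReactionRecord":
        """The reverse reaction (sides swapped)."""
        return replace(self, reactant=self.product, product=self.reactant,
                       smiles=None)


@dataclass
class CGRVertex:
    map_num: int
    in_reac: bool
    in_prod: bool
    reac: Optional[AtomAttrs]
    prod: Optional[AtomAttrs]


@dataclass
class CGREdge:
    key: Tuple[int, int]  # sorted map-number pair
    in_reac: bool
    in_prod: bool
    reac: Optional[BondAttrs]
    prod: Optional[BondAttrs]


@dataclass
class CGRGraph:
    """Union graph of the two reaction sides, keyed by atom-map numbers.

    Vertices are ordered by map number and edges by their sorted key, so any
    relabeling of map numbers permutes rows predictably.
    """

    vertices: Dict[int, CGRVertex]
    edges: Dict[Tuple[int, int], CGREdge]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_vertices(self) -> List[CGRVertex]:
        return [self.vertices[k] for k in sorted(self.vertices)]

    def sorted_edges(self) -> List[CGREdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def bonds_broken(self) -> int:
        """Edges present in the reactants but not in the products."""
        return sum(1 for e in self.edges.values() if e.in_reac and not e.in_prod)

    def bonds_formed(self) -> int:
        """Edges present in the products but not in the reactants."""
        return sum(1 for e in self.edges.values() if e.in_prod and not e.in_reac)

    def charge_change(self) -> int:
        """Sum of product formal charges minus sum of reactant formal charges."""
        dq = 0
        for v in self.vertices.values():
            if v.in_prod:
                dq += v.prod.formal_charge
            if v.in_reac:
                dq -= v.reac.formal_charge
        return dq


def _parse_side(smiles: str, keep_explicit_h: bool) -> Chem.Mol:
    if not smiles.strip():
        raise ReactionParseError("empty reaction side")
    params = Chem.SmilesParserParams()
    params.removeHs = not keep_explicit_h
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise ReactionParseError(f"invalid SMILES: {smiles!r}")
    return mol


def parse_reaction(reaction_smiles: str, keep_explicit_h: bool = False,
                   strict: bool = True) -> ReactionRecord:
    """Parse a ``reactants>agents>products`` reaction SMILES.

    The agents field is tokenized and discarded from the graphs. With
    ``keep_explicit_h`` set, hydrogens written as explicit atoms (``[H:1]``)
    stay in the graph; otherwise RDKit folds them into implicit H counts.

    With ``strict`` (default), mapping violations -- an unmapped atom, a
    duplicate map number within a side, or an element mismatch between sides
    -- raise :class:`AtomMappingError`; pass ``strict=False`` to get the
    record regardless and inspect it with :func:`validate_mapping`.
    """
    parts = reaction_smiles.split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"expected 'reactants>agents>products', got {reaction_smiles!r}")
    reac_s, agent_s, prod_s = parts
    reactant = _parse_side(reac_s, keep_explicit_h)
    product = _parse_side(prod_s, keep_explicit_h)
    agents = [t for t in agent_s.split(".") if t]
    record = ReactionRecord(reactant=reactant, product=product, agents=agents,
                            smiles=reaction_smiles)
    if strict:
        issues = validate_mapping(record)
        if issues:
            raise AtomMappingError("; ".join(issues))
    return record


def _side_map(mol: Chem.Mol, side: str, issues: List[str]) -> Dict[int, Chem.Atom]:
    """Map-number -> atom for one side, recording violations."""
    out: Dict[int, Chem.Atom] = {}
    for atom in mol.GetAtoms():
        num = atom.GetAtomMapNum()
        if num < 1:
            issues.append(f"unmapped atom {atom.GetSymbol()} (idx "
                          f"{atom.GetIdx()}) on {side} side")
            continue
        if num in out:
            issues.append(f"duplicate map number {num} on {side} side")
            continue
        out[num] = atom
    return out


def validate_mapping(record: ReactionRecord) -> List[str]:
    """Report mapping violations; an empty list means the record is usable.

    Imbalance (atoms present on only one side) is allowed and not reported.
    """
    issues: List[str] = []
    reac = _side_map(record.reactant, "reactant", issues)
    prod = _side_map(record.product, "product", issues)
    for num in sorted(set(reac) & set(prod)):
        if reac[num].GetAtomicNum() != prod[num].GetAtomicNum():
            issues.append(
                f"element mismatch at map {num}: "
                f"{reac[num].GetSymbol()} (reactant) vs "
                f"{prod[num].GetSymbol()} (product)")
    return issues


def _side_edges(mol: Chem.Mol) -> Dict[Tuple[int, int], Chem.Bond]:
    out: Dict[Tuple[int, int], Chem.Bond] = {}
    for bond in mol.GetBonds():
        i = bond.GetBeginAtom().GetAtomMapNum()
        j = bond.GetEndAtom().GetAtomMapNum()
        out[(min(i, j), max(i, j))] = bond
    return out


def build_cgr(record: ReactionRecord) -> CGRGraph:
    """Superpose the reactant and product graphs into a CGR.

    Vertex and edge sets are the unions over both sides, keyed by map
    numbers; per-side attribute blocks are filled from whichever side the
    atom or bond exists on.
    """
    issues: List[str] = []
    reac_atoms = _side_map(record.reactant, "reactant", issues)
    prod_atoms = _side_map(record.product, "product", issues)
    if issues:
        raise AtomMappingError("; ".join(issues))

    vertices: Dict[int, CGRVertex] = {}
    for num in sorted(set(reac_atoms) | set(prod_atoms)):
        ra = reac_atoms.get(num)
        pa = prod_atoms.get(num)
        if ra is not None and pa is not None \
                and ra.GetAtomicNum() != pa.GetAtomicNum():
            raise CGRConsistencyError(
                f"element mismatch at map {num}: {ra.GetSymbol()} vs "
                f"{pa.GetSymbol()}")
        vertices[num] = CGRVertex(
            map_num=num, in_reac=ra is not None, in_prod=pa is not None,
            reac=AtomAttrs.from_rdkit(ra) if ra is not None else None,
            prod=AtomAttrs.from_rdkit(pa) if pa is not None else None)

    reac_bonds = _side_edges(record.reactant)
    prod_bonds = _side_edges(record.product)
    edges: Dict[Tuple[int, int], CGREdge] = {}
    for key in sorted(set(reac_bonds) | set(prod_bonds)):
        rb = reac_bonds.get(key)
        pb = prod_bonds.get(key)
        edges[key] = CGREdge(
            key=key, in_reac=rb is not None, in_prod=pb is not None,
            reac=BondAttrs.from_rdkit(rb) if rb is not None else None,
            prod=BondAttrs.from_rdkit(pb) if pb is not None else None)
    return CGRGraph(vertices=vertices, edges=edges)


def strip_atom_maps(mol: Chem.Mol) -> Chem.Mol:
    """Copy of ``mol`` with all atom-map numbers cleared."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def canonical_side(mol: Chem.Mol) -> str:
    """Canonical SMILES of one reaction side, atom maps stripped."""
    return Chem.MolToSmiles(strip_atom_maps(mol))


def condition_free_key(record: ReactionRecord) -> str:
    """Canonical ``reactants>>products`` string, ignoring agents and maps.

    Identical reactions run under different conditions (solvents, enzymes)
    share this key.
    """
    return f"{canonical_side(record.reactant)}>>{canonical_side(record.product)}"


def direction_free_key(record: ReactionRecord) -> Tuple[str, str]:
    """Unordered pair of canonical sides; equates a reaction and its reverse."""
    a = canonical_side(record.reactant)
    b = canonical_side(record.product)
    return (a, b) if a <= b else (b, a)
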