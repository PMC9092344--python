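"""Train/validation/test splitting protocols for reaction datasets.

Four kinds are supported: plain ``random``; ``random_grouped``, a random
split over unique condition-free reactions so that replicates of one
reaction under different conditions (solvents, enzymes) co-locate;
``directed_scaffold``, a scaffold split on the reactant side constrained so
that a reaction and its reverse always share a partition; and
``predefined``, which reads index files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .rxn_graph import (ReactionRecord, condition_free_key,
                        direction_free_key)

SPLIT_KINDS = ("random", "random_grouped", "directed_scaffold", "predefined")

Partition = Tuple[List[int], List[int], List[int]]


@dataclass
class SplitSpec:
    """Split protocol, fractions (default 80/10/10) and seed."""

    kind: str = "random"
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    index_files: Optional[Tuple[str, str, str]] = None

    def __post_init__(self):
        if self.kind not in SPLIT_KINDS:
            raise ValueError(f"kind must be one of {SPLIT_KINDS}")
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions) \
                or not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("fractions must be three non-negative numbers "
                             "summing to 1")


def _sizes(n: int, fractions: Sequence[float]) -> Tuple[int, int, int]:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return n_train, n_val, n - n_train - n_val


def _partition_units(n_units: int, spec: SplitSpec,
                     rng: np.random.Generator) -> List[np.ndarray]:
    order = rng.permutation(n_units)
    n_tr, n_va, _ = _sizes(n_units, spec.fractions)
    return [order[:n_tr], order[n_tr:n_tr + n_va], order[n_tr + n_va:]]


def random_split(records: Sequence, spec: SplitSpec) -> Partition:
    """Uniform random partition; sizes within one record of the fractions."""
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(spec.seed)
    parts = _partition_units(n, spec, rng)
    return tuple(sorted(p.tolist()) for p in parts)  # type: ignore[return-value]


def _expand_groups(groups: Dict[object, List[int]], spec: SplitSpec,
                   rng: np.random.Generator) -> Partition:
    keys = list(groups)
    parts = _partition_units(len(keys), spec, rng)
    out: List[List[int]] = [[], [], []]
    for p, unit_idx in enumerate(parts):
        for u in unit_idx:
            out[p].extend(groups[keys[u]])
        out[p].sort()
    return tuple(out)  # type: ignore[return-value]


def grouped_random_split(records: Sequence[ReactionRecord],
                         spec: SplitSpec) -> Partition:
    """Random split over unique condition-free reactions.

    All records sharing a canonical ``reactants>>products`` string (maps
    and agents ignored) land in the same partition, so a reaction measured
    in several solvents or with several enzymes never leaks across sets.
    """
    groups: Dict[str, List[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(condition_free_key(rec), []).append(i)
    return _expand_groups(groups, spec, np.random.default_rng(spec.seed))


def _side_scaffold(smiles: str) -> str:
    """Generic ring-system framework of one side; multi-molecule sides use
    the sorted, dot-joined frameworks of the components."""
    frags = []
    for part in smiles.split("."):
        mol = Chem.MolFromSmiles(part)
        if mol is None:
            frags.append(part)
            continue
        try:
            scaf = MurckoScaffold.GetScaffoldForMol(mol)
            scaf = MurckoScaffold.MakeScaffoldGeneric(scaf)
            frags.append(Chem.MolToSmiles(scaf))
        except Exception:  # noqa: BLE001 -- exotic valence; fall back
            frags.append("")
    return ".".join(sorted(frags))


def directed_scaffold_split(records: Sequence[ReactionRecord],
                            spec: SplitSpec) -> Partition:
    """Scaffold split on the reactant side with forward/reverse pairing.

    Records are first grouped by the unordered pair of canonical sides, so
    a reaction and its reverse can never straddle partitions; pair groups
    are then bucketed by the generic Murcko framework of the
    lexicographically smaller side (a direction-independent choice) and
    buckets are assigned largest-first to training, then validation, then
    test. With fewer than three scaffold buckets no scaffold split exists;
    a warning is emitted and a grouped random split (pairs kept together)
    is used instead.
    """
    rng = np.random.default_rng(spec.seed)
    pairs: Dict[Tuple[str, str], List[int]] = {}
    for i, rec in enumerate(records):
        pairs.setdefault(direction_free_key(rec), []).append(i)

    buckets: Dict[str, List[int]] = {}
    for key, idx in pairs.items():
        buckets.setdefault(_side_scaffold(key[0]), []).extend(idx)

    if len(buckets) < 3:
        warnings.warn("fewer than 3 scaffold buckets; falling back to a "
                      "grouped random split over forward/reverse pairs")
        return _expand_groups(pairs, spec, rng)

    # largest buckets to training first; random tie-break among equal sizes
    keys = list(buckets)
    tie = rng.permutation(len(keys))
    order = sorted(range(len(keys)),
                   key=lambda i: (-len(buckets[keys[i]]), tie[i]))
    n = len(records)
    n_tr, n_va, _ = _sizes(n, spec.fractions)
    out: List[List[int]] = [[], [], []]
    for i in order:
        idx = buckets[keys[i]]
        if len(out[0]) + len(idx) <= n_tr or len(out[0]) == 0:
            out[0].extend(idx)
        elif len(out[1]) + len(idx) <= n_va or len(out[1]) == 0:
            out[1].extend(idx)
        else:
            out[2].extend(idx)
    for p in out:
        p.sort()
    return tuple(out)  # type: ignore[return-value]


def predefined_split(records: Sequence, spec: SplitSpec) -> Partition:
    """Read one plain-text index file (one integer per line) per partition."""
    if spec.index_files is None or len(spec.index_files) != 3:
        raise ValueError("predefined split requires three index files")
    parts: List[List[int]] = []
    for path in spec.index_files:
        with open(path) as fh:
            parts.append(sorted(int(line) for line in fh if line.strip()))
    seen = [i for p in parts for i in p]
    if len(set(seen)) != len(seen):
        raise ValueError("predefined partitions overlap")
    if seen and (min(seen) < 0 or max(seen) >= len(records)):
        raise ValueError("predefined index out of range")
    return tuple(parts)  # type: ignore[return-value]


def make_split(records: Sequence[ReactionRecord], spec: SplitSpec) -> Partition:
    """Dispatch on ``spec.kind``."""
    return {
        "random": random_split,
        "random_grouped": grouped_random_split,
        "directed_scaffold": directed_scaffold_split,
        "predefined": predefined_split,
    }[spec.kind](records, spec)


def save_split(partition: Partition, paths: Tuple[str, str, str]) -> None:
    for part, path in zip(partition, paths):
        with open(path, "w") as fh:
            fh.write("\n".join(str(i) for i in part) + "\n")
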