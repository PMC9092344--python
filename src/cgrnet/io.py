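"""CSV dataset reading for reaction tables and descriptor files.

The dataset dialect is a UTF-8 comma-separated file with a mandatory
header; the reaction column (default ``smiles``) holds atom-mapped
reaction SMILES and the remaining named columns hold targets. An optional
row-aligned descriptor CSV supplies a fixed-width float vector per
reaction.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rxn_graph import ReactionRecord, parse_reaction


class DatasetError(ValueError):
    pass


def read_dataset(data_path: str, reaction_column: str = "smiles",
                 target_columns: Optional[Sequence[str]] = None,
                 features_path: Optional[str] = None,
                 keep_explicit_h: bool = False,
                 task: str = "regression",
                 skip_invalid: bool = False
                 ) -> Tuple[List[ReactionRecord], List[str]]:
    """Read a reaction CSV (and optional descriptor CSV) into records.

    Returns the records and a report of skipped rows (empty unless
    ``skip_invalid``); without ``skip_invalid`` the first bad row raises,
    naming its line number.
    """
    df = pd.read_csv(data_path)
    if reaction_column not in df.columns:
        raise DatasetError(f"{data_path}: missing reaction column "
                           f"{reaction_column!r}")
    if target_columns is None:
        target_columns = [c for c in df.columns if c != reaction_column]
    for col in target_columns:
        if col not in df.columns:
            raise DatasetError(f"{data_path}: missing target column {col!r}")

    features = None
    if features_path is not None:
        fdf = pd.read_csv(features_path)
        if len(fdf) != len(df):
            raise DatasetError(
                f"row-count mismatch: {data_path} has {len(df)} rows but "
                f"{features_path} has {len(fdf)}")
        features = fdf.to_numpy(dtype=float)

    records: List[ReactionRecord] = []
    report: List[str] = []
    for i, (_, row) in enumerate(df.iterrows()):
        line_no = i + 2  # header is line 1
        try:
            rec = parse_reaction(str(row[reaction_column]),
                                 keep_explicit_h=keep_explicit_h)
        except ValueError as exc:
            msg = f"line {line_no}: {exc}"
            if not skip_invalid:
                raise DatasetError(f"{data_path}: {msg}") from exc
            report.append(msg)
            continue
        if task == "multiclass":
            rec.targets = np.array([row[target_columns[0]]], dtype=object)
        else:
            rec.targets = np.array([float(row[c]) for c in target_columns])
        if features is not None:
            rec.extra_features = features[i]
        records.append(rec)
    return records, report
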