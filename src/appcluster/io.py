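"""Reading and writing event tables, labels and split-tree reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("appcluster")

__all__ = ["EventMatrix", "read_events", "write_labels_tsv", "write_tree_json"]


@dataclass
class EventMatrix:
    """An n x d numeric event matrix with optional per-event labels."""

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0:
        raise ValueError(f"{path} contains no rows")
    return df


def read_events(
    path: str | Path,
    feature_columns: list[str] | None = None,
    label_column: str | None = None,
) -> EventMatrix:
    """Load a delimited event table into an EventMatrix.

    ``feature_columns`` defaults to all numeric columns except the label
    column.  Rows with non-finite feature values are dropped and the
    exclusion count logged.  Missing columns raise an error naming them.
    """
    df = _read_table(path)
    for col in (feature_columns or []) + ([label_column] if label_column else []):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    if feature_columns is None:
        numeric = df.select_dtypes(include=[np.number]).columns.tolist()
        feature_columns = [c for c in numeric if c != label_column]
        if not feature_columns:
            raise ValueError(f"no numeric feature columns found in {path}")
    X = df[feature_columns].to_numpy(dtype=float)
    finite = np.all(np.isfinite(X), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.warning("dropped %d rows with non-finite feature values", n_dropped)
    labels = None
    if label_column is not None:
        labels = df.loc[finite, label_column].to_numpy()
    return EventMatrix(X=X[finite], feature_names=list(feature_columns), labels=labels)


def write_labels_tsv(path: str | Path, labels: np.ndarray) -> None:
    """One 0-based integer cluster ID per line, aligned to input row order."""
    np.savetxt(path, np.asarray(labels, dtype=np.int64), fmt="%d")


def write_tree_json(path: str | Path, tree) -> None:
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2)
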