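"""Readers and writers: TSV character matrices, Newick trees, run configs.

Character matrices are tab-separated with a header row of character ids and
a first column of cell ids; entries are integers with 0 = unedited and
-1 = missing.  Trees are standard Newick with branch lengths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import LineageTree

__all__ = [
    "read_character_matrix",
    "write_character_matrix",
    "read_newick",
    "write_newick",
    "RunConfig",
    "write_provenance",
]

_CELL_COL = "cell"


def read_character_matrix(path) -> pd.DataFrame:
    """Read a TSV character matrix; validates integer entries, rectangular
    shape and unique cell ids."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty character matrix file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"no character columns in {path}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell ids: {dupes}")
    if df.isna().any().any():
        raise ValueError(f"ragged or missing entries in {path}")
    try:
        values = df.to_numpy()
        as_int = values.astype(np.int64)
        if not np.array_equal(as_int, values.astype(float)):
            raise ValueError
    except (ValueError, TypeError):
        raise ValueError(f"non-integer entries in {path}") from None
    out = pd.DataFrame(as_int, index=df.index.astype(str), columns=df.columns)
    out.index.name = _CELL_COL
    return out


def write_character_matrix(matrix: pd.DataFrame, path) -> None:
    matrix = matrix.copy()
    matrix.index.name = _CELL_COL
    matrix.to_csv(path, sep="\t")


def read_newick(path) -> LineageTree:
    return LineageTree.from_newick(Path(path).read_text())


def write_newick(tree: LineageTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


@dataclass
class RunConfig:
    """Declarative run configuration; round-trips losslessly through JSON."""

    command: str
    seed: int = 0
    out_dir: str = "."
    options: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


def write_provenance(path, command: str, seed, options: dict) -> None:
    """Record what produced an artifact (command, seed, options, version)."""
    from . import __version__

    record = {"command": command, "seed": seed, "options": options,
              "version": __version__}
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True,
                                     default=str) + "\n")
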