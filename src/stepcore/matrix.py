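"""Labeled symmetric relationship matrices and their TSV round-trip format."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Recognized matrix kinds.  ``Astar`` is the only directional one.
KINDS = ("A", "A22", "G", "Ga", "H", "Hcor", "D", "Astar")

_SYM_TOL = 1e-8


@dataclass
class RelationshipMatrix:
    """A square matrix over an ordered set of genotype identifiers.

    Parameters
    ----------
    ids
        Row/column labels, in order.
    values
        Square ``float64`` array, symmetric unless ``kind == "Astar"``.
    kind
        One of :data:`KINDS`; records which stage of the pipeline
        produced the matrix (pedigree A, genomic G, hybrid H, ...).
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "A"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate identifiers in matrix labels")
        if self.kind not in KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.kind != "Astar" and n > 0:
            if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
                raise ValueError(f"{self.kind} matrix is not symmetric")
        self._index = {g: k for k, g in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, i: str, j: str) -> float:
        """Entry for the identifier pair ``(i, j)``."""
        return float(self.values[self._index[i], self._index[j]])

    def indices(self, ids) -> np.ndarray:
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise KeyError(f"ids not in matrix: {missing}")
        return np.array([self._index[i] for i in ids], dtype=int)

    def submatrix(self, ids, kind: str | None = None) -> "RelationshipMatrix":
        """Restrict to ``ids`` (in the given order)."""
        idx = self.indices(ids)
        return RelationshipMatrix(
            list(ids), self.values[np.ix_(idx, idx)], kind or self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        """Write a full square TSV with a ``# kind:`` metadata line."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# kind: {self.kind}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str | None = None) -> "RelationshipMatrix":
        path = Path(path)
        with path.open() as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = first.lstrip("#").strip()
                if meta.startswith("kind:") and kind is None:
                    kind = meta.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0,
                             float_precision="round_trip")
        ids = [str(i) for i in df.index]
        if [str(c) for c in df.columns] != ids:
            raise ValueError(f"{path}: row and column labels differ")
        return cls(ids, df.to_numpy(dtype=float), kind or "A")
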