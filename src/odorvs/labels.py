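"""Binary multi-label odor-annotation container.

Molecules carry sets of qualitative odor notes ("fruity", "green", ...);
the dataset convention is that every molecule has at least one note and the
note-frequency distribution is heavily skewed (the most frequent note covers
roughly a quarter of the molecules, the rarest well under 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LabelMatrix:
    """Binary molecule x odor-note matrix.

    Parameters
    ----------
    molecule_ids : list of str
        One identifier per row.
    notes : list of str
        Odor-note names, one per column.
    matrix : ndarray of shape (n_molecules, n_notes)
        Binary (0/1) annotation matrix. Every row must have at least one
        positive entry.
    """

    molecule_ids: list[str]
    notes: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("label matrix must be 2-D")
        n, c = self.matrix.shape
        if n != len(self.molecule_ids):
            raise ValueError(
                f"{len(self.molecule_ids)} molecule ids but {n} matrix rows"
            )
        if c != len(self.notes):
            raise ValueError(f"{len(self.notes)} notes but {c} matrix columns")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("label matrix entries must be 0 or 1")
        if (self.matrix.sum(axis=1) == 0).any():
            bad = [self.molecule_ids[i]
                   for i in np.flatnonzero(self.matrix.sum(axis=1) == 0)][:5]
            raise ValueError(f"molecules without any label: {bad}")
        self.matrix = self.matrix.astype(np.int8)

    @property
    def n_molecules(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_notes(self) -> int:
        return self.matrix.shape[1]

    @property
    def class_counts(self) -> np.ndarray:
        """Number of positive molecules per note."""
        return self.matrix.sum(axis=0).astype(int)

    @property
    def class_frequencies(self) -> np.ndarray:
        """Fraction of molecules carrying each note."""
        return self.class_counts / self.n_molecules

    def subset(self, indices: np.ndarray) -> "LabelMatrix":
        """Row-subset keeping all note columns."""
        indices = np.asarray(indices)
        return LabelMatrix(
            molecule_ids=[self.molecule_ids[i] for i in indices],
            notes=list(self.notes),
            matrix=self.matrix[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        """Two-column table: molecule_id, semicolon-joined note names."""
        joined = [
            ";".join(self.notes[j] for j in np.flatnonzero(row))
            for row in self.matrix
        ]
        return pd.DataFrame({"molecule_id": self.molecule_ids, "notes": joined})

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "LabelMatrix":
        """Read a label table written by :meth:`write`.

        Note columns are ordered by decreasing frequency (ties by name) so
        class index 0 is always the most frequent note.
        """
        df = pd.read_csv(path, sep=sep, dtype=str)
        if not {"molecule_id", "notes"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns molecule_id, notes")
        note_sets = [set(s.split(";")) for s in df["notes"]]
        counts: dict[str, int] = {}
        for s in note_sets:
            for note in s:
                counts[note] = counts.get(note, 0) + 1
        notes = sorted(counts, key=lambda k: (-counts[k], k))
        col = {note: j for j, note in enumerate(notes)}
        mat = np.zeros((len(df), len(notes)), dtype=np.int8)
        for i, s in enumerate(note_sets):
            for note in s:
                mat[i, col[note]] = 1
        return cls(list(df["molecule_id"]), notes, mat)
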