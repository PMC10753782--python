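"""Aligned protein sequences (multiple sequence alignment container)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from ._lg import AA_ORDER

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass
class Msa:
    """Equal-length aligned amino-acid rows keyed by label."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows are not equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    def encoded(self) -> np.ndarray:
        """(n_taxa, n_sites) int8 codes; gaps/unknowns are -1 (missing)."""
        arr = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int8)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row.upper()):
                arr[i, j] = _AA_INDEX.get(ch, -1)
        return arr

    def resample_columns(self, rng: np.random.Generator) -> "Msa":
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        return Msa(list(self.labels), rows)

    def take_columns(self, idx) -> "Msa":
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        return Msa(list(self.labels), rows)

    # -- FASTA -----------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str) -> "Msa":
        labels, rows = [], []
        for rec in SeqIO.parse(path, "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not labels:
            raise ValueError(f"{path}: empty alignment")
        return cls(labels, rows)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.rows):
                fh.write(f">{label}\n{row}\n")
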