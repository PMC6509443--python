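"""Aligned haplotype sequences over the 5-letter alphabet {A, C, G, T, -} plus N.

Gap ('-') is a real character state; N is "unknown" and is treated as a
wildcard downstream. Anything else read from a FASTA is normalised to N with
a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

ALPHABET = frozenset("ACGT-N")

__all__ = ["HaplotypeAlignment", "AlignmentError", "read_fasta_alignment", "write_fasta"]


class AlignmentError(ValueError):
    pass


@dataclass
class HaplotypeAlignment:
    """Equal-length aligned sequences with a sample -> population mapping."""

    sequences: np.ndarray  # (n, L) array of single characters, dtype 'U1'
    sample_ids: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype="U1")
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.sequences.ndim != 2:
            raise AlignmentError("sequences must form a 2-D character matrix")
        if len(self.sample_ids) != self.sequences.shape[0]:
            raise AlignmentError("sample_ids length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids")
        bad = ~np.isin(self.sequences, list(ALPHABET))
        if bad.any():
            raise AlignmentError("characters outside {A,C,G,T,-,N}")

    @property
    def n_samples(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-sequence fraction of N characters."""
        return (self.sequences == "N").mean(axis=1)

    def take(self, idx) -> "HaplotypeAlignment":
        return HaplotypeAlignment(
            self.sequences[idx], self.sample_ids[idx], self.populations[idx]
        )

    def seq_str(self, i: int) -> str:
        return "".join(self.sequences[i])


def read_fasta_alignment(
    path: str | Path,
    populations: dict[str, str] | None = None,
) -> HaplotypeAlignment:
    """Read an aligned FASTA; all records must have equal length.

    Characters are upper-cased; anything outside {A,C,G,T,-,N} becomes N
    (with a warning). Population labels come from ``populations`` keyed by
    record id, defaulting to ``"?"``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: empty FASTA")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        offenders = [r.id for r in records if len(r.seq) != len(records[0].seq)]
        raise AlignmentError(
            f"{path}: unequal sequence lengths (e.g. {offenders[:5]})"
        )
    mat = np.array([list(str(r.seq).upper()) for r in records], dtype="U1")
    foreign = ~np.isin(mat, list(ALPHABET))
    if foreign.any():
        warnings.warn(
            f"{path}: {int(foreign.sum())} characters outside ACGT-N mapped to N",
            stacklevel=2,
        )
        mat[foreign] = "N"
    ids = np.array([r.id for r in records], dtype=object)
    pops = np.array(
        [populations.get(i, "?") if populations else "?" for i in ids], dtype=object
    )
    return HaplotypeAlignment(mat, ids, pops)


def write_fasta(aln: HaplotypeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(aln.n_samples):
            fh.write(f">{aln.sample_ids[i]}\n{aln.seq_str(i)}\n")
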