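"""Sequence-space evaluation statistics for designed sequences.

Covers the three quantities used to characterize fixed-backbone designs:
native sequence recovery (fraction of positions matching the native
residue), similarity of the designed-sequence profile to a reference PSSM
(one minus the mean per-position base-2 Jensen-Shannon divergence, so the
score lives in [0, 1]), and design diversity (one minus mean pairwise
sequence identity within a design set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon
from biotite.sequence.io.fasta import FastaFile

from .potts import Alphabet, ContractError, SequenceState

__all__ = [
    "PSSM",
    "DesignSet",
    "sequence_recovery",
    "sequence_profile",
    "pssm_similarity",
    "design_diversity",
    "read_fasta_designs",
    "write_fasta_designs",
    "read_pssm_tsv",
    "write_pssm_tsv",
]


@dataclass(frozen=True)
class PSSM:
    """Per-position amino-acid probability table (rows sum to 1)."""

    probabilities: np.ndarray  # (L, A)
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 2 or p.shape[1] != self.alphabet.size:
            raise ContractError("PSSM must be an L x A table")
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ContractError("PSSM rows must be nonnegative and sum to 1")

    @property
    def L(self) -> int:
        return int(self.probabilities.shape[0])


@dataclass(frozen=True)
class DesignSet:
    """n >= 1 equal-length designed sequences plus provenance metadata."""

    sequences: tuple[SequenceState, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if len(self.sequences) < 1:
            raise ContractError("design set needs at least one sequence")
        L = len(self.sequences[0])
        alpha = self.sequences[0].alphabet.symbols
        for s in self.sequences:
            if len(s) != L or s.alphabet.symbols != alpha:
                raise ContractError("design set sequences must share length and alphabet")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    def as_matrix(self) -> np.ndarray:
        return np.stack([s.residues for s in self.sequences])


def sequence_recovery(designed: SequenceState, native: SequenceState) -> float:
    """Fraction of positions where the designed residue matches the native."""
    if len(designed) != len(native):
        raise ContractError("sequences must have equal length")
    return float(np.mean(designed.residues == native.residues))


def sequence_profile(d: DesignSet, pseudocount: float = 0.0) -> PSSM:
    """Pseudocount-smoothed per-position residue frequency table."""
    if pseudocount < 0:
        raise ContractError("pseudocount must be nonnegative")
    alpha = d.sequences[0].alphabet
    counts = np.full((d.L, alpha.size), pseudocount, dtype=np.float64)
    for s in d.sequences:
        np.add.at(counts, (np.arange(d.L), s.residues), 1.0)
    return PSSM(counts / counts.sum(axis=1, keepdims=True), alpha)


def pssm_similarity(profile: PSSM, reference: PSSM) -> float:
    """1 - mean per-position base-2 Jensen-Shannon divergence, in [0, 1].

    Symmetric in its arguments; 1 exactly when all rows match, 0 when every
    position pair is a disjoint point mass (JSD attains its 1-bit maximum).
    """
    if profile.probabilities.shape != reference.probabilities.shape:
        raise ContractError("PSSM shapes must match")
    jsd = (
        jensenshannon(profile.probabilities, reference.probabilities, base=2, axis=1)
        ** 2
    )
    jsd = np.nan_to_num(jsd, nan=0.0)  # identical rows can yield 0/0 under sqrt
    return float(1.0 - np.clip(jsd, 0.0, 1.0).mean())


def design_diversity(d: DesignSet) -> tuple[float, float]:
    """(mean pairwise identity, diversity = 1 - identity) over all pairs."""
    if d.n < 2:
        raise ContractError("diversity needs at least two sequences")
    mat = d.as_matrix()
    idents = [
        float(np.mean(mat[i] == mat[j])) for i, j in combinations(range(d.n), 2)
    ]
    identity = float(np.mean(idents))
    return identity, 1.0 - identity


# ---------------------------------------------------------------------------
# I/O


def read_fasta_designs(path, alphabet: Alphabet | None = None) -> DesignSet:
    alpha = alphabet or Alphabet()
    fasta = FastaFile.read(path)
    seqs = [alpha.encode(seq) for seq in fasta.values()]
    if not seqs:
        raise ContractError(f"no sequences in {path}")
    return DesignSet(tuple(seqs), {"source": str(path)})


def write_fasta_designs(d: DesignSet, path, headers: Sequence[str] | None = None) -> None:
    fasta = FastaFile()
    for idx, s in enumerate(d.sequences):
        name = headers[idx] if headers is not None else f"design_{idx}"
        fasta[name] = str(s)
    fasta.write(path)


def write_pssm_tsv(pssm: PSSM, path) -> None:
    """L rows x A columns, header row = alphabet symbols."""
    with open(path, "w") as fh:
        fh.write("\t".join(pssm.alphabet.symbols) + "\n")
        for row in pssm.probabilities:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def read_pssm_tsv(path) -> PSSM:
    with open(path) as fh:
        header = fh.readline().split()
        alpha = Alphabet("".join(header))
        rows = [[float(x) for x in line.split()] for line in fh if line.strip()]
    return PSSM(np.asarray(rows), alpha)
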