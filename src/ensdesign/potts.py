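"""Potts sequence models: energy, exact distributions, averaging, gauge.

A Potts model over length-``L`` sequences assigns each sequence ``S`` the
energy

    E(S) = sum_i h[i, s_i] + sum_{i<j in edges} J[{i,j}][s_i, s_j]

and the Boltzmann probability ``p(S) = exp(-E(S)) / Z``.  Fields ``h`` score
individual residue identities per site; couplings ``J`` score residue pairs
on an explicit edge set (models derived from k-NN structure graphs are
sparse).  Energies are dimensionless (units of kT at the sampling
temperature).

Ensemble conditioning rests on the linearity of ``E`` in ``(h, J)``:
averaging parameters across conformers averages energies, which makes the
averaged Boltzmann distribution the renormalized geometric mean
(product-of-experts) of the per-conformer distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CANONICAL_AMINO_ACIDS",
    "Alphabet",
    "SequenceState",
    "PottsModel",
    "ExactDistribution",
    "energy",
    "site_substitution_energies",
    "average_models",
    "enumerate_distribution",
    "apply_zero_sum_gauge",
    "load_potts_json",
    "save_potts_json",
]

#: Canonical one-letter amino-acid order used throughout the package.
CANONICAL_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

POTTS_JSON_VERSION = "1"


class ContractError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet with a bijective index <-> symbol mapping."""

    symbols: str = CANONICAL_AMINO_ACIDS

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ContractError("alphabet symbols must be unique")
        if len(self.symbols) < 2:
            raise ContractError("alphabet needs at least 2 symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        i = self.symbols.find(symbol)
        if i < 0:
            raise ContractError(f"symbol {symbol!r} not in alphabet")
        return i

    def encode(self, seq: str) -> "SequenceState":
        return SequenceState(
            residues=np.array([self.index(c) for c in seq], dtype=np.int64),
            alphabet=self,
        )

    def decode(self, indices: np.ndarray) -> str:
        return "".join(self.symbols[int(i)] for i in indices)


@dataclass(frozen=True)
class SequenceState:
    """A length-L sequence of alphabet indices."""

    residues: np.ndarray
    alphabet: Alphabet

    def __post_init__(self) -> None:
        r = np.asarray(self.residues, dtype=np.int64)
        object.__setattr__(self, "residues", r)
        if r.ndim != 1 or r.size < 1:
            raise ContractError("residues must be a nonempty 1-D index array")
        if r.min(initial=0) < 0 or r.max(initial=0) >= self.alphabet.size:
            raise ContractError("residue index out of alphabet range")

    def __len__(self) -> int:
        return int(self.residues.size)

    def __str__(self) -> str:
        return self.alphabet.decode(self.residues)

    def with_site(self, site: int, a: int) -> "SequenceState":
        r = self.residues.copy()
        r[site] = a
        return SequenceState(r, self.alphabet)


class PottsModel:
    """Fields ``h`` (L x A) plus per-edge A x A coupling blocks.

    One block is stored per unordered pair ``{i, j}`` with ``i < j``; axis 0
    of the block indexes the residue at the smaller site index.  The
    :meth:`coupling` accessor transposes transparently for ``(j, i)``
    queries, so callers never double-count.
    """

    def __init__(
        self,
        h: np.ndarray,
        couplings: Mapping[tuple[int, int], np.ndarray] | None = None,
        alphabet: Alphabet | None = None,
    ) -> None:
        h = np.asarray(h, dtype=np.float64)
        if h.ndim != 2:
            raise ContractError("h must be an L x A matrix")
        self.h = h
        self.L, self.A = h.shape
        self.alphabet = alphabet if alphabet is not None else _default_alphabet(self.A)
        if self.alphabet.size != self.A:
            raise ContractError("alphabet size does not match h columns")
        self.couplings: dict[tuple[int, int], np.ndarray] = {}
        for (i, j), block in (couplings or {}).items():
            i, j = int(i), int(j)
            if not (0 <= i < j < self.L):
                raise ContractError(f"invalid edge ({i}, {j}) for L={self.L}")
            if (i, j) in self.couplings:
                raise ContractError(f"duplicate edge ({i}, {j})")
            block = np.asarray(block, dtype=np.float64)
            if block.shape != (self.A, self.A):
                raise ContractError(f"coupling block for ({i}, {j}) must be A x A")
            self.couplings[(i, j)] = block
        if not np.all(np.isfinite(self.h)):
            raise ContractError("h contains non-finite values")
        for block in self.couplings.values():
            if not np.all(np.isfinite(block)):
                raise ContractError("J contains non-finite values")
        self._neighbors: dict[int, list[tuple[int, np.ndarray]]] | None = None

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.couplings)

    def coupling(self, i: int, j: int) -> np.ndarray:
        """Coupling block oriented as (residue at i, residue at j)."""
        if i < j:
            return self.couplings[(i, j)]
        return self.couplings[(j, i)].T

    def neighbors(self, site: int) -> list[tuple[int, np.ndarray]]:
        """(other site, block oriented (site, other)) pairs; cached."""
        if self._neighbors is None:
            nb: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(self.L)}
            for (i, j), block in self.couplings.items():
                nb[i].append((j, block))
                nb[j].append((i, block.T))
            self._neighbors = nb
        return self._neighbors[site]

    def dense_couplings(self) -> np.ndarray:
        """L x L x A x A symmetric tensor (zeros off the edge set).

        Convenience for vectorized samplers at modest L; the sparse per-edge
        mapping remains the canonical storage.
        """
        J = np.zeros((self.L, self.L, self.A, self.A))
        for (i, j), block in self.couplings.items():
            J[i, j] = block
            J[j, i] = block.T
        return J

    def copy(self) -> "PottsModel":
        return PottsModel(
            self.h.copy(),
            {e: b.copy() for e, b in self.couplings.items()},
            self.alphabet,
        )

    def _check_seq(self, seq: SequenceState) -> None:
        if len(seq) != self.L:
            raise ContractError(f"sequence length {len(seq)} != model L {self.L}")
        if seq.alphabet.symbols != self.alphabet.symbols:
            raise ContractError("sequence alphabet does not match model alphabet")


def _default_alphabet(A: int) -> Alphabet:
    if A == 20:
        return Alphabet()
    return Alphabet(CANONICAL_AMINO_ACIDS[:A])


def energy(model: PottsModel, seq: SequenceState) -> float:
    """Potts energy E(S) = sum_i h[i, s_i] + sum_{edges} J[{i,j}][s_i, s_j]."""
    model._check_seq(seq)
    s = seq.residues
    e = float(model.h[np.arange(model.L), s].sum())
    for (i, j), block in model.couplings.items():
        e += float(block[s[i], s[j]])
    return e


def site_substitution_energies(
    model: PottsModel, seq: SequenceState, site: int
) -> np.ndarray:
    """Length-A vector: entry ``a`` is the full energy with ``site`` set to ``a``.

    Computed locally in O(A * degree(site)); entry at the current residue
    equals ``energy(model, seq)``.
    """
    model._check_seq(seq)
    if not 0 <= site < model.L:
        raise ContractError(f"site {site} out of range for L={model.L}")
    s = seq.residues
    local = model.h[site].copy()
    for j, block in model.neighbors(site):
        local += block[:, s[j]]
    # energy of the rest of the sequence, independent of the residue at `site`
    rest = energy(model, seq) - local[s[site]]
    return rest + local


def local_fields(model: PottsModel, seq: SequenceState) -> np.ndarray:
    """L x A matrix of conditional energies: row i is h[i] + sum_j J_ij[:, s_j].

    Row ``i`` differs from ``site_substitution_energies`` by a constant
    (the energy of the remainder), so softmax(-row/T) gives the full
    conditional at site ``i`` directly.
    """
    model._check_seq(seq)
    s = seq.residues
    out = model.h.copy()
    for (i, j), block in model.couplings.items():
        out[i] += block[:, s[j]]
        out[j] += block[s[i], :]
    return out


def average_models(
    models: Sequence[PottsModel], weights: Sequence[float] | None = None
) -> PottsModel:
    """Weighted mean of fields and couplings across an ensemble of models.

    The edge set of the result is the union of the inputs' edge sets with
    absent couplings treated as zero, so for every sequence S the averaged
    energy equals the weighted mean of per-model energies exactly (E is
    linear in its parameters).  Default weights are uniform 1/K.
    """
    if len(models) == 0:
        raise ContractError("average_models needs at least one model")
    L, alpha = models[0].L, models[0].alphabet
    for m in models[1:]:
        if m.L != L or m.alphabet.symbols != alpha.symbols:
            raise ContractError("models must share L and alphabet")
    K = len(models)
    if weights is None:
        w = np.full(K, 1.0 / K)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (K,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ContractError("weights must be a nonnegative simplex vector")
    h = sum(wk * m.h for wk, m in zip(w, models))
    union: dict[tuple[int, int], np.ndarray] = {}
    for wk, m in zip(w, models):
        for e, block in m.couplings.items():
            if e in union:
                union[e] = union[e] + wk * block
            else:
                union[e] = wk * block
    return PottsModel(h, union, alpha)


def _all_sequences(L: int, A: int) -> np.ndarray:
    """All A^L index sequences in lexicographic order, shape (A^L, L)."""
    grids = np.meshgrid(*[np.arange(A)] * L, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _all_energies(model: PottsModel) -> np.ndarray:
    seqs = _all_sequences(model.L, model.A)
    e = model.h[np.arange(model.L), seqs].sum(axis=1)
    for (i, j), block in model.couplings.items():
        e += block[seqs[:, i], seqs[:, j]]
    return e


@dataclass(frozen=True)
class ExactDistribution:
    """Brute-force Boltzmann distribution over all A^L sequences."""

    model: PottsModel
    log_z: float
    probabilities: np.ndarray  # lexicographic over sequences
    log_probabilities: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def sequences(self) -> np.ndarray:
        return _all_sequences(self.model.L, self.model.A)

    def marginal(self, site: int) -> np.ndarray:
        seqs = self.sequences()
        out = np.zeros(self.model.A)
        np.add.at(out, seqs[:, site], self.probabilities)
        return out


DEFAULT_ENUMERATION_CAP = 10**6


def enumerate_distribution(
    model: PottsModel, cap: int = DEFAULT_ENUMERATION_CAP
) -> ExactDistribution:
    """Exact p(S) = exp(-E(S))/Z by enumeration, in log domain.

    Refuses when A^L exceeds ``cap`` (default 10^6 states).
    """
    n_states = model.A**model.L
    if n_states > cap:
        raise ContractError(
            f"A^L = {n_states} exceeds the enumeration cap {cap}; "
            "raise `cap` explicitly to force"
        )
    neg_e = -_all_energies(model)
    log_z = float(logsumexp(neg_e))
    logp = neg_e - log_z
    return ExactDistribution(model, log_z, np.exp(logp), logp)


def apply_zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Canonical (h, J) representative with zero-mean coupling rows/columns.

    For each edge block the row means, column means, and grand mean are
    shifted into the fields (and a constant, dropped into the first site's
    field), leaving every sequence probability unchanged.  Fields are then
    centered per site; the per-site constants are discarded, which changes
    logZ but no probability.
    """
    h = model.h.copy()
    new_J: dict[tuple[int, int], np.ndarray] = {}
    A = model.A
    for (i, j), block in model.couplings.items():
        row = block.mean(axis=1, keepdims=True)   # per-residue-at-i mean
        col = block.mean(axis=0, keepdims=True)   # per-residue-at-j mean
        grand = block.mean()
        new_J[(i, j)] = block - row - col + grand
        h[i] += row.ravel() - grand
        h[j] += col.ravel()
    h -= h.mean(axis=1, keepdims=True)
    return PottsModel(h, new_J, model.alphabet)


# ---------------------------------------------------------------------------
# Potts JSON serialization (package-defined, versioned)

def save_potts_json(model: PottsModel, path) -> None:
    """Write the canonical JSON form: version, alphabet, L, h, edges, J."""
    edges = model.edges
    doc = {
        "version": POTTS_JSON_VERSION,
        "alphabet": model.alphabet.symbols,
        "L": model.L,
        "h": model.h.tolist(),
        "edges": [list(e) for e in edges],
        "J": [model.couplings[e].tolist() for e in edges],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_potts_json(path) -> PottsModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != POTTS_JSON_VERSION:
        raise ContractError(f"unsupported Potts JSON version {doc.get('version')!r}")
    alpha = Alphabet(doc["alphabet"])
    h = np.asarray(doc["h"], dtype=np.float64)
    if h.shape[0] != doc["L"]:
        raise ContractError("h row count disagrees with declared L")
    couplings = {
        (int(i), int(j)): np.asarray(block, dtype=np.float64)
        for (i, j), block in zip(doc["edges"], doc["J"])
    }
    return PottsModel(h, couplings, alpha)
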