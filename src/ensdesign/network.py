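"""Toy-scale graph network mapping backbone feature graphs to Potts models.

The network follows the MPNN encoder/decoder pattern: encoder layers pass
messages over the k-NN residue graph and update node states; decoder
layers additionally update edge states, with *no* causal mask, so fields
and couplings for every site are produced in a single forward pass.
Sitewise fields come from a linear projection of final node embeddings;
each undirected coupling block comes from a transpose-symmetrized linear
projection of the two directed edge embeddings.

Training minimizes the sequence pseudolikelihood of the predicted Potts
model.  The message-passing trunk is a deterministic random featurizer
(fixed by the init seed); only the field/coupling projection heads are
trained, which makes the objective convex in the trainable parameters and
keeps optimization fast and reliable at desk scale.  Gradients are
analytic: the pseudolikelihood gradient in (h, J) is the standard
``indicator - conditional`` residual, chained through the linear heads.

Exact likelihood is intractable for Potts models; pseudolikelihood (the
product of per-site full conditionals) is the standard consistent
surrogate and is what the decoder's non-causal, single-pass design
supports directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .potts import (
    Alphabet,
    ContractError,
    PottsModel,
    SequenceState,
    average_models,
    local_fields,
)
from .structure import FeatureGraph, FeaturizerConfig, StructureEnsemble, featurize

__all__ = [
    "NetworkConfig",
    "NetworkParams",
    "TrainConfig",
    "init_network",
    "predict_potts",
    "pseudolikelihood_loss",
    "train",
    "design_for_ensemble",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = "1"

D_NODE = 6  # sin/cos of phi, psi, omega


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults: 3 encoder + 3 decoder message-passing layers, hidden width
    128.  The ``large`` preset deepens to 5 + 5 layers at width 256.  The
    decoder never applies a causal mask (``causal_mask`` must stay off):
    every site's terms are predicted jointly in one pass.
    """

    n_encoder_layers: int = 3
    n_decoder_layers: int = 3
    hidden_dim: int = 128
    alphabet: Alphabet = field(default_factory=Alphabet)
    causal_mask: bool = False
    rbf_count: int = 16

    def __post_init__(self) -> None:
        if min(self.n_encoder_layers, self.n_decoder_layers, self.hidden_dim) < 1:
            raise ContractError("layer counts and hidden_dim must be positive")
        if self.causal_mask:
            raise ContractError("the decoder is non-causal; causal_mask must be off")

    @classmethod
    def large(cls, **kwargs) -> "NetworkConfig":
        return cls(n_encoder_layers=5, n_decoder_layers=5, hidden_dim=256, **kwargs)

    @property
    def d_edge(self) -> int:
        return 16 * self.rbf_count + 2


@dataclass
class NetworkParams:
    """Serializable parameter collection plus config echo and init seed.

    ``trunk`` holds the fixed message-passing weights; ``heads`` holds the
    trainable field/coupling projections.  ``forward_pass_count`` is an
    instrumented counter incremented once per network evaluation.
    """

    config: NetworkConfig
    seed: int
    trunk: dict[str, np.ndarray]
    heads: dict[str, np.ndarray]
    forward_pass_count: int = 0

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.config,
            self.seed,
            {k: v.copy() for k, v in self.trunk.items()},
            {k: v.copy() for k, v in self.heads.items()},
            self.forward_pass_count,
        )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.05
    epochs: int = 150
    batch_size: int = 0  # 0 = full batch
    seed: int = 0
    weight_decay: float = 1e-4
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ContractError("learning_rate and epochs must be positive")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ContractError("validation_fraction must be in [0, 1)")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))


def init_network(cfg: NetworkConfig, seed: int = 0) -> NetworkParams:
    """Deterministic parameter initialization from ``seed``."""
    rng = np.random.default_rng(seed)
    H = cfg.hidden_dim
    trunk: dict[str, np.ndarray] = {
        "node_in": _glorot(rng, D_NODE, H),
        "edge_in": _glorot(rng, cfg.d_edge, H),
    }
    for l in range(cfg.n_encoder_layers):
        trunk[f"enc{l}_msg"] = _glorot(rng, 3 * H, H)
        trunk[f"enc{l}_upd"] = _glorot(rng, 2 * H, H)
    for l in range(cfg.n_decoder_layers):
        trunk[f"dec{l}_msg"] = _glorot(rng, 3 * H, H)
        trunk[f"dec{l}_upd"] = _glorot(rng, 2 * H, H)
        trunk[f"dec{l}_edge"] = _glorot(rng, 3 * H, H)
    A = cfg.alphabet.size
    heads = {
        "W_h": rng.normal(0.0, 1e-2, size=(H, A)),
        "b_h": np.zeros(A),
        "W_j": rng.normal(0.0, 1e-2, size=(H, A * A)),
        "b_j": np.zeros(A * A),
    }
    return NetworkParams(cfg, seed, trunk, heads)


# ---------------------------------------------------------------------------
# Forward trunk (fixed weights)


def _embed(params: NetworkParams, g: FeatureGraph):
    """Run message passing; return node embeddings and directed edge embeddings.

    Returns ``(node_emb (L, H), edge_emb (L, k, H))`` where ``edge_emb[i, n]``
    belongs to the directed edge i -> neighbor_idx[i, n].
    """
    cfg = params.config
    t = params.trunk
    nbr = g.neighbor_idx
    if g.node_features.shape[1] != D_NODE or g.edge_features.shape[2] != cfg.d_edge:
        raise ContractError("feature graph dimensions do not match network config")
    hN = np.tanh(g.node_features @ t["node_in"])
    hE = np.tanh(g.edge_features @ t["edge_in"])

    def node_update(hN, hE, wm, wu):
        cat = np.concatenate(
            [np.broadcast_to(hN[:, None, :], hE.shape), hN[nbr], hE], axis=-1
        )
        msg = np.tanh(cat @ wm).mean(axis=1)
        return np.tanh(np.concatenate([hN, msg], axis=-1) @ wu)

    for l in range(cfg.n_encoder_layers):
        hN = node_update(hN, hE, t[f"enc{l}_msg"], t[f"enc{l}_upd"])
    for l in range(cfg.n_decoder_layers):
        hN = node_update(hN, hE, t[f"dec{l}_msg"], t[f"dec{l}_upd"])
        cat = np.concatenate(
            [np.broadcast_to(hN[:, None, :], hE.shape), hN[nbr], hE], axis=-1
        )
        hE = np.tanh(cat @ t[f"dec{l}_edge"])
    return hN, hE


def _undirected_edges(g: FeatureGraph) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Map unordered edge {i<j} -> directed occurrences as (row, col) into edge_emb."""
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    nbr = g.neighbor_idx
    for i in range(g.L):
        for n in range(g.k):
            j = int(nbr[i, n])
            key = (i, j) if i < j else (j, i)
            edges.setdefault(key, []).append((i, n))
    return edges


def _heads_to_potts(params: NetworkParams, node_emb, edge_emb, edges) -> PottsModel:
    cfg = params.config
    A = cfg.alphabet.size
    h = node_emb @ params.heads["W_h"] + params.heads["b_h"]
    b_j = params.heads["b_j"].reshape(A, A)
    b_sym = 0.5 * (b_j + b_j.T)
    couplings = {}
    for (i, j), dirs in edges.items():
        block = np.zeros((A, A))
        for row, col in dirs:
            proj = (edge_emb[row, col] @ params.heads["W_j"]).reshape(A, A)
            # orient axis 0 to the smaller site index
            block += proj if row == i else proj.T
        couplings[(i, j)] = block / len(dirs) + b_sym
    return PottsModel(h, couplings, cfg.alphabet)


def predict_potts(params: NetworkParams, g: FeatureGraph) -> PottsModel:
    """Single forward pass: feature graph -> Potts model.

    Fields from the node-embedding projection; one coupling block per
    undirected graph edge from the transpose-symmetrized average of the
    directed edge-embedding projections.  Increments the instrumented
    ``forward_pass_count``.
    """
    node_emb, edge_emb = _embed(params, g)
    params.forward_pass_count += 1
    return _heads_to_potts(params, node_emb, edge_emb, _undirected_edges(g))


def pseudolikelihood_loss(model: PottsModel, seq: SequenceState) -> float:
    """Mean negative log full-conditional: -(1/L) sum_i log p(s_i | s_-i)."""
    rows = local_fields(model, seq)  # (L, A) conditional energies
    neg = -rows
    neg -= neg.max(axis=1, keepdims=True)
    logp = neg - np.log(np.exp(neg).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(model.L), seq.residues].mean())


# ---------------------------------------------------------------------------
# Training (analytic gradients through the linear heads)


class _GraphBatch:
    """Embeddings and edge indexing for one graph plus its paired sequences.

    Items sharing a feature graph object are batched so every per-epoch
    quantity is a handful of vectorized array operations.
    """

    def __init__(self, params: NetworkParams, g: FeatureGraph):
        self.node_emb, edge_emb = _embed(params, g)
        params.forward_pass_count += 1
        edges = _undirected_edges(g)
        keys = sorted(edges)
        self.ia = np.array([i for i, _ in keys], dtype=np.int64)
        self.ja = np.array([j for _, j in keys], dtype=np.int64)
        flat = edge_emb.reshape(-1, edge_emb.shape[-1])
        dir_rows, dir_edge, dir_fwd, share = [], [], [], []
        for e, key in enumerate(keys):
            dirs = edges[key]
            share.append(1.0 / len(dirs))
            for row, col in dirs:
                dir_rows.append(row * g.k + col)
                dir_edge.append(e)
                dir_fwd.append(row == key[0])
        self.E = len(keys)
        self.emb_dir = flat[np.array(dir_rows, dtype=np.int64)]
        self.dir_edge = np.array(dir_edge, dtype=np.int64)
        self.dir_fwd = np.array(dir_fwd, dtype=bool)
        self.share = np.array(share)
        self.seqs = np.empty((0, g.L), dtype=np.int64)

    def add_sequence(self, seq: SequenceState) -> None:
        self.seqs = np.vstack([self.seqs, seq.residues[None, :]])

    def blocks(self, heads: dict[str, np.ndarray], A: int) -> np.ndarray:
        """(E, A, A) coupling blocks from the current heads."""
        proj = (self.emb_dir @ heads["W_j"]).reshape(-1, A, A)
        proj = np.where(self.dir_fwd[:, None, None], proj, proj.transpose(0, 2, 1))
        blocks = np.zeros((self.E, A, A))
        np.add.at(blocks, self.dir_edge, proj)
        blocks *= self.share[:, None, None]
        b_j = heads["b_j"].reshape(A, A)
        return blocks + 0.5 * (b_j + b_j.T)

    def loss_and_grads(self, heads, A, grads) -> float:
        """Summed (over sequences) PLL loss; accumulates head gradients."""
        S = self.seqs
        n, L = S.shape
        ia, ja = self.ia, self.ja
        oh = np.eye(A)[S]  # (n, L, A)
        blocks = self.blocks(heads, A)
        rows = np.tile(self.node_emb @ heads["W_h"] + heads["b_h"], (n, 1, 1))
        n_idx = np.arange(n)[:, None]
        np.add.at(rows, (n_idx, ia[None, :]),
                  np.einsum("eab,neb->nea", blocks, oh[:, ja]))
        np.add.at(rows, (n_idx, ja[None, :]),
                  np.einsum("eba,neb->nea", blocks, oh[:, ia]))
        neg = -rows
        neg -= neg.max(axis=-1, keepdims=True)
        q = np.exp(neg)
        q /= q.sum(axis=-1, keepdims=True)
        loss = float(
            -np.log(q[n_idx, np.arange(L)[None, :], S] + 1e-300).sum() / L
        )
        g = (oh - q) / L  # d(summed loss)/d rows
        grads["W_h"] += self.node_emb.T @ g.sum(axis=0)
        grads["b_h"] += g.sum(axis=(0, 1))
        gj = np.einsum("nea,neb->eab", g[:, ia], oh[:, ja])
        gj += np.einsum("nea,neb->eba", g[:, ja], oh[:, ia])
        grads["b_j"] += 0.5 * (gj + gj.transpose(0, 2, 1)).sum(axis=0).ravel()
        gj *= self.share[:, None, None]
        g_dir = np.where(
            self.dir_fwd[:, None, None],
            gj[self.dir_edge],
            gj[self.dir_edge].transpose(0, 2, 1),
        )
        grads["W_j"] += self.emb_dir.T @ g_dir.reshape(len(g_dir), A * A)
        return loss


def train(
    params: NetworkParams,
    dataset: Sequence[tuple[FeatureGraph, SequenceState]],
    cfg: TrainConfig,
) -> tuple[NetworkParams, list[float]]:
    """Fit the projection heads by full-batch Adam on mean pseudolikelihood.

    Trunk embeddings are computed once per structure (items sharing a
    graph object are batched); each epoch then costs only the linear-head
    forward/backward, with analytic gradients.  Returns updated params and
    the per-epoch loss history.  Raises on an empty dataset or non-finite
    loss.
    """
    if len(dataset) == 0:
        raise ContractError("training dataset is empty")
    params = params.copy()
    A = params.config.alphabet.size
    batches: dict[int, _GraphBatch] = {}
    for g, seq in dataset:
        if id(g) not in batches:
            batches[id(g)] = _GraphBatch(params, g)
        batches[id(g)].add_sequence(seq)
    batch_list = list(batches.values())

    heads = params.heads
    m = {k: np.zeros_like(v) for k, v in heads.items()}
    v = {k: np.zeros_like(vv) for k, vv in heads.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    n = len(dataset)
    history: list[float] = []
    for step in range(1, cfg.epochs + 1):
        grads = {k: np.zeros_like(vv) for k, vv in heads.items()}
        total = sum(b.loss_and_grads(heads, A, grads) for b in batch_list) / n
        if not np.isfinite(total):
            raise FloatingPointError("pseudolikelihood loss became non-finite")
        history.append(total)
        for k in heads:
            gk = grads[k] / n
            if k.startswith("W_"):
                gk = gk + cfg.weight_decay * heads[k]
            m[k] = b1 * m[k] + (1 - b1) * gk
            v[k] = b2 * v[k] + (1 - b2) * gk**2
            mhat = m[k] / (1 - b1**step)
            vhat = v[k] / (1 - b2**step)
            heads[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
    return params, history


def design_for_ensemble(
    params: NetworkParams,
    ensemble: StructureEnsemble,
    fcfg: FeaturizerConfig,
) -> tuple[PottsModel, int]:
    """Per-conformer Potts prediction followed by uniform parameter averaging.

    Exactly one forward pass per ensemble member (K total); the returned
    count is independent of how many sequences are later sampled from the
    averaged model, which is what makes ensemble conditioning cheap.
    """
    before = params.forward_pass_count
    models = [predict_potts(params, featurize(s, fcfg)) for s in ensemble.members()]
    n_passes = params.forward_pass_count - before
    return average_models(models), n_passes


# ---------------------------------------------------------------------------
# Checkpoints (versioned JSON; exact float round-trip)


def save_checkpoint(params: NetworkParams, path) -> None:
    cfg = params.config
    doc = {
        "version": CHECKPOINT_VERSION,
        "config": {
            "n_encoder_layers": cfg.n_encoder_layers,
            "n_decoder_layers": cfg.n_decoder_layers,
            "hidden_dim": cfg.hidden_dim,
            "alphabet": cfg.alphabet.symbols,
            "rbf_count": cfg.rbf_count,
        },
        "seed": params.seed,
        "trunk": {k: {"shape": list(v.shape), "data": v.ravel().tolist()}
                  for k, v in params.trunk.items()},
        "heads": {k: {"shape": list(v.shape), "data": v.ravel().tolist()}
                  for k, v in params.heads.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path) -> NetworkParams:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != CHECKPOINT_VERSION:
        raise ContractError(f"unsupported checkpoint version {doc.get('version')!r}")
    c = doc["config"]
    cfg = NetworkConfig(
        n_encoder_layers=c["n_encoder_layers"],
        n_decoder_layers=c["n_decoder_layers"],
        hidden_dim=c["hidden_dim"],
        alphabet=Alphabet(c["alphabet"]),
        rbf_count=c["rbf_count"],
    )
    def arrs(d):
        return {k: np.array(v["data"]).reshape(v["shape"]) for k, v in d.items()}
    return NetworkParams(cfg, doc["seed"], arrs(doc["trunk"]), arrs(doc["heads"]))
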