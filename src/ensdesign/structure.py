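"""Backbone structure handling: PDB I/O, superposition, ensembles, features.

A :class:`BackboneStructure` holds the four backbone heavy atoms
(N, CA, C, O) per residue in angstroms.  Conformational ensembles pair a
reference backbone with K-1 conformers of identical residue topology; a
cheap ensemble source is i.i.d. Gaussian coordinate noise
(:func:`gaussian_ensemble`).  :func:`featurize` builds the k-nearest-
neighbour residue graph with rigid-motion-invariant node features
(backbone dihedral sines/cosines) and edge features (radial-basis-encoded
backbone atom-pair distances plus sequence-separation terms) consumed by
the Potts prediction network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .potts import ContractError

__all__ = [
    "BackboneStructure",
    "StructureEnsemble",
    "FeaturizerConfig",
    "FeatureGraph",
    "read_backbone_pdb",
    "write_backbone_pdb",
    "kabsch_superpose",
    "kabsch_rmsd",
    "gaussian_ensemble",
    "ensemble_diversity",
    "featurize",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class BackboneStructure:
    """Per-residue backbone records with N/CA/C/O coordinates in angstroms."""

    chain_ids: np.ndarray  # (L,) str
    res_ids: np.ndarray  # (L,) int, PDB numbering
    ins_codes: np.ndarray  # (L,) str
    res_names: np.ndarray  # (L,) str, three-letter
    coords: np.ndarray  # (L, 4, 3) float, atom order = BACKBONE_ATOMS

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        object.__setattr__(self, "coords", c)
        if c.ndim != 3 or c.shape[1:] != (4, 3) or c.shape[0] < 1:
            raise ContractError("coords must have shape (L, 4, 3)")
        if not np.all(np.isfinite(c)):
            raise ContractError("coordinates must be finite")

    @property
    def L(self) -> int:
        return int(self.coords.shape[0])

    def __len__(self) -> int:
        return self.L

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, 1, :]

    def with_coords(self, coords: np.ndarray) -> "BackboneStructure":
        return BackboneStructure(
            self.chain_ids, self.res_ids, self.ins_codes, self.res_names, coords
        )

    def same_topology(self, other: "BackboneStructure") -> bool:
        return (
            self.L == other.L
            and np.array_equal(self.chain_ids, other.chain_ids)
            and np.array_equal(self.res_ids, other.res_ids)
            and np.array_equal(self.res_names, other.res_names)
        )


@dataclass(frozen=True)
class StructureEnsemble:
    """A reference backbone plus K-1 conformers of identical topology."""

    reference: BackboneStructure
    conformers: tuple[BackboneStructure, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "conformers", tuple(self.conformers))
        for c in self.conformers:
            if not self.reference.same_topology(c):
                raise ContractError("ensemble members must share residue topology")

    @property
    def K(self) -> int:
        return 1 + len(self.conformers)

    def members(self) -> list[BackboneStructure]:
        return [self.reference, *self.conformers]


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)


def _from_atom_array(atoms, gap_policy: str) -> BackboneStructure:
    atoms = atoms[np.isin(atoms.atom_name, BACKBONE_ATOMS)]
    atoms = atoms[~atoms.hetero]
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    recs = []
    for lo, hi in zip(starts[:-1], starts[1:]):
        res = atoms[lo:hi]
        names = list(res.atom_name)
        if any(a not in names for a in BACKBONE_ATOMS):
            label = f"{res.chain_id[0]}:{res.res_name[0]}{res.res_id[0]}"
            if gap_policy == "reject":
                missing = [a for a in BACKBONE_ATOMS if a not in names]
                raise ContractError(
                    f"residue {label} is missing backbone atoms {missing}"
                )
            elif gap_policy == "drop":
                continue
            else:
                raise ContractError(f"unknown gap policy {gap_policy!r}")
        # PDB stores 3 decimals; rounding undoes the float32 parse error
        xyz = np.round(
            np.stack([res.coord[names.index(a)] for a in BACKBONE_ATOMS]).astype(
                np.float64
            ),
            3,
        )
        ins = res.ins_code[0] if "ins_code" in res.get_annotation_categories() else ""
        recs.append((res.chain_id[0], int(res.res_id[0]), ins, res.res_name[0], xyz))
    if not recs:
        raise ContractError("no complete backbone residues found")
    return BackboneStructure(
        chain_ids=np.array([r[0] for r in recs]),
        res_ids=np.array([r[1] for r in recs], dtype=np.int64),
        ins_codes=np.array([r[2] for r in recs]),
        res_names=np.array([r[3] for r in recs]),
        coords=np.stack([r[4] for r in recs]).astype(np.float64),
    )


def read_backbone_pdb(path, gap_policy: str = "reject") -> list[BackboneStructure]:
    """Read backbone structures from a PDB file; one entry per MODEL record.

    Residues missing any of N/CA/C/O raise an error naming the residue
    under the default ``reject`` policy, or are silently omitted under
    ``drop``.
    """
    pdb = PDBFile.read(path)
    n_models = pdb.get_model_count()
    out = []
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m, extra_fields=["b_factor"])
        out.append(_from_atom_array(atoms, gap_policy))
    return out


def write_backbone_pdb(
    structures: BackboneStructure | Sequence[BackboneStructure], path
) -> None:
    """Write one or more backbone structures as a (multi-model) PDB file."""
    if isinstance(structures, BackboneStructure):
        structures = [structures]
    ref = structures[0]
    arrays = []
    for s in structures:
        if not ref.same_topology(s):
            raise ContractError("all models must share residue topology")
        n = 4 * s.L
        arr = struc.AtomArray(n)
        arr.coord = s.coords.reshape(n, 3)
        arr.chain_id = np.repeat(s.chain_ids, 4)
        arr.res_id = np.repeat(s.res_ids, 4)
        arr.ins_code = np.repeat(s.ins_codes, 4)
        arr.res_name = np.repeat(s.res_names, 4)
        arr.atom_name = np.tile(np.array(BACKBONE_ATOMS), s.L)
        arr.element = np.tile(np.array(["N", "C", "C", "O"]), s.L)
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(struc.stack(arrays))
    pdb.write(path)


# ---------------------------------------------------------------------------
# Superposition and ensembles

_ATOM_INDEX = {a: i for i, a in enumerate(BACKBONE_ATOMS)}


def _atom_coords(s: BackboneStructure, atoms: Sequence[str]) -> np.ndarray:
    idx = [_ATOM_INDEX[a] for a in atoms]
    return s.coords[:, idx, :].reshape(-1, 3)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of point set P onto Q.

    Returns (R, t) with ``P @ R.T + t`` optimally aligned to Q; R is a
    proper rotation (reflections excluded via the sign of det).
    """
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    return R, t


def kabsch_rmsd(
    a: BackboneStructure,
    b: BackboneStructure,
    superpose: bool = True,
    atoms: Sequence[str] = ("CA",),
    return_transform: bool = False,
):
    """RMSD between two equal-topology backbones over the given atom set.

    With ``superpose`` the optimal proper rotation/translation is applied
    first; without it the raw coordinate RMSD is returned.
    """
    if a.L != b.L:
        raise ContractError("structures must have equal length")
    P, Q = _atom_coords(a, atoms), _atom_coords(b, atoms)
    if superpose:
        R, t = kabsch_superpose(P, Q)
        P = P @ R.T + t
    else:
        R, t = np.eye(3), np.zeros(3)
    rmsd = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
    if return_transform:
        return rmsd, R, t
    return rmsd


def gaussian_ensemble(
    s: BackboneStructure, sigma: float, K: int, seed: int = 0
) -> StructureEnsemble:
    """Ensemble from i.i.d. Gaussian coordinate noise around a backbone.

    Each of the K-1 conformers adds zero-mean noise with standard
    deviation ``sigma`` (angstroms, per coordinate axis, independently per
    atom) to every backbone atom.
    """
    if sigma < 0:
        raise ContractError("sigma must be nonnegative")
    if K < 1:
        raise ContractError("K must be >= 1")
    rng = np.random.default_rng(seed)
    conformers = [
        s.with_coords(s.coords + rng.normal(0.0, sigma, size=s.coords.shape))
        for _ in range(K - 1)
    ]
    return StructureEnsemble(s, tuple(conformers))


def ensemble_diversity(e: StructureEnsemble) -> float:
    """Mean superposed CA RMSD (angstroms) of conformers to the reference."""
    if e.K < 2:
        raise ContractError("ensemble diversity needs K >= 2")
    return float(
        np.mean([kabsch_rmsd(c, e.reference, superpose=True) for c in e.conformers])
    )


# ---------------------------------------------------------------------------
# Featurization


@dataclass(frozen=True)
class FeaturizerConfig:
    k_neighbors: int = 30
    rbf_count: int = 16
    rbf_min: float = 2.0  # angstrom
    rbf_max: float = 22.0  # angstrom
    include_sidechain_distances: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors < 1 or self.rbf_count < 1:
            raise ContractError("k_neighbors and rbf_count must be positive")
        if not self.rbf_min < self.rbf_max:
            raise ContractError("rbf_min must be < rbf_max")


@dataclass(frozen=True)
class FeatureGraph:
    """k-NN residue graph with node and edge feature tensors."""

    neighbor_idx: np.ndarray  # (L, k) int
    node_features: np.ndarray  # (L, d_node)
    edge_features: np.ndarray  # (L, k, d_edge)

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.node_features)) and np.all(np.isfinite(self.edge_features))):
            raise ContractError("features must be finite")
        L = self.neighbor_idx.shape[0]
        if np.any(self.neighbor_idx == np.arange(L)[:, None]):
            raise ContractError("neighbor table must exclude self")

    @property
    def L(self) -> int:
        return int(self.neighbor_idx.shape[0])

    @property
    def k(self) -> int:
        return int(self.neighbor_idx.shape[1])


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral angle(s) in radians for stacked coordinate rows."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x)


def backbone_dihedrals(s: BackboneStructure) -> np.ndarray:
    """(L, 3) phi/psi/omega in radians; zero where undefined (termini, chain breaks)."""
    N, CA, C = s.coords[:, 0], s.coords[:, 1], s.coords[:, 2]
    out = np.zeros((s.L, 3))
    if s.L < 2:
        return out
    same = s.chain_ids[:-1] == s.chain_ids[1:]
    phi = _dihedral(C[:-1], N[1:], CA[1:], C[1:])
    psi = _dihedral(N[:-1], CA[:-1], C[:-1], N[1:])
    omega = _dihedral(CA[:-1], C[:-1], N[1:], CA[1:])
    out[1:, 0] = np.where(same, phi, 0.0)
    out[:-1, 1] = np.where(same, psi, 0.0)
    out[1:, 2] = np.where(same, omega, 0.0)
    return out


def rbf_encode(d: np.ndarray, cfg: FeaturizerConfig) -> np.ndarray:
    """Gaussian RBF encoding of distances; width equals the center spacing."""
    centers = np.linspace(cfg.rbf_min, cfg.rbf_max, cfg.rbf_count)
    width = centers[1] - centers[0] if cfg.rbf_count > 1 else (cfg.rbf_max - cfg.rbf_min)
    z = (d[..., None] - centers) / width
    return np.exp(-(z**2))


MAX_SEQ_SEPARATION = 32


def featurize(
    s: BackboneStructure,
    cfg: FeaturizerConfig,
    sidechain_coords: np.ndarray | None = None,
) -> FeatureGraph:
    """k-NN graph on CA-CA distances with invariant node/edge features.

    Node features: sines and cosines of phi/psi/omega (6 per residue).
    Edge features per neighbour: RBF encodings of the 16 backbone
    atom-pair distances (N/CA/C/O x N/CA/C/O), the clipped signed
    sequence separation scaled to [-1, 1], and a same-chain flag.  When
    ``cfg.include_sidechain_distances`` is on and per-residue sidechain
    reference coordinates (L, 3) are supplied as context, an RBF channel
    of their pairwise distances is appended.
    """
    if s.L <= cfg.k_neighbors:
        raise ContractError(
            f"chain length {s.L} must exceed k_neighbors={cfg.k_neighbors}"
        )
    ca = s.ca
    d2 = np.sum((ca[:, None, :] - ca[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    # quantized distances + index tie-break: neighbor order is then stable
    # under rigid motions despite floating-point jitter and exact ties
    order = np.lexsort(
        (np.arange(s.L)[None, :].repeat(s.L, 0), np.round(d2, 6)), axis=1
    )
    nbr = order[:, : cfg.k_neighbors]

    dih = backbone_dihedrals(s)
    node = np.concatenate([np.sin(dih), np.cos(dih)], axis=1)

    # (L, k, 4, 4) pairwise backbone atom distances along each edge
    xi = s.coords[:, None, :, None, :]  # (L, 1, 4, 1, 3)
    xj = s.coords[nbr][:, :, None, :, :]  # (L, k, 1, 4, 3)
    pair_d = np.sqrt(np.sum((xi - xj) ** 2, axis=-1))  # (L, k, 4, 4)
    rbf = rbf_encode(pair_d, cfg).reshape(s.L, cfg.k_neighbors, -1)

    sep = nbr - np.arange(s.L)[:, None]
    sep = np.clip(sep, -MAX_SEQ_SEPARATION, MAX_SEQ_SEPARATION) / MAX_SEQ_SEPARATION
    same_chain = (s.chain_ids[nbr] == s.chain_ids[:, None]).astype(np.float64)
    channels = [rbf, sep[..., None], same_chain[..., None]]
    if cfg.include_sidechain_distances and sidechain_coords is not None:
        sc = np.asarray(sidechain_coords, dtype=np.float64)
        if sc.shape != (s.L, 3):
            raise ContractError("sidechain_coords must have shape (L, 3)")
        sc_d = np.sqrt(np.sum((sc[:, None, :] - sc[nbr]) ** 2, axis=-1))
        channels.append(rbf_encode(sc_d, cfg))
    edge = np.concatenate(channels, axis=-1)
    return FeatureGraph(nbr, node, edge)
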