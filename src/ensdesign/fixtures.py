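"""Deterministic synthetic inputs: toy backbones, random Potts models, and
rule-based structure-to-sequence datasets.

Everything here is a pure function of its spec (seed included): equal
specs yield bit-equal outputs.  The structure-to-sequence rule is a
documented geometric toy — residue choice driven by a burial proxy (CA
neighbour count) and charge complementarity at spatial contacts — designed
so that a small network can partially recover it from backbone geometry
within CPU minutes.  It makes no claim of biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .potts import Alphabet, ContractError, PottsModel, SequenceState
from .structure import BackboneStructure

__all__ = [
    "FixtureSpec",
    "RuleParams",
    "StructureSequenceDataset",
    "make_toy_backbone",
    "make_random_potts",
    "make_structure_sequence_dataset",
]

# Ideal backbone internal coordinates (angstroms / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

PHI_PSI = {"helix": (-60.0, -45.0), "extended": (-135.0, 135.0)}


@dataclass(frozen=True)
class FixtureSpec:
    kind: Literal["helix", "extended", "perturbed"] = "helix"
    length: int = 20
    seed: int = 0
    noise_sigma: float = 0.0  # angstrom, used by kind="perturbed"

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ContractError("toy backbones need length >= 4")
        if self.noise_sigma < 0:
            raise ContractError("noise_sigma must be nonnegative")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: position of atom d given chain a-b-c and internals."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phis: np.ndarray, psis: np.ndarray) -> np.ndarray:
    """(L, 4, 3) N/CA/C/O coordinates from per-residue phi/psi (omega=180)."""
    L = phis.shape[0]
    coords = np.zeros((L, 4, 3))
    # seed the first residue with ideal geometry in a canonical frame
    coords[0, 0] = np.array([0.0, 0.0, 0.0])  # N
    coords[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])  # CA
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )  # C
    for i in range(1, L):
        n = _place_atom(
            coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2],
            BOND_C_N, ANGLE_CA_C_N, psis[i - 1],
        )
        ca = _place_atom(
            coords[i - 1, 1], coords[i - 1, 2], n, BOND_N_CA, ANGLE_C_N_CA, 180.0
        )
        c = _place_atom(coords[i - 1, 2], n, ca, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords[i, 0], coords[i, 1], coords[i, 2] = n, ca, c
    for i in range(L):
        # carbonyl O anti to the next residue's N (psi + 180 about N-CA-C)
        psi = psis[i] if i < L - 1 else PHI_PSI["helix"][1]
        coords[i, 3] = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2],
            BOND_C_O, ANGLE_CA_C_O, psi + 180.0,
        )
    return coords


def _as_structure(coords: np.ndarray) -> BackboneStructure:
    L = coords.shape[0]
    return BackboneStructure(
        chain_ids=np.array(["A"] * L),
        res_ids=np.arange(1, L + 1, dtype=np.int64),
        ins_codes=np.array([""] * L),
        res_names=np.array(["ALA"] * L),
        coords=coords,
    )


def make_toy_backbone(spec: FixtureSpec) -> BackboneStructure:
    """Ideal-geometry toy backbone built from internal coordinates.

    ``helix``: phi/psi = (-60, -45); ``extended``: (-135, 135);
    ``perturbed``: helix plus i.i.d. Gaussian coordinate noise at
    ``noise_sigma``.
    """
    base_kind = "extended" if spec.kind == "extended" else "helix"
    phi, psi = PHI_PSI[base_kind]
    coords = _build_backbone(
        np.full(spec.length, phi), np.full(spec.length, psi)
    )
    if spec.kind == "perturbed":
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    return _as_structure(coords)


def make_random_potts(
    L: int,
    A: int,
    edge_density: float = 0.5,
    field_scale: float = 1.0,
    coupling_scale: float = 1.0,
    seed: int = 0,
) -> PottsModel:
    """Random Potts model: centered Gaussian fields/couplings on a seeded
    random edge subset of round(density * L*(L-1)/2) pairs."""
    if not 0.0 <= edge_density <= 1.0:
        raise ContractError("edge_density must be in [0, 1]")
    if field_scale < 0 or coupling_scale < 0:
        raise ContractError("scales must be nonnegative")
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, field_scale, size=(L, A)) if field_scale > 0 else np.zeros((L, A))
    all_pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    n_edges = int(round(edge_density * len(all_pairs)))
    chosen = rng.choice(len(all_pairs), size=n_edges, replace=False) if n_edges else []
    couplings = {
        all_pairs[int(e)]: rng.normal(0.0, coupling_scale, size=(A, A))
        for e in sorted(chosen)
    }
    return PottsModel(h, couplings)


# ---------------------------------------------------------------------------
# Rule-based structure -> sequence dataset


@dataclass(frozen=True)
class RuleParams:
    """Geometric sequence-assignment rule constants.

    Burial = number of other CA atoms within ``burial_radius``; sites at or
    above ``burial_threshold`` take hydrophobic residues (cycled by burial
    count), exposed sites take charged/polar residues with K<->E
    complementarity at the nearest earlier spatial contact.  Each residue
    is replaced by a uniform random one with probability ``label_noise``.
    """

    burial_radius: float = 10.0  # angstrom
    burial_threshold: int = 7
    contact_radius: float = 9.0  # angstrom, |i - j| > 3
    label_noise: float = 0.05
    buried_letters: str = "LVIFAM"
    exposed_letters: str = "KE"


@dataclass(frozen=True)
class StructureSequenceDataset:
    train: tuple[tuple[BackboneStructure, SequenceState], ...]
    heldout: tuple[tuple[BackboneStructure, SequenceState], ...]
    rule: RuleParams
    seed: int


def _varied_backbone(length: int, rng: np.random.Generator) -> BackboneStructure:
    """Backbone with helix/extended segments from a seeded two-state chain."""
    phis, psis = np.empty(length), np.empty(length)
    state = "helix" if rng.random() < 0.7 else "extended"
    for i in range(length):
        if rng.random() < 0.15:
            state = "extended" if state == "helix" else "helix"
        phi, psi = PHI_PSI[state]
        phis[i] = phi + rng.normal(0.0, 8.0)
        psis[i] = psi + rng.normal(0.0, 8.0)
    return _as_structure(_build_backbone(phis, psis))


def rule_sequence(
    s: BackboneStructure, rule: RuleParams, rng: np.random.Generator
) -> SequenceState:
    """Apply the geometric rule; deterministic given coordinates when
    ``label_noise`` is zero."""
    alpha = Alphabet()
    ca = s.ca
    d = np.sqrt(np.sum((ca[:, None] - ca[None, :]) ** 2, axis=-1))
    np.fill_diagonal(d, np.inf)
    burial = (d < rule.burial_radius).sum(axis=1)
    seq = np.zeros(s.L, dtype=np.int64)
    sep = np.abs(np.arange(s.L)[:, None] - np.arange(s.L)[None, :])
    contact = (d < rule.contact_radius) & (sep > 3)
    exposed_set = {alpha.index(c) for c in rule.exposed_letters}
    for i in range(s.L):
        if burial[i] >= rule.burial_threshold:
            cyc = rule.buried_letters
            letter = cyc[(int(burial[i]) - rule.burial_threshold) % len(cyc)]
        else:
            partners = [j for j in range(i) if contact[i, j] and int(seq[j]) in exposed_set]
            if partners:
                j = min(partners, key=lambda j: d[i, j])
                prev = alpha.symbols[seq[j]]
                letter = "E" if prev == "K" else "K"
            else:
                letter = rule.exposed_letters[i % len(rule.exposed_letters)]
        seq[i] = alpha.index(letter)
    if rule.label_noise > 0:
        flip = rng.random(s.L) < rule.label_noise
        seq[flip] = rng.integers(0, alpha.size, size=int(flip.sum()))
    return SequenceState(seq, alpha)


def make_structure_sequence_dataset(
    n: int,
    length: int = 40,
    rule_params: RuleParams | None = None,
    noise_sigma: float = 0.1,
    seed: int = 0,
    heldout_fraction: float = 0.2,
) -> StructureSequenceDataset:
    """Paired (backbone, sequence) dataset with a disjoint held-out split.

    Each item is a varied toy backbone; its sequence comes from the
    geometric rule evaluated on the clean coordinates, after which the
    *stored* backbone is perturbed by Gaussian noise at ``noise_sigma`` (so
    observed geometry is an imperfect witness of the rule's input, as for
    real structures).
    """
    if n < 2:
        raise ContractError("dataset needs n >= 2")
    rule = rule_params or RuleParams()
    rng = np.random.default_rng(seed)
    items = []
    for _ in range(n):
        s = _varied_backbone(length, rng)
        seq = rule_sequence(s, rule, rng)
        if noise_sigma > 0:
            s = s.with_coords(s.coords + rng.normal(0.0, noise_sigma, s.coords.shape))
        items.append((s, seq))
    n_held = max(1, int(round(heldout_fraction * n)))
    return StructureSequenceDataset(
        train=tuple(items[:-n_held]),
        heldout=tuple(items[-n_held:]),
        rule=rule,
        seed=seed,
    )
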