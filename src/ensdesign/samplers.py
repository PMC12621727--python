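"""Sequence samplers for Potts models.

Two exact MCMC samplers target the composite Boltzmann distribution
``p(S) proportional to exp(-(E(S) + lambda * LCP(S)) / T)``:

* :func:`dlmc_sample` — Discrete Langevin Monte Carlo: every step proposes a
  substitution at *every* site simultaneously from a factorized,
  locally-informed categorical proposal (probabilities shaped by the local
  energy changes, with a step-size-controlled laziness term), then applies a
  Metropolis–Hastings correction with the reverse-proposal ratio so the
  chain is exact.
* :func:`gibbs_sample` — systematic-scan single-site Gibbs with a seeded
  site permutation per sweep; the reference sampler used to cross-check
  DLMC.

The local composition perplexity (LCP) restraint penalizes low-complexity
sequence: every length-``w`` window whose composition perplexity
``exp(entropy)`` falls below a floor ``P_min`` contributes a squared hinge
``(P_min - P_window)**2``.

Inner chain loops are compiled with numba when available; the identical
code path runs as plain Python otherwise.  All randomness is pre-drawn from
a seeded ``numpy`` Generator, so chains are bit-reproducible across
platforms and independent of the compilation mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .potts import ContractError, PottsModel, SequenceState, energy

__all__ = [
    "SamplerConfig",
    "LCPConfig",
    "SamplerTrace",
    "lcp_penalty",
    "composite_energy",
    "dlmc_sample",
    "gibbs_sample",
    "geometric_mean_combine",
    "tied_conditional_decode",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


@dataclass(frozen=True)
class LCPConfig:
    """Local-composition-perplexity restraint parameters.

    ``window_width`` residues per window (default 16), perplexity floor
    ``p_min`` (default 8 effective residue types), hinge weight ``weight``
    and a small pseudocount that smooths window compositions.
    """

    enabled: bool = False
    window_width: int = 16
    p_min: float = 8.0
    weight: float = 1.0
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.window_width < 1:
            raise ContractError("window_width must be positive")
        if self.p_min < 1.0:
            raise ContractError("p_min must be >= 1")
        if self.weight < 0 or self.pseudocount < 0:
            raise ContractError("weight and pseudocount must be nonnegative")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC controls shared by DLMC and Gibbs.

    One *step* proposes all sites once (DLMC) or sweeps all sites once
    (Gibbs), so ``burn_in`` and ``thinning`` are in sweep-equivalents.
    Defaults resolved at sampling time: ``burn_in = 10 * L`` and
    ``thinning = 1``.  ``temperature_schedule`` may be a scalar (constant)
    or a per-step array; ``n_steps``, when given, must equal
    ``burn_in + n_samples * thinning``.
    """

    n_steps: int | None = None
    temperature_schedule: float | Sequence[float] = 1.0
    dlmc_step_size: float = 1.0
    mh_correction: bool = True
    seed: int = 0
    burn_in: int | None = None
    thinning: int = 1

    def __post_init__(self) -> None:
        if self.dlmc_step_size <= 0:
            raise ContractError("dlmc_step_size must be positive")
        if self.thinning < 1:
            raise ContractError("thinning must be a positive integer")
        if self.burn_in is not None and self.burn_in < 0:
            raise ContractError("burn_in must be nonnegative")

    def resolve(self, L: int, n_samples: int) -> tuple[int, int, np.ndarray]:
        burn = 10 * L if self.burn_in is None else self.burn_in
        total = burn + n_samples * self.thinning
        if self.n_steps is not None and self.n_steps != total:
            raise ContractError(
                f"n_steps={self.n_steps} inconsistent with burn_in + "
                f"n_samples * thinning = {total}"
            )
        ts = self.temperature_schedule
        if np.isscalar(ts):
            temps = np.full(total, float(ts))
        else:
            temps = np.asarray(ts, dtype=np.float64)
            if temps.shape != (total,):
                raise ContractError("temperature schedule length must equal n_steps")
        if np.any(temps <= 0):
            raise ContractError("temperatures must be positive")
        return burn, total, temps


@dataclass
class SamplerTrace:
    """Diagnostics: recorded composite energies, acceptance rate, seed echo."""

    energies: np.ndarray
    acceptance_rate: float
    seed: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.acceptance_rate <= 1.0


# ---------------------------------------------------------------------------
# LCP restraint


def lcp_penalty(seq: SequenceState, cfg: LCPConfig) -> float:
    """Sum over length-w windows of ``max(0, P_min - P_window)**2``.

    ``P_window = exp(H)`` with ``H`` the natural-log entropy of the
    pseudocount-smoothed window composition; zero when every window is at
    or above the perplexity floor.
    """
    L = len(seq)
    w = cfg.window_width
    if w > L:
        raise ContractError(f"LCP window {w} longer than sequence {L}")
    s = seq.residues
    A = seq.alphabet.size
    onehot = np.zeros((L, A))
    onehot[np.arange(L), s] = 1.0
    csum = np.vstack([np.zeros(A), np.cumsum(onehot, axis=0)])
    counts = csum[w:] - csum[:-w]  # (L - w + 1, A)
    p = (counts + cfg.pseudocount) / (w + A * cfg.pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    perp = np.exp(-plogp.sum(axis=1))
    hinge = np.maximum(0.0, cfg.p_min - perp)
    return float((hinge**2).sum())


def composite_energy(model: PottsModel, seq: SequenceState, cfg: LCPConfig) -> float:
    """Potts energy plus ``weight * lcp_penalty``; the sampler's target."""
    e = energy(model, seq)
    if cfg.enabled and cfg.weight > 0:
        e += cfg.weight * lcp_penalty(seq, cfg)
    return e


# ---------------------------------------------------------------------------
# Compiled chain kernels.  All operate on dense arrays:
#   h: (L, A) fields; J: (L, L, A, A) symmetric couplings, zero diagonal.


@njit(cache=False)
def _win_pen(counts, w, A, pmin, pc):
    denom = w + A * pc
    H = 0.0
    for a in range(A):
        p = (counts[a] + pc) / denom
        if p > 0.0:
            H -= p * math.log(p)
    d = pmin - math.exp(H)
    return d * d if d > 0.0 else 0.0


@njit(cache=False)
def _lcp_total(s, w, A, pmin, pc):
    L = s.shape[0]
    nw = L - w + 1
    tot = 0.0
    counts = np.zeros(A)
    for i in range(w):
        counts[s[i]] += 1.0
    tot += _win_pen(counts, w, A, pmin, pc)
    for v in range(1, nw):
        counts[s[v - 1]] -= 1.0
        counts[s[v + w - 1]] += 1.0
        tot += _win_pen(counts, w, A, pmin, pc)
    return tot


@njit(cache=False)
def _lcp_site_deltas(s, w, A, pmin, pc, out):
    """out[i, a] = LCP(s with site i -> a) - LCP(s), exact per single site."""
    L = s.shape[0]
    nw = L - w + 1
    counts = np.zeros((nw, A))
    base = np.zeros(nw)
    for v in range(nw):
        for i in range(v, v + w):
            counts[v, s[i]] += 1.0
        base[v] = _win_pen(counts[v], w, A, pmin, pc)
    for i in range(L):
        lo = max(0, i - w + 1)
        hi = min(nw - 1, i)
        for a in range(A):
            d = 0.0
            if a != s[i]:
                for v in range(lo, hi + 1):
                    counts[v, s[i]] -= 1.0
                    counts[v, a] += 1.0
                    d += _win_pen(counts[v], w, A, pmin, pc) - base[v]
                    counts[v, s[i]] += 1.0
                    counts[v, a] -= 1.0
            out[i, a] = d


@njit(cache=False)
def _local_energies(h, J, s, out):
    L, A = h.shape
    for i in range(L):
        for a in range(A):
            e = h[i, a]
            for j in range(L):
                if j != i:
                    e += J[i, j, a, s[j]]
            out[i, a] = e


@njit(cache=False)
def _potts_energy(h, J, s):
    L = h.shape[0]
    e = 0.0
    for i in range(L):
        e += h[i, s[i]]
        for j in range(i + 1, L):
            e += J[i, j, s[i], s[j]]
    return e


@njit(cache=False)
def _dlmc_kernel(
    h, J, s, temps, step_size, mh_on, lcp_on, w, pmin, lam, pc,
    burn_in, thinning, u_prop, u_acc, samples, energies,
):
    L, A = h.shape
    n_steps = temps.shape[0]
    loc = np.empty((L, A))
    loc2 = np.empty((L, A))
    lcpd = np.zeros((L, A))
    lcpd2 = np.zeros((L, A))
    logq = np.empty(A)
    s2 = np.empty(L, dtype=np.int64)
    lazy = 0.5 / step_size
    e_comp = _potts_energy(h, J, s)
    if lcp_on:
        e_comp += lam * _lcp_total(s, w, A, pmin, pc)
    n_acc = 0
    n_rec = 0
    for t in range(n_steps):
        T = temps[t]
        _local_energies(h, J, s, loc)
        if lcp_on:
            _lcp_site_deltas(s, w, A, pmin, pc, lcpd)
        fwd = 0.0
        for i in range(L):
            m = -1e308
            for a in range(A):
                v = -(loc[i, a] + lam * lcpd[i, a]) / (2.0 * T)
                if a != s[i]:
                    v -= lazy
                logq[a] = v
                if v > m:
                    m = v
            z = 0.0
            for a in range(A):
                z += math.exp(logq[a] - m)
            lz = m + math.log(z)
            # inverse-CDF draw
            u = u_prop[t, i]
            acc_p = 0.0
            pick = A - 1
            for a in range(A):
                acc_p += math.exp(logq[a] - lz)
                if u < acc_p:
                    pick = a
                    break
            s2[i] = pick
            fwd += logq[pick] - lz
        accept = True
        if mh_on:
            e2 = _potts_energy(h, J, s2)
            if lcp_on:
                e2 += lam * _lcp_total(s2, w, A, pmin, pc)
            _local_energies(h, J, s2, loc2)
            if lcp_on:
                _lcp_site_deltas(s2, w, A, pmin, pc, lcpd2)
            rev = 0.0
            for i in range(L):
                m = -1e308
                for a in range(A):
                    v = -(loc2[i, a] + lam * lcpd2[i, a]) / (2.0 * T)
                    if a != s2[i]:
                        v -= lazy
                    logq[a] = v
                    if v > m:
                        m = v
                z = 0.0
                for a in range(A):
                    z += math.exp(logq[a] - m)
                rev += logq[s[i]] - (m + math.log(z))
            log_alpha = -(e2 - e_comp) / T + rev - fwd
            accept = math.log(u_acc[t]) < log_alpha
            if accept:
                e_comp = e2
        if accept:
            for i in range(L):
                s[i] = s2[i]
            n_acc += 1
        if not mh_on:
            e_comp = _potts_energy(h, J, s)
            if lcp_on:
                e_comp += lam * _lcp_total(s, w, A, pmin, pc)
        if t >= burn_in and (t - burn_in) % thinning == 0:
            if n_rec < samples.shape[0]:
                for i in range(L):
                    samples[n_rec, i] = s[i]
                energies[n_rec] = e_comp
                n_rec += 1
    return n_acc


@njit(cache=False)
def _gibbs_kernel(
    h, J, s, temps, lcp_on, w, pmin, lam, pc,
    burn_in, thinning, perms, u, samples, energies,
):
    L, A = h.shape
    n_steps = temps.shape[0]
    lcpd = np.zeros((L, A))
    logq = np.empty(A)
    n_rec = 0
    for t in range(n_steps):
        T = temps[t]
        for k in range(L):
            i = perms[t, k]
            if lcp_on:
                _lcp_site_deltas(s, w, A, pmin, pc, lcpd)
            m = -1e308
            for a in range(A):
                e = h[i, a]
                for j in range(L):
                    if j != i:
                        e += J[i, j, a, s[j]]
                if lcp_on:
                    e += lam * lcpd[i, a]
                v = -e / T
                logq[a] = v
                if v > m:
                    m = v
            z = 0.0
            for a in range(A):
                z += math.exp(logq[a] - m)
            lz = m + math.log(z)
            uv = u[t, k]
            acc_p = 0.0
            pick = A - 1
            for a in range(A):
                acc_p += math.exp(logq[a] - lz)
                if uv < acc_p:
                    pick = a
                    break
            s[i] = pick
        if t >= burn_in and (t - burn_in) % thinning == 0:
            if n_rec < samples.shape[0]:
                for i in range(L):
                    samples[n_rec, i] = s[i]
                e_comp = _potts_energy(h, J, s)
                if lcp_on:
                    e_comp += lam * _lcp_total(s, w, A, pmin, pc)
                energies[n_rec] = e_comp
                n_rec += 1
    return n_rec


# ---------------------------------------------------------------------------
# Public sampler API


def _prepare(model: PottsModel, cfg: SamplerConfig, lcp: LCPConfig, n_samples, init):
    if n_samples < 1:
        raise ContractError("n_samples must be positive")
    if lcp.enabled and lcp.window_width > model.L:
        raise ContractError("LCP window longer than sequence")
    burn, total, temps = cfg.resolve(model.L, n_samples)
    rng = np.random.default_rng(cfg.seed)
    if init is None:
        s0 = rng.integers(0, model.A, size=model.L).astype(np.int64)
    else:
        model._check_seq(init)
        s0 = init.residues.astype(np.int64).copy()
    return burn, total, temps, rng, s0


def dlmc_sample(
    model: PottsModel,
    cfg: SamplerConfig,
    lcp: LCPConfig,
    n_samples: int,
    init: SequenceState | None = None,
) -> tuple[np.ndarray, SamplerTrace]:
    """Discrete Langevin Monte Carlo sampling from the composite model.

    Each step proposes, independently at every site, a substitution with
    probability proportional to
    ``exp(-delta_i(a) / (2T) - 1[a != s_i] / (2 * step_size))`` where
    ``delta_i(a)`` is the composite local energy; with ``mh_correction``
    the joint proposal is accepted with the standard reverse-proposal
    ratio, making the stationary law exactly
    ``p(S) proportional to exp(-composite_energy(S)/T)``.

    Returns an ``(n_samples, L)`` index array of post-burn-in thinned
    states plus a :class:`SamplerTrace`.  Fully reproducible from
    ``cfg.seed``.
    """
    burn, total, temps, rng, s = _prepare(model, cfg, lcp, n_samples, init)
    u_prop = rng.random((total, model.L))
    u_acc = rng.random(total)
    samples = np.empty((n_samples, model.L), dtype=np.int64)
    energies = np.empty(n_samples)
    n_acc = _dlmc_kernel(
        model.h, model.dense_couplings(), s, temps, float(cfg.dlmc_step_size),
        bool(cfg.mh_correction), bool(lcp.enabled and lcp.weight > 0),
        int(lcp.window_width), float(lcp.p_min), float(lcp.weight),
        float(lcp.pseudocount), burn, int(cfg.thinning), u_prop, u_acc,
        samples, energies,
    )
    trace = SamplerTrace(energies, n_acc / total, cfg.seed)
    return samples, trace


def gibbs_sample(
    model: PottsModel,
    cfg: SamplerConfig,
    lcp: LCPConfig,
    n_samples: int,
    init: SequenceState | None = None,
) -> tuple[np.ndarray, SamplerTrace]:
    """Systematic-scan Gibbs sampling of the same composite target.

    One step is a full sweep over a seeded per-sweep site permutation;
    every site update draws from its exact full conditional, so the sweep
    is rejection-free.
    """
    burn, total, temps, rng, s = _prepare(model, cfg, lcp, n_samples, init)
    perms = np.empty((total, model.L), dtype=np.int64)
    for t in range(total):
        perms[t] = rng.permutation(model.L)
    u = rng.random((total, model.L))
    samples = np.empty((n_samples, model.L), dtype=np.int64)
    energies = np.empty(n_samples)
    _gibbs_kernel(
        model.h, model.dense_couplings(), s, temps,
        bool(lcp.enabled and lcp.weight > 0), int(lcp.window_width),
        float(lcp.p_min), float(lcp.weight), float(lcp.pseudocount),
        burn, int(cfg.thinning), perms, u, samples, energies,
    )
    trace = SamplerTrace(energies, 1.0, cfg.seed)
    return samples, trace


def geometric_mean_combine(
    logit_sets: Sequence[np.ndarray] | np.ndarray,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Softmax of the weighted mean of logit vectors.

    Identical (exactly, not just asymptotically) to renormalizing the
    weighted geometric mean of the per-set softmax distributions — the
    identity behind tied autoregressive decoding across an ensemble.
    """
    logits = np.asarray(logit_sets, dtype=np.float64)
    if logits.ndim == 1:
        logits = logits[None, :]
    if logits.size == 0:
        raise ContractError("geometric_mean_combine needs at least one logit set")
    if not np.all(np.isfinite(logits)):
        raise ContractError("logits must be finite")
    K = logits.shape[0]
    if weights is None:
        w = np.full(K, 1.0 / K)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (K,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ContractError("weights must be a nonnegative simplex vector")
    mean = w @ logits
    mean -= mean.max()
    p = np.exp(mean)
    return p / p.sum()


def tied_conditional_decode(
    models: Sequence[PottsModel],
    order: Sequence[int],
    cfg: SamplerConfig,
) -> SequenceState:
    """Autoregressive decode with per-site logits averaged across models.

    Sites are assigned in ``order``; at each site the full-conditional
    logits given all already-assigned sites (unassigned sites contribute no
    coupling terms) are computed per model and combined with
    :func:`geometric_mean_combine` under uniform weights.
    """
    if len(models) == 0:
        raise ContractError("need at least one model")
    L, A = models[0].L, models[0].A
    for m in models[1:]:
        if m.L != L or m.alphabet.symbols != models[0].alphabet.symbols:
            raise ContractError("models must share L and alphabet")
    order = np.asarray(order, dtype=np.int64)
    if sorted(order.tolist()) != list(range(L)):
        raise ContractError("order must be a permutation of all sites")
    rng = np.random.default_rng(cfg.seed)
    s = np.zeros(L, dtype=np.int64)
    assigned = np.zeros(L, dtype=bool)
    for i in order:
        logit_sets = np.empty((len(models), A))
        for k, m in enumerate(models):
            e = m.h[i].copy()
            for j, block in m.neighbors(i):
                if assigned[j]:
                    e += block[:, s[j]]
            logit_sets[k] = -e
        p = geometric_mean_combine(logit_sets)
        s[i] = rng.choice(A, p=p)
        assigned[i] = True
    return SequenceState(s, models[0].alphabet)
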