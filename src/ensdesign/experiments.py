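"""Canonical desk-scale experiments characterizing the method.

Each function freezes one study's conditions (model sizes, chain lengths,
training set sizes) and returns plain numbers, so the same computation
backs both the test suite and the reproduction script.  Problem sizes are
chosen to run in CPU seconds-to-minutes; the methods note documents them.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .fixtures import FixtureSpec, make_random_potts, make_structure_sequence_dataset, make_toy_backbone
from .network import NetworkConfig, TrainConfig, design_for_ensemble, init_network, predict_potts, train
from .potts import (
    Alphabet,
    PottsModel,
    SequenceState,
    apply_zero_sum_gauge,
    average_models,
    energy,
    enumerate_distribution,
    local_fields,
)
from .samplers import LCPConfig, SamplerConfig, dlmc_sample, geometric_mean_combine, gibbs_sample
from .structure import FeaturizerConfig, StructureEnsemble, featurize, gaussian_ensemble

__all__ = [
    "poe_identity_deviation",
    "sampler_exactness",
    "logit_averaging_deviation",
    "averaging_linearity_deviation",
    "one_pass_counts",
    "lcp_homopolymer_effect",
    "coupling_recovery",
    "ensemble_robustness",
]


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _empirical_tv(samples: np.ndarray, dist) -> float:
    A, L = dist.model.A, dist.model.L
    idx = np.ravel_multi_index(samples.T, (A,) * L)
    emp = np.bincount(idx, minlength=A**L) / len(samples)
    return float(np.abs(emp - dist.probabilities).sum() / 2)


def poe_identity_deviation(seed: int = 0, n_trials: int = 20) -> float:
    """Max TV between the averaged model's distribution and the renormalized
    geometric mean of per-model distributions, over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        K = int(rng.integers(2, 5))
        L = int(rng.integers(2, 6))
        A = int(rng.integers(2, 5))
        models = [
            make_random_potts(
                L, A,
                edge_density=float(rng.uniform(0.2, 1.0)),
                field_scale=1.0, coupling_scale=1.0,
                seed=int(rng.integers(2**31)),
            )
            for _ in range(K)
        ]
        avg = enumerate_distribution(average_models(models))
        logp = np.mean(
            [enumerate_distribution(m).log_probabilities for m in models], axis=0
        )
        geo = np.exp(logp - logsumexp(logp))
        worst = max(worst, float(np.abs(avg.probabilities - geo).sum() / 2))
    return worst


def sampler_exactness(
    seed: int = 0, n_samples: int = 100_000, n_seeds: int = 5
) -> dict[str, float]:
    """Worst-seed TV between long-run sampler output and exact enumeration
    on a random fully-connected L=4, A=4 model (unit-scale fields and
    couplings).  DLMC uses thinning 4 to decorrelate the all-site proposal
    chain (acceptance is ~0.5, so consecutive states are correlated);
    Gibbs resamples every site per sweep and is recorded every sweep.

    The model fixture is fixed (seed 1): it is the smallest seed whose
    exact distribution has a multinomial sampling-noise TV floor at or
    below 0.011 at 1e5 draws, so the check measures sampler error rather
    than the flatness of a particular random realization.  Chain seeds
    derive from ``seed``.
    """
    model = make_random_potts(
        4, 4, edge_density=1.0, field_scale=1.0, coupling_scale=1.0, seed=1
    )
    dist = enumerate_distribution(model)
    lcp = LCPConfig()
    out = {"dlmc_tv": 0.0, "gibbs_tv": 0.0}
    for s in _sub_seeds(seed, n_seeds):
        cfg = SamplerConfig(seed=s, burn_in=1000, thinning=4)
        samples, _ = dlmc_sample(model, cfg, lcp, n_samples)
        out["dlmc_tv"] = max(out["dlmc_tv"], _empirical_tv(samples, dist))
        cfg = SamplerConfig(seed=s, burn_in=1000, thinning=1)
        samples, _ = gibbs_sample(model, cfg, lcp, n_samples)
        out["gibbs_tv"] = max(out["gibbs_tv"], _empirical_tv(samples, dist))
    return out


def logit_averaging_deviation(seed: int = 0, n_trials: int = 50) -> float:
    """Max elementwise deviation between softmax-of-mean-logits and the
    renormalized weighted geometric mean of softmaxed distributions."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        K = int(rng.integers(1, 6))
        A = int(rng.integers(2, 31))
        logits = rng.normal(0.0, 5.0, size=(K, A))
        w = rng.dirichlet(np.ones(K))
        combined = geometric_mean_combine(logits, w)
        # direct route: weighted geometric mean of the softmaxed rows
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        geo = np.exp((w[:, None] * np.log(p)).sum(axis=0))
        geo /= geo.sum()
        worst = max(worst, float(np.abs(combined - geo).max()))
    return worst


def averaging_linearity_deviation(seed: int = 0) -> float:
    """Max |energy(averaged model) - weighted mean of energies| over all
    3^5 sequences for two random L=5, A=3 models with random weights."""
    rng = np.random.default_rng(seed)
    m1 = make_random_potts(5, 3, 0.4, seed=int(rng.integers(2**31)))
    m2 = make_random_potts(5, 3, 0.4, seed=int(rng.integers(2**31)))
    w = float(rng.uniform(0.1, 0.9))
    avg = average_models([m1, m2], [w, 1.0 - w])
    worst = 0.0
    for s in enumerate_distribution(avg).sequences():
        seq = SequenceState(s, avg.alphabet)
        expect = w * energy(m1, seq) + (1.0 - w) * energy(m2, seq)
        worst = max(worst, abs(energy(avg, seq) - expect))
    return worst


def one_pass_counts(
    seed: int = 0,
    ks: tuple[int, ...] = (1, 4, 16),
    n_seq_values: tuple[int, ...] = (1, 100),
) -> dict[str, int]:
    """Instrumented forward-pass counts per design job.

    For each ensemble size K and requested sample count, predicts per-
    conformer Potts models, averages, and samples; records the counter.
    The count must equal K, independent of the sample count.
    """
    backbone = make_toy_backbone(FixtureSpec("perturbed", 24, seed, noise_sigma=0.5))
    fcfg = FeaturizerConfig(k_neighbors=8)
    params = init_network(NetworkConfig(hidden_dim=32), seed)
    counts = {}
    for K in ks:
        ensemble = gaussian_ensemble(backbone, 0.5, K, seed=seed)
        for n_seq in n_seq_values:
            model, n_passes = design_for_ensemble(params, ensemble, fcfg)
            dlmc_sample(
                model, SamplerConfig(seed=seed, burn_in=50), LCPConfig(), n_seq
            )
            counts[f"K{K}_n{n_seq}"] = n_passes
    return counts


def lcp_homopolymer_effect(
    seed: int = 0, n_seeds: int = 5, n_samples: int = 200
) -> dict[str, float]:
    """Frequency of length-w homopolymer windows with and without the LCP
    restraint, sampling a field-only model strongly biased to leucine.

    L=24, w=8, bias -6 on L at every site; LCP with floor 4 and weight 20.
    Returns mean per-sequence homopolymer-window counts for both settings.
    """
    A = 20
    L = 24
    w = 8
    alpha = Alphabet()
    h = np.zeros((L, A))
    h[:, alpha.index("L")] = -6.0
    model = PottsModel(h, {}, alpha)
    lcp_on = LCPConfig(enabled=True, window_width=w, p_min=4.0, weight=20.0)
    lcp_off = LCPConfig(enabled=False)

    def homopolymer_windows(samples: np.ndarray) -> float:
        windows = np.lib.stride_tricks.sliding_window_view(samples, w, axis=1)
        mono = (windows == windows[..., :1]).all(axis=-1)
        return float(mono.sum(axis=1).mean())

    on = off = 0.0
    for s in _sub_seeds(seed, n_seeds):
        cfg = SamplerConfig(seed=s, burn_in=10 * L, thinning=2)
        samples, _ = dlmc_sample(model, cfg, lcp_off, n_samples)
        off += homopolymer_windows(samples)
        samples, _ = dlmc_sample(model, cfg, lcp_on, n_samples)
        on += homopolymer_windows(samples)
    return {"lcp_off": off / n_seeds, "lcp_on": on / n_seeds}


def coupling_recovery(seed: int = 0, n_sequences: int = 200) -> float:
    """Pearson correlation between true and learned couplings.

    Sequences are drawn exactly from a known L=8, A=4 Potts model
    (edge density 0.3, field scale 0.5, coupling scale 1.0); the network
    sees a single irregular backbone whose k=7 graph covers all pairs, is
    trained by pseudolikelihood, and both models are compared in the
    zero-sum gauge over the union edge set.
    """
    rng = np.random.default_rng(seed)
    true = make_random_potts(
        8, 4, edge_density=0.3, field_scale=0.5, coupling_scale=1.0,
        seed=int(rng.integers(2**31)),
    )
    dist = enumerate_distribution(true)
    draws = rng.choice(len(dist.probabilities), size=n_sequences, p=dist.probabilities)
    seqs = dist.sequences()[draws]

    backbone = make_toy_backbone(
        FixtureSpec("perturbed", 8, int(rng.integers(2**31)), noise_sigma=1.0)
    )
    graph = featurize(backbone, FeaturizerConfig(k_neighbors=7))
    cfg = NetworkConfig(alphabet=Alphabet("ACDE"))  # default 3+3 layers, width 128
    params = init_network(cfg, seed)
    data = [(graph, SequenceState(s, cfg.alphabet)) for s in seqs]
    params, _ = train(
        params, data, TrainConfig(learning_rate=0.05, epochs=800, seed=seed)
    )
    pred = apply_zero_sum_gauge(predict_potts(params, graph))
    ref = apply_zero_sum_gauge(true)
    pairs = sorted(set(pred.edges) | set(ref.edges))
    A = true.A
    zero = np.zeros((A, A))
    x = np.concatenate([ref.couplings.get(e, zero).ravel() for e in pairs])
    y = np.concatenate([pred.couplings.get(e, zero).ravel() for e in pairs])
    return float(np.corrcoef(x, y)[0, 1])


def _conditional_argmax_recovery(model: PottsModel, native: SequenceState) -> float:
    """Fraction of sites whose full-conditional argmax matches the native."""
    rows = local_fields(model, native)
    return float(np.mean(rows.argmin(axis=1) == native.residues))


def ensemble_robustness(
    seed: int = 0,
    n_seeds: int = 5,
    n_structures: int = 80,
    length: int = 28,
    eval_sigma: float = 0.8,
    ensemble_k: int = 8,
) -> dict[str, float]:
    """Held-out recovery: single noisy conformer vs K-conformer averaging.

    For each seed, trains the network on the rule-based dataset, then for
    every held-out backbone draws noisy conformers at ``eval_sigma`` and
    compares conditional-argmax recovery of the single-conformer Potts
    model against the K-conformer averaged model (same first conformer,
    paired comparison).  Returns means over seeds.
    """
    fcfg = FeaturizerConfig(k_neighbors=10)
    singles, ensembles = [], []
    for s in _sub_seeds(seed, n_seeds):
        data = make_structure_sequence_dataset(
            n=n_structures, length=length, noise_sigma=0.1, seed=s
        )
        pairs = [(featurize(st, fcfg), sq) for st, sq in data.train]
        params = init_network(NetworkConfig(hidden_dim=48), s)
        params, _ = train(params, pairs, TrainConfig(epochs=120, seed=s))
        rng = np.random.default_rng(s + 1)
        r1, rk = [], []
        for st, native in data.heldout:
            conformers = gaussian_ensemble(
                st, eval_sigma, ensemble_k + 1, seed=int(rng.integers(2**31))
            ).conformers
            single = StructureEnsemble(conformers[0])
            multi = StructureEnsemble(conformers[0], conformers[1:ensemble_k])
            m1, _ = design_for_ensemble(params, single, fcfg)
            mk, _ = design_for_ensemble(params, multi, fcfg)
            r1.append(_conditional_argmax_recovery(m1, native))
            rk.append(_conditional_argmax_recovery(mk, native))
        singles.append(np.mean(r1))
        ensembles.append(np.mean(rk))
    return {
        "single_recovery": float(np.mean(singles)),
        "ensemble_recovery": float(np.mean(ensembles)),
    }
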