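"""Samplers: LCP restraint, DLMC/Gibbs exactness, logit averaging, decoding."""

import math

import numpy as np
import pytest

from ensdesign.fixtures import make_random_potts
from ensdesign.potts import (
    Alphabet,
    ContractError,
    PottsModel,
    SequenceState,
    average_models,
    energy,
    enumerate_distribution,
)
from ensdesign.samplers import (
    LCPConfig,
    SamplerConfig,
    composite_energy,
    dlmc_sample,
    geometric_mean_combine,
    gibbs_sample,
    lcp_penalty,
    tied_conditional_decode,
)


def empirical_tv(samples, dist):
    A, L = dist.model.A, dist.model.L
    idx = np.ravel_multi_index(samples.T, (A,) * L)
    emp = np.bincount(idx, minlength=A**L) / len(samples)
    return np.abs(emp - dist.probabilities).sum() / 2


def naive_lcp(seq, cfg):
    """Window-by-window oracle with explicit entropy computation."""
    s = seq.residues
    A = seq.alphabet.size
    total = 0.0
    for start in range(len(s) - cfg.window_width + 1):
        window = s[start : start + cfg.window_width]
        counts = np.bincount(window, minlength=A) + cfg.pseudocount
        p = counts / counts.sum()
        H = -sum(pi * math.log(pi) for pi in p if pi > 0)
        total += max(0.0, cfg.p_min - math.exp(H)) ** 2
    return total


class TestLCP:
    def test_max_diversity_window_zero(self):
        alpha = Alphabet()
        seq = alpha.encode("ACDEFGHIKLMNPQRS")  # 16 distinct residues
        cfg = LCPConfig(enabled=True, window_width=16, p_min=8.0)
        assert lcp_penalty(seq, cfg) == 0.0

    def test_homopolymer_zero_pseudocount_limit(self):
        alpha = Alphabet()
        seq = alpha.encode("A" * 16)
        cfg = LCPConfig(enabled=True, window_width=16, p_min=8.0, pseudocount=1e-12)
        assert lcp_penalty(seq, cfg) == pytest.approx((8.0 - 1.0) ** 2, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alpha = Alphabet()
        seq = SequenceState(rng.integers(0, 20, size=30), alpha)
        cfg = LCPConfig(enabled=True, window_width=9, p_min=5.0, pseudocount=0.1)
        assert lcp_penalty(seq, cfg) == pytest.approx(naive_lcp(seq, cfg), abs=1e-10)

    def test_window_longer_than_sequence(self):
        seq = Alphabet().encode("ACD")
        with pytest.raises(ContractError):
            lcp_penalty(seq, LCPConfig(window_width=16))

    def test_composite_energy_decomposition(self, rng):
        m = make_random_potts(20, 20, 0.2, seed=3)
        seq = SequenceState(rng.integers(0, 20, size=20), m.alphabet)
        off = LCPConfig(enabled=False)
        assert composite_energy(m, seq, off) == energy(m, seq)
        on = LCPConfig(enabled=True, window_width=8, weight=2.5)
        expect = energy(m, seq) + 2.5 * lcp_penalty(seq, on)
        assert composite_energy(m, seq, on) == pytest.approx(expect)
        zero_model = PottsModel(np.zeros((20, 20)))
        assert composite_energy(zero_model, seq, on) == pytest.approx(
            2.5 * lcp_penalty(seq, on)
        )


class TestChains:
    def test_flat_target_uniform(self):
        m = PottsModel(np.zeros((4, 3)))
        dist = enumerate_distribution(m)
        cfg = SamplerConfig(seed=0, burn_in=200, thinning=1)
        for sampler in (dlmc_sample, gibbs_sample):
            samples, _ = sampler(m, cfg, LCPConfig(), 50_000)
            assert empirical_tv(samples, dist) < 0.02

    def test_dlmc_matches_enumeration(self):
        m = make_random_potts(4, 4, 1.0, seed=2)
        dist = enumerate_distribution(m)
        cfg = SamplerConfig(seed=1, burn_in=500, thinning=2)
        samples, trace = dlmc_sample(m, cfg, LCPConfig(), 30_000)
        assert empirical_tv(samples, dist) < 0.03
        assert 0.05 < trace.acceptance_rate <= 1.0

    def test_gibbs_matches_enumeration(self):
        m = make_random_potts(4, 4, 1.0, seed=2)
        dist = enumerate_distribution(m)
        cfg = SamplerConfig(seed=1, burn_in=500, thinning=1)
        samples, trace = gibbs_sample(m, cfg, LCPConfig(), 30_000)
        assert empirical_tv(samples, dist) < 0.03
        assert trace.acceptance_rate == 1.0

    def test_cross_sampler_marginals_agree(self):
        m = make_random_potts(4, 4, 1.0, seed=8)
        cfg = SamplerConfig(seed=5, burn_in=500, thinning=2)
        s1, _ = dlmc_sample(m, cfg, LCPConfig(), 30_000)
        s2, _ = gibbs_sample(m, cfg, LCPConfig(), 30_000)
        for site in range(m.L):
            p1 = np.bincount(s1[:, site], minlength=m.A) / len(s1)
            p2 = np.bincount(s2[:, site], minlength=m.A) / len(s2)
            assert np.abs(p1 - p2).sum() / 2 < 0.03

    def test_seed_determinism(self):
        m = make_random_potts(5, 4, 0.5, seed=3)
        cfg = SamplerConfig(seed=77, burn_in=100, thinning=1)
        a1, t1 = dlmc_sample(m, cfg, LCPConfig(), 500)
        a2, t2 = dlmc_sample(m, cfg, LCPConfig(), 500)
        np.testing.assert_array_equal(a1, a2)
        assert t1.acceptance_rate == t2.acceptance_rate
        g1, _ = gibbs_sample(m, cfg, LCPConfig(), 500)
        g2, _ = gibbs_sample(m, cfg, LCPConfig(), 500)
        np.testing.assert_array_equal(g1, g2)

    def test_init_state_respected_and_trace_shape(self):
        m = make_random_potts(5, 4, 0.5, seed=3)
        init = SequenceState(np.zeros(5, dtype=int), m.alphabet)
        cfg = SamplerConfig(seed=0, burn_in=0, thinning=3)
        samples, trace = dlmc_sample(m, cfg, LCPConfig(), 100, init=init)
        assert samples.shape == (100, 5)
        assert trace.energies.shape == (100,)

    def test_temperature_monotonicity(self):
        m = make_random_potts(4, 4, 1.0, seed=4)
        means = []
        for T in (2.0, 1.0, 0.5):
            cfg = SamplerConfig(
                seed=11, burn_in=500, thinning=1, temperature_schedule=T
            )
            samples, _ = gibbs_sample(m, cfg, LCPConfig(), 20_000)
            means.append(
                np.mean([energy(m, SequenceState(s, m.alphabet)) for s in samples[::20]])
            )
        assert means[0] > means[1] - 0.05
        assert means[1] > means[2] - 0.05

    def test_lcp_reduces_homopolymer_bias(self):
        # field-only model strongly favoring one residue
        alpha = Alphabet()
        h = np.zeros((16, 20))
        h[:, alpha.index("L")] = -5.0
        m = PottsModel(h, {}, alpha)
        cfg = SamplerConfig(seed=0, burn_in=200, thinning=2)
        off, _ = dlmc_sample(m, cfg, LCPConfig(enabled=False), 300)
        on, _ = dlmc_sample(
            m, cfg,
            LCPConfig(enabled=True, window_width=8, p_min=4.0, weight=20.0), 300,
        )
        win_off = np.lib.stride_tricks.sliding_window_view(off, 8, axis=1)
        win_on = np.lib.stride_tricks.sliding_window_view(on, 8, axis=1)
        mono_off = (win_off == win_off[..., :1]).all(axis=-1).mean()
        mono_on = (win_on == win_on[..., :1]).all(axis=-1).mean()
        assert mono_on < mono_off

    def test_poe_target_not_the_mixture(self):
        """Sampling the averaged model targets the product of experts, which
        is measurably different from the per-model mixture."""
        h1 = np.array([[0.0, 4.0, 4.0], [0.0, 4.0, 4.0]])
        h2 = np.array([[4.0, 0.0, 4.0], [4.0, 0.0, 4.0]])
        m1, m2 = PottsModel(h1), PottsModel(h2)
        avg = average_models([m1, m2])
        poe = enumerate_distribution(avg).probabilities
        mixture = 0.5 * (
            enumerate_distribution(m1).probabilities
            + enumerate_distribution(m2).probabilities
        )
        assert np.abs(poe - mixture).sum() / 2 > 0.1
        cfg = SamplerConfig(seed=9, burn_in=300, thinning=1)
        samples, _ = gibbs_sample(avg, cfg, LCPConfig(), 20_000)
        idx = np.ravel_multi_index(samples.T, (3, 3))
        emp = np.bincount(idx, minlength=9) / len(samples)
        assert np.abs(emp - poe).sum() / 2 < 0.02
        assert np.abs(emp - mixture).sum() / 2 > 0.08


class TestLogitCombination:
    def test_single_set_is_softmax(self):
        logits = np.array([1.0, 2.0, 0.5])
        p = geometric_mean_combine([logits])
        expect = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(p, expect, atol=1e-12)

    def test_identical_sets_idempotent(self):
        logits = np.array([1.0, -2.0, 0.5])
        p1 = geometric_mean_combine([logits])
        pk = geometric_mean_combine([logits] * 5)
        np.testing.assert_allclose(p1, pk, atol=1e-14)

    def test_symmetric_pair_gives_uniform(self):
        p = geometric_mean_combine([np.array([0.0, 1.0]), np.array([1.0, 0.0])])
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)
        # explicit geometric-mean-then-normalize route
        pa = np.exp([0.0, 1.0]) / np.exp([0.0, 1.0]).sum()
        pb = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        geo = np.sqrt(pa * pb)
        np.testing.assert_allclose(p, geo / geo.sum(), atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            geometric_mean_combine(np.empty((0, 3)))


class TestTiedDecode:
    def test_zero_model_uniform_iid(self):
        m = PottsModel(np.zeros((4, 3)))
        draws = np.stack(
            [
                tied_conditional_decode(
                    [m], [0, 1, 2, 3], SamplerConfig(seed=s)
                ).residues
                for s in range(3000)
            ]
        )
        freqs = np.bincount(draws.ravel(), minlength=3) / draws.size
        np.testing.assert_allclose(freqs, 1 / 3, atol=0.02)

    def test_identical_models_match_single(self):
        m = make_random_potts(5, 3, 0.6, seed=1)
        cfg = SamplerConfig(seed=4)
        one = tied_conditional_decode([m], [3, 0, 4, 1, 2], cfg)
        many = tied_conditional_decode([m, m, m], [3, 0, 4, 1, 2], cfg)
        np.testing.assert_array_equal(one.residues, many.residues)

    def test_first_site_marginal_matches_combined_conditional(self):
        m1 = make_random_potts(2, 3, 1.0, field_scale=1.0, seed=2)
        m2 = make_random_potts(2, 3, 1.0, field_scale=1.0, seed=3)
        expect = geometric_mean_combine([-m1.h[0], -m2.h[0]])
        draws = np.array(
            [
                tied_conditional_decode([m1, m2], [0, 1], SamplerConfig(seed=s))
                .residues[0]
                for s in range(6000)
            ]
        )
        emp = np.bincount(draws, minlength=3) / len(draws)
        assert np.abs(emp - expect).sum() / 2 < 0.03

    def test_invalid_permutation(self):
        m = make_random_potts(3, 3, 0.5, seed=0)
        with pytest.raises(ContractError):
            tied_conditional_decode([m], [0, 0, 2], SamplerConfig(seed=0))
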