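"""Potts core: energies, averaging, enumeration, gauge, serialization."""

import numpy as np
import pytest
from scipy.special import logsumexp

from ensdesign.fixtures import make_random_potts
from ensdesign.potts import (
    Alphabet,
    ContractError,
    PottsModel,
    SequenceState,
    apply_zero_sum_gauge,
    average_models,
    energy,
    enumerate_distribution,
    load_potts_json,
    save_potts_json,
    site_substitution_energies,
)

from conftest import loop_energy, random_seq


class TestAlphabet:
    def test_default_is_20_canonical(self):
        a = Alphabet()
        assert a.size == 20
        assert a.index(a.symbols[7]) == 7

    def test_rejects_duplicates_and_unknown(self):
        with pytest.raises(ContractError):
            Alphabet("AAC")
        with pytest.raises(ContractError):
            Alphabet("AC").index("W")

    def test_encode_decode_roundtrip(self):
        a = Alphabet()
        s = a.encode("ACDEFGHIKLMNPQRSTVWY")
        assert str(s) == "ACDEFGHIKLMNPQRSTVWY"


class TestEnergy:
    def test_zero_model_gives_zero(self, rng):
        m = PottsModel(np.zeros((6, 4)), {(0, 3): np.zeros((4, 4))})
        assert energy(m, random_seq(m, rng)) == 0.0

    def test_single_site_field_lookup(self):
        m = PottsModel(np.array([[0.0, 1.0]]))
        assert energy(m, SequenceState(np.array([1]), m.alphabet)) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_term_by_term_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = make_random_potts(5, 4, edge_density=0.7, seed=seed)
        for _ in range(20):
            s = random_seq(m, rng)
            assert energy(m, s) == pytest.approx(loop_energy(m, s), abs=1e-12)

    def test_length_mismatch_rejected(self, small_model):
        bad = SequenceState(np.zeros(3, dtype=int), small_model.alphabet)
        with pytest.raises(ContractError):
            energy(small_model, bad)


class TestSiteSubstitution:
    def test_zero_model_all_zero(self, rng):
        m = PottsModel(np.zeros((4, 3)))
        s = random_seq(m, rng)
        assert np.all(site_substitution_energies(m, s, 2) == 0.0)

    def test_identity_substitution_equals_energy(self, small_model, rng):
        s = random_seq(small_model, rng)
        for site in range(small_model.L):
            v = site_substitution_energies(small_model, s, site)
            assert v[s.residues[site]] == pytest.approx(energy(small_model, s))

    def test_matches_naive_full_recomputation(self, rng):
        m = make_random_potts(6, 4, edge_density=0.5, seed=9)
        s = random_seq(m, rng)
        for site in range(m.L):
            v = site_substitution_energies(m, s, site)
            naive = [energy(m, s.with_site(site, a)) for a in range(m.A)]
            np.testing.assert_allclose(v, naive, atol=1e-10)

    def test_site_out_of_range(self, small_model, rng):
        with pytest.raises(ContractError):
            site_substitution_energies(small_model, random_seq(small_model, rng), 99)


class TestAverageModels:
    def test_identical_copies_idempotent(self, small_model):
        avg = average_models([small_model] * 4)
        np.testing.assert_allclose(avg.h, small_model.h, atol=1e-12)
        for e in small_model.couplings:
            np.testing.assert_allclose(
                avg.couplings[e], small_model.couplings[e], atol=1e-12
            )

    def test_single_model_unchanged(self, small_model):
        avg = average_models([small_model])
        np.testing.assert_array_equal(avg.h, small_model.h)

    def test_disjoint_edges_energy_is_mean(self):
        m1 = PottsModel(np.zeros((5, 3)), {(0, 1): np.ones((3, 3))})
        m2 = PottsModel(np.zeros((5, 3)), {(2, 4): 2 * np.ones((3, 3))})
        avg = average_models([m1, m2])
        assert set(avg.couplings) == {(0, 1), (2, 4)}
        for s in enumerate_distribution(avg).sequences():
            seq = SequenceState(s, avg.alphabet)
            expect = 0.5 * (energy(m1, seq) + energy(m2, seq))
            assert energy(avg, seq) == pytest.approx(expect, abs=1e-9)

    def test_weighted_linearity(self, rng):
        models = [make_random_potts(4, 3, 0.5, seed=s) for s in range(3)]
        w = [0.5, 0.3, 0.2]
        avg = average_models(models, w)
        for _ in range(30):
            seq = random_seq(avg, rng)
            expect = sum(wk * energy(m, seq) for wk, m in zip(w, models))
            assert energy(avg, seq) == pytest.approx(expect, abs=1e-9)

    def test_invalid_inputs(self, small_model):
        with pytest.raises(ContractError):
            average_models([])
        with pytest.raises(ContractError):
            average_models([small_model, make_random_potts(3, 4, seed=0)])
        with pytest.raises(ContractError):
            average_models([small_model, small_model], [0.9, 0.9])


class TestEnumeration:
    def test_zero_model_uniform(self):
        m = PottsModel(np.zeros((3, 3)))
        d = enumerate_distribution(m)
        np.testing.assert_allclose(d.probabilities, 1 / 27, atol=1e-12)

    def test_single_site_softmax(self):
        m = PottsModel(np.array([[0.0, 1.0]]))
        d = enumerate_distribution(m)
        expect = np.exp([0.0, -1.0])
        expect /= expect.sum()
        np.testing.assert_allclose(d.probabilities, expect, atol=1e-9)
        assert d.probabilities[0] == pytest.approx(0.7311, abs=1e-4)

    def test_probabilities_sum_to_one_and_gauge_shift(self, small_model):
        d = enumerate_distribution(small_model)
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        shifted = small_model.copy()
        shifted.h[2] += 7.5  # constant shift of one site's fields
        d2 = enumerate_distribution(shifted)
        np.testing.assert_allclose(d.probabilities, d2.probabilities, atol=1e-9)
        assert d2.log_z == pytest.approx(d.log_z - 7.5, abs=1e-9)

    def test_no_overflow_for_large_energies(self):
        m = PottsModel(np.array([[0.0, 700.0], [0.0, -700.0]]))
        d = enumerate_distribution(m)
        assert np.all(np.isfinite(d.probabilities))
        assert d.probabilities.sum() == pytest.approx(1.0)

    def test_cap_refusal_names_cap(self):
        m = make_random_potts(12, 4, 0.1, seed=0)
        with pytest.raises(ContractError, match="cap"):
            enumerate_distribution(m, cap=10**5)


class TestZeroSumGauge:
    def test_couplings_have_zero_marginals(self):
        m = make_random_potts(4, 3, edge_density=1.0, seed=5)
        g = apply_zero_sum_gauge(m)
        for block in g.couplings.values():
            np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-12)

    def test_distribution_preserved(self):
        m = make_random_potts(4, 3, edge_density=1.0, seed=6)
        tv = (
            np.abs(
                enumerate_distribution(m).probabilities
                - enumerate_distribution(apply_zero_sum_gauge(m)).probabilities
            ).sum()
            / 2
        )
        assert tv < 1e-9

    def test_idempotent(self):
        m = make_random_potts(4, 3, edge_density=1.0, seed=7)
        g1 = apply_zero_sum_gauge(m)
        g2 = apply_zero_sum_gauge(g1)
        np.testing.assert_allclose(g1.h, g2.h, atol=1e-12)
        for e in g1.couplings:
            np.testing.assert_allclose(g1.couplings[e], g2.couplings[e], atol=1e-12)

    def test_zero_model_stays_zero(self):
        g = apply_zero_sum_gauge(PottsModel(np.zeros((3, 4))))
        assert np.all(g.h == 0.0)


class TestPottsJson:
    def test_roundtrip_bit_exact(self, small_model, tmp_path):
        p = tmp_path / "m.json"
        save_potts_json(small_model, p)
        back = load_potts_json(p)
        np.testing.assert_array_equal(back.h, small_model.h)
        assert back.edges == small_model.edges
        for e in small_model.couplings:
            np.testing.assert_array_equal(back.couplings[e], small_model.couplings[e])
        assert back.alphabet.symbols == small_model.alphabet.symbols

    def test_invalid_edge_rejected(self):
        with pytest.raises(ContractError):
            PottsModel(np.zeros((3, 2)), {(2, 1): np.zeros((2, 2))})
        with pytest.raises(ContractError):
            PottsModel(np.zeros((3, 2)), {(0, 5): np.zeros((2, 2))})

    def test_coupling_accessor_transposes(self, small_model):
        i, j = small_model.edges[0]
        np.testing.assert_array_equal(
            small_model.coupling(j, i), small_model.coupling(i, j).T
        )
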