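"""Disequilibrium statistics: F_IS, R', mixture maxima, expected T-score
distributions and the Monte-Carlo exact test — each checked against an
independent oracle (closed form, brute-force enumeration or permutation)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from musselmix.diseq import (TScoreDistribution, expected_tscore_mixture,
                             expected_tscore_panmixia, fis, mc_exact_test,
                             mixture_maxima, r_prime)
from musselmix.genotypes import build_registry, pooled_from_dosages

from conftest import make_dosage_frame


def biallelic_reg(f_me, f_mt, loci=None):
    loci = loci or [f"L{i+1}" for i in range(len(f_me))]
    me = {l: {"e": 1 - a, "t": a} for l, a in zip(loci, f_me)}
    mt = {l: {"e": 1 - b, "t": b} for l, b in zip(loci, f_mt)}
    return build_registry(me, mt)


class TestFis:
    def test_complete_mixture_gives_one(self):
        d = np.array([[0] * 4] * 5 + [[2] * 4] * 5, dtype=float)
        per_locus, mean = fis(make_dosage_frame(d))
        assert np.allclose(per_locus, 1.0)
        assert mean == pytest.approx(1.0)

    def test_all_heterozygotes_give_minus_one(self):
        d = np.ones((6, 4))
        _, mean = fis(make_dosage_frame(d))
        assert mean == pytest.approx(-1.0)

    def test_hwe_sample_near_zero(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.5, size=(5000, 4)).astype(float)
        _, mean = fis(make_dosage_frame(d))
        assert abs(mean) < 0.05

    def test_monomorphic_locus_excluded_with_warning(self):
        d = np.column_stack([np.zeros(6), np.ones(6)])
        with pytest.warns(UserWarning, match="monomorphic"):
            per_locus, mean = fis(make_dosage_frame(d, ["mono", "het"]))
        assert np.isnan(per_locus["mono"])
        assert mean == pytest.approx(-1.0)

    def test_matches_bruteforce_genotype_counting(self):
        # independent recount on a tiny fixture
        d = np.array([[0, 2], [1, 1], [2, 0], [1, 2], [0, 1], [2, 2]], dtype=float)
        per_locus, _ = fis(make_dosage_frame(d, ["A", "B"]))
        for j, locus in enumerate(["A", "B"]):
            col = d[:, j]
            h_obs = sum(1 for x in col if x == 1) / len(col)
            p = sum(col) / (2 * len(col))
            expected = 1 - h_obs / (2 * p * (1 - p))
            assert per_locus[locus] == pytest.approx(expected)


class TestRPrime:
    def test_perfect_association(self):
        d = np.array([[2] * 4] * 5 + [[0] * 4] * 5, dtype=float)
        per_pair, mean = r_prime(make_dosage_frame(d))
        assert np.allclose(per_pair, 1.0)
        assert mean == pytest.approx(1.0)

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(5)
        d = np.column_stack([rng.permutation(np.repeat([0, 1, 2], 700))
                             for _ in range(4)]).astype(float)
        _, mean = r_prime(make_dosage_frame(d))
        assert abs(mean) < 0.05

    def test_equals_burrows_composite_oracle(self):
        # fold in the within-locus departure terms by explicit matrix arithmetic
        d = np.array([[0, 0], [1, 2], [2, 2], [1, 0], [2, 1], [0, 1]], dtype=float)
        per_pair, _ = r_prime(make_dosage_frame(d, ["A", "B"]))
        x, y = d[:, 0], d[:, 1]
        n = len(x)
        delta = (x @ y / n - x.mean() * y.mean()) / 2  # Burrows composite
        def pq_plus_D(v):
            p = v.sum() / (2 * n)
            f_hom = np.mean(v == 2)
            return p * (1 - p) + (f_hom - p ** 2)
        oracle = delta / np.sqrt(pq_plus_D(x) * pq_plus_D(y))
        assert per_pair["A:B"] == pytest.approx(oracle)

    def test_monomorphic_pair_excluded(self):
        d = np.column_stack([np.zeros(6), [0, 1, 2, 1, 0, 2], [2, 1, 0, 1, 2, 0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            per_pair, _ = r_prime(make_dosage_frame(d, ["m", "a", "b"]))
        assert np.isnan(per_pair["m:a"])
        assert not np.isnan(per_pair["a:b"])


class TestMixtureMaxima:
    def test_fully_diagnostic_fifty_fifty(self):
        reg = biallelic_reg([0.0] * 4, [1.0] * 4)
        fis_max, r_max, m = mixture_maxima({l: 0.5 for l in reg.loci}, reg)
        assert fis_max == pytest.approx(1.0)
        assert r_max == pytest.approx(1.0)
        assert m == pytest.approx(0.5)

    def test_partial_refs_closed_form(self):
        reg = biallelic_reg([0.1], [0.9], ["L"])
        fis_max, _, m = mixture_maxima({"L": 0.5}, reg)
        assert m == pytest.approx(0.5)
        assert fis_max == pytest.approx(1 - 0.18 / 0.5)

    @pytest.mark.parametrize("m_true", [0.0, 1.0])
    def test_pure_sample_has_zero_maxima(self, m_true):
        reg = biallelic_reg([0.1] * 4, [0.9] * 4)
        obs = {l: 0.1 + 0.8 * m_true for l in reg.loci}
        fis_max, r_max, m = mixture_maxima(obs, reg)
        assert m == pytest.approx(m_true)
        assert fis_max == pytest.approx(0.0, abs=1e-12)
        assert r_max == pytest.approx(0.0, abs=1e-12)

    def test_maximized_near_even_mixture(self):
        reg = biallelic_reg([0.1] * 4, [0.9] * 4)
        vals = []
        for m in (0.1, 0.3, 0.5, 0.7, 0.9):
            obs = {l: 0.1 + 0.8 * m for l in reg.loci}
            vals.append(mixture_maxima(obs, reg)[0])
        assert vals[2] == max(vals)

    def test_simulated_mixture_recovers_maxima(self):
        # empirical F_IS/R' of a 50:50 non-interbreeding mixture converge
        # to the computed maxima
        rng = np.random.default_rng(21)
        reg = biallelic_reg([0.1] * 4, [0.9] * 4)
        n = 4000
        d_me = rng.binomial(2, 0.1, size=(n // 2, 4))
        d_mt = rng.binomial(2, 0.9, size=(n // 2, 4))
        d = np.vstack([d_me, d_mt]).astype(float)
        pooled = make_dosage_frame(d)
        _, fis_emp = fis(pooled)
        _, r_emp = r_prime(pooled)
        fis_max, r_max, _ = mixture_maxima(dict(zip(pooled.loci,
                                                    d.mean(axis=0) / 2)), reg)
        assert fis_emp == pytest.approx(fis_max, abs=0.05)
        assert r_emp == pytest.approx(r_max, abs=0.05)


def enumerate_panmixia(t_freqs):
    """Independent 3^L enumeration oracle for the panmictic score pmf."""
    L = len(t_freqs)
    out = np.zeros(2 * L + 1)
    for combo in itertools.product((0, 1, 2), repeat=L):
        p = 1.0
        for d, t in zip(combo, t_freqs):
            p *= binom.pmf(d, 2, t)
        out[sum(combo)] += p
    return out


class TestExpectedDistributions:
    def test_single_locus_half(self):
        dist = expected_tscore_panmixia([0.5])
        assert np.allclose(dist.probabilities, [0.25, 0.5, 0.25])

    def test_four_loci_half_is_binomial8(self):
        dist = expected_tscore_panmixia([0.5] * 4)
        assert dist.probabilities[4] == pytest.approx(70 / 256)
        assert np.allclose(dist.probabilities, binom.pmf(np.arange(9), 8, 0.5))

    def test_zero_freq_point_mass(self):
        dist = expected_tscore_panmixia([0.0] * 4)
        assert dist.probabilities[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [(0.1, 0.4, 0.6, 0.9), (0.05, 0.05, 0.9, 0.5)])
    def test_convolution_equals_enumeration(self, t):
        dist = expected_tscore_panmixia(list(t))
        assert np.allclose(dist.probabilities, enumerate_panmixia(t), atol=1e-12)

    def test_mean_identity(self):
        t = [0.12, 0.55, 0.8, 0.33]
        dist = expected_tscore_panmixia(t)
        assert dist.mean() == pytest.approx(2 * sum(t))

    def test_mixture_m0_is_me_reference(self):
        reg = biallelic_reg([0.1] * 4, [0.9] * 4)
        d0 = expected_tscore_mixture(0.0, reg)
        ref = expected_tscore_panmixia([0.1] * 4)
        assert np.allclose(d0.probabilities, ref.probabilities)

    def test_mixture_diagnostic_bimodal(self):
        reg = biallelic_reg([0.0] * 4, [1.0] * 4)
        d = expected_tscore_mixture(0.5, reg)
        assert d.probabilities[0] == pytest.approx(0.5)
        assert d.probabilities[8] == pytest.approx(0.5)
        assert np.allclose(d.probabilities[1:8], 0.0)

    def test_mixture_matches_two_component_enumeration(self):
        reg = biallelic_reg([0.1] * 4, [0.9] * 4)
        m = 0.3
        d = expected_tscore_mixture(m, reg)
        oracle = m * enumerate_panmixia([0.9] * 4) + (1 - m) * enumerate_panmixia([0.1] * 4)
        assert np.allclose(d.probabilities, oracle, atol=1e-12)

    def test_distribution_validation(self):
        with pytest.raises(ValueError):
            TScoreDistribution(np.array([0.5, 0.4]), "empirical")


class TestMcExactTest:
    def test_perfect_fit_p_one(self):
        expected = expected_tscore_panmixia([0.5] * 2)  # (1,4,6,4,1)/16
        observed = expected.probabilities * 16
        res = mc_exact_test(observed, expected, n_reps=500, seed=1)
        assert res.chi2_observed == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_maximal_discrepancy(self):
        expected = expected_tscore_panmixia([0.0] * 4)  # point mass at 0
        observed = np.zeros(9)
        observed[8] = 20
        res = mc_exact_test(observed, expected, n_reps=2000, seed=2)
        assert res.p_value == pytest.approx(1 / 2001)

    def test_seed_required(self):
        expected = expected_tscore_panmixia([0.5])
        with pytest.raises(ValueError, match="seed"):
            mc_exact_test([1, 2, 1], expected)

    def test_null_rejection_rate_quick(self):
        # super-uniformity under the null, small trial count
        rng = np.random.default_rng(3)
        expected = expected_tscore_panmixia([0.3, 0.5, 0.7, 0.4])
        rejections = 0
        trials = 200
        for k in range(trials):
            obs = rng.multinomial(60, expected.probabilities)
            res = mc_exact_test(obs, expected, n_reps=400, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert rejections / trials < 0.10
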