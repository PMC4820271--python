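"""Pooling, T-score and T-frequency behaviour of the genotype core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from musselmix.genotypes import (UnresolvableAlleleError, build_registry, pool,
                                 pooled_from_dosages, t_frequency, t_score,
                                 allele_frequencies)

from conftest import make_dosage_frame


class TestBuildRegistry:
    def test_two_allele_locus(self):
        reg = build_registry({"L": {"a": 0.9, "b": 0.1}}, {"L": {"a": 0.1, "b": 0.9}})
        assert reg.pooling["L"] == {"a": "E", "b": "T"}
        assert reg.ref_t.loc["L", "ME"] == pytest.approx(0.1)
        assert reg.ref_t.loc["L", "MT"] == pytest.approx(0.9)

    def test_three_allele_locus_pairwise(self):
        reg = build_registry({"L": {"a": 0.8, "b": 0.15, "c": 0.05}},
                             {"L": {"a": 0.05, "b": 0.05, "c": 0.90}})
        assert reg.pooling["L"] == {"a": "E", "b": "E", "c": "T"}

    def test_tie_goes_to_E_with_warning(self):
        with pytest.warns(UserWarning, match="equal reference"):
            reg = build_registry({"L": {"a": 0.3, "b": 0.3, "c": 0.4}},
                                 {"L": {"a": 0.3, "b": 0.1, "c": 0.6}})
        assert reg.pooling["L"]["a"] == "E"
        assert reg.pooling["L"]["c"] == "T"

    def test_bad_frequency_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            build_registry({"L": {"a": 0.5, "b": 0.4}}, {"L": {"a": 0.1, "b": 0.9}})


class TestPool:
    def test_dosages(self, small_table, biallelic_registry):
        reg = biallelic_registry  # 110 -> T, 100 -> E
        pooled = pool(small_table, reg)
        # i1 all (110,110) -> 2; i2 all het -> 1; i3 hom E -> 0 with missing L4
        assert pooled.dosage[0].tolist() == [2, 2, 2, 2]
        assert pooled.dosage[1].tolist() == [1, 1, 1, 1]
        assert pooled.dosage[2][0] == 0 and np.isnan(pooled.dosage[2][3])

    def test_unresolvable_allele_raises(self, small_table):
        reg = build_registry({"L1": {"100": 1.0}, "L2": {"100": 1.0},
                              "L3": {"100": 1.0}, "L4": {"100": 1.0}},
                             {"L1": {"100": 0.0, "999": 1.0}, "L2": {"100": 0.0, "999": 1.0},
                              "L3": {"100": 0.0, "999": 1.0}, "L4": {"100": 0.0, "999": 1.0}})
        with pytest.raises(UnresolvableAlleleError, match="110"):
            pool(small_table, reg)

    @given(st.lists(st.lists(st.sampled_from([0, 1, 2]), min_size=4, max_size=4),
                    min_size=1, max_size=20))
    def test_pooling_conserves_allele_counts(self, rows):
        # per locus, T-count + E-count = 2 x individuals
        d = np.asarray(rows, dtype=float)
        t_counts = d.sum(axis=0)
        e_counts = (2 - d).sum(axis=0)
        assert np.allclose(t_counts + e_counts, 2 * len(rows))


class TestTScore:
    @pytest.mark.parametrize("dosages,score,n_loci", [
        ([2, 2, 2, 2], 8, 4),
        ([1, 1, 1, 1], 4, 4),
        ([2, 1, 0, np.nan], 3, 3),
    ])
    def test_examples(self, dosages, score, n_loci):
        pooled = make_dosage_frame([dosages])
        hi = t_score(pooled)
        assert hi["t_score"].iloc[0] == score
        assert hi["n_loci_scored"].iloc[0] == n_loci

    def test_all_missing_flagged_unscorable(self):
        pooled = make_dosage_frame([[np.nan] * 4, [1, 1, 1, 1]])
        hi = t_score(pooled)
        assert not hi["scorable"].iloc[0]
        assert hi["scorable"].iloc[1]

    def test_matches_bruteforce_recount_from_raw_labels(self, small_table,
                                                        biallelic_registry):
        pooled = pool(small_table, biallelic_registry)
        hi = t_score(pooled)
        for i, iid in enumerate(small_table.ids):
            manual = 0
            for j, locus in enumerate(small_table.loci):
                cell = small_table.alleles[i, j]
                if cell[0] is None:
                    continue
                manual += sum(biallelic_registry.pooling[locus][a] == "T"
                              for a in cell)
            assert hi.loc[iid, "t_score"] == manual

    def test_bounds_invariant(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(50, 4)).astype(float)
        d[rng.random((50, 4)) < 0.2] = np.nan
        hi = t_score(make_dosage_frame(d))
        ok = hi["scorable"]
        assert (hi.loc[ok, "t_score"] <= 2 * hi.loc[ok, "n_loci_scored"]).all()
        assert (hi.loc[ok, "t_score"] >= 0).all()


class TestTFrequency:
    def test_reference_endpoints(self, biallelic_registry):
        # every individual homozygous E except enough hets to hit the ME ref
        reg = biallelic_registry  # refs 0.1 / 0.9 everywhere
        d_me = np.tile([1, 0, 0, 0, 0, 0, 0, 0, 0, 1], (4, 1)).T  # p = 0.1
        pooled = pooled_from_dosages(d_me.astype(float), reg.loci, reg)
        assert t_frequency(pooled) == pytest.approx(0.0)
        pooled_mt = pooled_from_dosages((2 - d_me).astype(float), reg.loci, reg)
        assert t_frequency(pooled_mt) == pytest.approx(1.0)

    def test_midpoint_single_locus(self):
        reg = build_registry({"L": {"a": 0.9, "b": 0.1}}, {"L": {"a": 0.1, "b": 0.9}})
        pooled = pooled_from_dosages(np.array([[1.0], [1.0]]), ["L"], reg)
        assert t_frequency(pooled) == pytest.approx(0.5)

    def test_clipping_outside_reference_span(self):
        reg = build_registry({"L": {"a": 0.9, "b": 0.1}}, {"L": {"a": 0.1, "b": 0.9}})
        pooled = pooled_from_dosages(np.zeros((5, 1)), ["L"], reg)  # obs 0 < 0.1
        assert t_frequency(pooled) == 0.0

    def test_equals_rescaled_mean_dosage_for_diagnostic_refs(self, diag_freqs):
        reg = diag_freqs.registry()  # refs 0 / 1
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(40, 4)).astype(float)
        pooled = pooled_from_dosages(d, reg.loci, reg)
        assert t_frequency(pooled) == pytest.approx(float(np.mean(d / 2)))

    def test_monotone_in_observed_frequency(self):
        reg = build_registry({"L": {"a": 0.9, "b": 0.1}}, {"L": {"a": 0.1, "b": 0.9}})
        vals = []
        for k in range(11):
            d = np.array([[2.0]] * k + [[0.0]] * (10 - k))
            vals.append(t_frequency(pooled_from_dosages(d, ["L"], reg)))
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestAlleleFrequencies:
    def test_count_oracle(self, small_table, biallelic_registry):
        sub = small_table.subset(["i1", "i2", "i3", "i4"])
        af = allele_frequencies(sub, biallelic_registry)
        l1 = af[af["locus"] == "L1"].set_index("allele")
        # L1 alleles among i1..i4: 110,110 / 100,110 / 100,100 / 110,110
        assert l1.loc["110", "count"] == 5
        assert l1.loc["110", "freq"] == pytest.approx(5 / 8)

    def test_frequencies_sum_to_one(self, small_table):
        af = allele_frequencies(small_table)
        sums = af.groupby("locus")["freq"].sum()
        assert np.allclose(sums, 1.0)

    def test_empty_locus_omitted(self):
        from musselmix.genotypes import GenotypeTable
        t = GenotypeTable.from_records(
            ["L1", "L2"], [("i1", "s", "x", "unknown", [("100", "100"), None])])
        af = allele_frequencies(t)
        assert set(af["locus"]) == {"L1"}
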