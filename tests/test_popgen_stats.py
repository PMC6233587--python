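"""Allele frequencies, heterozygosities, PIC/PI, Botstein categories,
private alleles and transfer rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from palmssr.popgen_stats import (
    GenotypeTable,
    TransferMatrix,
    allele_frequencies,
    classify_pic,
    locus_stats,
    private_alleles,
    round_half_up,
    transfer_rates,
)
from palmssr.repeat_mining import ContractError
from palmssr.synthetic_data import (
    GenotypeConfig,
    LocusPlan,
    simulate_genotypes,
)

import pandas as pd


def _table(calls, groups=None, loci=None):
    calls = np.asarray(calls)
    n, m = calls.shape[0], calls.shape[1]
    return GenotypeTable(
        sample_ids=[f"s{i}" for i in range(n)],
        groups=groups or ["g1"] * n,
        loci=loci or [f"L{j}" for j in range(m)],
        calls=calls,
    )


class TestAlleleFrequencies:
    def test_simple_counting(self):
        table = _table([[[100, 100]], [[100, 103]]])
        freqs = allele_frequencies(table)
        assert freqs.overall["L0"].freqs == {100: 0.75, 103: 0.25}
        assert freqs.overall["L0"].n_typed == 2

    def test_missing_excluded_from_denominator(self):
        table = _table([[[100, 100]], [[0, 0]], [[100, 103]]])
        rec = allele_frequencies(table).overall["L0"]
        assert rec.n_typed == 2
        assert rec.freqs == {100: 0.75, 103: 0.25}

    def test_all_missing_locus_flagged_undefined(self):
        table = _table([[[0, 0]], [[0, 0]]])
        freqs = allele_frequencies(table)
        assert not freqs.overall["L0"].defined
        assert freqs.undefined_loci() == ["L0"]

    def test_matches_counting_oracle_on_random_table(self, rng):
        calls = rng.choice([0, 100, 103, 106, 109], size=(25, 6, 2))
        table = _table(calls)
        freqs = allele_frequencies(table)
        for j, locus in enumerate(table.loci):
            tally: dict[int, int] = {}
            n_typed = 0
            for i in range(25):
                a, b = calls[i, j]
                if a == 0 or b == 0:
                    continue
                n_typed += 1
                for x in (a, b):
                    tally[x] = tally.get(x, 0) + 1
            expected = {a: c / (2 * n_typed) for a, c in tally.items()}
            assert freqs.overall[locus].freqs == pytest.approx(expected)

    def test_frequencies_sum_to_one(self, small_table):
        table, _ = small_table
        freqs = allele_frequencies(table, by_group=True)
        for locus in table.loci:
            if freqs.overall[locus].defined:
                assert sum(freqs.overall[locus].freqs.values()) == pytest.approx(1.0)


class TestLocusStats:
    def test_equifrequent_biallelic_closed_forms(self):
        table = _table([[[100, 103]], [[103, 100]]])
        stats = locus_stats(allele_frequencies(table), table)["L0"]
        assert stats.he == pytest.approx(0.5)
        assert stats.ne == pytest.approx(2.0)
        assert stats.shannon == pytest.approx(math.log(2))
        assert stats.pic == pytest.approx(0.375)
        assert stats.pi == pytest.approx(0.375)
        assert stats.ho == 1.0

    def test_monomorphic_locus(self):
        table = _table([[[100, 100]], [[100, 100]]])
        stats = locus_stats(allele_frequencies(table), table)["L0"]
        assert stats.he == 0.0 and stats.ho == 0.0
        assert stats.ne == 1.0 and stats.pic == 0.0
        assert stats.pi == 1.0 and stats.shannon == 0.0
        assert stats.category == "null"

    def test_four_equifrequent_alleles(self):
        calls = [[[100, 103]], [[106, 109]], [[100, 106]], [[103, 109]]]
        table = _table(calls)
        stats = locus_stats(allele_frequencies(table), table)["L0"]
        assert stats.ne == pytest.approx(4.0)
        assert stats.shannon == pytest.approx(math.log(4))
        assert stats.pic == pytest.approx(0.703125)

    def test_unbiased_he_flag(self):
        table = _table([[[100, 103]], [[103, 100]]])
        stats = locus_stats(allele_frequencies(table), table, unbiased_he=True)["L0"]
        assert stats.he == pytest.approx(0.5 * 4 / 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.05, 1.0), min_size=1, max_size=6))
    def test_invariant_bounds(self, weights):
        p = np.array(weights) / sum(weights)
        from palmssr.popgen_stats import _stats_from_freqs

        ne, he, shannon, pic, pi = _stats_from_freqs(p)
        assert 0.0 <= he < 1.0
        assert ne >= 1.0 - 1e-12
        assert pic <= he + 1e-12
        assert 0.0 < pi <= 1.0 + 1e-12

    @pytest.mark.parametrize("p", [0.1 * k for k in range(1, 10)])
    def test_biallelic_pic_identity(self, p):
        # with two alleles PIC = He - 2 p^2 q^2
        from palmssr.popgen_stats import _stats_from_freqs

        q = 1.0 - p
        _, he, _, pic, _ = _stats_from_freqs(np.array([p, q]))
        assert pic == pytest.approx(he - 2 * p * p * q * q)

    def test_parameter_recovery_bias_below_two_percent(self, rng):
        cfg = GenotypeConfig(
            group_sizes={"g": 500},
            loci=[LocusPlan(n_alleles=4, divergence=0.0) for _ in range(20)],
            missing_rate=0.0,
        )
        table, truth = simulate_genotypes(cfg, rng)
        freqs = allele_frequencies(table)
        errors = [
            abs(freqs.overall[l].freqs.get(a, 0.0) - p)
            for l in table.loci
            for a, p in truth["ancestral"][l].items()
        ]
        assert max(np.mean(errors), 0.0) < 0.02


class TestClassifyPic:
    @pytest.mark.parametrize(
        "pic,category",
        [
            (0.50, "high"),
            (0.77, "high"),
            (0.49, "medium"),
            (0.25, "medium"),
            (0.24, "low"),
            (0.05, "low"),
            (0.0, "null"),
        ],
    )
    def test_boundaries(self, pic, category):
        assert classify_pic(pic) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            classify_pic(1.0)
        with pytest.raises(ContractError):
            classify_pic(-0.1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.999999))
    def test_partition_is_exhaustive(self, pic):
        assert classify_pic(pic) in {"high", "medium", "low", "null"}


class TestPrivateAlleles:
    def _grouped_table(self):
        calls = [
            [[100, 100], [200, 203]],
            [[100, 103], [200, 200]],
            [[100, 100], [200, 200]],
            [[100, 106], [200, 200]],
        ]
        return _table(calls, groups=["g1", "g1", "g2", "g2"])

    def test_single_group_support(self):
        table = self._grouped_table()
        freqs = allele_frequencies(table, by_group=True)
        priv = private_alleles(freqs)
        found = {(p.locus, p.allele, p.group) for p in priv}
        assert ("L0", 103, "g1") in found
        assert ("L0", 106, "g2") in found
        assert ("L1", 203, "g1") in found
        assert all(allele != 100 for _, allele, _ in found)

    def test_frequency_is_within_owner(self):
        table = self._grouped_table()
        priv = private_alleles(allele_frequencies(table, by_group=True))
        by_key = {(p.locus, p.allele): p.frequency for p in priv}
        assert by_key[("L0", 103)] == pytest.approx(0.25)

    def test_requires_two_groups(self):
        table = _table([[[100, 103]]])
        with pytest.raises(ContractError):
            private_alleles(allele_frequencies(table, by_group=True))

    def test_relabelling_invariance(self, small_table):
        table, _ = small_table
        priv1 = private_alleles(allele_frequencies(table, by_group=True))
        relabel = {"north": "B", "centre": "C", "south": "A"}
        table2 = GenotypeTable(
            sample_ids=table.sample_ids,
            groups=[relabel[g] for g in table.groups],
            loci=table.loci,
            calls=table.calls,
        )
        priv2 = private_alleles(allele_frequencies(table2, by_group=True))
        set1 = {(p.locus, p.allele, relabel[p.group], p.frequency) for p in priv1}
        set2 = {(p.locus, p.allele, p.group, p.frequency) for p in priv2}
        assert set1 == set2

    def test_matches_support_set_oracle(self, small_table):
        table, _ = small_table
        freqs = allele_frequencies(table, by_group=True)
        priv = {(p.locus, p.allele) for p in private_alleles(freqs)}
        oracle = set()
        for locus in table.loci:
            alleles = set()
            for g in freqs.by_group:
                alleles |= set(freqs.by_group[g][locus].freqs)
            for a in alleles:
                owners = [
                    g for g in freqs.by_group
                    if freqs.by_group[g][locus].freqs.get(a, 0.0) > 0
                ]
                if len(owners) == 1:
                    oracle.add((locus, a))
        assert priv == oracle


class TestTransferRates:
    def _matrix(self, counts, total=145):
        markers = [f"M{i}" for i in range(total)]
        rows = {
            sp: [1.0] * k + [0.0] * (total - k) for sp, k in counts.items()
        }
        return TransferMatrix(data=pd.DataFrame(rows, index=markers).T)

    def test_full_transfer(self):
        rates = transfer_rates(self._matrix({"sp": 145}))
        assert rates["sp"].percent_1dp == 100.0 and rates["sp"].percent_int == 100

    def test_published_style_rounding(self):
        rates = transfer_rates(self._matrix({"a": 117, "b": 144, "c": 143}))
        assert rates["a"].percent_1dp == 80.7
        assert rates["b"].percent_int == 99
        assert rates["c"].percent_1dp == 98.6  # 143/145 = 98.62

    def test_missing_counts_as_not_amplified(self):
        df = pd.DataFrame({"M1": [1.0], "M2": [np.nan], "M3": [0.0]}, index=["sp"])
        rates = transfer_rates(TransferMatrix(data=df))
        assert rates["sp"].amplified == 1
        assert rates["sp"].percent_1dp == pytest.approx(33.3)

    def test_counting_oracle_on_random_matrix(self, rng):
        vals = rng.integers(0, 2, size=(4, 50)).astype(float)
        df = pd.DataFrame(vals, index=[f"sp{i}" for i in range(4)],
                          columns=[f"M{j}" for j in range(50)])
        rates = transfer_rates(TransferMatrix(data=df))
        for i, sp in enumerate(df.index):
            count = int(vals[i].sum())
            assert rates[sp].amplified == count
            assert rates[sp].percent_1dp == pytest.approx(
                round_half_up(100 * count / 50, 1)
            )

    def test_round_half_up(self):
        assert round_half_up(98.62, 0) == 99.0
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(80.689655, 1) == 80.7
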