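"""Diversity estimators against hand values and an ANOVA-route oracle."""

import itertools
import math

import numpy as np
import pytest

from mscan.diversity_stats import (
    allelic_richness,
    expected_heterozygosity,
    trimmed_mean_fst,
    weir_cockerham,
    weir_cockerham_components,
)
from mscan.genotype_io import AlleleCountTable, GenotypeDataset


def table(counts, pops=None):
    pops = pops or [f"p{i}" for i in range(len(counts))]
    return AlleleCountTable(locus="X", populations=pops, counts=counts)


class TestExpectedHeterozygosity:
    @pytest.mark.parametrize("counts,expected", [
        ({1: 10}, 0.0),                       # monomorphic
        ({1: 2, 2: 2}, (4 / 3) * 0.5),        # hand evaluation: 0.6667
    ])
    def test_hand_values(self, counts, expected):
        assert expected_heterozygosity(table([counts]), 0) == pytest.approx(
            expected, abs=1e-9)

    def test_equifrequent_large_n_limit(self):
        got = expected_heterozygosity(table([{1: 5000, 2: 5000}]), 0)
        assert got == pytest.approx(0.5, abs=1e-4)

    def test_relabeling_invariance(self):
        a = table([{1: 3, 2: 5, 3: 2}])
        b = table([{9: 3, 4: 5, 70: 2}])
        assert expected_heterozygosity(a) == expected_heterozygosity(b)

    def test_undefined_below_two_copies(self):
        assert math.isnan(expected_heterozygosity(table([{1: 1}]), 0))


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        assert allelic_richness(table([{1: 8}]), g=4) == pytest.approx(1.0)

    def test_hand_value_matches_enumeration(self):
        # {A:5, B:5}, g=2: E[#alleles] = 1*P(same) + 2*P(diff)
        # = 20/45 + 2*25/45 = 14/9, and the estimator 2*(1 - C(5,2)/C(10,2))
        got = allelic_richness(table([{1: 5, 2: 5}]), g=2)
        assert got == pytest.approx(14 / 9, abs=1e-9)

    def test_g_equals_n_gives_observed_alleles(self):
        got = allelic_richness(table([{1: 4, 2: 3, 3: 3}]), g=10)
        assert got == pytest.approx(3.0)

    def test_monotone_in_g(self):
        t = table([{1: 6, 2: 3, 3: 1}])
        vals = [allelic_richness(t, g=g) for g in range(1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_oversized_g_skips_population(self):
        t = table([{1: 2, 2: 2}, {1: 10, 2: 10}])
        # g=10 exceeds population 1 (n=4): only population 2 contributes
        assert allelic_richness(t, g=10) == pytest.approx(
            allelic_richness(table([{1: 10, 2: 10}]), g=10))


def _ds_from_genotype_counts(pop_counts):
    """Build a 2-population, 2-allele dataset from (n11, n12, n22) per pop."""
    genotypes = []
    for (n11, n12, n22) in pop_counts:
        rows = ([[1, 1]] * n11) + ([[1, 2]] * n12) + ([[2, 2]] * n22)
        genotypes.append(np.array(rows, dtype=np.int64).reshape(-1, 1, 2))
    return GenotypeDataset(
        populations=[f"p{i}" for i in range(len(pop_counts))],
        loci=["L"], genotypes=genotypes)


def _anova_components(pop_counts):
    """Weir-Cockerham components via explicit sums of squares.

    An independent route: build the 0/1 gene-copy indicators for each
    allele and decompose their variance into populations / individuals
    within populations / copies within individuals.
    """
    n_i = np.array([sum(c) for c in pop_counts], dtype=float)
    r = len(pop_counts)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for allele in (1, 2):
        x = []  # per population: list of per-individual copy counts of allele
        for (n11, n12, n22) in pop_counts:
            dose = [2] * n11 + [1] * n12 + [0] * n22
            if allele == 2:
                dose = [2 - d for d in dose]
            x.append(np.array(dose, dtype=float))
        p_i = np.array([d.sum() / (2 * len(d)) for d in x])
        pbar = (n_i * p_i).sum() / n_i.sum()
        ssp = (2 * n_i * (p_i - pbar) ** 2).sum()
        ssi = sum((2 * (d / 2 - pi) ** 2).sum() for d, pi in zip(x, p_i))
        ssg = sum(((d == 1) * 0.5).sum() for d in x)  # within-individual SS
        msp = ssp / (r - 1)
        msi = ssi / (n_i.sum() - r)
        msg = ssg / n_i.sum()
        C += msg
        B += (msi - msg) / 2
        A += (msp - msi) / (2 * nc)
    return A, B, C


class TestWeirCockerham:
    def test_fixed_differences_give_one(self):
        ds = _ds_from_genotype_counts([(4, 0, 0), (0, 0, 4)])
        a, b, c = weir_cockerham_components(ds, "L")
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        doses = rng.choice([0, 1, 2], size=100, p=[0.25, 0.5, 0.25])
        n11 = int((doses == 2).sum()); n12 = int((doses == 1).sum())
        n22 = int((doses == 0).sum())
        half = (n11 // 2, n12 // 2, n22 // 2)
        other = (n11 - half[0], n12 - half[1], n22 - half[2])
        ds = _ds_from_genotype_counts([half, other])
        a, b, c = weir_cockerham_components(ds, "L")
        assert abs(a / (a + b + c)) < 0.05

    def test_exhaustive_small_tables_match_anova_oracle(self):
        """Closed-form variance components equal the sums-of-squares route
        on every 2-pop, 2-allele genotype table with <= 4 individuals."""
        configs = [
            (n11, n12, n22)
            for n11, n12, n22 in itertools.product(range(5), repeat=3)
            if 2 <= n11 + n12 + n22 <= 4
        ]
        checked = 0
        for pc in itertools.product(configs, repeat=2):
            ds = _ds_from_genotype_counts(list(pc))
            a1, b1, c1 = weir_cockerham_components(ds, "L")
            if math.isnan(a1):
                continue
            a2, b2, c2 = _anova_components(list(pc))
            assert a1 == pytest.approx(a2, abs=1e-10)
            assert b1 == pytest.approx(b2, abs=1e-10)
            assert c1 == pytest.approx(c2, abs=1e-10)
            checked += 1
        assert checked > 500

    def test_multilocus_ci_contains_point(self, neutral_small):
        _, ml = weir_cockerham(neutral_small, n_boot=200, rng=5)
        assert ml.ci_low <= ml.point <= ml.ci_high

    def test_monomorphic_locus_excluded(self):
        g1 = np.array([[[1, 1]], [[1, 1]]])
        g2 = np.array([[[1, 1]], [[1, 1]]])
        ds = GenotypeDataset(populations=["a", "b"], loci=["L"],
                             genotypes=[g1, g2])
        a, b, c = weir_cockerham_components(ds, "L")
        assert math.isnan(a)


class TestTrimmedMean:
    def test_hand_case(self):
        assert trimmed_mean_fst(range(1, 11), trim=0.30) == pytest.approx(5.5)

    def test_trim_zero_is_mean(self):
        vals = [0.1, 0.2, 0.4]
        assert trimmed_mean_fst(vals, trim=0.0) == pytest.approx(np.mean(vals))

    def test_equal_values(self):
        assert trimmed_mean_fst([0.2] * 10) == pytest.approx(0.2)

    def test_overtrim_errors(self):
        with pytest.raises(ValueError):
            trimmed_mean_fst([1.0, 2.0], trim=0.5)
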