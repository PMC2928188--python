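"""EM haplotype inference, multiallelic D', and the exact test."""

import numpy as np
import pytest
from scipy import stats

from mscan.genotype_io import GenotypeDataset, LocusInfo, MarkerMap
from mscan.ld_analysis import (
    em_haplotypes,
    ld_exact_test,
    ld_summary,
    multiallelic_dprime,
)
from mscan.synthetic_data import SweepConfig, simulate_sweep_forward


def ds_from_pairs(pairs_a, pairs_b):
    g = np.stack([
        np.stack([np.array(pairs_a)[:, 0], np.array(pairs_b)[:, 0]], axis=1),
        np.stack([np.array(pairs_a)[:, 1], np.array(pairs_b)[:, 1]], axis=1),
    ], axis=2)
    return GenotypeDataset(populations=["p"], loci=["A", "B"],
                           genotypes=[g.astype(np.int64)])


class TestDprime:
    def test_hand_case(self):
        h = np.array([[0.4, 0.1], [0.1, 0.4]])
        assert multiallelic_dprime(h) == pytest.approx(0.6)

    def test_complete_ld(self):
        assert multiallelic_dprime(np.array([[0.5, 0], [0, 0.5]])) == \
            pytest.approx(1.0)

    def test_equilibrium_zero(self):
        h = np.outer([0.3, 0.7], [0.2, 0.5, 0.3])
        assert multiallelic_dprime(h) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_undefined(self):
        assert np.isnan(multiallelic_dprime(np.array([[0.6, 0.4]])))

    def test_relabel_and_swap_invariance(self, rng):
        for _ in range(20):
            h = rng.dirichlet(np.ones(6)).reshape(2, 3)
            d = multiallelic_dprime(h)
            assert 0.0 <= d <= 1.0 + 1e-12
            assert multiallelic_dprime(h.T) == pytest.approx(d)
            perm = h[::-1, :][:, rng.permutation(3)]
            assert multiallelic_dprime(perm) == pytest.approx(d)


class TestEM:
    def test_phase_known_equals_gamete_counts(self):
        # no double heterozygotes: haplotypes countable directly
        pa = [(1, 1)] * 6 + [(1, 2)] * 4
        pb = [(1, 1)] * 6 + [(1, 1)] * 4
        hf = em_haplotypes(ds_from_pairs(pa, pb), "A", "B")
        # gametes: 12 (1,1) from homozygotes + 4 (1,1) + 4 (2,1)
        assert hf.h[0, 0] == pytest.approx(16 / 20)
        assert hf.h[1, 0] == pytest.approx(4 / 20)

    def test_single_double_het_matches_likelihood_grid(self):
        """One ambiguous individual among AABB/aabb homozygotes: EM phase
        weight matches a brute-force likelihood maximization over the one
        free haplotype frequency."""
        pa = [(1, 1)] * 5 + [(2, 2)] * 5 + [(1, 2)]
        pb = [(1, 1)] * 5 + [(2, 2)] * 5 + [(1, 2)]
        hf = em_haplotypes(ds_from_pairs(pa, pb), "A", "B", tol=1e-10)
        # brute force: by symmetry the MLE lives in the 1-parameter family
        # indexed by the phase split w of the single ambiguous individual
        grid = np.linspace(0, 1, 2001)
        best, best_ll = None, -np.inf
        for w in grid:
            counts = np.zeros((2, 2))
            counts[0, 0] = 10 + w
            counts[1, 1] = 10 + w
            counts[0, 1] = 1 - w
            counts[1, 0] = 1 - w
            h = counts / 22
            ll = (10 * np.log(h[0, 0]) + 10 * np.log(h[1, 1])
                  + np.log(h[0, 0] * h[1, 1] + h[0, 1] * h[1, 0]))
            if ll > best_ll:
                best, best_ll = h, ll
        assert np.abs(hf.h - best).max() < 1e-4
        assert hf.log_likelihood >= best_ll - 1e-6

    def test_equilibrium_recovers_product(self, rng):
        n = 200
        a = rng.choice([1, 2, 3], size=(n, 2), p=[0.5, 0.3, 0.2])
        b = rng.choice([1, 2], size=(n, 2), p=[0.6, 0.4])
        ds = ds_from_pairs(a, b)
        hf = em_haplotypes(ds, "A", "B")
        assert np.abs(hf.h - np.outer(hf.p, hf.q)).max() < 0.05

    def test_too_few_individuals(self):
        with pytest.raises(ValueError, match=">= 10"):
            em_haplotypes(ds_from_pairs([(1, 2)] * 5, [(1, 2)] * 5), "A", "B")


class TestExactTest:
    def test_fisher_2x2_oracle(self):
        p, se = ld_exact_test(np.array([[5, 0], [0, 5]]), mc_tables=100000,
                              rng=1)
        exact = 2 / 252
        assert abs(p - exact) < max(3 * se, 5e-4)

    def test_degenerate_tables(self):
        assert ld_exact_test(np.array([[3, 4, 5]]), rng=0)[0] == 1.0
        assert ld_exact_test(np.array([[2, 0], [3, 0]]), rng=0)[0] == 1.0

    def test_uniform_under_independence(self, rng):
        ps = []
        for _ in range(120):
            a = rng.choice(3, size=150, p=[0.5, 0.3, 0.2])
            b = rng.choice(3, size=150, p=[0.4, 0.4, 0.2])
            T = np.zeros((3, 3), dtype=int)
            np.add.at(T, (a, b), 1)
            p, _ = ld_exact_test(T, mc_tables=20000,
                                 rng=int(rng.integers(2**31 - 1)))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def linked_map():
    loci = [LocusInfo("M1", "1", 100, 200), LocusInfo("M2", "1", 900, 950)]
    loci += [LocusInfo(f"M{i}", str(i), 10, 20) for i in range(3, 11)]
    return MarkerMap(loci)


class TestSummary:
    def test_unlinked_no_contrast(self, linked_map, rng):
        cfg = SweepConfig(N=100, generations=30, s=0.0, c=[0.5] * 10,
                          mu=1e-4, n_pops=1, selected_pops=[], seed=17,
                          sample_sizes=[100])
        ds, _ = simulate_sweep_forward(cfg)
        out = ld_summary(ds, linked_map, mc_tables=5000, rng=3)
        assert out["n_syntenic"] == 1
        assert out["mannwhitney_p"] > 0.05 or (
            out["syntenic_mean_dprime"] <= out["nonsyntenic_mean_dprime"] + 0.2)

    def test_sweep_elevates_syntenic_ld(self, linked_map):
        """Two markers hitchhiking on the same selected site end up in LD
        with each other, lifting the syntenic group mean."""
        wins = 0
        reps = 5
        for rep in range(reps):
            # moderate selection and linkage keep the hitchhiking markers
            # polymorphic so D' stays defined
            cfg = SweepConfig(N=200, generations=50, s=0.3, h=1.0,
                              c=[0.03, 0.08] + [0.5] * 8, mu=1e-4,
                              n_pops=1, selected_pops=[0], seed=300 + rep,
                              sample_sizes=[100])
            ds, _ = simulate_sweep_forward(cfg)
            out = ld_summary(ds, linked_map, mc_tables=5000, rng=rep)
            if out["n_syntenic"] == 0 or np.isnan(out["syntenic_mean_dprime"]):
                continue
            wins += (out["syntenic_mean_dprime"]
                     > out["nonsyntenic_mean_dprime"])
        assert wins > reps / 2

    def test_pair_counts_match_enumeration(self, linked_map, rng):
        from mscan.genotype_io import enumerate_syntenic_pairs
        cfg = SweepConfig(N=80, generations=20, s=0.0, c=[0.5] * 10,
                          mu=1e-4, n_pops=1, selected_pops=[], seed=5,
                          sample_sizes=[80])
        ds, _ = simulate_sweep_forward(cfg)
        out = ld_summary(ds, linked_map, mc_tables=2000, rng=1)
        assert out["n_syntenic"] == len(enumerate_syntenic_pairs(linked_map))
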