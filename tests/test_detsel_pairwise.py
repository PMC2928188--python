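"""Divergence branch lengths, simulated envelopes, phenotype splits."""

import numpy as np
import pytest

from mscan.detsel_pairwise import (
    BranchLengths,
    NuisanceGrid,
    branch_lengths,
    flag_outliers,
    polled_vs_horned_split,
    simulate_envelope,
)
from mscan.genotype_io import GenotypeDataset
from mscan.synthetic_data import SweepConfig, simulate_sweep_forward


def pair_ds(alleles_a, alleles_b, loci=("L",)):
    ga = np.asarray(alleles_a, dtype=np.int64).reshape(-1, len(loci), 2)
    gb = np.asarray(alleles_b, dtype=np.int64).reshape(-1, len(loci), 2)
    return GenotypeDataset(populations=["a", "b"], loci=list(loci),
                           genotypes=[ga, gb])


class TestBranchLengths:
    def test_fixed_differences(self):
        ds = pair_ds([[1, 1]] * 10, [[2, 2]] * 10)
        bl = branch_lengths(ds, "a", "b", "L")
        assert bl.f1 == pytest.approx(1.0)
        assert bl.f2 == pytest.approx(1.0)

    def test_panmictic_near_zero(self, rng):
        f1s, f2s = [], []
        for _ in range(100):
            pool = rng.choice(6, size=200, p=[.3, .25, .2, .1, .1, .05]) + 1
            ds = pair_ds(pool[:100].reshape(50, 2), pool[100:].reshape(50, 2))
            bl = branch_lengths(ds, "a", "b", "L")
            f1s.append(bl.f1)
            f2s.append(bl.f2)
        assert abs(np.mean(f1s)) < 0.05
        assert abs(np.mean(f2s)) < 0.05

    def test_identity_oracle(self):
        """Small table vs direct identity-probability sums."""
        ds = pair_ds([[1, 1], [1, 2], [2, 2]], [[1, 1], [1, 1], [1, 2]])
        bl = branch_lengths(ds, "a", "b", "L")
        # pop a: counts {1:3, 2:3}, n=6; pop b: counts {1:5, 2:1}
        q1 = (3 * 2 + 3 * 2) / (6 * 5)
        q2 = (5 * 4 + 1 * 0) / (6 * 5)
        q12 = (3 / 6) * (5 / 6) + (3 / 6) * (1 / 6)
        assert bl.f1 == pytest.approx((q1 - q12) / (1 - q12))
        assert bl.f2 == pytest.approx((q2 - q12) / (1 - q12))

    def test_swap_exchanges_coordinates(self):
        ds = pair_ds([[1, 1], [1, 2], [2, 2]], [[1, 1], [1, 1], [1, 2]])
        ab = branch_lengths(ds, "a", "b", "L")
        ba = branch_lengths(ds, "b", "a", "L")
        assert (ab.f1, ab.f2) == (ba.f2, ba.f1)

    def test_monomorphic_skipped(self):
        ds = pair_ds([[1, 1]] * 5, [[1, 1]] * 5)
        assert branch_lengths(ds, "a", "b", "L") is None


class TestEnvelope:
    def test_degenerate_divergence_time_centers_at_origin(self):
        grid = NuisanceGrid(mu=(1e-3,), ancestral_ne=(5000.0,),
                            t0=(5000.0,), div_t=(1e-9,), n0=(500.0,))
        env = simulate_envelope(grid, sample_sizes=(40, 40), sims=300, rng=1)
        assert abs(np.mean(env.points[:, 0])) < 0.05
        assert abs(np.mean(env.points[:, 1])) < 0.05

    def test_centroid_grows_with_divergence_time(self):
        cents = []
        for t in (20.0, 200.0):
            grid = NuisanceGrid(mu=(1e-3,), ancestral_ne=(5000.0,),
                                t0=(5000.0,), div_t=(t,), n0=(100.0,))
            env = simulate_envelope(grid, sample_sizes=(40, 40), sims=300,
                                    rng=2)
            cents.append(env.points[:, :2].mean())
        assert cents[1] > cents[0]

    def test_coverage_near_nominal(self):
        """Held-out neutral replicates fall outside the 95% region about
        5% of the time."""
        env = simulate_envelope(NuisanceGrid(), sample_sizes=(38, 38),
                                sims=2500, rng=4)
        held = simulate_envelope(NuisanceGrid(), sample_sizes=(38, 38),
                                 sims=400, rng=9)
        obs = [BranchLengths(f"l{i}", p[0], p[1], 38, 38, int(p[2]))
               for i, p in enumerate(held.points)]
        flags = flag_outliers(obs, env)
        rate95 = np.mean([f[0.95] for f in flags.values()])
        rate99 = np.mean([f[0.99] for f in flags.values()])
        assert 0.01 < rate95 < 0.10
        assert rate99 < rate95 + 0.01

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_envelope(NuisanceGrid(mu=()), sample_sizes=(10, 10),
                              sims=10, rng=0)


class TestPhenotypeSplit:
    def test_nineteen_nineteen(self, rng):
        g1 = rng.integers(1, 4, size=(25, 2, 2))
        g2 = rng.integers(1, 4, size=(20, 2, 2))
        ds = GenotypeDataset(populations=["x", "y"], loci=["A", "B"],
                             genotypes=[g1, g2])
        labels = {
            "x": ["polled"] * 10 + ["horned"] * 10 + [None] * 5,
            "y": ["polled"] * 9 + ["horned"] * 9 + [None] * 2,
        }
        out = polled_vs_horned_split(ds, labels)
        assert out.populations == ["polled", "horned"]
        assert out.n_individuals == [19, 19]

    def test_single_class_errors(self):
        ds = GenotypeDataset(populations=["x"], loci=["A"],
                             genotypes=[np.ones((6, 1, 2), dtype=int)])
        with pytest.raises(ValueError, match="no individuals"):
            polled_vs_horned_split(ds, {"x": ["polled"] * 6})

    def test_small_class_errors(self):
        ds = GenotypeDataset(populations=["x"], loci=["A"],
                             genotypes=[np.ones((8, 1, 2), dtype=int)])
        with pytest.raises(ValueError, match=">= 5"):
            polled_vs_horned_split(
                ds, {"x": ["polled"] * 4 + ["horned"] * 4})


class TestPower:
    def test_swept_locus_outside_envelope(self):
        """A locus hitchhiking in population 1 only gains a large F_1 and
        leaves the neutral envelope in most replicates."""
        # nuisance cells chosen to match the scenario's neutral divergence
        # (t/N small), the way the nulls are tuned to the observed data
        grid = NuisanceGrid(mu=(1e-3, 1e-4), ancestral_ne=(5000.0,),
                            t0=(500.0, 5000.0), div_t=(50.0,),
                            n0=(150.0, 500.0))
        env = simulate_envelope(grid, sample_sizes=(80, 80), sims=1500,
                                rng=11)
        hits = 0
        reps = 6
        for rep in range(reps):
            cfg = SweepConfig(N=150, generations=60, s=0.5, h=1.0,
                              c=[0.001] + [0.5] * 9, mu=1e-4, n_pops=2,
                              selected_pops=[0], seed=700 + rep,
                              sample_sizes=[40, 40])
            ds, _ = simulate_sweep_forward(cfg)
            bl = branch_lengths(ds, "pop1", "pop2", "M1")
            if bl is None:
                hits += 1  # fully swept to monomorphism: extreme signal
                continue
            flags = flag_outliers([bl], env)
            hits += flags["M1"][0.95]
        assert hits > reps / 2
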