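"""Pairwise population-divergence outlier test (DetSel-style).

For two populations that split from a common ancestor, per-locus
population-specific divergence ("branch length") estimates

    F_i = (Q_i - Q_12) / (1 - Q_12)

are built from small-sample-corrected gene identities: Q_i the probability
two distinct gene copies within population i are identical in state, Q_12
the identity of one copy from each population. Neutral loci share the
demography, so their (F_1, F_2) pairs cluster; the joint null is simulated
by coalescent replicates of a split model (ancestor of size N_e, bottleneck
to N_0 at T_0 generations ago, split t generations ago, infinite-allele
mutation at rate mu) over a grid of nuisance parameters, binned by observed
allele number, with 95%/99% highest-density regions from a 2-D Gaussian
KDE. Loci outside the matching region are candidate selection targets.
The polled-vs-horned design splits labeled individuals (pooled across
source populations) into two phenotype subpopulations before testing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import msprime
import numpy as np
from scipy.stats import gaussian_kde

from .genotype_io import GenotypeDataset, allele_counts

logger = logging.getLogger("mscan")

__all__ = [
    "BranchLengths",
    "NuisanceGrid",
    "Envelope",
    "branch_lengths",
    "simulate_envelope",
    "flag_outliers",
    "polled_vs_horned_split",
]


@dataclass
class BranchLengths:
    locus: str
    f1: float
    f2: float
    n1: int
    n2: int
    k: int


@dataclass
class NuisanceGrid:
    """Null-model nuisance parameters; each replicate draws one cell."""

    mu: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    ancestral_ne: tuple[float, ...] = (500.0, 5000.0, 50000.0)
    t0: tuple[float, ...] = (50.0, 500.0, 5000.0)
    div_t: tuple[float, ...] = (50.0, 500.0)
    n0: tuple[float, ...] = (50.0, 500.0)

    def cells(self):
        return list(itertools.product(self.mu, self.ancestral_ne, self.t0,
                                      self.div_t, self.n0))


@dataclass
class Envelope:
    """Simulated (F1, F2) null points binned by allele count."""

    points: np.ndarray       # (n, 3): f1, f2, k
    k_bins: list[tuple[int, int]]
    bin_of: dict[int, int]   # k value -> bin index
    sample_sizes: tuple[int, int]
    kdes: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)  # (bin, level) -> density


def _identities(counts1: dict[int, int], counts2: dict[int, int]):
    """(Q1, Q2, Q12) with within-population identities bias-corrected."""
    n1 = sum(counts1.values())
    n2 = sum(counts2.values())
    q1 = (sum(c * c for c in counts1.values()) - n1) / (n1 * (n1 - 1))
    q2 = (sum(c * c for c in counts2.values()) - n2) / (n2 * (n2 - 1))
    alleles = set(counts1) | set(counts2)
    q12 = sum((counts1.get(a, 0) / n1) * (counts2.get(a, 0) / n2)
              for a in alleles)
    return q1, q2, q12


def branch_lengths(
    ds: GenotypeDataset, pop_a, pop_b, locus: str
) -> BranchLengths | None:
    """Moment estimators (F1, F2) for one locus and one population pair.

    Returns None (with a warning) when the locus is monomorphic in the
    pooled pair or the between-population identity equals 1, where the
    estimator is undefined.
    """
    tab = allele_counts(ds, locus)
    ia, ib = ds.pop_index(pop_a), ds.pop_index(pop_b)
    c1, c2 = tab.counts[ia], tab.counts[ib]
    n1, n2 = sum(c1.values()), sum(c2.values())
    if n1 < 2 or n2 < 2:
        return None
    k = len(set(c1) | set(c2))
    if k < 2:
        logger.warning("branch_lengths: %s monomorphic in pair; skipped",
                       locus)
        return None
    q1, q2, q12 = _identities(c1, c2)
    if q12 >= 1.0:
        logger.warning("branch_lengths: %s has Q12=1; skipped", locus)
        return None
    f1 = (q1 - q12) / (1 - q12)
    f2 = (q2 - q12) / (1 - q12)
    return BranchLengths(locus=locus, f1=float(f1), f2=float(f2),
                         n1=n1, n2=n2, k=k)


# ---------------------------------------------------------------------------
# Null simulation
# ---------------------------------------------------------------------------

def _simulate_pair_locus(
    n1: int, n2: int, mu: float, ne: float, t0: float, t: float, n0: float,
    seed: int,
):
    """One coalescent replicate of the split model; returns allele arrays."""
    demog = msprime.Demography()
    demog.add_population(name="P1", initial_size=n0)
    demog.add_population(name="P2", initial_size=n0)
    demog.add_population(name="ANC", initial_size=n0)
    demog.add_population_split(time=t, derived=["P1", "P2"], ancestral="ANC")
    if t0 > t:
        demog.add_population_parameters_change(
            time=t0, population="ANC", initial_size=ne)
    ts = msprime.sim_ancestry(
        samples={"P1": n1 // 2, "P2": n2 // 2}, demography=demog,
        sequence_length=1, discrete_genome=True, random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.InfiniteAlleles(), random_seed=seed + 1)
    if mts.num_sites == 0:
        states = np.zeros(n1 + n2, dtype=np.int64)
    else:
        var = next(mts.variants())
        states = np.asarray(var.genotypes, dtype=np.int64)
    return states[:n1], states[n1:]


def simulate_envelope(
    grid: NuisanceGrid,
    sample_sizes: tuple[int, int],
    sims: int = 10000,
    rng: np.random.Generator | int | None = None,
    levels: tuple[float, ...] = (0.95, 0.99),
    min_bin: int = 200,
) -> Envelope:
    """Simulate the joint neutral distribution of (F1, F2).

    Each replicate draws a nuisance-grid cell uniformly, simulates the
    split model, and records (F1, F2, k). Points are binned by allele
    count k (bins under ``min_bin`` points merge rightward) and per-bin
    highest-density regions are thresholded from a Gaussian KDE evaluated
    at the bin's own points.
    """
    rng = np.random.default_rng(rng)
    cells = grid.cells()
    if not cells:
        raise ValueError("empty nuisance grid")
    n1, n2 = sample_sizes
    pts = []
    for s in range(sims):
        mu, ne, t0, t, n0 = cells[rng.integers(len(cells))]
        a1, a2 = _simulate_pair_locus(
            n1, n2, mu, ne, t0, t, n0, seed=int(rng.integers(2**31 - 2)) + 1)
        c1 = {int(v): int(c) for v, c in zip(*np.unique(a1, return_counts=True))}
        c2 = {int(v): int(c) for v, c in zip(*np.unique(a2, return_counts=True))}
        k = len(set(c1) | set(c2))
        if k < 2:
            continue
        q1, q2, q12 = _identities(c1, c2)
        if q12 >= 1.0:
            continue
        pts.append(((q1 - q12) / (1 - q12), (q2 - q12) / (1 - q12), k))
    points = np.asarray(pts)
    if points.shape[0] < 10 * min_bin:
        logger.warning("envelope: only %d usable points", points.shape[0])

    ks = points[:, 2].astype(int)
    kmax = ks.max()
    # contiguous k-bins with at least min_bin points (merge rightward)
    k_bins: list[tuple[int, int]] = []
    lo = 2
    count = 0
    for k in range(2, kmax + 1):
        count += int((ks == k).sum())
        if count >= min_bin:
            k_bins.append((lo, k))
            lo, count = k + 1, 0
    if count > 0 or not k_bins:
        if k_bins:
            last = k_bins.pop()
            k_bins.append((last[0], kmax))
        else:
            k_bins.append((2, kmax))
    bin_of = {}
    for bi, (a, b) in enumerate(k_bins):
        for k in range(a, b + 1):
            bin_of[k] = bi

    env = Envelope(points=points, k_bins=k_bins, bin_of=bin_of,
                   sample_sizes=(n1, n2))
    for bi, (a, b) in enumerate(k_bins):
        sel = points[(ks >= a) & (ks <= b)]
        # fit the KDE on one half, calibrate the density thresholds on the
        # other: in-sample density quantiles would overstate coverage
        perm = rng.permutation(sel.shape[0])
        half = sel.shape[0] // 2
        fit, cal = sel[perm[:half]], sel[perm[half:]]
        jitter = 1e-6 * rng.standard_normal((2, fit.shape[0]))
        kde = gaussian_kde(fit[:, :2].T + jitter)
        env.kdes.append(kde)
        dens = kde(cal[:, :2].T)
        for lv in levels:
            env.thresholds[(bi, lv)] = float(np.quantile(dens, 1 - lv))
    return env


def flag_outliers(
    observed: list[BranchLengths],
    env: Envelope,
    levels: tuple[float, ...] = (0.95, 0.99),
) -> dict[str, dict[float, bool]]:
    """Inside/outside calls per locus at each confidence level.

    A locus whose (F1, F2) density in the k-matched KDE falls below the
    level's threshold is outside that envelope (True = outlier). Loci with
    k beyond the simulated range use the widest (last) bin, with warning.
    """
    out: dict[str, dict[float, bool]] = {}
    kmax = max(env.bin_of)
    for bl in observed:
        if bl is None:
            continue
        if bl.k in env.bin_of:
            bi = env.bin_of[bl.k]
        else:
            logger.warning(
                "flag_outliers: %s has k=%d beyond simulated range; widest "
                "bin used", bl.locus, bl.k)
            bi = env.bin_of[kmax]
        dens = float(env.kdes[bi]([[bl.f1], [bl.f2]])[0])
        out[bl.locus] = {
            lv: dens < env.thresholds[(bi, lv)] for lv in levels
        }
    return out


def polled_vs_horned_split(
    ds: GenotypeDataset,
    phenotype_labels: dict[str, list[str | None]],
    classes: tuple[str, str] = ("polled", "horned"),
) -> GenotypeDataset:
    """Two-subpopulation dataset from per-individual phenotype labels.

    ``phenotype_labels[pop][i]`` labels individual i of population ``pop``
    (None = unknown, excluded). Individuals are pooled across source
    populations into one population per phenotype class; each class needs
    at least 5 individuals.
    """
    blocks = {c: [] for c in classes}
    for pop, labels in phenotype_labels.items():
        pi = ds.pop_index(pop)
        g = ds.genotypes[pi]
        if len(labels) != g.shape[0]:
            raise ValueError(
                f"labels for {pop} have length {len(labels)}, expected "
                f"{g.shape[0]}")
        lab = np.array([l if l is not None else "" for l in labels])
        for c in classes:
            sel = lab == c
            if sel.any():
                blocks[c].append(g[sel])
    genotypes = []
    for c in classes:
        if not blocks[c]:
            raise ValueError(f"phenotype class {c!r} has no individuals")
        arr = np.vstack(blocks[c])
        if arr.shape[0] < 5:
            raise ValueError(
                f"phenotype class {c!r} has {arr.shape[0]} individuals; "
                "need >= 5")
        genotypes.append(arr)
    return GenotypeDataset(populations=list(classes), loci=list(ds.loci),
                           genotypes=genotypes)
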