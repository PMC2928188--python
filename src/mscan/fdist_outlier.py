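"""FDIST-style frequentist F_ST outlier test.

The joint null distribution of (heterozygosity, F_ST) for single loci is
simulated under a finite island model calibrated so that the mean simulated
F_ST matches the trimmed-mean F_ST of the data (the "neutral" average,
computed after deleting the 30% largest and smallest per-locus values).
Each observed locus is then placed in the null conditional on its
heterozygosity: q is the fraction of null F_ST values below the observed one
among the null points nearest in H_E, and the two-sided P is 2*min(q, 1-q).
High-tail outliers indicate directional (diversifying) selection, low-tail
outliers balancing/homogenizing selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._coalescent import simulate_island_locus
from .diversity_stats import weir_cockerham, trimmed_mean_fst
from .genotype_io import GenotypeDataset

logger = logging.getLogger("mscan")

__all__ = [
    "FdistNull",
    "FdistResult",
    "calibrate_migration",
    "simulate_null",
    "fdist_pvalues",
    "fdist_scan",
]


@dataclass
class FdistNull:
    he: np.ndarray     # mean within-population expected heterozygosity
    fst: np.ndarray    # Weir-Cockerham theta per simulated locus
    n_demes: int
    sampled_pops: int
    sample_size: int   # diploids per sampled population
    mutation_model: str
    target_fst: float
    migration_rate: float
    iterations: int


@dataclass
class FdistResult:
    locus: str
    he: float
    fst: float
    quantile: float
    p_value: float
    direction: str  # "directional", "balancing", "none"


def _null_summaries(mat: np.ndarray, sampled_pops: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate (mean H_E, WC F_ST) from an (reps, n) allele matrix."""
    reps, n = mat.shape
    per = n // sampled_pops
    he = np.empty(reps)
    fst = np.empty(reps)
    pops = mat.reshape(reps, sampled_pops, per)
    for r in range(reps):
        he[r], fst[r] = _he_fst_one(pops[r])
    return he, fst


def _he_fst_one(pop_alleles: np.ndarray) -> tuple[float, float]:
    """Unbiased mean H_E and haploid-data WC theta for one locus.

    ``pop_alleles``: (n_pops, n_copies) gene copies. The variance-components
    estimator here is the haploid form (components a and b only), which is
    the natural null summary when gametes are simulated directly.
    """
    r, n_cop = pop_alleles.shape
    alleles = np.unique(pop_alleles)
    if alleles.size < 2:
        return float("nan"), float("nan")
    n_i = np.full(r, n_cop, dtype=float)
    nbar = n_cop
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    A = D = 0.0
    he = 0.0
    freqs = np.stack([(pop_alleles == al).mean(axis=1) for al in alleles])
    he = (n_cop / (n_cop - 1) * (1 - (freqs ** 2).sum(axis=0))).mean()
    for ai in range(alleles.size):
        p_i = freqs[ai]
        pbar = p_i.mean()
        s2 = ((p_i - pbar) ** 2).sum() / (r - 1)
        # haploid (gene-copy) variance components, Weir & Cockerham
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
        A += a
        D += a + b
    if D == 0:
        return float(he), float("nan")
    return float(he), float(A / D)


def _pilot_mean_fst(
    m: float, d: int, sampled_pops: int, sample_size: int,
    mutation_model: str, theta_range: tuple[float, float], n_pilot: int,
    seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    thetas = np.exp(rng.uniform(np.log(theta_range[0]),
                                np.log(theta_range[1]), size=n_pilot)) / d
    mat = simulate_island_locus(
        [2 * sample_size] * sampled_pops, d=d, m=m, theta=1.0,
        model=mutation_model, n_reps=n_pilot,
        seed=int(rng.integers(2**31 - 1)) + 1, theta_per_rep=thetas,
    )
    _, fst = _null_summaries(mat, sampled_pops)
    return float(np.nanmean(fst))


def calibrate_migration(
    target_fst: float,
    d: int = 100,
    sampled_pops: int = 10,
    sample_size: int = 50,
    mutation_model: str = "IAM",
    theta_range: tuple[float, float] = (0.05, 10.0),
    n_pilot: int = 400,
    tol: float = 0.005,
    max_steps: int = 50,
    seed: int = 1,
) -> float:
    """Migration rate whose pilot mean simulated F_ST hits ``target_fst``.

    Bisection on log10(m), seeded from the island-model closed form
    F_ST ~ 1/(1 + 4Nm (d/(d-1))^2); deterministic given ``seed``. Raises on
    non-convergence with the bisection trace attached.
    """
    if not (0 < target_fst < 1):
        raise ValueError("target F_ST must be in (0, 1)")
    N = 1000.0  # engine time-scale; only 4Nm matters
    corr = (d / (d - 1)) ** 2 if d > 1 else 1.0
    m0 = (1 / target_fst - 1) / (4 * N * corr)
    lo, hi = np.log10(m0) - 1.2, np.log10(m0) + 1.2
    trace = []
    # bisection with common random numbers: the same pilot seed at every
    # step keeps the pilot mean monotone in m
    for step in range(max_steps):
        mid = 0.5 * (lo + hi)
        got = _pilot_mean_fst(10 ** mid, d, sampled_pops, sample_size,
                              mutation_model, theta_range, n_pilot, seed)
        trace.append((10 ** mid, got))
        if abs(got - target_fst) <= tol:
            return float(10 ** mid)
        if got > target_fst:
            lo = mid  # too much structure -> need more migration
        else:
            hi = mid
    raise RuntimeError(
        f"migration calibration did not converge in {max_steps} steps; "
        f"trace={trace[-5:]}"
    )


def simulate_null(
    migration_rate: float,
    iterations: int = 50000,
    d: int = 100,
    sampled_pops: int = 10,
    sample_size: int = 50,
    mutation_model: str = "IAM",
    theta_range: tuple[float, float] = (0.05, 10.0),
    target_fst: float = float("nan"),
    seed: int = 1,
) -> FdistNull:
    """Simulate the null cloud of (H_E, F_ST) points.

    One island-coalescent locus per replicate; theta (here scaled to the
    whole metapopulation, 4*d*N*mu, the quantity that sets heterozygosity
    under the island model) is drawn log-uniformly over ``theta_range`` so
    the null covers the whole heterozygosity range. Monomorphic replicates
    are dropped.
    """
    rng = np.random.default_rng(seed)
    thetas = np.exp(rng.uniform(np.log(theta_range[0]), np.log(theta_range[1]),
                                size=iterations)) / d
    mat = simulate_island_locus(
        [2 * sample_size] * sampled_pops, d=d, m=migration_rate, theta=1.0,
        model=mutation_model, n_reps=iterations,
        seed=int(rng.integers(2**31 - 1)) + 1, theta_per_rep=thetas,
    )
    he, fst = _null_summaries(mat, sampled_pops)
    ok = np.isfinite(he) & np.isfinite(fst)
    dropped = iterations - int(ok.sum())
    if dropped:
        logger.info("null simulation: dropped %d monomorphic replicates", dropped)
    return FdistNull(
        he=he[ok], fst=fst[ok], n_demes=d, sampled_pops=sampled_pops,
        sample_size=sample_size, mutation_model=mutation_model,
        target_fst=target_fst, migration_rate=migration_rate,
        iterations=iterations,
    )


def fdist_pvalues(
    observed: list[tuple[str, float, float]],
    null: FdistNull,
    window_frac: float = 0.02,
    level: float = 0.05,
) -> list[FdistResult]:
    """Conditional quantiles and two-sided P-values for observed loci.

    ``observed`` holds (locus, H_E, F_ST). For each locus the null points
    nearest in H_E (a fraction ``window_frac`` of the cloud, at least 100)
    form the conditional sample; q = fraction of their F_ST values strictly
    below the observed (+ half the ties, a mid-P convention that keeps q
    continuous); P = 2*min(q, 1-q).
    """
    if null.he.size < 1000:
        raise ValueError("null cloud too small (< 1000 points)")
    w = max(100, int(round(window_frac * null.he.size)))
    order = np.argsort(null.he)
    he_sorted = null.he[order]
    fst_sorted = null.fst[order]
    lo_he, hi_he = he_sorted[0], he_sorted[-1]
    out = []
    for locus, he, fst in observed:
        if not np.isfinite(he) or not np.isfinite(fst):
            out.append(FdistResult(locus, he, fst, float("nan"),
                                   float("nan"), "none"))
            continue
        if he < lo_he or he > hi_he:
            logger.warning(
                "locus %s: observed H_E %.3f outside null range; using "
                "widest window", locus, he)
        j = np.searchsorted(he_sorted, he)
        a = max(0, min(j - w // 2, he_sorted.size - w))
        sel = fst_sorted[a:a + w]
        q = ((sel < fst).sum() + 0.5 * (sel == fst).sum()) / sel.size
        p = 2 * min(q, 1 - q)
        if p < level:
            direction = "directional" if q > 0.5 else "balancing"
        else:
            direction = "none"
        out.append(FdistResult(locus, float(he), float(fst), float(q),
                               float(p), direction))
    return out


def fdist_scan(
    ds: GenotypeDataset,
    iterations: int = 50000,
    trim: float = 0.30,
    d: int = 100,
    sampled_pops: int | None = None,
    sample_size: int = 50,
    mutation_model: str = "IAM",
    window_frac: float = 0.02,
    theta_range: tuple[float, float] | None = None,
    seed: int = 1,
) -> tuple[list[FdistResult], FdistNull, float]:
    """End-to-end scan: trimmed-mean F_ST -> calibration -> null -> P-values.

    Returns (results, null, trimmed_mean). Observed per-locus H_E here is
    the mean within-population unbiased heterozygosity, matching the null
    summary. The null theta grid, unless given, is derived from the
    observed heterozygosity range via the IAM equilibrium H = theta/(1+theta)
    (widened 2x both ways), so the conditional cloud covers every locus.
    """
    from .diversity_stats import expected_heterozygosity
    from .genotype_io import allele_counts

    records, ml = weir_cockerham(ds, n_boot=0, rng=seed)
    fsts = {r.locus: r.F_ST for r in records}
    target = trimmed_mean_fst(list(fsts.values()), trim=trim)
    if sampled_pops is None:
        sampled_pops = ds.n_populations
    hes = np.array([
        expected_heterozygosity(allele_counts(ds, r.locus)) for r in records
    ])
    hes = hes[np.isfinite(hes)]
    if theta_range is None:
        h_lo = float(np.clip(hes.min(), 0.02, 0.98))
        h_hi = float(np.clip(hes.max(), 0.02, 0.98))
        theta_range = (0.5 * h_lo / (1 - h_lo), 2.0 * h_hi / (1 - h_hi))
    m = calibrate_migration(
        target, d=d, sampled_pops=sampled_pops, sample_size=sample_size,
        mutation_model=mutation_model, theta_range=theta_range, seed=seed,
    )
    null = simulate_null(
        m, iterations=iterations, d=d, sampled_pops=sampled_pops,
        sample_size=sample_size, mutation_model=mutation_model,
        theta_range=theta_range, target_fst=target, seed=seed + 1,
    )
    observed = []
    for r in records:
        he = expected_heterozygosity(allele_counts(ds, r.locus))
        observed.append((r.locus, he, fsts[r.locus]))
    return fdist_pvalues(observed, null, window_frac=window_frac), null, target
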