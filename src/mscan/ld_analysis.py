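"""Two-locus linkage disequilibrium for unphased multiallelic genotypes.

Haplotype frequencies are estimated by EM (double heterozygotes split
between their two phase resolutions in proportion to current haplotype
frequencies), the normalized disequilibrium D' is the allele-frequency
weighted multiallelic form, and significance comes from a Markov-chain
Monte-Carlo exact test on the gamete contingency table (the
Metropolis swap chain over tables with fixed margins, as used for R x C
extensions of Fisher's exact test). Summaries compare syntenic against
non-syntenic marker pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats as sstats

from .genotype_io import GenotypeDataset, MarkerMap, enumerate_syntenic_pairs

logger = logging.getLogger("mscan")

__all__ = [
    "HaplotypeFreqs",
    "LDRecord",
    "em_haplotypes",
    "multiallelic_dprime",
    "ld_exact_test",
    "ld_summary",
    "pairwise_ld",
]


@dataclass
class HaplotypeFreqs:
    locus_a: str
    locus_b: str
    alleles_a: list[int]
    alleles_b: list[int]
    h: np.ndarray            # (len(alleles_a), len(alleles_b)), sums to 1
    log_likelihood: float
    converged: bool
    n_individuals: int

    @property
    def p(self) -> np.ndarray:
        return self.h.sum(axis=1)

    @property
    def q(self) -> np.ndarray:
        return self.h.sum(axis=0)


@dataclass
class LDRecord:
    locus_a: str
    locus_b: str
    dprime: float
    p_value: float
    p_se: float
    chromosome: str
    distance_bp: float
    syntenic: bool


def _two_locus_genotypes(
    ds: GenotypeDataset, locus_a: str, locus_b: str, pops=None
) -> np.ndarray:
    """(n, 4) array of [a1, a2, b1, b2] for doubly-typed individuals."""
    ia, ib = ds.locus_index(locus_a), ds.locus_index(locus_b)
    idx = (range(ds.n_populations) if pops is None
           else [ds.pop_index(p) for p in pops])
    rows = []
    for p in idx:
        g = ds.genotypes[p]
        ok = (g[:, ia, :] != 0).all(axis=1) & (g[:, ib, :] != 0).all(axis=1)
        if ok.any():
            rows.append(np.hstack([g[ok][:, ia, :], g[ok][:, ib, :]]))
    if not rows:
        return np.empty((0, 4), dtype=np.int64)
    return np.vstack(rows)


def em_haplotypes(
    ds: GenotypeDataset,
    locus_a: str,
    locus_b: str,
    pops=None,
    tol: float = 1e-6,
    max_iters: int = 500,
) -> HaplotypeFreqs:
    """EM haplotype-frequency estimation for one locus pair.

    Only individuals typed at both loci contribute (>= 10 required). The
    log-likelihood is monotone non-decreasing across iterations (asserted);
    convergence is max |delta h| < tol.
    """
    G = _two_locus_genotypes(ds, locus_a, locus_b, pops)
    n = G.shape[0]
    if n < 10:
        raise ValueError(
            f"em_haplotypes: only {n} doubly-typed individuals at "
            f"({locus_a}, {locus_b}); need >= 10")
    alleles_a = sorted(set(G[:, 0]) | set(G[:, 1]))
    alleles_b = sorted(set(G[:, 2]) | set(G[:, 3]))
    amap = {a: i for i, a in enumerate(alleles_a)}
    bmap = {b: i for i, b in enumerate(alleles_b)}
    A, B = len(alleles_a), len(alleles_b)

    a1 = np.array([amap[x] for x in G[:, 0]])
    a2 = np.array([amap[x] for x in G[:, 1]])
    b1 = np.array([bmap[x] for x in G[:, 2]])
    b2 = np.array([bmap[x] for x in G[:, 3]])
    double_het = (a1 != a2) & (b1 != b2)

    # init: product of allele frequencies
    pa = np.bincount(np.concatenate([a1, a2]), minlength=A) / (2 * n)
    qb = np.bincount(np.concatenate([b1, b2]), minlength=B) / (2 * n)
    h = np.outer(pa, qb)
    h /= h.sum()

    ll_prev = -np.inf
    converged = False
    for _ in range(max_iters):
        counts = np.zeros((A, B))
        ll = 0.0
        # phase-known individuals: gametes are (a1,b1)+(a2,b2) wlog for
        # single-locus hets the pairing is arbitrary but equivalent
        w1 = h[a1, b1] * h[a2, b2]
        w2 = h[a1, b2] * h[a2, b1]
        tot = np.where(double_het, w1 + w2, 1.0)
        frac1 = np.where(double_het, np.divide(
            w1, tot, out=np.full_like(w1, 0.5), where=tot > 0), 1.0)
        np.add.at(counts, (a1, b1), frac1)
        np.add.at(counts, (a2, b2), frac1)
        np.add.at(counts, (a1, b2), 1 - frac1)
        np.add.at(counts, (a2, b1), 1 - frac1)
        # log-likelihood of the genotype data under current h
        mult = np.where(double_het, w1 + w2,
                        h[a1, b1] * h[a2, b2])
        # single-het / homozygote phase multiplicity constants are absorbed
        with np.errstate(divide="ignore"):
            ll = float(np.log(np.maximum(mult, 1e-300)).sum())
        assert ll >= ll_prev - 1e-8, "EM log-likelihood decreased"
        new_h = counts / (2 * n)
        delta = np.abs(new_h - h).max()
        h = new_h
        if ll_prev != -np.inf and delta < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    if not converged:
        logger.warning("EM did not converge for (%s, %s); best estimate "
                       "returned", locus_a, locus_b)
    return HaplotypeFreqs(
        locus_a=locus_a, locus_b=locus_b, alleles_a=alleles_a,
        alleles_b=alleles_b, h=h, log_likelihood=float(ll_prev),
        converged=converged, n_individuals=n,
    )


def multiallelic_dprime(hf: HaplotypeFreqs | np.ndarray) -> float:
    """Frequency-weighted multiallelic D'.

    D' = sum_u sum_v p_u q_v |D_uv| / Dmax_uv with D_uv = h_uv - p_u q_v
    and Dmax_uv the usual one-sided bound. Returns nan if either locus is
    monomorphic.
    """
    h = hf.h if isinstance(hf, HaplotypeFreqs) else np.asarray(hf, dtype=float)
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    if (p > 0).sum() < 2 or (q > 0).sum() < 2:
        return float("nan")
    total = 0.0
    for u in range(h.shape[0]):
        if p[u] == 0:
            continue
        for v in range(h.shape[1]):
            if q[v] == 0:
                continue
            d = h[u, v] - p[u] * q[v]
            if d < 0:
                dmax = min(p[u] * q[v], (1 - p[u]) * (1 - q[v]))
            else:
                dmax = min(p[u] * (1 - q[v]), (1 - p[u]) * q[v])
            if dmax <= 0:
                continue
            total += p[u] * q[v] * abs(d) / dmax
    return float(total)


# ---------------------------------------------------------------------------
# Markov-chain exact test on the gamete contingency table
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mc_exact_chain(table, n_steps, burn_in, seed):
    """Fraction of visited fixed-margin tables at most as probable as the
    start, via the +/- diagonal swap Metropolis chain."""
    np.random.seed(seed)
    R, Cn = table.shape
    T = table.copy()
    # log pi(T) = const - sum lgamma(t+1)
    logpi = 0.0
    for i in range(R):
        for j in range(Cn):
            logpi -= math.lgamma(T[i, j] + 1.0)
    logpi_obs = logpi
    hits = 0.0
    count = 0
    total = burn_in + n_steps
    for step in range(total):
        i1 = np.random.randint(R)
        i2 = np.random.randint(R - 1)
        if i2 >= i1:
            i2 += 1
        j1 = np.random.randint(Cn)
        j2 = np.random.randint(Cn - 1)
        if j2 >= j1:
            j2 += 1
        # move: T[i1,j1]--, T[i2,j2]--, T[i1,j2]++, T[i2,j1]++
        a, b = T[i1, j1], T[i2, j2]
        c, d = T[i1, j2], T[i2, j1]
        if a > 0 and b > 0:
            ratio = (a * b) / ((c + 1.0) * (d + 1.0))
            if np.random.random() < ratio:
                T[i1, j1] -= 1
                T[i2, j2] -= 1
                T[i1, j2] += 1
                T[i2, j1] += 1
                logpi += math.log(ratio)
        if step >= burn_in:
            count += 1
            if logpi <= logpi_obs + 1e-9:
                hits += 1.0
    return hits / count


def ld_exact_test(
    table: np.ndarray,
    mc_tables: int = 100000,
    burn_in: int = 1000,
    rng: np.random.Generator | int | None = None,
    n_batches: int = 20,
) -> tuple[float, float]:
    """Monte-Carlo exact test P for an R x C contingency table.

    Explores ``mc_tables`` margin-preserving tables with the diagonal-swap
    Markov chain; P is the proportion whose conditional probability does
    not exceed the observed table's. Returns (P, standard error) with the
    SE from independent chain segments. Degenerate margins give P = 1.
    """
    rng = np.random.default_rng(rng)
    T = np.asarray(table, dtype=np.int64)
    if T.ndim != 2:
        raise ValueError("table must be 2-D")
    rows = T.sum(axis=1)
    cols = T.sum(axis=0)
    T = T[rows > 0][:, cols > 0]
    if T.shape[0] < 2 or T.shape[1] < 2:
        return 1.0, 0.0
    per = max(mc_tables // n_batches, 100)
    ps = np.empty(n_batches)
    for b in range(n_batches):
        ps[b] = _mc_exact_chain(T, per, burn_in,
                                int(rng.integers(2**31 - 1)))
    return float(ps.mean()), float(ps.std(ddof=1) / math.sqrt(n_batches))


def _gamete_table(hf: HaplotypeFreqs) -> np.ndarray:
    """Integer gamete contingency table from EM-weighted haplotype counts.

    Expected counts 2n*h rounded by largest remainder so the total is
    exactly 2n.
    """
    target = 2 * hf.n_individuals
    raw = hf.h * target
    base = np.floor(raw).astype(np.int64)
    short = target - base.sum()
    if short > 0:
        rem = (raw - base).ravel()
        for idx in np.argsort(rem)[::-1][:short]:
            base.ravel()[idx] += 1
    return base


def pairwise_ld(
    ds: GenotypeDataset,
    locus_a: str,
    locus_b: str,
    pops=None,
    mc_tables: int = 100000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float]:
    """(D', exact P, SE) for one locus pair in a population subset.

    D' and the gamete table come from the EM fit on the pooled subset.
    """
    hf = em_haplotypes(ds, locus_a, locus_b, pops=pops)
    dp = multiallelic_dprime(hf)
    p, se = ld_exact_test(_gamete_table(hf), mc_tables=mc_tables, rng=rng)
    return dp, p, se


def ld_summary(
    ds: GenotypeDataset,
    mmap: MarkerMap,
    pops=None,
    mc_tables: int = 20000,
    rng: np.random.Generator | int | None = None,
    max_nonsyntenic: int | None = None,
) -> dict:
    """Syntenic vs non-syntenic D' contrast over all locus pairs.

    Returns per-chromosome syntenic mean D', the non-syntenic mean, a
    Mann-Whitney test between the two groups, significant-pair counts at
    P < 0.05, and the per-pair records. ``max_nonsyntenic`` subsamples the
    (large) non-syntenic pair set deterministically for speed.
    """
    rng = np.random.default_rng(rng)
    syn = {(a, b): (chrom, dist)
           for a, b, chrom, dist in enumerate_syntenic_pairs(mmap)}
    loci = [l for l in ds.loci if l in mmap]
    all_pairs = list(itertools.combinations(loci, 2))
    nonsyn = [pr for pr in all_pairs
              if pr not in syn and (pr[1], pr[0]) not in syn]
    if max_nonsyntenic is not None and len(nonsyn) > max_nonsyntenic:
        idx = rng.choice(len(nonsyn), size=max_nonsyntenic, replace=False)
        nonsyn = [nonsyn[i] for i in sorted(idx)]

    records: list[LDRecord] = []
    for (a, b) in list(syn.keys()) + nonsyn:
        if a not in ds.loci or b not in ds.loci:
            continue
        is_syn = (a, b) in syn
        chrom, dist = syn.get((a, b), ("NA", float("nan")))
        try:
            dp, p, se = pairwise_ld(ds, a, b, pops=pops,
                                    mc_tables=mc_tables,
                                    rng=int(rng.integers(2**31 - 1)))
        except ValueError:
            continue
        records.append(LDRecord(a, b, dp, p, se, chrom, dist, is_syn))

    syn_d = [r.dprime for r in records if r.syntenic and np.isfinite(r.dprime)]
    non_d = [r.dprime for r in records
             if not r.syntenic and np.isfinite(r.dprime)]
    if syn_d and non_d:
        mw = sstats.mannwhitneyu(syn_d, non_d, alternative="greater")
        mw_p = float(mw.pvalue)
    else:
        mw_p = float("nan")
    per_chrom: dict[str, float] = {}
    for chrom in sorted({r.chromosome for r in records if r.syntenic}):
        vals = [r.dprime for r in records
                if r.syntenic and r.chromosome == chrom
                and np.isfinite(r.dprime)]
        if vals:
            per_chrom[chrom] = float(np.mean(vals))
    return {
        "syntenic_mean_dprime": float(np.mean(syn_d)) if syn_d else float("nan"),
        "nonsyntenic_mean_dprime": (float(np.mean(non_d)) if non_d
                                    else float("nan")),
        "syntenic_mean_by_chromosome": per_chrom,
        "mannwhitney_p": mw_p,
        "n_syntenic_sig": sum(r.p_value < 0.05 for r in records if r.syntenic),
        "n_syntenic": sum(r.syntenic for r in records),
        "n_nonsyntenic_sig": sum(r.p_value < 0.05 for r in records
                                 if not r.syntenic),
        "n_nonsyntenic": sum(not r.syntenic for r in records),
        "records": records,
    }
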