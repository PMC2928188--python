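"""Per-locus variability and differentiation estimators.

Implements the FSTAT-style summary battery: unbiased expected heterozygosity
(Nei), rarefied allelic richness, and Weir & Cockerham's variance-components
estimators of F_ST (theta) and F_IS (f) for multiallelic co-dominant data,
with a multi-locus ratio-of-sums estimate, bootstrap-over-loci confidence
intervals and jackknife-over-populations per-locus standard deviations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeDataset, AlleleCountTable, allele_counts

logger = logging.getLogger("mscan")

__all__ = [
    "DiversityRecord",
    "MultiLocusFst",
    "expected_heterozygosity",
    "allelic_richness",
    "weir_cockerham_components",
    "weir_cockerham",
    "trimmed_mean_fst",
    "diversity_table",
]


@dataclass
class DiversityRecord:
    locus: str
    H_E: float
    A_R: float
    F_IS: float
    F_ST: float
    F_ST_sd: float = float("nan")


@dataclass
class MultiLocusFst:
    point: float
    ci_low: float
    ci_high: float
    per_locus: dict[str, float] = field(default_factory=dict)
    per_locus_sd: dict[str, float] = field(default_factory=dict)


def expected_heterozygosity(
    table: AlleleCountTable, pop: str | int | None = None
) -> float:
    """Nei's unbiased gene diversity (n/(n-1))(1 - sum p_i^2).

    With ``pop`` omitted the per-population values are averaged over
    populations with data (n >= 2). Returns nan when undefined.
    """
    def _one(counts: dict[int, int]) -> float:
        n = sum(counts.values())
        if n < 2:
            return float("nan")
        p2 = sum((c / n) ** 2 for c in counts.values())
        return n / (n - 1) * (1.0 - p2)

    if pop is not None:
        i = table.populations.index(pop) if isinstance(pop, str) else int(pop)
        h = _one(table.counts[i])
        if math.isnan(h):
            logger.warning("H_E undefined (n<2) at %s, population %s",
                           table.locus, pop)
        return h
    vals = [_one(c) for c in table.counts]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def allelic_richness(table: AlleleCountTable, g: int | None = None) -> float:
    """Rarefied allelic richness at ``g`` gene copies, averaged over pops.

    A_R = sum_alleles [1 - C(n - n_i, g) / C(n, g)], the expected number of
    distinct alleles in a subsample of ``g`` copies (El Mousadik & Petit).
    Default ``g`` is the smallest non-missing per-population count (FSTAT
    convention). Populations with n < g are skipped with a warning.
    """
    ns = [n for n in table.n_pop if n > 0]
    if not ns:
        return float("nan")
    if g is None:
        g = min(ns)
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    vals = []
    for pop, counts in zip(table.populations, table.counts):
        n = sum(counts.values())
        if n == 0:
            continue
        if g > n:
            logger.warning(
                "allelic richness: population %s has n=%d < g=%d at %s; skipped",
                pop, n, g, table.locus)
            continue
        # 1 - C(n-ni, g)/C(n, g), via log-gammas for stability
        a = 0.0
        for ni in counts.values():
            if n - ni < g:
                a += 1.0
            else:
                a += 1.0 - math.exp(
                    _lchoose(n - ni, g) - _lchoose(n, g))
        vals.append(a)
    return float(np.mean(vals)) if vals else float("nan")


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def weir_cockerham_components(
    ds: GenotypeDataset, locus: str
) -> tuple[float, float, float]:
    """Summed variance components (a, b, c) over alleles at one locus.

    a: among populations; b: among individuals within populations;
    c: within individuals. theta = a/(a+b+c); f (F_IS) = 1 - c/(b+c).
    Populations with no data at the locus are dropped. Returns nans when the
    locus is informative in fewer than two populations or monomorphic.
    """
    li = ds.locus_index(locus)
    pops = []
    for g in ds.genotypes:
        calls = g[:, li, :]
        ok = (calls != 0).all(axis=1)
        if ok.sum() >= 1:
            pops.append(calls[ok])
    r = len(pops)
    if r < 2:
        return (float("nan"),) * 3
    alleles = sorted({int(a) for p in pops for a in np.unique(p)})
    if len(alleles) < 2:
        return (float("nan"),) * 3

    n_i = np.array([p.shape[0] for p in pops], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)

    A = B = C = 0.0
    for al in alleles:
        p_i = np.array([(p == al).sum() / (2 * p.shape[0]) for p in pops])
        # proportion of individuals heterozygous for allele `al`
        h_i = np.array([
            ((p == al).sum(axis=1) == 1).mean() for p in pops
        ])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a; B += b; C += c
    return A, B, C


def weir_cockerham(
    ds: GenotypeDataset,
    loci: list[str] | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[list[DiversityRecord], MultiLocusFst]:
    """Per-locus (F_ST, F_IS) and the multi-locus ratio-of-sums F_ST.

    Multi-locus point estimate is sum(a)/sum(a+b+c) over informative loci;
    95% CI by bootstrap over loci; per-locus SD by jackknife over populations.
    Monomorphic loci get nan and are excluded from the multi-locus sums.
    """
    rng = np.random.default_rng(rng)
    loci = list(ds.loci) if loci is None else list(loci)
    comps: dict[str, tuple[float, float, float]] = {}
    records = []
    for loc in loci:
        a, b, c = weir_cockerham_components(ds, loc)
        tot = a + b + c
        fst = a / tot if tot and not math.isnan(tot) and tot != 0 else float("nan")
        fis = 1 - c / (b + c) if (b + c) and not math.isnan(b + c) else float("nan")
        if not math.isnan(a):
            comps[loc] = (a, b, c)
        tab = allele_counts(ds, loc)
        records.append(DiversityRecord(
            locus=loc,
            H_E=expected_heterozygosity(tab),
            A_R=allelic_richness(tab),
            F_IS=fis,
            F_ST=fst,
            F_ST_sd=_jackknife_fst_sd(ds, loc),
        ))

    good = list(comps)
    if good:
        A = np.array([comps[l][0] for l in good])
        T = np.array([sum(comps[l]) for l in good])
        point = A.sum() / T.sum()
        if n_boot > 0:
            boots = np.empty(n_boot)
            for bi in range(n_boot):
                idx = rng.integers(0, len(good), len(good))
                boots[bi] = A[idx].sum() / T[idx].sum()
            lo, hi = np.quantile(boots, [0.025, 0.975])
            lo, hi = min(lo, point), max(hi, point)
        else:
            lo = hi = point
    else:
        point, lo, hi = (float("nan"),) * 3
    ml = MultiLocusFst(
        point=float(point), ci_low=float(lo), ci_high=float(hi),
        per_locus={r.locus: r.F_ST for r in records},
        per_locus_sd={r.locus: r.F_ST_sd for r in records},
    )
    return records, ml


def _jackknife_fst_sd(ds: GenotypeDataset, locus: str) -> float:
    """Delete-one-population jackknife SD of the per-locus theta."""
    r = ds.n_populations
    if r < 3:
        return float("nan")
    vals = []
    for drop in range(r):
        keep = [p for i, p in enumerate(ds.populations) if i != drop]
        sub = ds.subset_populations(keep)
        a, b, c = weir_cockerham_components(sub, locus)
        tot = a + b + c
        if tot and not math.isnan(tot):
            vals.append(a / tot)
    if len(vals) < 3:
        return float("nan")
    v = np.asarray(vals)
    return float(math.sqrt((len(v) - 1) / len(v) * ((v - v.mean()) ** 2).sum()))


def trimmed_mean_fst(values, trim: float = 0.30) -> float:
    """Mean F_ST after deleting the floor(trim*L) largest and smallest values.

    The neutral calibration target for the FDIST-style null: trimming the
    tails removes candidate outlier loci from the average.
    """
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no finite F_ST values to trim")
    k = int(math.floor(trim * vals.size))
    vals.sort()
    if 2 * k >= vals.size:
        raise ValueError("trim removes all values")
    return float(vals[k:vals.size - k].mean())


def diversity_table(records: list[DiversityRecord], mmap=None):
    """Wide per-locus summary as a DataFrame (study-summary columns)."""
    import pandas as pd

    rows = []
    for r in records:
        chrom = mmap[r.locus].chromosome if (mmap and r.locus in mmap) else "NA"
        rows.append({
            "locus": r.locus, "BTA": chrom, "A_R": r.A_R, "H_E": r.H_E,
            "F_IS": r.F_IS, "F_ST": r.F_ST, "F_ST_sd": r.F_ST_sd,
        })
    return pd.DataFrame(rows)
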