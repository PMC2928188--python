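"""Ewens-Watterson homozygosity test of neutrality (infinite-allele model).

Conditional on the sample size ``n`` and observed allele number ``k``, the
Ewens sampling formula gives the allele configuration a distribution that is
free of theta:  Pr(a) = n! / (prod_j j^{a_j} a_j!) / |s(n, k)|, where a_j is
the number of alleles seen j times and |s(n, k)| the unsigned Stirling
number of the first kind. Equivalently, the configuration is the cycle type
of a uniform random permutation of n elements with exactly k cycles; the
sampler here builds such a permutation exactly (no rejection) via the
Stirling recurrence, vectorized across Monte-Carlo draws.

The test compares observed homozygosity F = sum p_i^2 against the
conditional null: P_H is the lower-tail probability Pr(F_sim <= F_obs)
(small = diversity deficit / directional selection; large = diversity
excess / balancing selection; two-tailed at 0.05 means P_H < 0.025 or
> 0.975). P_E is the Slatkin-style exact probability: the summed null mass
of configurations no more probable than the observed one, estimated by the
same Monte-Carlo draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genotype_io import AlleleCountTable

logger = logging.getLogger("mscan")

__all__ = [
    "EwensResult",
    "observed_homozygosity",
    "ewens_conditional_sample",
    "enumerate_configurations",
    "configuration_log_prob",
    "ew_test",
]


@dataclass
class EwensResult:
    locus: str
    n: int
    k: int
    F_obs: float
    F_exp: float
    P_H: float
    P_E: float

    @property
    def significant(self) -> bool:
        """Two-tailed call at the 5% level on the homozygosity probability."""
        return self.P_H < 0.025 or self.P_H > 0.975


def observed_homozygosity(
    table: AlleleCountTable, pop: str | int | None = None
) -> float:
    """F = sum (n_i/n)^2 over alleles, pooled across populations by default."""
    counts = (
        table.pooled() if pop is None
        else table.counts[table.populations.index(pop) if isinstance(pop, str)
                          else int(pop)]
    )
    n = sum(counts.values())
    if n == 0:
        return float("nan")
    return sum(c * c for c in counts.values()) / (n * n)


# ---------------------------------------------------------------------------
# Stirling numbers and exact conditional sampling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _log_stirling_table(n: int, kmax: int) -> np.ndarray:
    """log |s(i, j)| for 0 <= i <= n, 0 <= j <= kmax (unsigned, 1st kind)."""
    tab = np.full((n + 1, kmax + 1), -np.inf)
    tab[0, 0] = 0.0
    for i in range(1, n + 1):
        jmax = min(i, kmax)
        prev = tab[i - 1]
        cur = tab[i]
        cur[1:jmax + 1] = np.logaddexp(
            prev[0:jmax], np.log(i - 1) + prev[1:jmax + 1]
            if i > 1 else -np.inf
        )
    return tab


def ewens_conditional_sample(
    n: int, k: int, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw allele-count configurations from the ESF conditional on (n, k).

    Returns a (size, k) array of allele copy-counts per draw, unsorted,
    summing to n. Exact two-pass construction: first the "new allele"
    indicators via the Stirling recurrence |s(i,j)| = |s(i-1,j-1)| +
    (i-1)|s(i-1,j)|, then cycle assembly by uniform insertion.
    """
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n")
    if k == n:
        return np.ones((size, n), dtype=np.int64)
    if k == 1:
        return np.full((size, 1), n, dtype=np.int64)
    tab = _log_stirling_table(n, k)
    k_rem = np.full(size, k, dtype=np.int64)
    new = np.empty((size, n), dtype=bool)
    # decide, for i = n..1, whether element i starts a new cycle
    for i in range(n, 0, -1):
        p_new = np.exp(tab[i - 1, k_rem - 1] - tab[i, k_rem])
        b = rng.random(size) < p_new
        new[:, i - 1] = b
        k_rem -= b
    # forward pass: element i joins the cycle of a uniform element j < i
    labels = np.zeros((size, n), dtype=np.int64)
    cyc_id = np.zeros(size, dtype=np.int64)
    counts = np.zeros((size, k), dtype=np.int64)
    rows = np.arange(size)
    for i in range(n):
        if i == 0:
            labels[:, 0] = 0
            counts[rows, 0] = 1
            cyc_id[:] = 1
            continue
        join_from = rng.integers(0, i, size=size)
        lab = np.where(new[:, i], cyc_id, labels[rows, join_from])
        labels[:, i] = lab
        counts[rows, lab] += 1
        cyc_id += new[:, i]
    return counts


def enumerate_configurations(n: int, k: int):
    """All allele configurations (sorted tuples) with their exact
    conditional probabilities; for small-sample oracles and tests."""
    tab = _log_stirling_table(n, k)
    out = []
    for part in _partitions_k(n, k):
        out.append((part, math.exp(configuration_log_prob(part) - tab[n, k])))
    return out


def _partitions_k(n: int, k: int, maxpart: int | None = None):
    """Partitions of n into exactly k parts, non-increasing tuples."""
    if maxpart is None:
        maxpart = n
    if k == 1:
        if n <= maxpart:
            yield (n,)
        return
    for first in range(min(n - k + 1, maxpart), 0, -1):
        for rest in _partitions_k(n - first, k - 1, first):
            yield (first,) + rest


def configuration_log_prob(config) -> float:
    """log of n! / (prod_j j^{a_j} a_j!) — the unnormalized ESF weight.

    Dividing by |s(n,k)| gives the conditional probability; the same weight
    ranks configurations for the exact test.
    """
    cfg = tuple(int(c) for c in config)
    n = sum(cfg)
    aj: dict[int, int] = {}
    for c in cfg:
        aj[c] = aj.get(c, 0) + 1
    lp = math.lgamma(n + 1)
    for j, a in aj.items():
        lp -= a * math.log(j) + math.lgamma(a + 1)
    return lp


def _config_log_probs(sims: np.ndarray, n: int) -> np.ndarray:
    """Vectorized `configuration_log_prob` over rows of a (size, k) array.

    Uses sum_j lgamma(a_j + 1) = sum over sorted positions of log(run length).
    """
    s = np.sort(sims, axis=1)
    term1 = np.log(s).sum(axis=1)
    size, k = s.shape
    run = np.ones(size)
    mult = np.zeros(size)
    for j in range(1, k):
        same = s[:, j] == s[:, j - 1]
        run = np.where(same, run + 1, 1.0)
        mult += np.where(same, np.log(run), 0.0)
    return math.lgamma(n + 1) - term1 - mult


# ---------------------------------------------------------------------------
# The test
# ---------------------------------------------------------------------------

def ew_test(
    table: AlleleCountTable,
    rng: np.random.Generator | int | None = None,
    n_repeats: int = 20,
    sims_per_repeat: int = 1000,
    pop: str | int | None = None,
) -> EwensResult:
    """Ewens-Watterson test on pooled (default) or per-population counts.

    P_H, F_exp and P_E are each the mean over ``n_repeats`` independent
    batches of ``sims_per_repeat`` conditional-ESF draws. Ties in F count
    as satisfying F_sim <= F_obs (so P_H is a closed lower tail).
    """
    rng = np.random.default_rng(rng)
    counts = (
        table.pooled() if pop is None
        else table.counts[table.populations.index(pop) if isinstance(pop, str)
                          else int(pop)]
    )
    n = sum(counts.values())
    k = len(counts)
    if n < 2 or k < 2:
        raise ValueError(
            f"Ewens-Watterson test undefined at {table.locus}: n={n}, k={k}"
        )
    obs = tuple(sorted(counts.values(), reverse=True))
    f_obs = sum(c * c for c in obs) / (n * n)
    lp_obs = configuration_log_prob(obs)

    ph, pe, fexp = [], [], []
    for _ in range(n_repeats):
        sims = ewens_conditional_sample(n, k, rng, size=sims_per_repeat)
        f_sim = (sims.astype(float) ** 2).sum(axis=1) / (n * n)
        ph.append((f_sim <= f_obs + 1e-12).mean())
        fexp.append(f_sim.mean())
        lp_sim = _config_log_probs(sims, n)
        pe.append((lp_sim <= lp_obs + 1e-9).mean())
    return EwensResult(
        locus=table.locus, n=n, k=k, F_obs=float(f_obs),
        F_exp=float(np.mean(fexp)), P_H=float(np.mean(ph)),
        P_E=float(np.mean(pe)),
    )
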