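"""Pairwise-population selective-sweep statistics lnRV, lnRH and lnRtheta'.

Variability at a neutral microsatellite scales with theta = 4*N_e*mu; a
locus hitchhiking with a recently selected allele has a locally reduced
N_e in the selected population, hence reduced variance in repeat number
(V), heterozygosity (H) and estimated theta. For a population pair the
log-ratios

    lnRV      = ln(V_1 / V_2)
    lnRH      = ln{ [(1/(1-H_1))^2 - 1] / [(1/(1-H_2))^2 - 1] }
    lnRtheta' = ln(theta'_1 / theta'_2)

are each approximately normal across neutral loci, so per pair and
statistic the across-locus z-score flags outliers at |z| > 1.96 (``*``)
and |z| > 2.58 (``**``). theta' is estimated per locus and population by
approximate Bayesian rejection against single-population stepwise-mutation
coalescent simulations (posterior median), a deliberately lightweight
stand-in for full demographic MCMC — methodologically analogous, not
identical, to heavyweight samplers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coalescent import simulate_island_locus
from .diversity_stats import expected_heterozygosity
from .genotype_io import GenotypeDataset, allele_counts

logger = logging.getLogger("mscan")

__all__ = [
    "LnRRecord",
    "FlagTable",
    "repeat_variance",
    "ln_rv",
    "ln_rh",
    "theta_prime",
    "standardize_and_flag",
    "lnr_scan",
    "polled_horned_pairs",
    "load_pairwise_flag_fixture",
    "summarize_flag_table",
]

FLAGS = ("n.s.", "*", "**")


@dataclass
class LnRRecord:
    locus: str
    pop_a: str
    pop_b: str
    statistic: str   # "lnRV", "lnRH", "lnRtheta"
    value: float
    z: float = float("nan")
    flag: str = "n.s."


@dataclass
class FlagTable:
    """Rows = population pairs, columns = 'statistic:locus', cells in
    {n.s., *, **} (the wide layout used for reporting pairwise scans)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.frame.values.ravel()) - set(FLAGS)
        if bad:
            raise ValueError(f"unknown flag symbols in table: {sorted(bad)}")


def _normalize_flag(x: str) -> str:
    t = str(x).strip().rstrip(".").lower().replace(" ", "")
    if t in ("ns", "n.s"):
        return "n.s."
    if t in ("*", "**"):
        return t
    raise ValueError(f"unknown flag symbol {x!r}")


def repeat_variance(
    ds: GenotypeDataset, locus: str, pop: str | int, motif_length: float = 1.0
) -> float:
    """Unbiased sample variance of repeat number over gene copies.

    Allele codes are divided by ``motif_length`` (default 1: codes already
    in repeat units); fragment-length codes with the true motif length give
    correct repeat variances up to the constant flank offset, which cancels
    in the variance.
    """
    li = ds.locus_index(locus)
    pi = ds.pop_index(pop)
    calls = ds.genotypes[pi][:, li, :].ravel()
    calls = calls[calls != 0]
    if calls.size < 2:
        return float("nan")
    return float(np.var(calls / motif_length, ddof=1))


def lnrv_from_variances(va: float, vb: float) -> float:
    """lnRV from two repeat-number variances."""
    return math.log(va / vb)


def lnrh_from_het(ha: float, hb: float) -> float:
    """lnRH from two expected heterozygosities (both strictly inside [0,1))."""
    ta = (1.0 / (1.0 - ha)) ** 2 - 1.0
    tb = (1.0 / (1.0 - hb)) ** 2 - 1.0
    return math.log(ta / tb)


def ln_rv(
    ds: GenotypeDataset, locus: str, pop_a, pop_b, motif_length: float = 1.0
) -> float:
    """ln of the ratio of repeat-number variances between two populations.

    A zero variance in either population would make the ratio degenerate;
    then a half-count correction (0.5/(n-1) added to both variances) is
    applied with a warning.
    """
    va = repeat_variance(ds, locus, pop_a, motif_length)
    vb = repeat_variance(ds, locus, pop_b, motif_length)
    if math.isnan(va) or math.isnan(vb):
        return float("nan")
    if va == 0.0 or vb == 0.0:
        na = _n_copies(ds, locus, pop_a)
        nb = _n_copies(ds, locus, pop_b)
        logger.warning(
            "lnRV at %s: zero variance (%s/%s); applying half-count "
            "correction", locus, pop_a, pop_b)
        va += 0.5 / (na - 1)
        vb += 0.5 / (nb - 1)
    return math.log(va / vb)


def _n_copies(ds: GenotypeDataset, locus: str, pop) -> int:
    li = ds.locus_index(locus)
    calls = ds.genotypes[ds.pop_index(pop)][:, li, :].ravel()
    return int((calls != 0).sum())


def _het_for_lnrh(ds: GenotypeDataset, locus: str, pop) -> float:
    tab = allele_counts(ds, locus)
    h = expected_heterozygosity(tab, ds.pop_index(pop))
    n = _n_copies(ds, locus, pop)
    if math.isnan(h) or n < 2:
        return float("nan")
    if h == 0.0:
        # smallest nonzero unbiased H at this n: one singleton allele
        logger.warning("lnRH at %s: H=0 in %s; using minimal nonzero H",
                       locus, pop)
        h = 2.0 / n
    if h >= 1.0:
        # all-distinct sample makes the unbiased estimate exactly 1
        logger.warning("lnRH at %s: H=1 in %s; using largest H below 1",
                       locus, pop)
        h = (n - 2) * (n + 1) / (n * (n - 1))
    return h


def ln_rh(ds: GenotypeDataset, locus: str, pop_a, pop_b) -> float:
    """lnRH from unbiased expected heterozygosities of the two populations.

    Under the stepwise model (1/(1-H))^2 - 1 is a moment estimator of
    theta, so lnRH is a theta log-ratio computed from H alone.
    """
    ha = _het_for_lnrh(ds, locus, pop_a)
    hb = _het_for_lnrh(ds, locus, pop_b)
    if math.isnan(ha) or math.isnan(hb):
        return float("nan")
    return lnrh_from_het(ha, hb)


# ---------------------------------------------------------------------------
# theta' by approximate Bayesian rejection under the SMM coalescent
# ---------------------------------------------------------------------------

def theta_prime(
    ds: GenotypeDataset,
    locus: str,
    pop,
    rng: np.random.Generator | int | None = None,
    n_sims: int = 2000,
    accept_frac: float = 0.05,
    theta_bounds: tuple[float, float] = (0.02, 64.0),
    motif_length: float = 1.0,
) -> float:
    """Posterior-median theta for one locus in one population.

    Rejection ABC: simulate ``n_sims`` single-population SMM coalescent
    loci with theta log-uniform over ``theta_bounds``, match on
    (H_E, ln V, k) standardized by the simulation spread, keep the closest
    ``accept_frac`` fraction, return the median accepted theta. Monomorphic
    data land near the lower bound. Deterministic given ``rng``.
    """
    rng = np.random.default_rng(rng)
    n = _n_copies(ds, locus, pop)
    if n < 10:
        raise ValueError(f"theta_prime needs >= 10 gene copies at {locus}")
    tab = allele_counts(ds, locus)
    pi = ds.pop_index(pop)
    h_obs = expected_heterozygosity(tab, pi)
    v_obs = repeat_variance(ds, locus, pop, motif_length)
    k_obs = len(tab.counts[pi])

    thetas = np.exp(rng.uniform(np.log(theta_bounds[0]),
                                np.log(theta_bounds[1]), size=n_sims))
    mat = simulate_island_locus(
        [n], d=1, m=0.0, theta=1.0, model="SMM", n_reps=n_sims,
        seed=int(rng.integers(2**31 - 1)) + 1, theta_per_rep=thetas,
    )
    h_sim = np.empty(n_sims)
    v_sim = np.empty(n_sims)
    k_sim = np.empty(n_sims)
    for r in range(n_sims):
        row = mat[r]
        _, cnt = np.unique(row, return_counts=True)
        p = cnt / n
        h_sim[r] = n / (n - 1) * (1 - (p ** 2).sum())
        v_sim[r] = np.var(row, ddof=1)
        k_sim[r] = cnt.size

    logv = np.log(v_sim + 1e-3)
    feats = np.stack([h_sim, logv, k_sim])
    obs = np.array([h_obs, np.log(v_obs + 1e-3), k_obs])
    sd = feats.std(axis=1)
    sd[sd == 0] = 1.0
    dist = np.sqrt((((feats - obs[:, None]) / sd[:, None]) ** 2).sum(axis=0))
    n_keep = max(int(accept_frac * n_sims), 50)
    if n_keep > n_sims:
        logger.warning("theta_prime: fewer sims than acceptance target")
        n_keep = n_sims
    keep = np.argsort(dist)[:n_keep]
    # local-linear regression adjustment (Beaumont-style): project accepted
    # log-thetas to the observed summary point to debias the posterior
    X = np.column_stack([np.ones(n_keep), (feats[:, keep] / sd[:, None]).T])
    y = np.log(thetas[keep])
    try:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        y_adj = float(np.array([1.0, *(obs / sd)]) @ coef) + resid
        med = float(np.exp(np.median(y_adj)))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
        med = float(np.median(thetas[keep]))
    return float(np.clip(med, theta_bounds[0], theta_bounds[1]))


def ln_rtheta(
    ds: GenotypeDataset, locus: str, pop_a, pop_b,
    rng: np.random.Generator | int | None = None, **kw,
) -> float:
    """ln(theta'_A / theta'_B) with a shared simulation budget."""
    rng = np.random.default_rng(rng)
    ta = theta_prime(ds, locus, pop_a, rng=rng, **kw)
    tb = theta_prime(ds, locus, pop_b, rng=rng, **kw)
    return math.log(ta / tb)


# ---------------------------------------------------------------------------
# Standardization, flagging, and the pairwise scan
# ---------------------------------------------------------------------------

def standardize_and_flag(
    values: dict[str, float], thresholds: tuple[float, float] = (1.96, 2.58)
) -> dict[str, tuple[float, str]]:
    """z-standardize one statistic across loci for one population pair.

    ``values`` maps locus -> statistic value; returns locus -> (z, flag)
    with '*' beyond the 95% threshold and '**' beyond 99%. Needs >= 5
    finite values; a zero SD yields all 'n.s.' with a warning.
    """
    finite = {k: v for k, v in values.items() if np.isfinite(v)}
    if len(finite) < 5:
        raise ValueError("standardization needs >= 5 finite locus values")
    arr = np.array(list(finite.values()))
    mean, sd = arr.mean(), arr.std(ddof=1)
    out = {}
    for loc, v in values.items():
        if not np.isfinite(v):
            out[loc] = (float("nan"), "n.s.")
            continue
        if sd == 0:
            logger.warning("standardize_and_flag: zero SD; all n.s.")
            out[loc] = (0.0, "n.s.")
            continue
        z = (v - mean) / sd
        t95, t99 = thresholds
        flag = "**" if abs(z) > t99 else ("*" if abs(z) > t95 else "n.s.")
        out[loc] = (float(z), flag)
    return out


def polled_horned_pairs(populations: list[str] | None = None):
    """The 12 'polled-group vs horned-group' population pairs.

    Three native polled-type populations crossed with four native horned
    populations; names follow the fixture's population labels.
    """
    polled = ["EasternFin", "WesternFin", "NorthernFin"]
    horned = ["Istoben", "Yakutian", "UkrainianGrey", "Kholmogory"]
    pairs = [(a, b) for a in polled for b in horned]
    if populations is not None:
        missing = {p for pair in pairs for p in pair} - set(populations)
        if missing:
            raise ValueError(f"preset populations absent: {sorted(missing)}")
    return pairs


def lnr_scan(
    ds: GenotypeDataset,
    pairs: list[tuple[str, str]],
    candidate_loci: list[str] | None = None,
    statistics: tuple[str, ...] = ("lnRV", "lnRH", "lnRtheta"),
    motif_length: float | dict[str, float] = 1.0,
    reference_loci: list[str] | None = None,
    rng: np.random.Generator | int | None = None,
    theta_sims: int = 1500,
) -> tuple[list[LnRRecord], FlagTable]:
    """Compute the chosen statistics for every pair and locus, z-flag them.

    Standardization uses all finite loci (``reference_loci`` restricts the
    mean/SD to a neutral reference set). ``candidate_loci`` restricts which
    loci appear as columns of the flag table (all loci by default). For
    lnRtheta the per-(locus, population) theta' values are computed once
    and reused across pairs.
    """
    rng = np.random.default_rng(rng)
    loci = list(ds.loci)
    report = loci if candidate_loci is None else list(candidate_loci)

    def motif(loc: str) -> float:
        if isinstance(motif_length, dict):
            return motif_length.get(loc, 1.0)
        return float(motif_length)

    theta_cache: dict[tuple[str, str], float] = {}
    if "lnRtheta" in statistics:
        pops_needed = sorted({p for pr in pairs for p in pr})
        for pop in pops_needed:
            for loc in loci:
                try:
                    theta_cache[(loc, pop)] = theta_prime(
                        ds, loc, pop, rng=rng, n_sims=theta_sims,
                        motif_length=motif(loc))
                except ValueError:
                    theta_cache[(loc, pop)] = float("nan")

    records: list[LnRRecord] = []
    cols: dict[str, dict[str, str]] = {}
    for (pa, pb) in pairs:
        pair_name = f"{pa}-{pb}"
        cols[pair_name] = {}
        for stat in statistics:
            vals: dict[str, float] = {}
            for loc in loci:
                if stat == "lnRV":
                    v = ln_rv(ds, loc, pa, pb, motif(loc))
                elif stat == "lnRH":
                    v = ln_rh(ds, loc, pa, pb)
                else:
                    ta = theta_cache.get((loc, pa), float("nan"))
                    tb = theta_cache.get((loc, pb), float("nan"))
                    v = (math.log(ta / tb)
                         if np.isfinite(ta) and np.isfinite(tb) and ta > 0
                         and tb > 0 else float("nan"))
                vals[loc] = v
            base = ({k: vals[k] for k in reference_loci}
                    if reference_loci is not None else vals)
            arr = np.array([v for v in base.values() if np.isfinite(v)])
            mean, sd = arr.mean(), arr.std(ddof=1)
            for loc in loci:
                v = vals[loc]
                if np.isfinite(v) and sd > 0:
                    z = (v - mean) / sd
                    flag = ("**" if abs(z) > 2.58 else
                            "*" if abs(z) > 1.96 else "n.s.")
                else:
                    z, flag = float("nan"), "n.s."
                records.append(LnRRecord(loc, pa, pb, stat, v, z, flag))
                if loc in report:
                    cols[pair_name][f"{stat}:{loc}"] = flag
    frame = pd.DataFrame.from_dict(cols, orient="index")
    frame.index.name = "pair"
    return records, FlagTable(frame=frame)


# ---------------------------------------------------------------------------
# Flag-table summaries (and the shipped wide-table fixture)
# ---------------------------------------------------------------------------

def load_pairwise_flag_fixture() -> FlagTable:
    """The shipped 12-pair x (3 statistics x 2 loci) significance matrix."""
    import importlib.resources

    ref = importlib.resources.files("mscan.data") / "pairwise_flags.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", index_col=0, dtype=str)
    df = df.map(_normalize_flag)
    df.index.name = "pair"
    return FlagTable(frame=df)


def summarize_flag_table(
    tbl: FlagTable,
    loci: list[str] | None = None,
    statistics: list[str] | None = None,
    pairs: list[str] | None = None,
) -> int:
    """Count significant cells ('*' or '**'), optionally sliced."""
    df = tbl.frame
    if pairs is not None:
        df = df.loc[pairs]
    cols = df.columns
    if statistics is not None:
        cols = [c for c in cols if c.split(":")[0] in statistics]
    if loci is not None:
        cols = [c for c in cols if c.split(":", 1)[1] in loci]
    sub = df[list(cols)]
    return int(sub.isin(["*", "**"]).values.sum())
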