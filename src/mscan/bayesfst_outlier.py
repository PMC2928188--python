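"""Hierarchical Bayesian F_ST outlier test.

Locus-by-population differentiation is modelled on the logistic scale,

    F_ST(i, j) = exp(a_i + b_j + g_ij) / (1 + exp(a_i + b_j + g_ij)),

with locus effects a_i, population effects b_j and interactions g_ij.
Allele counts in population j at locus i are Dirichlet-multinomial around
the locus-wide mean allele frequencies with concentration
(1 - F_ST(i,j)) / F_ST(i,j) (allele frequencies integrated out
analytically). Effects carry zero-mean normal priors whose scales get
half-Cauchy hyper-priors; b and the rows/columns of g are centered each
sweep (the compensating shift absorbed by a and b, which leaves the
likelihood invariant) for identifiability. Sampling is vectorized
Metropolis-within-Gibbs; outliers are read off the locus-effect posterior:
large positive a_i = unusually differentiated (directional selection),
large negative = unusually homogeneous (balancing selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotype_io import GenotypeDataset, allele_counts

logger = logging.getLogger("mscan")

__all__ = [
    "BayesFstPosterior",
    "BayesFstResult",
    "fit_bayesfst",
    "classify_outliers",
    "fst_from_effects",
]


@dataclass
class BayesFstPosterior:
    loci: list[str]
    populations: list[str]
    alpha: np.ndarray    # (n_chains, n_samples, L)
    beta: np.ndarray     # (n_chains, n_samples, J)
    mean_fst: np.ndarray  # (n_chains, n_samples) posterior mean F_ST(i,j)
    rhat_alpha: np.ndarray
    accept_rates: dict[str, float]

    @property
    def alpha_flat(self) -> np.ndarray:
        return self.alpha.reshape(-1, self.alpha.shape[-1])


@dataclass
class BayesFstResult:
    locus: str
    alpha_mean: float
    alpha_q025: float
    alpha_q975: float
    prob_positive: float
    direction: str


def fst_from_effects(alpha, beta, gamma=0.0, mu=0.0):
    """F_ST(i,j) from effects on the logistic scale (0.5 at all-zero).

    ``mu`` is the global intercept; with sum-to-zero alpha/beta/gamma it
    carries the genome-wide differentiation level, so locus effects are
    deviations from it and their sign is directly interpretable.
    """
    x = (mu + np.asarray(alpha)[..., :, None] + np.asarray(beta)[..., None, :]
         + gamma)
    return 1.0 / (1.0 + np.exp(-x))


def _prepare_counts(ds: GenotypeDataset):
    """Pad per-locus allele-count tables into a (L, J, A_max) tensor."""
    loci, tables = [], []
    for loc in ds.loci:
        tab = allele_counts(ds, loc)
        mat, alleles = tab.to_matrix()
        if len(alleles) < 2:
            logger.warning("bayesfst: locus %s monomorphic; excluded", loc)
            continue
        loci.append(loc)
        tables.append(mat)
    L = len(loci)
    J = ds.n_populations
    A = max(t.shape[1] for t in tables)
    C = np.zeros((L, J, A))
    for i, t in enumerate(tables):
        C[i, :, :t.shape[1]] = t
    pooled = C.sum(axis=1)                      # (L, A)
    pi = pooled / pooled.sum(axis=1, keepdims=True)
    n = C.sum(axis=2)                           # (L, J)
    return loci, C, pi, n


def _loglik(C, pi, n, F):
    """Dirichlet-multinomial log-likelihood per (locus, population) cell."""
    c = (1.0 - F) / F                           # concentration, (L, J)
    a = c[:, :, None] * pi[:, None, :]          # (L, J, A)
    ll = gammaln(c) - gammaln(c + n)
    ll += np.where(a > 0, gammaln(a + C) - gammaln(np.where(a > 0, a, 1.0)),
                   0.0).sum(axis=2)
    return ll


def fit_bayesfst(
    ds: GenotypeDataset,
    chains: int = 4,
    iterations: int = 20000,
    burn_in: float = 0.5,
    thin: int = 10,
    rng: np.random.Generator | int | None = None,
    include_interactions: bool = True,
    step: float = 0.35,
) -> BayesFstPosterior:
    """Sample the posterior of the hierarchical logistic F_ST model.

    ``iterations`` are per chain; the first ``burn_in`` fraction is
    discarded and the rest thinned by ``thin``. Priors: a_i ~ N(0, s_a^2),
    b_j ~ N(0, s_b^2), g_ij ~ N(0, s_g^2); s_a, s_b ~ half-Cauchy(0,1),
    s_g ~ half-Cauchy(0, 0.25) (interactions shrunk harder to keep the
    model identified at ~50 loci x 10 populations). Deterministic given
    ``rng``; a convergence warning is logged when split-R-hat of any locus
    effect exceeds 1.1.
    """
    master = np.random.default_rng(rng)
    loci, C, pi, n = _prepare_counts(ds)
    L, J = n.shape
    if L < 2 or J < 2:
        raise ValueError("bayesfst needs >= 2 polymorphic loci and >= 2 pops")
    keep_from = int(burn_in * iterations)
    kept = (iterations - keep_from) // thin
    alpha_out = np.empty((chains, kept, L))
    beta_out = np.empty((chains, kept, J))
    meanf_out = np.empty((chains, kept))
    acc = {"mu": 0.0, "alpha": 0.0, "beta": 0.0, "gamma": 0.0}

    for ch in range(chains):
        crng = np.random.default_rng(master.integers(2**31 - 1))
        mu = float(crng.normal(-2.0, 0.5))
        alpha = crng.normal(0, 0.3, L)
        beta = crng.normal(0, 0.3, J)
        gamma = np.zeros((L, J))
        s_a, s_b, s_g = 0.5, 0.5, 0.1
        F = fst_from_effects(alpha, beta, gamma, mu)
        ll = _loglik(C, pi, n, F)
        ki = 0
        step_a = step
        step_mu = step / np.sqrt(L * J)
        step_b = step / np.sqrt(L) * 2.0
        # Robbins-Monro-style step adaptation toward ~30% acceptance,
        # frozen at the end of burn-in so the kept chain is Markovian
        win = {"mu": 0.0, "alpha": 0.0, "beta": 0.0, "gamma": 0.0}
        g_mult = 1.0
        for it in range(iterations):
            # --- global intercept
            prop_mu = mu + crng.normal(0, step_mu)
            Fp = fst_from_effects(alpha, beta, gamma, prop_mu)
            llp = _loglik(C, pi, n, Fp)
            d = (llp - ll).sum() + (mu**2 - prop_mu**2) / (2 * 5.0**2)
            if np.log(crng.random()) < d:
                mu, F, ll = prop_mu, Fp, llp
                acc["mu"] += 1.0
                win["mu"] += 1.0

            # --- locus effects (independent across loci given the rest)
            prop = alpha + crng.normal(0, step_a, L)
            Fp = fst_from_effects(prop, beta, gamma, mu)
            llp = _loglik(C, pi, n, Fp)
            dpost = (llp - ll).sum(axis=1)
            dpost += (alpha**2 - prop**2) / (2 * s_a**2)
            ok = np.log(crng.random(L)) < dpost
            alpha = np.where(ok, prop, alpha)
            F[ok] = Fp[ok]
            ll[ok] = llp[ok]
            acc["alpha"] += ok.mean()
            win["alpha"] += ok.mean()

            # --- population effects (independent across populations)
            prop = beta + crng.normal(0, step_b, J)
            Fp = fst_from_effects(alpha, prop, gamma, mu)
            llp = _loglik(C, pi, n, Fp)
            dpost = (llp - ll).sum(axis=0)
            dpost += (beta**2 - prop**2) / (2 * s_b**2)
            ok = np.log(crng.random(J)) < dpost
            beta = np.where(ok, prop, beta)
            F[:, ok] = Fp[:, ok]
            ll[:, ok] = llp[:, ok]
            acc["beta"] += ok.mean()
            win["beta"] += ok.mean()

            # --- interactions (independent across cells); proposal scale
            # tracks the shrinkage prior so mixing survives small s_g
            if include_interactions:
                sg_step = max(s_g, 0.02) * g_mult
                propg = gamma + crng.normal(0, sg_step, (L, J))
                Fp = fst_from_effects(alpha, beta, propg, mu)
                llp = _loglik(C, pi, n, Fp)
                dpost = llp - ll + (gamma**2 - propg**2) / (2 * s_g**2)
                okg = np.log(crng.random((L, J))) < dpost
                gamma = np.where(okg, propg, gamma)
                F = np.where(okg, Fp, F)
                ll = np.where(okg, llp, ll)
                acc["gamma"] += okg.mean()
                win["gamma"] += okg.mean()

                # identifiability: move row/column means of gamma into
                # alpha/beta (likelihood-invariant reparameterization)
                rm = gamma.mean(axis=1)
                alpha = alpha + rm
                gamma = gamma - rm[:, None]
                cm = gamma.mean(axis=0)
                beta = beta + cm
                gamma = gamma - cm[None, :]
            # sum-to-zero: centers of alpha and beta move into mu
            am, bm = alpha.mean(), beta.mean()
            alpha = alpha - am
            beta = beta - bm
            mu = mu + am + bm

            # --- hyper-scales: log-scale Metropolis, half-Cauchy priors
            s_a = _update_scale(s_a, alpha, 1.0, crng)
            s_b = _update_scale(s_b, beta, 1.0, crng)
            if include_interactions:
                s_g = _update_scale(s_g, gamma.ravel(), 0.25, crng)

            if it < keep_from // 2 and (it + 1) % 50 == 0:
                fac = lambda a: float(np.exp(0.8 * (a / 50 - 0.30)))
                step_mu *= fac(win["mu"])
                step_a *= fac(win["alpha"])
                step_b *= fac(win["beta"])
                g_mult *= fac(win["gamma"])
                for kk in win:
                    win[kk] = 0.0

            if it >= keep_from and (it - keep_from) % thin == 0 and ki < kept:
                alpha_out[ch, ki] = alpha
                beta_out[ch, ki] = beta
                meanf_out[ch, ki] = F.mean()
                ki += 1

    for k in acc:
        acc[k] /= chains * iterations
    rhat = _split_rhat(alpha_out)
    if np.any(rhat > 1.1):
        worst = [loci[i] for i in np.nonzero(rhat > 1.1)[0]]
        logger.warning("bayesfst: R-hat > 1.1 for locus effects %s", worst)
    # sum-to-zero on beta is enforced each sweep; assert it held
    assert np.allclose(beta_out.mean(axis=-1), 0, atol=1e-8)
    return BayesFstPosterior(
        loci=loci, populations=list(ds.populations), alpha=alpha_out,
        beta=beta_out, mean_fst=meanf_out, rhat_alpha=rhat,
        accept_rates=acc,
    )


def _update_scale(s, values, cauchy_scale, rng, step=0.3):
    """Metropolis update of a prior scale with half-Cauchy(0, cs) prior."""
    m = values.size
    prop = s * np.exp(rng.normal(0, step))
    def logp(x):
        return (
            -m * np.log(x) - (values**2).sum() / (2 * x**2)
            - np.log(1 + (x / cauchy_scale) ** 2)
            + np.log(x)  # Jacobian of the log-scale walk
        )
    if np.log(rng.random()) < logp(prop) - logp(s):
        return prop
    return s


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter; draws is (chains, samples, P)."""
    c, s, p = draws.shape
    if s < 4:
        return np.full(p, np.nan)
    half = s // 2
    segs = draws[:, :2 * half].reshape(c * 2, half, p)
    means = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / W)


def classify_outliers(
    posterior: BayesFstPosterior, level: float = 0.05
) -> list[BayesFstResult]:
    """Call outliers from the locus-effect posterior tails.

    Directional when P(a_i > 0) >= 1 - level/2; balancing when
    <= level/2; otherwise none.
    """
    a = posterior.alpha_flat
    out = []
    for i, loc in enumerate(posterior.loci):
        ppos = float((a[:, i] > 0).mean())
        lo, hi = np.quantile(a[:, i], [0.025, 0.975])
        if ppos >= 1 - level / 2:
            d = "directional"
        elif ppos <= level / 2:
            d = "balancing"
        else:
            d = "none"
        out.append(BayesFstResult(
            locus=loc, alpha_mean=float(a[:, i].mean()),
            alpha_q025=float(lo), alpha_q975=float(hi),
            prob_positive=ppos, direction=d,
        ))
    return out
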