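"""Synthetic microsatellite genotype generators.

Two engines with one output type. Neutral multi-population variation is
simulated backward in time under the finite island coalescent (IAM or strict
SMM mutation); selective sweeps are simulated forward in time as diploid
Wright-Fisher populations at the gamete level, with a (by default dominant)
beneficial allele, per-marker recombination distances to the selected site,
and mutation — the regime where hitchhiking, dominance and recombination all
matter. ``make_study_fixture`` combines the two into a 10-population,
51-locus dataset shaped like the cattle study the pipeline targets: 366
individuals, 7 + 16 loci mapped to chromosomes "1" and "20", one population
typed at only 41 loci, and two chromosome-1 loci swept in three populations.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np

from ._coalescent import simulate_island_locus
from .genotype_io import GenotypeDataset, MarkerMap, read_marker_map

logger = logging.getLogger("mscan")

__all__ = [
    "SimConfig",
    "SweepConfig",
    "SweepTruth",
    "simulate_island_neutral",
    "simulate_sweep_forward",
    "make_study_fixture",
    "STUDY_POP_SIZES",
    "STUDY_POP_NAMES",
]

# Diploid sample sizes of the study the fixture emulates (366 animals total).
STUDY_POP_SIZES = [40, 40, 31, 37, 26, 40, 51, 32, 30, 39]
STUDY_POP_NAMES = [
    "Ayrshire", "Holstein", "EasternFin", "WesternFin", "NorthernFin",
    "Istoben", "Yakutian", "Kholmogory", "UkrainianGrey", "Jersey",
]
# The three native populations carrying the swept haplotypes in the fixture.
FIXTURE_SELECTED_POPS = [2, 3, 4]


@dataclass
class SimConfig:
    """Neutral island-model generator parameters.

    theta = 4*N_e*mu per locus (a scalar or one value per locus);
    migration_rate is per gene copy per generation.
    """

    n_demes: int = 100
    sampled_pops: int = 10
    sample_sizes: list[int] = field(default_factory=lambda: [50] * 10)
    n_loci: int = 50
    mutation_model: str = "IAM"
    theta: float | list[float] = 2.0
    migration_rate: float = 0.02
    deme_size: float = 1000.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sampled_pops > self.n_demes:
            raise ValueError("sampled_pops must not exceed n_demes")
        if len(self.sample_sizes) != self.sampled_pops:
            raise ValueError("sample_sizes length must equal sampled_pops")
        if any(s < 2 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2 diploids")
        th = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if (th <= 0).any():
            raise ValueError("theta must be positive")
        if self.n_demes > 1 and self.migration_rate <= 0:
            raise ValueError("migration rate must be positive")
        if self.mutation_model not in ("IAM", "SMM"):
            raise ValueError("mutation_model must be IAM or SMM")


@dataclass
class SweepConfig:
    """Forward Wright-Fisher sweep generator parameters.

    A beneficial allele (selection s, dominance h; h=1 mimics a dominant
    allele such as polled) arises in ``selected_pops``; each of ``n_markers``
    microsatellites recombines with the selected site at fraction ``c[k]``
    per meiosis. All populations start from a shared neutral ancestral pool
    (coalescent at ``theta_ancestral``) and drift for ``generations``.
    """

    N: int = 200
    generations: int = 100
    s: float = 0.5
    h: float = 1.0
    c: list[float] = field(default_factory=lambda: [0.001])
    mu: float = 1e-4
    mutation_model: str = "SMM"
    n_pops: int = 2
    sample_sizes: list[int] | None = None
    selected_pops: list[int] = field(default_factory=lambda: [0])
    theta_ancestral: float = 4.0
    max_retries: int = 200
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sample_sizes is None:
            self.sample_sizes = [min(50, self.N)] * self.n_pops
        if any(not (0.0 <= ck <= 0.5) for ck in self.c):
            raise ValueError("recombination fractions must lie in [0, 0.5]")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("dominance h must lie in [0, 1]")
        if any(p < 0 or p >= self.n_pops for p in self.selected_pops):
            raise ValueError("selected_pops out of range")
        if any(n > self.N for n in self.sample_sizes):
            raise ValueError("sample sizes cannot exceed N")


@dataclass
class SweepTruth:
    """Ground truth emitted alongside a sweep dataset."""

    linked_loci: list[str]
    selected_pops: list[int]
    trajectories: dict[int, np.ndarray]  # pop -> beneficial-allele frequency
    fixed: dict[int, bool]
    retries: int


def simulate_island_neutral(cfg: SimConfig) -> GenotypeDataset:
    """Unlinked neutral loci under the finite island coalescent.

    Gene copies sampled per deme are paired at random into diploids; loci
    are independent. Expected F_ST at equilibrium decreases with migration,
    approximately 1/(1 + 4Nm (d/(d-1))^2) for d demes.
    """
    ss = np.asarray(cfg.sample_sizes, dtype=np.int64)
    spd = 2 * ss
    th = np.atleast_1d(np.asarray(cfg.theta, dtype=float))
    if th.size == 1:
        theta_per_rep = np.full(cfg.n_loci, th[0])
    elif th.size == cfg.n_loci:
        theta_per_rep = th.astype(float)
    else:
        raise ValueError("theta must be scalar or one value per locus")
    mat = simulate_island_locus(
        spd, d=cfg.n_demes, m=cfg.migration_rate, theta=1.0,
        model=cfg.mutation_model, n_reps=cfg.n_loci, seed=cfg.seed % (2**31),
        theta_per_rep=theta_per_rep, N=cfg.deme_size,
    )  # (n_loci, total gene copies)
    rng = np.random.default_rng(cfg.seed)
    genotypes = []
    offsets = np.concatenate([[0], np.cumsum(spd)])
    loci = [f"L{i + 1}" for i in range(cfg.n_loci)]
    for p in range(cfg.sampled_pops):
        block = mat[:, offsets[p]:offsets[p + 1]]  # (n_loci, 2*ndip)
        g = np.empty((ss[p], cfg.n_loci, 2), dtype=np.int64)
        for l in range(cfg.n_loci):
            copies = rng.permutation(block[l])
            g[:, l, 0] = copies[0::2]
            g[:, l, 1] = copies[1::2]
        genotypes.append(g)
    return GenotypeDataset(
        populations=[f"pop{p + 1}" for p in range(cfg.sampled_pops)],
        loci=loci, genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# Forward sweep engine
# ---------------------------------------------------------------------------

def _ancestral_pool(theta: float, size: int, model: str, seed: int) -> np.ndarray:
    """A sample of `size` gene copies from one panmictic ancestral deme."""
    return simulate_island_locus(
        [size], d=1, m=0.0, theta=theta, model=model, n_reps=1, seed=seed
    )[0]


def _evolve_population(
    gametes: np.ndarray, s: float, h: float, c: np.ndarray, mu: float,
    model: str, generations: int, rng: np.random.Generator,
    track_benef: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Run one Wright-Fisher population forward; returns (gametes, traj).

    ``gametes`` is (2N, 1+L): column 0 the selected-site allele (0/1),
    columns 1..L the marker alleles. Selection acts on diploids paired from
    consecutive gamete rows; each offspring gamete is a recombinant meiotic
    product of one fitness-weighted parent diploid.
    """
    twoN, width = gametes.shape
    N = twoN // 2
    L = width - 1
    traj = np.empty(generations + 1)
    new_allele = int(gametes[:, 1:].max()) + 1 if L else 1
    for gen in range(generations):
        traj[gen] = gametes[:, 0].mean()
        ga = gametes[0::2]
        gb = gametes[1::2]
        nben = ga[:, 0] + gb[:, 0]
        w = np.where(nben == 2, 1 + s, np.where(nben == 1, 1 + h * s, 1.0))
        probs = w / w.sum()
        parents = rng.choice(N, size=twoN, p=probs)
        pa, pb = ga[parents], gb[parents]
        # meiosis: pick the haplotype transmitting the selected site, then
        # recombine each marker independently at fraction c[k]
        pick_b = rng.random(twoN) < 0.5
        same = np.where(pick_b[:, None], pb, pa)
        other = np.where(pick_b[:, None], pa, pb)
        rec = rng.random((twoN, L)) < c[None, :]
        out = np.empty_like(gametes)
        out[:, 0] = same[:, 0]
        out[:, 1:] = np.where(rec, other[:, 1:], same[:, 1:])
        # mutation
        if mu > 0 and L:
            hits = rng.random((twoN, L)) < mu
            if hits.any():
                idx = np.nonzero(hits)
                if model == "SMM":
                    steps = rng.choice([-1, 1], size=len(idx[0]))
                    vals = out[:, 1:][idx] + steps
                    vals[vals < 1] = 2  # reflect at repeat count 1
                    out[:, 1:][idx] = vals
                else:
                    for r, k in zip(*idx):
                        out[r, 1 + k] = new_allele
                        new_allele += 1
        gametes = rng.permutation(out, axis=0)
        if track_benef and gametes[:, 0].sum() == 0:
            traj[gen + 1:] = 0.0
            return gametes, traj
    traj[generations] = gametes[:, 0].mean()
    return gametes, traj


def simulate_sweep_forward(
    cfg: SweepConfig,
) -> tuple[GenotypeDataset, SweepTruth]:
    """Forward diploid sweep simulation across populations.

    In ``selected_pops`` a single beneficial copy is seeded and the run is
    restarted (fresh randomness, up to ``max_retries``) whenever it is lost,
    so post-sweep summaries are conditioned on establishment. Unselected
    populations drift neutrally from the same ancestral pool. Marker loci
    are named ``M1..ML``; the dataset records markers only (the selected
    site itself is a phenotype locus, not a typed microsatellite).
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(cfg.c)
    c = np.asarray(cfg.c, dtype=float)
    twoN = 2 * cfg.N
    # shared ancestral pools, one per marker
    pools = [
        _ancestral_pool(cfg.theta_ancestral, twoN, cfg.mutation_model,
                        int(rng.integers(2**31 - 1)) + 1)
        for _ in range(L)
    ]
    genotypes = []
    trajectories: dict[int, np.ndarray] = {}
    fixed: dict[int, bool] = {}
    total_retries = 0
    for p in range(cfg.n_pops):
        selected = p in cfg.selected_pops
        attempts = 0
        while True:
            # every population starts from the same ancestral gamete pool
            # (drift separates them only after the split; iid resampling
            # would add a spurious founder bottleneck per population)
            g0 = np.zeros((twoN, 1 + L), dtype=np.int64)
            for k in range(L):
                g0[:, 1 + k] = rng.permutation(pools[k])
            if selected and cfg.s > 0:
                g0[rng.integers(twoN), 0] = 1
            gam, traj = _evolve_population(
                g0, cfg.s, cfg.h, c, cfg.mu, cfg.mutation_model,
                cfg.generations, rng, track_benef=selected and cfg.s > 0,
            )
            if not (selected and cfg.s > 0) or traj[-1] > 0:
                break
            attempts += 1
            total_retries += 1
            if attempts >= cfg.max_retries:
                raise RuntimeError(
                    f"beneficial allele lost in population {p} after "
                    f"{attempts} retries"
                )
        trajectories[p] = traj
        fixed[p] = bool(selected and traj[-1] == 1.0)
        # sample diploids
        take = rng.choice(cfg.N, size=cfg.sample_sizes[p], replace=False)
        ga = gam[0::2][take, 1:]
        gb = gam[1::2][take, 1:]
        genotypes.append(np.stack([ga, gb], axis=2))
    ds = GenotypeDataset(
        populations=[f"pop{p + 1}" for p in range(cfg.n_pops)],
        loci=[f"M{k + 1}" for k in range(L)],
        genotypes=genotypes,
    )
    truth = SweepTruth(
        linked_loci=[f"M{k + 1}" for k in range(L) if cfg.c[k] < 0.5],
        selected_pops=list(cfg.selected_pops),
        trajectories=trajectories,
        fixed=fixed,
        retries=total_retries,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# Study-shaped fixture
# ---------------------------------------------------------------------------

def load_reference_marker_map() -> MarkerMap:
    """The 51-locus marker map shipped with the package (7 on "1", 16 on "20")."""
    ref = importlib.resources.files("mscan.data") / "marker_map.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_marker_map(p)


# Loci the Jersey-like population is not typed at (41 of 51 typed).
_JERSEY_MISSING = [
    "DIK4591", "DIK1044", "DIK5019", "NRDIKM033", "BMS2461", "DIK2695",
    "GHRpromS", "DIK4835", "UMBTL78", "HAUT27",
]
_SWEEP_LOCI = {"AGLA17": 0.002, "SOD1": 0.008}  # locus -> c to selected site


def make_study_fixture(
    seed: int = 1,
    sweep: bool = True,
    generations: int = 100,
    N: int = 200,
) -> tuple[GenotypeDataset, MarkerMap]:
    """Deterministic 10-population, 51-locus dataset shaped like the study.

    366 individuals split 40/40/31/37/26/40/51/32/30/39; loci named and
    mapped per the shipped marker map; the last population is masked at 10
    loci; with ``sweep=True`` the two centromeric chromosome-1 loci are
    replaced by forward-sweep output with the beneficial allele driven
    through populations 3-5 (the "native polled" group).
    """
    mmap = load_reference_marker_map()
    rng = np.random.default_rng(seed)
    n_loci = len(mmap)
    # deme-level theta; the metapopulation-effective theta is ~20x larger,
    # spanning expected heterozygosities of roughly 0.08-0.8 under the SMM
    thetas = np.exp(rng.uniform(np.log(0.008), np.log(0.55), size=n_loci))
    cfg = SimConfig(
        n_demes=20, sampled_pops=10, sample_sizes=STUDY_POP_SIZES,
        n_loci=n_loci, mutation_model="SMM", theta=list(thetas),
        migration_rate=0.0017, deme_size=1000.0,
        seed=int(rng.integers(2**31 - 1)) + 1,
    )
    ds = simulate_island_neutral(cfg)
    # marker ascertainment: genotyping panels use loci known to be
    # polymorphic, so monomorphic draws are resimulated (theta doubled
    # after each failed round)
    for _ in range(20):
        mono = [i for i in range(n_loci)
                if len({a for g in ds.genotypes
                        for a in np.unique(g[:, i, :]) if a != 0}) < 2]
        if not mono:
            break
        thetas[mono] *= 1.5
        redo = SimConfig(
            n_demes=20, sampled_pops=10, sample_sizes=STUDY_POP_SIZES,
            n_loci=len(mono), mutation_model="SMM",
            theta=list(thetas[mono]), migration_rate=0.0017,
            deme_size=1000.0, seed=int(rng.integers(2**31 - 1)) + 1,
        )
        sub = simulate_island_neutral(redo)
        for j, i in enumerate(mono):
            for p in range(10):
                ds.genotypes[p][:, i, :] = sub.genotypes[p][:, j, :]
    ds.populations = list(STUDY_POP_NAMES)
    ds.loci = mmap.names

    if sweep:
        scfg = SweepConfig(
            N=N, generations=generations, s=0.5, h=1.0,
            c=list(_SWEEP_LOCI.values()), mu=1e-4, mutation_model="SMM",
            n_pops=10, sample_sizes=STUDY_POP_SIZES,
            selected_pops=FIXTURE_SELECTED_POPS,
            theta_ancestral=4.0, seed=int(rng.integers(2**31 - 1)) + 1,
        )
        sweep_ds, _ = simulate_sweep_forward(scfg)
        for k, name in enumerate(_SWEEP_LOCI):
            li = ds.loci.index(name)
            for p in range(10):
                ds.genotypes[p][:, li, :] = sweep_ds.genotypes[p][:, k, :]

    # Jersey-like population typed at only 41 loci
    for name in _JERSEY_MISSING:
        ds.genotypes[-1][:, ds.loci.index(name), :] = 0
    return ds, mmap
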