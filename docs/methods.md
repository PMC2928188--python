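# Methods

This note documents the models behind each module, the defaults and why,
the numerical choices, and what the synthetic-data generators do and do
not emulate.

## Data model

Genotypes are unordered diploid pairs of positive-integer allele codes
(repeat counts or fragment lengths; 0 = missing), organised as populations
× individuals × loci. GENEPOP text (2- or 3-digit encodings, `POP`
delimiters in any case, label before the last comma) is the interchange
format; marker positions come from a TSV `locus / chromosome / start_bp /
end_bp` with `NA` for missing. Intervals with start > end are normalised
to (min, max) with a warning, and intervals spanning more than 10 Mb are
flagged as suspect, since microsatellite amplicons are under a kilobase.
Whether codes are repeat counts or fragment lengths is metadata: lnRV
takes an explicit per-locus motif length (default 1, i.e. codes already in
repeat units); a constant flank offset cancels in the variance, so
fragment-length codes with the right motif length are handled correctly.

## Island-model coalescent engine

The symmetric island model (d demes of diploid size N, migration m per
gene copy per generation) is simulated backward in time with a Gillespie
loop over coalescence (rate k_i(k_i−1)/(4N) per deme) and migration (rate
k·m) events, exploiting deme exchangeability. Mutations are Poisson on
branches: IAM (every mutation a brand-new allele) or strict SMM (±1 steps,
reflecting at repeat count 1; root state 100, far from the bound). The
loop is numba-compiled; a 100-deme, 1000-sample genealogy simulates in
~4 ms, which is what makes ~10⁴-replicate nulls practical. Only the
products θ = 4Nμ and 4Nm matter; N merely sets the time scale. In
multi-deme nulls the θ grid is expressed at the metapopulation scale
(4·d·N·μ), the quantity that actually sets heterozygosity. The engine is
cross-checked in tests against the closed-form island-model expectation
F_ST ≈ 1/(1 + 4Nm(d/(d−1))²); msprime serves as the simulator for the
two-population split model (divergence-envelope null), where its generic
demography machinery is fast.

## Synthetic data

**Neutral generator** (`simulate_island_neutral`): unlinked loci,
independent genealogies, gene copies paired randomly into diploids.

**Sweep generator** (`simulate_sweep_forward`): forward diploid
Wright–Fisher at the gamete level. Each population starts from one shared
ancestral gamete pool (a single-population coalescent sample at
θ_ancestral, default 4), so populations share ancestry and drift apart
only after the split; i.i.d. resampling of founders would insert a
spurious bottleneck per population and was deliberately avoided. In
selected populations one beneficial copy is seeded (selection s, default
0.5; dominance h, default 1 to mimic a dominant allele such as polled);
runs where it is lost are restarted (cap 200) so post-sweep summaries are
conditioned on establishment. Each marker recombines with the selected
site at its own fraction c_k per meiosis; markers are conditionally
independent given the selected site, which matches the star-like geometry
of hitchhiking but ignores marker–marker interference. Mutation is per
gamete per generation (default 10⁻⁴), SMM or IAM.

**Study-shaped fixture** (`make_study_fixture`): 10 populations of
40/40/31/37/26/40/51/32/30/39 diploids (366 total) at the 51 mapped loci
of the shipped marker map (7 on chromosome "1", 16 on "20"); the last
population is untyped at 10 loci; the two centromeric chromosome-1 loci
are replaced by sweep output with the beneficial allele driven through
populations 3–5. Neutral parameters: 20 demes of N = 1000, m = 0.0017
(≈ F_ST 0.12), per-locus deme-level θ log-uniform on [0.008, 0.55], SMM —
chosen once to give a multi-locus F_ST near 0.12 and heterozygosities
spanning roughly 0.05–0.8, the ranges typical of diverged cattle breeds.
Monomorphic draws are resimulated with θ increased 1.5× per round,
emulating the ascertainment of marker panels (published microsatellites
are chosen because they are polymorphic).

What the generators do **not** emulate: genotyping error and allelic
dropout, non-equilibrium demography (expansions, admixture), linkage among
neutral markers away from the selected site, and mutation-rate
heterogeneity beyond the θ grid. Passing tests therefore demonstrate
statistical correctness and power under idealised mutation–drift–migration
dynamics, not robustness to those real-data complications.

## Diversity statistics

H_E is Nei's unbiased gene diversity (FSTAT's convention; the raw Σp² form
is also conceivable but the unbiased one was adopted). A_R uses
hypergeometric rarefaction to g gene copies, g defaulting to the smallest
per-population non-missing count. Weir–Cockerham components (a, b, c) are
summed over alleles; the multi-locus estimate is ratio-of-sums; per-locus
SDs are delete-one-population jackknives; the 95% CI is a 1000-replicate
bootstrap over loci. Negative estimates are reported as-is. The estimator
is verified to 10⁻¹⁰ against an independent sums-of-squares (ANOVA)
decomposition on exhaustive small tables.

## Ewens–Watterson test

Conditional on (n, k) the infinite-allele configuration probability is
θ-free: Pr(a) = n!/(∏_j j^{a_j} a_j!)/|s(n,k)| — the cycle type of a
uniform permutation of n elements with exactly k cycles. The sampler
decides "starts a new cycle" per element by the Stirling ratio
|s(i−1,k−1)|/|s(i,k)| (log-space table) and assembles cycles by uniform
insertion; it is exact (no rejection) and vectorised across draws, and is
validated against full enumeration for all n ≤ 8. P_H is the lower-tail
probability Pr(F_sim ≤ F_obs) — small values mean a homozygosity deficit
(directional-selection side), large values an excess of evenness
(balancing side) — with two-tailed significance at P_H < 0.025 or > 0.975.
P_E is the Slatkin-style exact probability (summed null mass of
configurations no more probable than observed), estimated from the same
draws; the "exact test" column of microsatellite survey tables is not
formally defined anywhere we know of, and the Slatkin reading was chosen
and is flagged here. Defaults: 20 repeats × 1000 simulations, pooled
counts across populations (per-population runs available).

## FDIST-style outlier test

Null: one island-coalescent locus per replicate (default 100 demes, 10
sampled populations, 50 diploids each — "sample sizes of 100" read as 100
gene copies — IAM), with metapopulation θ drawn log-uniformly over a grid
derived from the observed heterozygosity range via H = θ/(1+θ) widened 2×
both ways. Migration is calibrated by bisection on log m so the pilot mean
F_ST (400 replicates, common random numbers so the pilot mean is monotone
in m) matches the trimmed-mean F_ST within 0.005. The F_ST summary for
null replicates is the haploid (gene-copy level) Weir–Cockerham form,
appropriate because gametes are simulated directly. Conditioning on
heterozygosity uses the nearest 2% of null points in H_E (at least 100);
q is the fraction of their F_ST values below the observed with half-weight
ties (mid-P), and P = 2·min(q, 1−q). Under the calibrated null the
P-values are uniform (KS-checked) and the 5% flag rate is nominal.
Defaults: 50,000 iterations; the tests and the acceptance script use
10,000, which leaves calibration and uniformity statements unchanged at
Monte-Carlo precision.

## Hierarchical Bayesian F_ST test

F_ST(i,j) = logistic(μ + α_i + β_j + γ_ij). The likelihood integrates
allele frequencies analytically: counts are multinomial-Dirichlet with
concentration (1−F)/F around the locus-wide pooled frequencies (an
empirical-Bayes plug-in for the ancestral frequencies). An explicit
intercept μ (vague N(0, 5²)) carries the genome-wide level and α, β, γ are
kept sum-to-zero by likelihood-invariant recentering each sweep, so
P(α_i > 0) directly reads "more differentiated than the genome average".
Priors: α, β ~ N(0, σ²) with σ ~ half-Cauchy(0, 1); γ ~ N(0, σ_γ²) with
σ_γ ~ half-Cauchy(0, 0.25) — interactions are shrunk harder to keep ~50
loci × 10 populations identified. Sampling is Metropolis-within-Gibbs,
vectorised over the (locus × population × allele) tensor; blocks (μ, α, β,
γ, scales) have independent acceptances, step sizes adapt toward ~30%
acceptance during the first half of burn-in and are then frozen so the
kept chain is Markovian. Convergence is reported as split-R-hat over
chains with a warning above 1.1. Defaults: 4 chains × 20,000 iterations,
50% burn-in, thin 10; validation runs use 2 × 2000–2500, at which the
hot-locus recovery and common-F_ST coverage properties already hold.
Outliers: directional if P(α_i > 0) ≥ 1 − level/2, balancing if ≤ level/2.

## Pairwise lnR statistics

lnRV uses unbiased gene-copy variances of repeat number; a zero variance
gets a half-count correction (0.5/(n−1) added to both variances) with a
warning. lnRH uses unbiased H; H = 0 is replaced by the smallest nonzero
unbiased value at that n (2/n, one singleton) and H = 1 by the largest
value below 1 ((n−2)(n+1)/(n(n−1))), both with warnings. θ' is a
deliberately lightweight replacement for full demographic MCMC: rejection
ABC against single-population SMM coalescent simulations (θ log-uniform on
[0.02, 64], summaries (H_E, ln V, k) standardised by the simulation
spread, closest 5% kept, Beaumont-style local-linear regression adjustment
on log θ, posterior median reported). The lnRθ' column is therefore
methodologically analogous, not identical, to estimates from heavyweight
samplers; its calibration (median within [θ/2, 2θ] for ~90% of replicates
at n = 100) and rank monotonicity are tested. Standardisation is per pair
and statistic across all finite loci by default (`reference_loci`
restricts to a neutral panel); flags are `*` at |z| > 1.96 and `**` at
|z| > 2.58. The 12-pair preset crosses the three native polled-type
populations with the four native horned populations.

## Linkage disequilibrium

EM haplotype estimation splits double heterozygotes between their two
phase resolutions by current haplotype-frequency products; log-likelihood
monotonicity is asserted every iteration; convergence is max |Δh| < 10⁻⁶.
D′ is the allele-frequency-weighted multiallelic form Σ p_u q_v
|D_uv|/D_max,uv. Significance comes from the Metropolis diagonal-swap
Markov chain over fixed-margin contingency tables (the R × C extension of
Fisher's exact test): default 100,000 explored tables after 1,000 burn-in,
run as 20 independent segments whose spread gives the standard error; the
chain statistic is the table's conditional log-probability −Σ log t_ij!.
The tested table is reconstructed from EM-weighted gametes rounded by
largest remainder. The 2 × 2 case is verified against the hypergeometric
closed form, and P-values are uniform for independent loci. Pair-level
summaries compare syntenic vs non-syntenic mean D′ with a one-sided
Mann–Whitney test. Population subsets are explicit; the default is all
populations pooled for the EM fit.

## Divergence envelopes

Gene identities use the bias-corrected within-population form
Q_i = (Σ n_iu² − n_i)/(n_i(n_i−1)) and the cross-population product form
Q_12; F_i = (Q_i − Q_12)/(1 − Q_12). The null simulates, per replicate,
one cell of the nuisance grid (defaults: IAM μ ∈ {10⁻², 10⁻³, 10⁻⁴},
ancestral N_e ∈ {500, 5000, 50000}, bottleneck time T₀ ∈ {50, 500, 5000},
divergence time t ∈ {50, 500}, pre-split size N₀ ∈ {50, 500}) with
msprime: daughters of size N₀ split at t; the ancestral lineage keeps size
N₀ back to T₀ and size N_e beyond (if T₀ ≤ t the ancestor is N_e
throughout). Points are binned by allele count k (bins under 200 points
merge rightward); per bin a 2-D Gaussian KDE is fitted on half the points
and the 95%/99% density thresholds are calibrated on the other half —
in-sample thresholds systematically overstate coverage. A locus is
outside a level when its density falls below that threshold. Loci
monomorphic in the pooled pair are skipped with a warning (the estimator
is undefined there, and its discreteness at extreme counts is the known
edge case). The phenotype-split helper pools labeled individuals across
source populations into two subpopulations (minimum 5 per class).

## Pipeline

`run_scan` derives per-module seeds as crc32(master, module-name) so
modules are independently reproducible; artifacts (locus summary TSV,
pairwise flag matrix, JSON metadata) are byte-stable given the master
seed. The consensus tier counts distinct test families flagging a locus
(raw 5% thresholds per test, the multiple-testing philosophy being that
agreement across families, not per-test correction, controls false
positives; a Benjamini–Hochberg column can be added downstream from the
per-test P-values in the report). Module failures are trapped into the
report's error section; the CLI exits nonzero if any occurred.

## Problem sizes used by tests and the acceptance script

Simulation-heavy checks run at reduced but statistically adequate sizes,
stated here as the package's validation design: FDIST null 10,000
replicates with 2,000 observed loci for uniformity; Ewens neutral
calibration 500 loci × (4 × 500) simulations; Bayesian recovery 5
replicate datasets at 2 chains × 2,000 iterations; lnRH sweep power 9
forward replicates (N = 150, s = 0.5, c = 0.001 vs 0.5); divergence
envelopes 1,500–2,500 replicates with 6 sweep replicates; the sweep-LD
contrast uses moderate selection (s = 0.3, c = 0.03/0.08) so hitchhiking
markers stay polymorphic and D′ remains defined. Majority-vote assertions
(detection in > half the replicates, controls below half) are used where
per-replicate power is high but not 1.

## Known limitations

- The FDIST-style null assumes equal deme sizes and symmetric migration;
  real breed histories violate both, so its outliers inherit the usual
  sensitivity to demography.
- The Bayesian model plugs in pooled frequencies rather than integrating
  ancestral frequencies; with few populations this slightly understates
  uncertainty in α.
- θ' from summary-statistic ABC has wider intervals than a full
  likelihood sampler; lnRθ' flags are correspondingly conservative.
- The sweep generator's markers are conditionally independent given the
  selected site; LD among the markers themselves is therefore induced
  only through hitchhiking, not background linkage.
- KDE-based envelopes are approximate at extreme allele counts where few
  null points exist; bins are merged but the widest bin is still used for
  out-of-range k with a warning.
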