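# Methods

`episel` simulates divergent genomic selection on a Drosophila-like
genome and evaluates how trait architecture (additive vs. complementary
epistasis) and the GBLUP evaluation model shape the response. This note
documents the models, the synthetic-data generator, the numerical
choices, and what the desk-scale results do and do not establish.

## Genome and founders

The simulated genome has three chromosomes (X ~22 Mb / 70 cM, chr2
~48 Mb / 107 cM, chr3 ~52 Mb / 110 cM female map; the male map is zero —
male Drosophila do not recombine). Chromosome 4 is ignored, as is usual
in Drosophila population genetics (tiny, non-recombining).

Founders emulate a panel of ~205 fully inbred sequenced lines. Per-site
allele frequencies are drawn i.i.d. from a symmetric Beta(0.2, 0.2),
giving the U-shaped site frequency spectrum of sequence variants; each
line's genotype at a site is a single Bernoulli draw copied to both
haplotypes (fully homozygous lines), and sites are independent given
frequencies, so long-range LD in the panel is ~1/n_lines in r² terms.
Sites monomorphic across the sampled lines are redrawn. Real phased
haplotypes can be supplied as a VCF instead (indels and non-biallelic
records are skipped; unphased genotypes rejected).

What the generator does **not** emulate: the short-range LD blocks and
haplotype mosaic of a real panel, any inbreeding structure among lines,
and — critically — the *joint* distribution of causal-variant effects and
frequencies of real data beyond the three summary statistics it is
calibrated to (see "Trait architecture"). Results that hinge on that
joint distribution (the exact magnitude of the downward response, the
additive share of epistatic variance) are therefore reproduced only
approximately; results that hinge on the calibrated structure itself
(heritability calibration, response asymmetry, LD buildup, variance
erosion under downward selection) reproduce well.

## Trait architecture

400 causal SNPs (QTN) are grouped into 200 disjoint pairs. Absolute
effects are bimodal: 103 "large" effects, lognormal with median 5× the
exponential median and log-SD 0.5 (emulating association-study estimates,
which are upward-biased), plus 297 Exponential(rate 5) effects; signs are
± with equal probability. A pair's value `z` is the arithmetic mean of
its two (signed) member effects; averaging signed values is a choice —
the alternative (averaging magnitudes) would avoid near-cancelling pairs,
but signed averaging is the plain reading of "arithmetic mean" and the
resulting |z| distribution is logged.

Complementary epistasis assigns the pair value by the two-locus table

|        | C1C1 | C1C2 | C2C2 |
|--------|------|------|------|
| B1B1   | z    | z    | 0    |
| B1B2   | z    | z    | 0    |
| B2B2   | 0    | 0    | 0    |

i.e. complete dominance (a = d) at each locus, B1/C1 dominant, and the
double mutant no better than either single one. The additive architecture
scores each locus a, 0, −a for dominant homozygote, heterozygote and
recessive homozygote with a = z of its pair. An individual's genotypic
value is the sum over pairs (complementary) or loci (additive).

**Frequency calibration.** At every QTN the minor (alternative) allele is
the recessive one. The generator then chooses pair signs and matches
pairs to sites so that (i) the mean frequency of trait-increasing alleles
is ≈0.17 and (ii) the Pearson correlation between |effect| and
increasing-allele frequency is ≈−0.42 — the signature of a trait under
past directional selection. Mechanically: a Gaussian-copula latent score
rank-matches |z| to site pairs sorted by minor-frequency sum, and the
fraction of pairs flipped to positive sign (making the *common* dominant
allele the increasing one) is solved by bisection to hit the target mean.
Achieved values are stored on the QTN set and an error names the best
achievable values when the targets are infeasible on the supplied panel.

Two structural consequences of this calibration are worth knowing:

* For a complementary pair with recessive-allele frequencies q, the
  additive share of its genetic variance is 4q(1−q)/(2−q²) ≈ 0.29 at
  q = 0.17. With the mean increasing-allele frequency pinned at 0.17 and
  large |z| forced onto rare alleles by the −0.42 coupling, the
  genotypic-variance-weighted additive share lands near 1/3, i.e.
  narrow-sense h² ≈ 0.17 of a broad-sense 0.5 — the pipeline measures
  exactly this (progeny-test h², see Metrics).
* The ~8% of pairs oriented positive put *decreasing* alleles at low
  frequency, which provides fuel for downward selection; how much such
  fuel real data contain is not identified by the three calibration
  statistics.

**Heritability.** Environmental variance is calibrated on the base
population: σ²_e = Var(g)(1−H²)/H² with H² = 0.5 by default; phenotypes
are y = g + e, e ~ N(0, σ²_e), drawn once at birth.

## Gene dropping

Meiosis places a Poisson(L) number of crossovers (L = female map length
in Morgans) uniformly on the cM scale — no interference — and the gamete
alternates parental haplotypes at crossovers, starting from a random
haplotype. Males transmit one intact haplotype per chromosome
(independent assortment, no recombination). X transmission: daughters
receive the sire's X intact plus a recombined maternal X; sons receive
only a recombined maternal X. Males' single X is stored duplicated in
both haplotype slots, so male X dosage is 0/2 ("dosage doubling") in
genotype matrices and the male X genotype class is homozygous for trait
scoring; a 0/1 coding was considered and rejected as the default because
the homozygote-equivalent convention keeps the dominance machinery
uniform across sexes. There is no mutation or gene conversion.

The base population starts from one individual per founder line and runs
10 generations of random mating at N = 500 (sire and dam drawn
independently per offspring, maximizing effective size), which restores
Hardy–Weinberg heterozygosity and dissipates what little long-range LD
line sampling induced.

## Kernels

From dosage matrix and reference frequencies p (recomputed each
evaluation cycle from all genotyped individuals entering the kernel —
cumulative data; a flag can freeze base-population frequencies):

* additive: G = MM′/Σ2pq, m = dosage − 2p;
* dominance: D = M_d M_d′/Σ4p²q², with the centered codes
  (−2q², 2pq, −2p²) for dosages (2, 1, 0) — zero-mean and orthogonal to
  the additive code under Hardy–Weinberg;
* additive×additive epistasis: the Hadamard product G∘G.

Sites monomorphic in the current reference are excluded (logged).
Kernels are symmetrized and ridge-stabilized (1e−8 on the diagonal)
before eigendecomposition; eigenvalues below 1e−10 of the maximum are
truncated (count logged). Dominance×dominance and additive×dominance
kernels are deliberately not built.

## GBLUP by Gibbs sampling

The evaluation model is y = 1μ + a (+ d + h) + e with
a ~ N(0, Gσ²_a), d ~ N(0, Dσ²_d), h ~ N(0, (G∘G)σ²_p), e ~ N(0, Iσ²_e);
variants A-SEQ/A-QTN use additive-only kernels on all sites / QTN only,
E-SEQ/E-QTN add the dominance and epistatic terms. The intercept has a
flat prior; every variance a scaled-inverse-χ² prior with df = 5 and
scale set by the R²-matching rule S = Var(y)·R²_share·(df+2)/mean(diag K)
(prior mode = Var(y)·R²_share/mean diag K), the prior R² of 0.5 split
equally among the genetic terms and 1−R² assigned to the residual.

Sampling is performed in each kernel's eigenbasis, where the coefficient
full conditional factorizes into univariate normals. With one kernel the
phenotype vector is rotated once and every iteration is O(n); with
several kernels each term is updated as a block (two matrix–vector
products per kernel per iteration). Variances are drawn from their
scaled-inverse-χ² full conditionals; chains are seeded and reproducible;
posterior summaries are post-burn-in means without thinning (effective
sample sizes are logged, not enforced). Defaults are 10,000 iterations
with 2,000 burn-in; the desk-scale configurations use 2,000/500, which a
10k-vs-200k chain-correlation check (≥0.999 at n = 500) shows is ample
for ranking candidates.

Selection candidates are ranked on the posterior-mean additive value
`a_hat` (fitted on all phenotypes and genotypes up to and including the
current generation); ranking on a_hat + d_hat + h_hat is available behind
a flag but is not the default, since truncation on *breeding* values is
the stated scheme.

## Selection scheme

N = 500 per generation; 25 sires + 25 dams (10% per sex) truncation-
selected (ties broken by id), paired one-to-one by a random permutation
(monogamous pairing reproduces the 25-family × 20-offspring arithmetic
exactly), 20 offspring per pair with an equal sex ratio; 7 discrete
generations; up and down directions. Replicates share the founder panel
and QTN effects but draw fresh base populations. Figure-style summaries
report mean, median and quartiles over replicates (the mode of a handful
of continuous values is ill-defined).

## Metrics

* **Breeding values** are estimated by their definition: the individual
  is mated to 1,000 randomly chosen opposite-sex individuals of its
  generation and bv = 2 × (offspring phenotype mean − population mean),
  the population mean taken over a fresh phenotype realization. Offspring
  are simulated at QTN columns only (crossovers live on the cM scale, so
  marginal transmission at a site subset is exact). **Additive variance**
  is the variance of these progeny-test values; a configurable subsample
  (tests use 100–150 individuals) bounds the cost.
* **Response** is (mean_t − mean_0)/SD_0 per replicate in base-population
  phenotypic SD units; **accuracy** is the Pearson correlation between
  progeny-test and predicted breeding values.
* **Substitution effects**: additive α = a; complementary α = z(1−q²_C)·q_B
  at the locus (partner marginalized under HWE — an exact 9-cell
  enumeration reduces to this closed form), and per-locus expected
  contributions 2pqα² with their cumulative spectrum are computed at any
  generation's frequencies (both t0 and t7 curves are produced).
* **LD** is the squared Pearson correlation of genotype dosages for
  same-chromosome pairs; decay with distance is fitted by nonlinear least
  squares to the drift–recombination expectation with first-order sample
  size correction,
  E[r²] = (10+C)/((2+C)(11+C)) · [1 + (3+C)(12+12C+C²)/(n(2+C)(11+C))],
  C = c·distance, n the number of genotyped individuals.
* **Inbreeding**: excess homozygosity F_h = (O−E)/(k−E) with
  E = Σ(1−2p_jq_j) at base-population frequencies.

## Numerical and scale choices

Desk-scale defaults — 5,000 sites, N = 500, 2,000-iteration chains,
3 replicates — keep a full three-cell reproduction (up/down additive,
up epistatic) under ten minutes on one CPU while preserving every
qualitative regime of the full-scale design (10 replicates, 10k chains,
millions of sites); `n_sites` is a free parameter because nothing in the
method fixes how many sequence sites enter G. Degenerate inputs are
errors, not silent fixes: monomorphic frequency references, zero genetic
variance at calibration, single-sex populations, infeasible calibration
targets (the error names the best achievable values).

## Known limitations

* Crossover interference is ignored (Poisson model).
* Sex-specific effect sizes, higher-order epistasis and other epistasis
  types (duplicate, sign) are out of scope, as are mutation, overlapping
  generations, and pedigree-BLUP comparisons.
* The progeny-test additive variance is a noisy estimator at desk scale;
  monotonicity checks on it are statistical, not exact.
* X-linked QTN make male genotypic values (doubled hemizygous dosage)
  transmit differently from autosomal ones, so even under additivity
  breeding values equal genotypic deviations only for autosomal traits;
  at the default genome composition this depresses the progeny-test h²
  by roughly 10% relative to the calibrated ratio.
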