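"""Evaluation metrics: progeny-test breeding values, additive variance,
response in SD units, prediction accuracy, allele-frequency change,
substitution effects and 2pq*alpha^2 contributions, LD decay with a
Hill-Weir fit, and excess-homozygosity genomic inbreeding.

Under non-additive gene action true breeding values have no closed form,
so they are estimated by their definition: twice the deviation of the
mean phenotype of a large progeny group (individual mated at random
within its generation) from the population mean.  The additive genetic
variance of a generation is the variance of these progeny-test breeding
values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .gene_drop import MALE, Population, _assemble_offspring, _offspring_sexes
from .traits import QTNSet, TraitModel

__all__ = [
    "BreedingValueEstimate",
    "HillWeirFit",
    "empirical_breeding_values",
    "additive_variance",
    "response_curve",
    "prediction_accuracy",
    "allele_frequency_change",
    "substitution_effect",
    "contribution_spectrum",
    "fraction_explaining",
    "ld_r2",
    "fit_hill_weir",
    "genomic_inbreeding",
]


@dataclass
class BreedingValueEstimate:
    individual: int
    bv: float
    n_test_offspring: int
    se: float


def reduce_to_qtn(pop: Population, trait: TraitModel) -> tuple[Population, TraitModel]:
    """Project a population onto its QTN columns (for cheap progeny tests).

    Crossover positions live on the cM scale, so marginal transmission at
    any site subset is exact; only genotypes at causal sites matter for
    offspring phenotypes.
    """
    qtn = trait.qtn
    cols = np.sort(qtn.site_index)
    pos_in = np.searchsorted(cols, qtn.site_index)
    qtn_red = replace(qtn, site_index=pos_in)
    trait_red = TraitModel(qtn=qtn_red, sigma_e2=trait.sigma_e2,
                           target_H2=trait.target_H2)
    pop_red = Population(
        generation=pop.generation,
        sites=pop.sites.subset(cols),
        haplotypes=np.ascontiguousarray(pop.haplotypes[:, :, cols]),
        sex=pop.sex, gv=pop.gv, phen=pop.phen, ids=pop.ids,
    )
    return pop_red, trait_red


def empirical_breeding_values(
    pop: Population,
    trait: TraitModel,
    individuals: np.ndarray | None = None,
    n_offspring: int = 1000,
    rng: np.random.Generator | None = None,
    qtn_only: bool = True,
) -> list[BreedingValueEstimate]:
    """Progeny-test 'true' breeding values: bv = 2 (offspring mean - pop mean).

    Each focal individual is mated to ``n_offspring`` randomly chosen
    opposite-sex individuals of the same generation (one offspring per
    mate); offspring receive fresh environmental deviates.  The population
    mean is taken over a fresh phenotype realization of the generation.
    """
    rng = rng or np.random.default_rng()
    if individuals is None:
        individuals = np.arange(pop.n)
    individuals = np.asarray(individuals)
    if len(pop.males) == 0 or len(pop.females) == 0:
        raise ValueError("progeny test requires both sexes in the population")
    work_pop, work_trait = reduce_to_qtn(pop, trait) if qtn_only else (pop, trait)
    pop_mean = float(np.mean(work_trait.phenotypes(pop.gv, rng)))
    out = []
    for i in individuals:
        i = int(i)
        if pop.sex[i] == MALE:
            sires = np.full(n_offspring, i)
            dams = rng.choice(pop.females, size=n_offspring, replace=True)
        else:
            dams = np.full(n_offspring, i)
            sires = rng.choice(pop.males, size=n_offspring, replace=True)
        sexes = _offspring_sexes(n_offspring, rng)
        off = _assemble_offspring(work_pop, sires, dams, sexes, work_trait, rng,
                                  pop.generation + 1)
        bv = 2.0 * (float(off.phen.mean()) - pop_mean)
        se = 2.0 * float(off.phen.std(ddof=1)) / np.sqrt(n_offspring)
        out.append(BreedingValueEstimate(individual=i, bv=bv,
                                         n_test_offspring=n_offspring, se=se))
    return out


def additive_variance(
    pop: Population,
    trait: TraitModel,
    n_offspring: int = 1000,
    rng: np.random.Generator | None = None,
    subsample: int | None = None,
) -> float:
    """Variance of progeny-test breeding values in the generation.

    ``subsample`` limits the number of tested individuals (each needs
    ``n_offspring`` simulated offspring); drawn at random without
    replacement when smaller than the population.
    """
    rng = rng or np.random.default_rng()
    idx = np.arange(pop.n)
    if subsample is not None and subsample < pop.n:
        idx = rng.choice(idx, size=subsample, replace=False)
    bvs = empirical_breeding_values(pop, trait, idx, n_offspring, rng)
    return float(np.var([b.bv for b in bvs], ddof=1))


def response_curve(per_gen: pd.DataFrame) -> pd.DataFrame:
    """Per-generation response in base-SD units, summarized over replicates.

    Expects columns (replicate, generation, mean_phen, sd_phen); response
    of a replicate at t is (mean_t - mean_0) / sd_0.
    """
    rows = []
    for rep, grp in per_gen.groupby("replicate"):
        grp = grp.sort_values("generation")
        base = grp.iloc[0]
        resp = (grp["mean_phen"] - base["mean_phen"]) / base["sd_phen"]
        rows.append(pd.DataFrame({"replicate": rep,
                                  "generation": grp["generation"].to_numpy(),
                                  "response_sd": resp.to_numpy()}))
    long = pd.concat(rows, ignore_index=True)
    return (long.groupby("generation")["response_sd"]
            .agg(["mean", "median",
                  lambda s: s.quantile(0.25), lambda s: s.quantile(0.75)])
            .rename(columns={"<lambda_0>": "q25", "<lambda_1>": "q75"})
            .reset_index())


def prediction_accuracy(true_bv: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between true and predicted breeding values."""
    true_bv = np.asarray(true_bv, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if np.std(true_bv) == 0 or np.std(predicted) == 0:
        return float("nan")
    return float(np.corrcoef(true_bv, predicted)[0, 1])


def increasing_allele_frequency(pop: Population, qtn: QTNSet) -> np.ndarray:
    """Frequency of the trait-increasing allele at each QTN."""
    f1 = pop.dosage(qtn.site_index).mean(axis=0) / 2.0
    return np.where(qtn.increasing_allele == 1, f1, 1.0 - f1)


def allele_frequency_change(pop_t0: Population, pop_t: Population,
                            qtn: QTNSet) -> np.ndarray:
    """Per-QTN change in frequency of the trait-increasing allele."""
    return (increasing_allele_frequency(pop_t, qtn)
            - increasing_allele_frequency(pop_t0, qtn))


def substitution_effect(qtn: QTNSet, freq_allele1: np.ndarray,
                        architecture: str | None = None) -> np.ndarray:
    """Allele-substitution effect alpha at each QTN, on the dominant-allele
    dosage scale, at the given allele-1 frequencies.

    Additive architecture: alpha = a (frequency independent).  Complementary:
    marginalizing the partner locus under Hardy-Weinberg, a locus sees the
    genotype means (v, v, 0) with v = z (1 - q_partner^2), i.e. a complete-
    dominance locus with a = d = v/2, whose substitution effect is
    alpha = a + d (q - p) = v q, q being its recessive-allele frequency.
    """
    arch = architecture or qtn.architecture
    eff = qtn.locus_effect
    if arch == "additive":
        return eff.copy()
    if arch != "complementary":
        raise ValueError(f"unknown architecture {arch!r}")
    f1 = np.asarray(freq_allele1, dtype=float)
    p_dom = np.where(qtn.dominant_allele == 1, f1, 1.0 - f1)
    q_rec = 1.0 - p_dom
    partner = np.empty(qtn.n_qtn, dtype=int)
    partner[qtn.pairs[:, 0]] = qtn.pairs[:, 1]
    partner[qtn.pairs[:, 1]] = qtn.pairs[:, 0]
    v = eff * (1.0 - q_rec[partner] ** 2)
    return v * q_rec


def contribution_spectrum(qtn: QTNSet, freq_allele1: np.ndarray,
                          architecture: str | None = None) -> pd.DataFrame:
    """Per-locus expected contribution 2 p q alpha^2, sorted descending.

    Returns a frame with columns (site_id, p, q, alpha, contribution,
    cum_fraction); loci fixed at the reference frequencies contribute 0.
    """
    f1 = np.asarray(freq_allele1, dtype=float)
    alpha = substitution_effect(qtn, f1, architecture)
    contrib = 2.0 * f1 * (1.0 - f1) * alpha**2
    order = np.argsort(contrib)[::-1]
    total = contrib.sum()
    cum = np.cumsum(contrib[order]) / total if total > 0 else np.zeros(len(contrib))
    return pd.DataFrame({
        "site_id": qtn.site_index[order],
        "p": f1[order],
        "q": 1.0 - f1[order],
        "alpha": alpha[order],
        "contribution": contrib[order],
        "cum_fraction": cum,
    })


def fraction_explaining(spectrum: pd.DataFrame, share: float = 0.9) -> float:
    """Smallest fraction of loci whose cumulative contribution reaches ``share``."""
    cum = spectrum["cum_fraction"].to_numpy()
    n_needed = int(np.searchsorted(cum, share) + 1)
    return n_needed / len(cum)


def ld_r2(
    dosages: np.ndarray,
    chromosome: np.ndarray,
    position_bp: np.ndarray,
    max_dist_bp: float | None = None,
    within_chromosome: bool = True,
) -> pd.DataFrame:
    """Pairwise LD as squared Pearson correlation of genotype dosages.

    Pairs are restricted to the same chromosome (unless
    ``within_chromosome=False``) and to distance <= ``max_dist_bp``.
    Monomorphic columns are dropped.  Returns (chrom, bp1, bp2, dist, r2).
    """
    dosages = np.asarray(dosages, dtype=float)
    chromosome = np.asarray(chromosome)
    position_bp = np.asarray(position_bp)
    keep = dosages.std(axis=0) > 0
    dosages, chromosome, position_bp = (dosages[:, keep], chromosome[keep],
                                        position_bp[keep])
    rows = []
    groups = ([(c, np.flatnonzero(chromosome == c)) for c in dict.fromkeys(chromosome)]
              if within_chromosome else [("all", np.arange(len(position_bp)))])
    for label, idx in groups:
        if len(idx) < 2:
            continue
        X = dosages[:, idx]
        R = np.corrcoef(X, rowvar=False)
        iu, ju = np.triu_indices(len(idx), k=1)
        d = np.abs(position_bp[idx][ju] - position_bp[idx][iu]).astype(float)
        r2 = R[iu, ju] ** 2
        if max_dist_bp is not None:
            m = d <= max_dist_bp
            iu, ju, d, r2 = iu[m], ju[m], d[m], r2[m]
        rows.append(pd.DataFrame({
            "chrom": label,
            "bp1": position_bp[idx][iu],
            "bp2": position_bp[idx][ju],
            "dist": d,
            "r2": r2,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "bp1", "bp2", "dist", "r2"])
    return pd.concat(rows, ignore_index=True)


def hill_weir_expectation(dist: np.ndarray, c_per_bp: float, n_sample: int) -> np.ndarray:
    """Expected r^2 at distance d for C = c_per_bp * d and sample size n.

    The drift-recombination expectation with the first-order sample-size
    correction commonly used for LD-decay curves:

        E[r^2] = (10+C) / ((2+C)(11+C))
                 * [1 + (3+C)(12+12C+C^2) / (n(2+C)(11+C))]
    """
    C = c_per_bp * np.asarray(dist, dtype=float)
    first = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (
        n_sample * (2.0 + C) * (11.0 + C)
    )
    return first * (1.0 + corr)


@dataclass
class HillWeirFit:
    """Fitted population recombination scaling for the r^2 decay curve."""

    C_per_bp: float
    n_sample: int
    residual_sse: float

    def predict(self, dist: np.ndarray) -> np.ndarray:
        return hill_weir_expectation(dist, self.C_per_bp, self.n_sample)

    @property
    def at_boundary(self) -> bool:
        """True when the fit ran to the flat, n-driven asymptote."""
        return self.C_per_bp >= 1.0  # >= 1 Morgan-equivalent per bp: degenerate


def fit_hill_weir(dist: np.ndarray, r2: np.ndarray, n_sample: int) -> HillWeirFit:
    """Nonlinear least-squares fit of the r^2 decay expectation.

    Fits the single scaling C = c * distance; requires at least three
    distinct distances.
    """
    dist = np.asarray(dist, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if len(np.unique(dist)) < 3:
        raise ValueError("need at least 3 distinct distances to fit")

    def residual(log_c):
        return hill_weir_expectation(dist, np.exp(log_c[0]), n_sample) - r2

    # initial scale: midpoint of decay near C ~ 4 at the median distance
    x0 = np.log(4.0 / max(np.median(dist), 1.0))
    sol = scipy.optimize.least_squares(residual, [x0], method="lm")
    c = float(np.exp(sol.x[0]))
    return HillWeirFit(C_per_bp=c, n_sample=n_sample,
                       residual_sse=float(np.sum(sol.fun**2)))


def genomic_inbreeding(dosages: np.ndarray, base_freqs: np.ndarray) -> pd.DataFrame:
    """Excess-homozygosity inbreeding F_h = (O - E) / (k - E) per individual.

    O is the observed homozygous-site count; E = sum_j (1 - 2 p_j q_j) the
    count expected under Hardy-Weinberg at base-population frequencies.
    """
    dosages = np.asarray(dosages)
    p = np.asarray(base_freqs, dtype=float)
    if dosages.shape[1] != len(p):
        raise ValueError("dosage columns do not match base frequencies")
    k = dosages.shape[1]
    O = (dosages != 1).sum(axis=1)
    E = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    F = (O - E) / (k - E)
    return pd.DataFrame({"individual": np.arange(dosages.shape[0]),
                         "O": O, "E": E, "F_h": F})
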