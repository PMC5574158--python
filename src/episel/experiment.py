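"""The divergent genomic-selection experiment.

Each run crosses a genetic architecture (additive or complementary
epistasis) with an evaluation model (A-SEQ, A-QTN, E-SEQ, E-QTN) and a
direction of selection (up/down): from a base population of N = 500
(built by 10 generations of random mating of fully inbred founder
lines), 25 sires and 25 dams (10% of each sex) are truncation-selected
each generation on their GBLUP additive value — fitted on all phenotypes
and genotypes up to and including the current generation — randomly
paired one-to-one, and each pair leaves 20 offspring with an equal sex
ratio.  The scheme runs for 7 discrete generations; replicates reuse the
founder panel and QTN effects but draw fresh base populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import founders, gene_drop, kernels, metrics, traits
from ._rng import child_seed, stream
from .gblup import ModelSpec, predict_candidates
from .gene_drop import Population
from .traits import QTNSet, TraitModel

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "build_base_population",
    "select_parents",
    "mate_selected",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """One experimental cell plus generator/model settings."""

    architecture: str = "complementary"
    model: str = "A-SEQ"
    direction: str = "up"
    n_generations: int = 7
    N: int = 500
    n_sires: int = 25
    n_dams: int = 25
    offspring_per_mating: int = 20
    burn_generations: int = 10
    n_replicates: int = 10
    seed: int = 0
    # synthetic founder generator
    n_sites: int = 5000
    n_lines: int = 205
    sfs_shape: float = 0.2
    # trait architecture
    n_large: int = 103
    n_small: int = 297
    exp_rate: float = 5.0
    target_H2: float = 0.5
    target_corr: float = -0.42
    target_mean_p_plus: float = 0.17
    qtn_corr_tol: float = 0.05
    qtn_mean_tol: float = 0.02
    # MCMC
    n_iter: int = 10_000
    mcmc_burn_in: int = 2_000
    prior_df: float = 5.0
    prior_R2: float = 0.5
    # per-generation progeny-test metrics (accuracy, additive variance);
    # 0 disables, None tests every individual
    bv_subsample: int | None = None
    bv_offspring: int = 1000
    track_inbreeding: bool = True

    def __post_init__(self) -> None:
        if self.architecture not in ("additive", "complementary"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down'")
        if self.n_sires * self.offspring_per_mating != self.N:
            raise ValueError(
                "n_sires * offspring_per_mating must equal N under "
                "monogamous one-to-one pairing"
            )
        if self.n_sires != self.n_dams:
            raise ValueError("one-to-one pairing needs n_sires == n_dams")

    @property
    def selection_proportion(self) -> float:
        return self.n_sires / (self.N / 2)


@dataclass
class ExperimentResult:
    """Per-generation, per-replicate metric tables and end-state snapshots."""

    config: ExperimentConfig
    per_generation: pd.DataFrame
    qtn_frequencies: pd.DataFrame  # long: replicate, generation, locus, p_plus
    qtn_dosage_snapshots: dict  # (replicate, generation) -> (n, n_qtn) dosage
    qtn_sites: pd.DataFrame  # chromosome/bp of each QTN locus
    base_stats: pd.DataFrame  # replicate, base mean/sd, sigma_e2

    def response(self) -> pd.DataFrame:
        return metrics.response_curve(self.per_generation)

    def cumulative_response(self) -> float:
        """Replicate-mean cumulative response at the final generation, in
        base-population phenotypic SD units."""
        r = self.response()
        return float(r.loc[r["generation"].idxmax(), "mean"])

    def mean_delta_p(self) -> float:
        """Mean change (over QTN and replicates) in increasing-allele
        frequency between the first and last generation."""
        f = self.qtn_frequencies
        t0, t7 = f["generation"].min(), f["generation"].max()
        wide = f.pivot_table(index=["replicate", "locus"], columns="generation",
                             values="p_plus")
        return float((wide[t7] - wide[t0]).mean())


def make_panel_and_qtn(
    config: ExperimentConfig,
) -> tuple[founders.HaplotypePanel, QTNSet]:
    """Founder panel and QTN set shared by all replicates of a run."""
    rng_f = stream(config.seed, "founders")
    freqs = founders.draw_site_frequencies(config.n_sites, config.sfs_shape,
                                           rng_f, n_lines=config.n_lines)
    sites = founders.make_genetic_map(config.n_sites, seed=stream(config.seed, "map"))
    panel = founders.make_founder_panel(freqs, config.n_lines, inbred=True,
                                        seed=stream(config.seed, "panel"),
                                        sites=sites)
    eff, src, pairs = traits.sample_qtn_effects(
        config.n_large, config.n_small, config.exp_rate,
        seed=stream(config.seed, "effects"))
    qtn = traits.assign_qtn_sites(
        eff, src, pairs, panel.allele_frequencies(),
        target_corr=config.target_corr,
        target_mean_p_plus=config.target_mean_p_plus,
        seed=stream(config.seed, "qtn"),
        architecture=config.architecture,
        corr_tol=config.qtn_corr_tol,
        mean_tol=config.qtn_mean_tol,
    )
    logger.info("QTN calibration: mean p+ = %.3f, corr(|effect|, p+) = %.3f",
                qtn.achieved_mean_p_plus, qtn.achieved_corr)
    return panel, qtn


def build_base_population(
    panel: founders.HaplotypePanel,
    qtn: QTNSet,
    N: int,
    burn_generations: int,
    rng: np.random.Generator,
    target_H2: float = 0.5,
) -> tuple[Population, TraitModel]:
    """Random-mate the founder lines into a heterozygous base population.

    Starting from one individual per (homozygous) line, ``burn_generations``
    rounds of random mating at size N dissipate long-range LD and restore
    Hardy-Weinberg heterozygosity; with 0 rounds the individuals are direct
    line crosses.  The environmental variance is then calibrated on this
    population's genotypic values and phenotypes drawn.
    """
    pop = gene_drop.population_from_lines(panel, None, rng)
    for _ in range(max(burn_generations, 1)):
        pop = gene_drop.random_mating_generation(pop, N, None, rng)
    dos = traits.qtn_allele1_dosage(pop.haplotypes, qtn)
    g = traits.genotypic_value(qtn.dominant_dosage(dos), qtn)
    sigma_e2 = traits.calibrate_environmental_variance(g, target_H2)
    trait = TraitModel(qtn=qtn, sigma_e2=sigma_e2, target_H2=target_H2)
    pop.gv = g
    pop.phen = trait.phenotypes(g, rng)
    pop.generation = 0
    return pop, trait


def select_parents(
    pop: Population,
    criterion: np.ndarray,
    n_sires: int,
    n_dams: int,
    direction: str = "up",
) -> tuple[np.ndarray, np.ndarray]:
    """Truncation-select the top (or bottom) individuals within each sex.

    Ties are broken by id for determinism; an all-equal criterion selects
    the first individuals by id (with a logged warning).
    """
    criterion = np.asarray(criterion, dtype=float)
    if np.ptp(criterion) == 0:
        logger.warning("selection criterion is constant; selecting by id")
    key = -criterion if direction == "up" else criterion

    def top(idx: np.ndarray, n: int) -> np.ndarray:
        if len(idx) < n:
            raise ValueError(f"need {n} candidates of one sex, have {len(idx)}")
        order = np.lexsort((pop.ids[idx], key[idx]))
        return idx[order[:n]]

    return top(pop.males, n_sires), top(pop.females, n_dams)


def mate_selected(
    pop: Population,
    sires: np.ndarray,
    dams: np.ndarray,
    offspring_per_mating: int,
    trait: TraitModel,
    rng: np.random.Generator,
) -> Population:
    """Random one-to-one pairing of the selected parents; each of the
    resulting matings leaves ``offspring_per_mating`` offspring with an
    equal sex ratio per family."""
    sires, dams = np.asarray(sires), np.asarray(dams)
    if len(sires) != len(dams):
        raise ValueError("sire and dam counts differ")
    paired_dams = dams[rng.permutation(len(dams))]
    sire_col = np.repeat(sires, offspring_per_mating)
    dam_col = np.repeat(paired_dams, offspring_per_mating)
    sexes = np.concatenate([
        gene_drop._offspring_sexes(offspring_per_mating, rng)
        for _ in range(len(sires))
    ])
    return gene_drop._assemble_offspring(pop, sire_col, dam_col, sexes, trait,
                                         rng, pop.generation + 1)


def _generation_metrics(
    pop: Population,
    trait: TraitModel,
    config: ExperimentConfig,
    replicate: int,
    fit,
    criterion: np.ndarray | None,
    base_freqs: np.ndarray,
) -> dict:
    row = {
        "replicate": replicate,
        "generation": pop.generation,
        "mean_phen": float(pop.phen.mean()),
        "sd_phen": float(pop.phen.std(ddof=1)),
        "mean_gv": float(pop.gv.mean()),
        "var_gv": float(pop.gv.var(ddof=1)),
    }
    if fit is not None:
        for k, v in fit.var_components.items():
            row[k] = v
    if config.track_inbreeding:
        F = metrics.genomic_inbreeding(pop.dosage(), base_freqs)
        row["mean_F"] = float(F["F_h"].mean())
    if config.bv_subsample != 0:
        # dedicated stream: progeny testing must not perturb the run itself
        rng = stream(config.seed, "progeny-test", replicate, pop.generation)
        idx = np.arange(pop.n)
        if config.bv_subsample is not None and config.bv_subsample < pop.n:
            idx = rng.choice(idx, size=config.bv_subsample, replace=False)
        bvs = np.array([b.bv for b in metrics.empirical_breeding_values(
            pop, trait, idx, config.bv_offspring, rng)])
        row["va"] = float(np.var(bvs, ddof=1))
        if criterion is not None:
            row["accuracy"] = metrics.prediction_accuracy(bvs, criterion[idx])
            row["accuracy_gv"] = metrics.prediction_accuracy(
                pop.gv[idx] - pop.gv.mean(), criterion[idx])
    return row


def run_replicate(
    config: ExperimentConfig,
    panel: founders.HaplotypePanel,
    qtn: QTNSet,
    replicate: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, dict]:
    """One replicate: fresh base population, then the full selection loop."""
    rng = stream(config.seed, "replicate", replicate)
    pop, trait = build_base_population(panel, qtn, config.N,
                                       config.burn_generations, rng,
                                       config.target_H2)
    base_freqs = pop.dosage().mean(axis=0) / 2.0
    base_stats = {"replicate": replicate,
                  "base_mean": float(pop.phen.mean()),
                  "base_sd": float(pop.phen.std(ddof=1)),
                  "sigma_e2": trait.sigma_e2}

    history_dos: list[np.ndarray] = []
    history_y: list[np.ndarray] = []
    rows, freq_rows = [], []
    snapshots = {}

    for t in range(config.n_generations + 1):
        history_dos.append(pop.dosage())
        history_y.append(pop.phen)
        if t in (0, config.n_generations):
            snapshots[(replicate, t)] = traits.qtn_allele1_dosage(
                pop.haplotypes, qtn)
        p_plus = metrics.increasing_allele_frequency(pop, qtn)
        freq_rows.append(pd.DataFrame({
            "replicate": replicate, "generation": t,
            "locus": np.arange(qtn.n_qtn), "p_plus": p_plus,
        }))

        fit, criterion = None, None
        if t < config.n_generations:
            dos = np.concatenate(history_dos, axis=0)
            y = np.concatenate(history_y)
            spec = ModelSpec(
                variant=config.model, n_iter=config.n_iter,
                burn_in=config.mcmc_burn_in, prior_df=config.prior_df,
                prior_R2=config.prior_R2,
                seed=child_seed(config.seed, "mcmc", replicate, t),
            )
            ks = kernels.build_kernels(dos, qtn, spec.marker_set,
                                       spec.with_nonadditive)
            cand = np.arange(len(y) - pop.n, len(y))
            criterion, fit = predict_candidates(y, ks, spec, cand)

        rows.append(_generation_metrics(pop, trait, config, replicate, fit,
                                        criterion, base_freqs))
        if t < config.n_generations:
            sires, dams = select_parents(pop, criterion, config.n_sires,
                                         config.n_dams, config.direction)
            pop = mate_selected(pop, sires, dams, config.offspring_per_mating,
                                trait, rng)
            logger.info("replicate %d generation %d -> %d: mean phen %.2f",
                        replicate, t, t + 1, float(pop.phen.mean()))

    return (pd.DataFrame(rows), pd.concat(freq_rows, ignore_index=True),
            snapshots, base_stats)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run all replicates of one experimental cell."""
    panel, qtn = make_panel_and_qtn(config)
    per_gen, freqs, base_rows = [], [], []
    snapshots: dict = {}
    for r in range(config.n_replicates):
        rows, frq, snaps, base = run_replicate(config, panel, qtn, r)
        per_gen.append(rows)
        freqs.append(frq)
        snapshots.update(snaps)
        base_rows.append(base)
    qtn_sites = pd.DataFrame({
        "locus": np.arange(qtn.n_qtn),
        "chromosome": panel.sites.chromosome[qtn.site_index],
        "position_bp": panel.sites.position_bp[qtn.site_index],
        "effect": qtn.locus_effect,
    })
    return ExperimentResult(
        config=config,
        per_generation=pd.concat(per_gen, ignore_index=True),
        qtn_frequencies=pd.concat(freqs, ignore_index=True),
        qtn_dosage_snapshots=snapshots,
        qtn_sites=qtn_sites,
        base_stats=pd.DataFrame(base_rows),
    )
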