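"""Reproduction of the study's headline quantities at desk scale.

Each function regenerates its inputs from the synthetic founder generator
(calibrated to mean increasing-allele frequency ~0.17, |effect|-frequency
correlation ~-0.42, U-shaped SFS, broad-sense H2 = 0.5), runs the method
and returns the measured quantity.  Problem sizes are the package's
desk-scale defaults: 5,000 sites, N = 500, 2,000-iteration chains and
3 replicates for the selection runs — chosen so a full reproduction runs
on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from . import gblup, kernels, metrics
from ._rng import child_seed, stream
from .experiment import (ExperimentConfig, build_base_population,
                         make_panel_and_qtn, run_experiment)

__all__ = [
    "desk_config",
    "heritability_calibration",
    "epistatic_narrow_h2",
    "chain_stability",
    "contribution_concentration",
    "selection_responses",
]


def desk_config(seed: int, **overrides) -> ExperimentConfig:
    """Desk-scale selection configuration (reduced MCMC, 3 replicates)."""
    base = dict(seed=seed, n_iter=2000, mcmc_burn_in=500, n_replicates=3,
                bv_subsample=0, track_inbreeding=False)
    base.update(overrides)
    return ExperimentConfig(**base)


def _base_population(seed: int, architecture: str = "complementary"):
    cfg = desk_config(seed, architecture=architecture)
    panel, qtn = make_panel_and_qtn(cfg)
    rng = stream(seed, "replication-base")
    pop, trait = build_base_population(panel, qtn, cfg.N,
                                       cfg.burn_generations, rng,
                                       cfg.target_H2)
    return cfg, panel, qtn, pop, trait, rng


def heritability_calibration(seed: int, n_redraws: int = 20,
                             architecture: str = "complementary") -> float:
    """Mean realized broad-sense H2 = Var(g)/Var(y) over phenotype redraws
    on the default base population (N = 500) after calibration."""
    _, _, _, pop, trait, rng = _base_population(seed, architecture)
    var_g = float(np.var(pop.gv, ddof=1))
    ratios = [var_g / float(np.var(trait.phenotypes(pop.gv, rng), ddof=1))
              for _ in range(n_redraws)]
    return float(np.mean(ratios))


def epistatic_narrow_h2(seed: int, n_individuals: int = 100,
                        n_offspring: int = 1000) -> float:
    """Narrow-sense h2 of the complementary base population: variance of
    progeny-test breeding values over phenotypic variance."""
    _, _, _, pop, trait, rng = _base_population(seed, "complementary")
    idx = rng.choice(pop.n, size=n_individuals, replace=False)
    bvs = np.array([b.bv for b in metrics.empirical_breeding_values(
        pop, trait, idx, n_offspring, rng)])
    var_p = float(np.var(trait.phenotypes(pop.gv, rng), ddof=1))
    return float(np.var(bvs, ddof=1) / var_p)


def chain_stability(seed: int, n_iter_short: int = 10_000,
                    n_iter_long: int = 200_000) -> float:
    """Correlation of posterior-mean additive values between a short and a
    long Gibbs chain (different seeds) on one 500-record dataset."""
    _, _, qtn, pop, trait, rng = _base_population(seed, "complementary")
    ks = kernels.build_kernels(pop.dosage(), qtn, "all_sites")
    eig = {"G": gblup.eigendecompose(ks.G)}
    fits = []
    for n_iter, tag in ((n_iter_short, 1), (n_iter_long, 2)):
        spec = gblup.ModelSpec(variant="A-SEQ", n_iter=n_iter, burn_in=2000,
                               seed=child_seed(seed, "chain", tag))
        fits.append(gblup.gibbs_fit(pop.phen, ks, spec, eig=eig))
    return float(np.corrcoef(fits[0].a_hat, fits[1].a_hat)[0, 1])


def contribution_concentration(seed: int, n_seeds: int = 10) -> float:
    """Percentage of QTN (sorted by 2pq alpha^2, alpha the per-locus
    additive value) needed to explain 90% of the summed expected
    contributions at base-population frequencies; averaged over generator
    seeds."""
    fracs = []
    for i in range(n_seeds):
        sub = child_seed(seed, "contribution", i)
        cfg = desk_config(sub, architecture="additive")
        panel, qtn = make_panel_and_qtn(cfg)
        rng = stream(sub, "replication-base")
        pop, _ = build_base_population(panel, qtn, cfg.N,
                                       cfg.burn_generations, rng)
        f1 = pop.dosage(qtn.site_index).mean(axis=0) / 2.0
        spectrum = metrics.contribution_spectrum(qtn, f1, "additive")
        fracs.append(metrics.fraction_explaining(spectrum, 0.9))
    return float(100.0 * np.mean(fracs))


def selection_responses(seed: int, n_replicates: int = 3,
                        track_va_down: bool = False) -> dict:
    """Run the three desk-scale divergent-selection cells with A-SEQ
    evaluation and return their cumulative responses (base-SD units) and
    the downward-additive allele-frequency change.

    Keys: ``additive_up``, ``additive_down`` (signed), ``epistatic_up``,
    ``delta_p_down`` plus the full :class:`ExperimentResult` objects under
    ``results``.
    """
    cells = {
        "additive_up": dict(architecture="additive", direction="up"),
        "additive_down": dict(architecture="additive", direction="down"),
        "epistatic_up": dict(architecture="complementary", direction="up"),
    }
    out: dict = {"results": {}}
    for name, cell in cells.items():
        overrides = dict(cell, model="A-SEQ", n_replicates=n_replicates)
        if track_va_down and name == "additive_down":
            overrides.update(bv_subsample=100, bv_offspring=250)
        res = run_experiment(desk_config(seed, **overrides))
        out["results"][name] = res
        out[name] = res.cumulative_response()
    out["delta_p_down"] = out["results"]["additive_down"].mean_delta_p()
    return out
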