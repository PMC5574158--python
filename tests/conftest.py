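"""Shared fixtures: a mid-size synthetic panel, QTN set and base population.

Everything is generated programmatically with fixed seeds; the panel is
large enough (1,200 sites, 60 lines) for frequency calibration to work
while keeping whole-module runtimes in seconds.
"""

import numpy as np
import pytest

from episel import experiment, founders, gene_drop, traits


@pytest.fixture(scope="session")
def panel_small():
    rng = np.random.default_rng(7)
    freqs = founders.draw_site_frequencies(1200, 0.2, rng, n_lines=60)
    sites = founders.make_genetic_map(1200, seed=rng)
    return founders.make_founder_panel(freqs, 60, inbred=True, seed=rng, sites=sites)


@pytest.fixture(scope="session")
def qtn_small(panel_small):
    eff, src, pairs = traits.sample_qtn_effects(10, 30, seed=11)
    return traits.assign_qtn_sites(
        eff, src, pairs, panel_small.allele_frequencies(),
        seed=13, corr_tol=0.15, mean_tol=0.06,
    )


@pytest.fixture(scope="session")
def base_pop_small(panel_small, qtn_small):
    """Complementary-architecture base population of 200 after 5 burn rounds."""
    rng = np.random.default_rng(17)
    pop, trait = experiment.build_base_population(panel_small, qtn_small,
                                                  N=200, burn_generations=5,
                                                  rng=rng)
    return pop, trait


@pytest.fixture(scope="session")
def hwe_genotypes():
    """Genotypes in exact-sampling Hardy-Weinberg at known frequencies."""
    rng = np.random.default_rng(23)
    p = rng.uniform(0.05, 0.95, 80)
    dos = ((rng.random((3000, 80)) < p).astype(np.int16)
           + (rng.random((3000, 80)) < p).astype(np.int16))
    return dos, p
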