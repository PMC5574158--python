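"""Metrics: progeny-test breeding values, substitution effects, LD,
Hill-Weir decay fit and genomic inbreeding against naive oracles."""

import numpy as np
import pandas as pd
import pytest

from episel import experiment, founders, gene_drop, metrics, traits


def _autosomal_additive_setup(seed=21, n_qtn=40, N=300):
    """Base population whose QTN sit on autosomes only (the BV = genotypic
    deviation identity is exact without X hemizygosity)."""
    rng = np.random.default_rng(seed)
    freqs = founders.draw_site_frequencies(900, 0.3, rng, n_lines=50)
    sites = founders.make_genetic_map(900, seed=rng)
    panel = founders.make_founder_panel(freqs, 50, seed=rng, sites=sites)
    auto = np.flatnonzero(panel.sites.chromosome != "X")
    qtn_sites = rng.choice(auto, size=n_qtn, replace=False)
    z = np.abs(rng.normal(0, 0.5, n_qtn // 2)) + 0.05
    qtn = traits.QTNSet(
        site_index=qtn_sites,
        pairs=np.arange(n_qtn).reshape(-1, 2),
        z=-z,
        dominant_allele=(panel.allele_frequencies()[qtn_sites] >= 0.5).astype(int),
        source=np.asarray(["exponential"] * n_qtn, dtype=object),
        architecture="additive",
    )
    pop = gene_drop.population_from_lines(panel, None, rng)
    for _ in range(4):
        pop = gene_drop.random_mating_generation(pop, N, None, rng)
    dos = traits.qtn_allele1_dosage(pop.haplotypes, qtn)
    g = traits.genotypic_value(qtn.dominant_dosage(dos), qtn, "additive")
    s2 = traits.calibrate_environmental_variance(g, 0.5)
    trait = traits.TraitModel(qtn=qtn, sigma_e2=s2)
    pop.gv, pop.phen = g, trait.phenotypes(g, rng)
    return pop, trait, rng


class TestBreedingValues:
    def test_additive_bv_tracks_genotypic_deviation(self):
        pop, trait, rng = _autosomal_additive_setup()
        idx = rng.choice(pop.n, 200, replace=False)
        bvs = np.array([b.bv for b in metrics.empirical_breeding_values(
            pop, trait, idx, n_offspring=1000, rng=rng)])
        dev = pop.gv[idx] - pop.gv.mean()
        assert np.corrcoef(bvs, dev)[0, 1] >= 0.98

    def test_se_scales_with_offspring_count(self):
        pop, trait, rng = _autosomal_additive_setup()
        b1 = metrics.empirical_breeding_values(pop, trait, [0], 400, rng)[0]
        b2 = metrics.empirical_breeding_values(pop, trait, [0], 1600, rng)[0]
        assert b2.se == pytest.approx(b1.se / 2, rel=0.25)

    def test_single_sex_population_rejected(self):
        pop, trait, rng = _autosomal_additive_setup()
        pop.sex[:] = 0
        with pytest.raises(ValueError, match="both sexes"):
            metrics.empirical_breeding_values(pop, trait, [0], 10, rng)


class TestAdditiveVariance:
    def test_matches_2pq_alpha2_in_additive_hwe_population(self):
        pop, trait, rng = _autosomal_additive_setup()
        va = metrics.additive_variance(pop, trait, n_offspring=500, rng=rng,
                                       subsample=150)
        f1 = pop.dosage(trait.qtn.site_index).mean(axis=0) / 2
        theory = float(np.sum(2 * f1 * (1 - f1) * trait.qtn.locus_effect**2))
        assert va == pytest.approx(theory, rel=0.15)

    def test_clonal_population_has_zero_additive_variance(self):
        pop, trait, rng = _autosomal_additive_setup(N=60)
        pop.haplotypes[:] = pop.haplotypes[0]
        pop.gv[:] = pop.gv[0]
        va = metrics.additive_variance(pop, trait, n_offspring=300, rng=rng,
                                       subsample=20)
        # only progeny-sampling noise remains
        assert va < 0.05 * np.var(pop.phen)


class TestResponseCurve:
    def test_zero_at_generation_zero_and_direction_sign(self):
        per_gen = pd.DataFrame({
            "replicate": [0, 0, 0, 1, 1, 1],
            "generation": [0, 1, 2, 0, 1, 2],
            "mean_phen": [0.0, 1.0, 2.0, 0.0, 2.0, 4.0],
            "sd_phen": [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
        })
        out = metrics.response_curve(per_gen)
        assert out.loc[out.generation == 0, "mean"].item() == 0.0
        assert out.loc[out.generation == 2, "mean"].item() == pytest.approx(1.5)
        assert out.loc[out.generation == 2, "q75"].item() == pytest.approx(1.75)


class TestPredictionAccuracy:
    def test_perfect_and_independent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        assert metrics.prediction_accuracy(x, x) == pytest.approx(1.0)
        assert metrics.prediction_accuracy(x, rng.normal(size=5000)) == pytest.approx(
            0.0, abs=0.05)

    def test_degenerate_input_gives_nan(self):
        assert np.isnan(metrics.prediction_accuracy(np.ones(5), np.arange(5.0)))


class TestSubstitutionEffect:
    @staticmethod
    def _alpha_oracle(z, pB, pC):
        """Numeric least squares of pair value on dominant dosage at B,
        marginalizing the partner under HWE — the 9-cell enumeration."""
        gB = np.array([2, 1, 0])
        wB = np.array([pB**2, 2 * pB * (1 - pB), (1 - pB) ** 2])
        wC = np.array([pC**2, 2 * pC * (1 - pC), (1 - pC) ** 2])
        vals = np.array([[traits.pair_value(b, c, z) for c in (2, 1, 0)]
                         for b in (2, 1, 0)])
        marg = vals @ wC
        xbar = np.sum(wB * gB)
        cov = np.sum(wB * (gB - xbar) * marg) - 0.0 * xbar
        mbar = np.sum(wB * marg)
        cov = np.sum(wB * (gB - xbar) * (marg - mbar))
        var = np.sum(wB * (gB - xbar) ** 2)
        return cov / var

    def test_closed_form_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            z = rng.normal()
            z = z if z != 0 else 1.0
            pB, pC = rng.uniform(0.05, 0.95, 2)
            qtn = traits.QTNSet(
                site_index=np.array([0, 1]), pairs=np.array([[0, 1]]),
                z=np.array([z]), dominant_allele=np.array([1, 1]),
                source=np.asarray(["exponential"] * 2, dtype=object),
                architecture="complementary")
            # freq_allele1 = dominant-allele frequency here
            alpha = metrics.substitution_effect(qtn, np.array([pB, pC]))
            want_B = self._alpha_oracle(z, pB, pC)
            want_C = self._alpha_oracle(z, pC, pB)
            assert alpha[0] == pytest.approx(want_B, abs=1e-8)
            assert alpha[1] == pytest.approx(want_C, abs=1e-8)

    def test_additive_alpha_is_a(self):
        qtn = traits.QTNSet(
            site_index=np.array([0, 1]), pairs=np.array([[0, 1]]),
            z=np.array([-0.7]), dominant_allele=np.array([1, 1]),
            source=np.asarray(["exponential"] * 2, dtype=object),
            architecture="additive")
        alpha = metrics.substitution_effect(qtn, np.array([0.3, 0.9]))
        np.testing.assert_allclose(alpha, [-0.7, -0.7])

    def test_partner_fixed_for_dominant_reduces_to_pure_dominance(self):
        # partner fixed dominant (qC = 0): alpha = z * q at the locus
        qtn = traits.QTNSet(
            site_index=np.array([0, 1]), pairs=np.array([[0, 1]]),
            z=np.array([1.5]), dominant_allele=np.array([1, 1]),
            source=np.asarray(["exponential"] * 2, dtype=object),
            architecture="complementary")
        alpha = metrics.substitution_effect(qtn, np.array([0.6, 1.0]))
        assert alpha[0] == pytest.approx(1.5 * 0.4)


class TestContributionSpectrum:
    def _uniform_qtn(self, n_pairs, z):
        n = 2 * n_pairs
        return traits.QTNSet(
            site_index=np.arange(n), pairs=np.arange(n).reshape(-1, 2),
            z=np.asarray(z), dominant_allele=np.ones(n, dtype=int),
            source=np.asarray(["exponential"] * n, dtype=object),
            architecture="additive")

    def test_equal_contributions_linear_cumulative(self):
        qtn = self._uniform_qtn(5, [1.0] * 5)
        spec = metrics.contribution_spectrum(qtn, np.full(10, 0.5))
        np.testing.assert_allclose(spec["cum_fraction"],
                                   np.arange(1, 11) / 10, atol=1e-12)
        assert metrics.fraction_explaining(spec, 0.9) == pytest.approx(0.9)

    def test_single_dominant_locus_explains_everything(self):
        qtn = self._uniform_qtn(2, [10.0, 1e-6])
        f1 = np.array([0.5, 1.0, 1.0, 1.0])  # only first locus polymorphic
        spec = metrics.contribution_spectrum(qtn, f1)
        assert metrics.fraction_explaining(spec, 0.9) == pytest.approx(0.25)
        assert spec["contribution"].iloc[1:].sum() == 0.0


class TestLdR2:
    def test_matches_naive_two_loop_oracle(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(50, 20))
        chrom = np.asarray(["2"] * 20, dtype=object)
        pos = np.sort(rng.choice(10**6, 20, replace=False))
        out = metrics.ld_r2(dos, chrom, pos)
        keep = np.flatnonzero(dos.std(axis=0) > 0)
        naive = {}
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                i, j = keep[a], keep[b]
                naive[(pos[i], pos[j])] = np.corrcoef(dos[:, i], dos[:, j])[0, 1] ** 2
        assert len(out) == len(naive)
        for _, row in out.iterrows():
            assert row["r2"] == pytest.approx(naive[(row.bp1, row.bp2)], abs=1e-12)

    def test_perfectly_coupled_and_distance_filter(self):
        dos = np.tile(np.array([[0], [1], [2]]), (10, 3))
        chrom = np.asarray(["2"] * 3, dtype=object)
        pos = np.array([100, 200, 10_000])
        out = metrics.ld_r2(dos, chrom, pos, max_dist_bp=500)
        assert np.allclose(out["r2"], 1.0)
        assert len(out) == 1  # only the 100 bp pair survives the filter

    def test_cross_chromosome_pairs_excluded(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, size=(30, 4))
        chrom = np.asarray(["2", "2", "3", "3"], dtype=object)
        pos = np.array([1, 2, 1, 2])
        out = metrics.ld_r2(dos, chrom, pos)
        assert set(out["chrom"]) <= {"2", "3"}
        assert len(out) == 2


class TestHillWeir:
    def test_recovers_scale_from_exact_curve(self):
        d = np.linspace(1e3, 5e6, 300)
        c_true = 2e-6
        r2 = metrics.hill_weir_expectation(d, c_true, 100)
        fit = metrics.fit_hill_weir(d, r2, 100)
        assert fit.C_per_bp == pytest.approx(c_true, rel=0.01)

    def test_fitted_curve_monotone_decreasing(self):
        d = np.linspace(1e3, 5e6, 50)
        r2 = metrics.hill_weir_expectation(d, 1e-6, 50)
        assert np.all(np.diff(r2) < 0)

    def test_flat_data_flagged_as_boundary(self):
        d = np.array([1e3, 1e4, 1e5, 1e6])
        r2 = np.full(4, 1.0 / 50)
        fit = metrics.fit_hill_weir(d, r2, 50)
        assert fit.at_boundary or fit.C_per_bp > 1e-3

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            metrics.fit_hill_weir(np.array([1.0, 1.0, 2.0]),
                                  np.array([0.1, 0.1, 0.2]), 10)


class TestGenomicInbreeding:
    def test_fully_homozygous_individual_is_one(self):
        dos = np.array([[0, 2, 2, 0]])
        out = metrics.genomic_inbreeding(dos, np.array([0.5, 0.5, 0.3, 0.7]))
        assert out["F_h"].iloc[0] == pytest.approx(1.0)

    def test_observed_equals_expected_gives_zero(self):
        p = np.array([0.5, 0.5])
        # E = 2 * (1 - 0.5) = 1; one heterozygote + one homozygote -> O = 1
        out = metrics.genomic_inbreeding(np.array([[1, 2]]), p)
        assert out["F_h"].iloc[0] == pytest.approx(0.0)

    def test_matches_naive_oracle_bitwise(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, 30)
        dos = rng.integers(0, 3, size=(20, 30))
        out = metrics.genomic_inbreeding(dos, p)
        E = sum(1 - 2 * pj * (1 - pj) for pj in p)
        for i in range(20):
            O = sum(1 for j in range(30) if dos[i, j] != 1)
            assert out["F_h"].iloc[i] == pytest.approx((O - E) / (30 - E),
                                                       abs=1e-12)

    def test_hwe_population_mean_near_zero(self, hwe_genotypes):
        dos, p = hwe_genotypes
        out = metrics.genomic_inbreeding(dos, p)
        assert out["F_h"].mean() == pytest.approx(0.0, abs=0.01)


class TestAlleleFrequencyChange:
    def test_drift_only_is_centered_and_fixation_formula(self, base_pop_small):
        pop, trait = base_pop_small
        rng = np.random.default_rng(6)
        nxt = gene_drop.random_mating_generation(pop, 400, trait, rng)
        dp = metrics.allele_frequency_change(pop, nxt, trait.qtn)
        assert abs(dp.mean()) < 0.03
        # fixation of an increasing allele from p0 gives dp = 1 - p0
        p0 = metrics.increasing_allele_frequency(pop, trait.qtn)
        fixed = nxt
        cols = trait.qtn.site_index
        inc = trait.qtn.increasing_allele
        fixed.haplotypes[:, :, cols] = inc.astype(np.uint8)
        dp2 = metrics.allele_frequency_change(pop, fixed, trait.qtn)
        np.testing.assert_allclose(dp2, 1 - p0, atol=1e-12)
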