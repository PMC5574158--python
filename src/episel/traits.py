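"""Trait architectures: additive vs. complementary-epistasis genetic models.

400 causal SNPs (QTN) are grouped into 200 pairs.  Under the complementary
model a pair contributes its value ``z`` only when *both* loci carry at
least one copy of their dominant allele:

    =========  =====  =====  =====
               C1C1   C1C2   C2C2
    B1B1         z      z     0
    B1B2         z      z     0
    B2B2         0      0     0
    =========  =====  =====  =====

i.e. complete dominance (a = d) at each locus and the double mutant is no
better than either single one.  Under the additive model each locus
contributes ``a``, 0 or ``-a`` for the dominant homozygote, heterozygote
and recessive homozygote, where ``a`` equals the ``z`` of its pair.

The absolute-effect distribution is bimodal: 103 "large" effects
(lognormal by default, emulating effects estimated in an association
study, which are biased upward) plus 297 small Exponential(rate 5)
effects.  Pair values are arithmetic means of the two member effects.
QTN are placed on panel sites so that the frequency of trait-increasing
alleles averages ~0.17 and correlates ~-0.42 with |effect| — the
signature of a trait under past directional selection.  At every QTN the
minor (alternative) allele is the recessive one; because most pair values
are oriented negative, the recessive minor allele is usually the
trait-increasing one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .founders import HaplotypePanel

__all__ = [
    "EffectRecord",
    "QTNSet",
    "TraitModel",
    "sample_qtn_effects",
    "assign_qtn_sites",
    "pair_value",
    "genotypic_value",
    "calibrate_environmental_variance",
]

Architecture = Literal["additive", "complementary"]


@dataclass
class EffectRecord:
    """One causal locus: site, per-locus value and dominance orientation."""

    site_id: int
    effect: float  # per-locus value z (= a in the additive architecture)
    source: str  # {"empirical_like", "exponential"}
    dominant_allele: int  # allele (0/1) playing the dominant B1/C1 role


@dataclass
class QTNSet:
    """400 causal loci grouped into 200 disjoint epistatic pairs.

    Arrays are locus-parallel (length ``n_qtn``); ``pairs`` holds locus
    indices (rows of the arrays), two per pair.  ``z`` is per *pair*
    (signed); each locus of a pair shares it as its per-locus value.
    """

    site_index: np.ndarray  # (n_qtn,) column indices into the panel
    pairs: np.ndarray  # (n_pairs, 2) locus indices
    z: np.ndarray  # (n_pairs,) signed pair values
    dominant_allele: np.ndarray  # (n_qtn,) in {0, 1}
    source: np.ndarray  # (n_qtn,) object
    architecture: Architecture = "complementary"
    achieved_corr: float | None = None
    achieved_mean_p_plus: float | None = None

    def __post_init__(self) -> None:
        n = len(self.site_index)
        if self.pairs.shape != (n // 2, 2):
            raise ValueError("pair count must equal locus count / 2")
        flat = np.sort(self.pairs.ravel())
        if not np.array_equal(flat, np.arange(n)):
            raise ValueError("every locus must appear in exactly one pair")
        if np.any(self.z == 0) or not np.all(np.isfinite(self.z)):
            raise ValueError("pair values must be finite and nonzero")

    @property
    def n_qtn(self) -> int:
        return len(self.site_index)

    @property
    def locus_effect(self) -> np.ndarray:
        """Per-locus signed value (the pair's z), length n_qtn."""
        eff = np.empty(self.n_qtn)
        eff[self.pairs[:, 0]] = self.z
        eff[self.pairs[:, 1]] = self.z
        return eff

    @property
    def increasing_allele(self) -> np.ndarray:
        """Allele (0/1) that increases the trait at each locus.

        With z > 0 the dominant allele increases the trait; with z < 0 the
        recessive one does (the best genotype zeroes the pair).
        """
        pos = self.locus_effect > 0
        return np.where(pos, self.dominant_allele, 1 - self.dominant_allele)

    def dominant_dosage(self, dosage_allele1: np.ndarray) -> np.ndarray:
        """Convert allele-1 dosage at QTN columns to dominant-allele dosage."""
        d = np.asarray(dosage_allele1)
        return np.where(self.dominant_allele == 1, d, 2 - d)

    def records(self) -> list[EffectRecord]:
        eff = self.locus_effect
        return [
            EffectRecord(int(self.site_index[i]), float(eff[i]),
                         str(self.source[i]), int(self.dominant_allele[i]))
            for i in range(self.n_qtn)
        ]


@dataclass
class TraitModel:
    """A QTN set plus the environmental variance calibrated to target H2."""

    qtn: QTNSet
    sigma_e2: float = 0.0
    target_H2: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be >= 0")

    def phenotypes(self, g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return g + rng.normal(0.0, np.sqrt(self.sigma_e2), size=len(g))


def sample_qtn_effects(
    n_large: int = 103,
    n_small: int = 297,
    exp_rate: float = 5.0,
    seed: int | np.random.Generator = 0,
    large_median_factor: float = 5.0,
    large_sigma_log: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample signed per-locus effects and the pair grouping.

    Small effects: |e| ~ Exponential(rate).  Large effects: |e| lognormal
    with median ``large_median_factor`` times the exponential median, so
    the pooled |effect| histogram is bimodal.  Signs are +/- with equal
    probability.  Loci are randomly grouped into pairs.

    Returns ``(effects, source, pairs)``: signed effects (n,), source tags
    (n,), and the (n/2, 2) random pair grouping.
    """
    n = n_large + n_small
    if n % 2:
        raise ValueError("n_large + n_small must be even to form pairs")
    if exp_rate <= 0:
        raise ValueError("exp_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    small = rng.exponential(1.0 / exp_rate, size=n_small)
    mu_log = np.log(large_median_factor * np.log(2.0) / exp_rate)
    large = rng.lognormal(mu_log, large_sigma_log, size=n_large)
    mag = np.concatenate([large, small])
    source = np.asarray(["empirical_like"] * n_large + ["exponential"] * n_small,
                        dtype=object)
    sign = rng.choice([-1.0, 1.0], size=n)
    perm = rng.permutation(n)
    pairs = perm.reshape(-1, 2)
    return mag * sign, source, pairs


def _pair_z(effects: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Signed pair value: arithmetic mean of the two member effects."""
    return 0.5 * (effects[pairs[:, 0]] + effects[pairs[:, 1]])


def assign_qtn_sites(
    effects: np.ndarray,
    source: np.ndarray,
    pairs: np.ndarray,
    freqs: np.ndarray,
    target_corr: float = -0.42,
    target_mean_p_plus: float = 0.17,
    seed: int | np.random.Generator = 0,
    architecture: Architecture = "complementary",
    corr_tol: float = 0.05,
    mean_tol: float = 0.02,
) -> QTNSet:
    """Place QTN on panel sites and orient pair signs to hit the targets.

    ``freqs`` are panel allele-1 frequencies.  The dominant allele at each
    QTN is the major allele (the minor/alternative allele is recessive).
    Two calibration knobs are tuned: the fraction of pairs given a negative
    z (which makes the rare recessive allele the increasing one) controls
    the mean frequency of increasing alleles, and a Gaussian-copula latent
    correlation matches large |z| to low-frequency increasing alleles,
    controlling the Pearson correlation between |effect| and p+.

    Raises if the targets are infeasible on the available frequencies; the
    achieved values are stored on the returned :class:`QTNSet`.
    """
    effects = np.asarray(effects, dtype=float)
    n = len(effects)
    n_pairs = n // 2
    if not (-1.0 < target_corr <= 0.0):
        raise ValueError("target_corr must be in (-1, 0]")
    if not (0.0 < target_mean_p_plus <= 0.5):
        raise ValueError("target_mean_p_plus must be in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    poly = np.flatnonzero((freqs > 0) & (freqs < 1))
    if len(poly) < n:
        raise ValueError(f"panel has only {len(poly)} polymorphic sites; need {n}")

    z = _pair_z(effects, pairs)
    abs_z = np.abs(z)
    # normal scores of |z| ranks for the copula
    u = np.argsort(np.argsort(abs_z))
    u = (u + 0.5) / n_pairs
    from scipy.stats import norm

    u = norm.ppf(u)
    xi = rng.standard_normal(n_pairs)

    site_idx = rng.choice(poly, size=n, replace=False)
    minor = np.minimum(freqs[site_idx], 1 - freqs[site_idx])
    site_pairs = rng.permutation(n).reshape(n_pairs, 2)
    s_minor = minor[site_pairs].sum(axis=1)  # per site-pair, sum of minor freqs

    order_sites = np.argsort(s_minor)  # ascending minor-freq sum

    def realize(rho_l: float, n_pos: int):
        v = rho_l * u + np.sqrt(max(0.0, 1 - rho_l**2)) * xi
        order_z = np.argsort(v)  # ascending propensity for high p+
        # rank-match: z-pair with lowest v gets the site-pair with lowest
        # minor-frequency sum (large |z| on rare increasing alleles)
        match = np.empty(n_pairs, dtype=int)
        match[order_z] = order_sites
        sign = np.full(n_pairs, -1.0)
        if n_pos:
            sign[order_z[-n_pos:]] = 1.0  # highest-propensity pairs positive
        # per-locus achieved values
        m_loc = minor[site_pairs[match]].reshape(-1)
        sg = np.repeat(sign, 2)
        p_plus = np.where(sg < 0, m_loc, 1 - m_loc)
        mean_p = float(p_plus.mean())
        if np.std(p_plus) == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(np.repeat(abs_z, 2), p_plus)[0, 1])
        return match, sign, mean_p, corr

    def solve_npos(rho_l: float) -> tuple[int, float]:
        # mean p+ is increasing in n_pos; bisection over integers
        lo, hi = 0, n_pairs
        _, _, m_lo, _ = realize(rho_l, lo)
        if m_lo >= target_mean_p_plus:
            return lo, m_lo
        _, _, m_hi, _ = realize(rho_l, hi)
        if m_hi <= target_mean_p_plus:
            return hi, m_hi
        while hi - lo > 1:
            mid = (lo + hi) // 2
            _, _, m_mid, _ = realize(rho_l, mid)
            if m_mid < target_mean_p_plus:
                lo = mid
            else:
                hi = mid
        _, _, m_lo, _ = realize(rho_l, lo)
        _, _, m_hi, _ = realize(rho_l, hi)
        return (lo, m_lo) if abs(m_lo - target_mean_p_plus) <= abs(m_hi - target_mean_p_plus) else (hi, m_hi)

    best = None
    rho_grid = [0.0] if target_corr == 0.0 else list(np.linspace(0.0, -0.99, 67))
    for rho_l in rho_grid:
        n_pos, mean_p = solve_npos(rho_l)
        match, sign, mean_p, corr = realize(rho_l, n_pos)
        cand = (abs(corr - target_corr), match, sign, mean_p, corr, n_pos, rho_l)
        if best is None or cand[0] < best[0]:
            best = cand
    _, match, sign, mean_p, corr, n_pos, rho_l = best
    if abs(corr - target_corr) > corr_tol or abs(mean_p - target_mean_p_plus) > mean_tol:
        raise ValueError(
            "infeasible targets: best achievable mean p+ = "
            f"{mean_p:.3f} (target {target_mean_p_plus}), corr = {corr:.3f} "
            f"(target {target_corr})"
        )

    # assemble locus-parallel arrays: pair k (effect indices pairs[k]) sits on
    # site-pair match[k]; member order within the pair is arbitrary
    site_index = np.empty(n, dtype=np.int64)
    src = np.empty(n, dtype=object)
    locus_pairs = np.empty((n_pairs, 2), dtype=int)
    for k in range(n_pairs):
        i, j = pairs[k]
        sA, sB = site_pairs[match[k]]
        site_index[2 * k] = site_idx[sA]
        site_index[2 * k + 1] = site_idx[sB]
        src[2 * k] = source[i]
        src[2 * k + 1] = source[j]
        locus_pairs[k] = (2 * k, 2 * k + 1)
    dominant = (freqs[site_index] >= 0.5).astype(np.int8)  # major allele dominant
    return QTNSet(
        site_index=site_index,
        pairs=locus_pairs,
        z=sign * abs_z,
        dominant_allele=dominant,
        source=src,
        architecture=architecture,
        achieved_corr=corr,
        achieved_mean_p_plus=mean_p,
    )


def pair_value(gB: int, gC: int, z: float) -> float:
    """Two-locus complementary value: z iff both loci carry >=1 dominant allele.

    ``gB``/``gC`` count copies of the dominant allele (0, 1 or 2).
    """
    if gB not in (0, 1, 2) or gC not in (0, 1, 2):
        raise ValueError("genotype counts must be 0, 1 or 2")
    return z if (gB >= 1 and gC >= 1) else 0.0


def genotypic_value(
    dominant_dosage: np.ndarray,
    qtn: QTNSet,
    architecture: Architecture | None = None,
) -> np.ndarray:
    """Genotypic values for a matrix of dominant-allele dosages (n x n_qtn).

    Complementary: sum over the 200 pairs of ``pair_value``.  Additive:
    sum over loci of (a, 0, -a) for dominant dosage (2, 1, 0) with a = z.
    """
    arch = architecture or qtn.architecture
    d = np.atleast_2d(np.asarray(dominant_dosage))
    if d.shape[1] != qtn.n_qtn:
        raise ValueError("dosage matrix has wrong number of QTN columns")
    if np.any((d < 0) | (d > 2)):
        raise ValueError("missing or invalid genotype in dosage matrix")
    if arch == "additive":
        return (d - 1.0) @ qtn.locus_effect
    if arch == "complementary":
        has_dom = d >= 1
        active = has_dom[:, qtn.pairs[:, 0]] & has_dom[:, qtn.pairs[:, 1]]
        return active @ qtn.z
    raise ValueError(f"unknown architecture {arch!r}")


def calibrate_environmental_variance(g: np.ndarray, target_H2: float = 0.5) -> float:
    """Environmental variance giving broad-sense heritability ``target_H2``.

    sigma_e^2 = Var(g) * (1 - H2) / H2, with Var the sample variance over
    the base population's genotypic values.
    """
    if not (0.0 < target_H2 < 1.0):
        raise ValueError("target_H2 must lie in (0, 1)")
    g = np.asarray(g, dtype=float)
    if len(g) < 2:
        raise ValueError("need at least 2 genotypic values")
    var_g = float(np.var(g, ddof=1))
    if var_g == 0.0:
        raise ValueError("zero genetic variance; cannot calibrate")
    return var_g * (1.0 - target_H2) / target_H2


def qtn_allele1_dosage(haplotypes: np.ndarray, qtn: QTNSet) -> np.ndarray:
    """Allele-1 dosage at QTN columns from an (n, 2, k) haplotype array."""
    cols = qtn.site_index
    return haplotypes[:, 0, cols].astype(np.int16) + haplotypes[:, 1, cols]


def trait_model_for_population(
    panel: HaplotypePanel,
    qtn: QTNSet,
    base_g: np.ndarray,
    target_H2: float = 0.5,
) -> TraitModel:
    """Bundle a QTN set with sigma_e^2 calibrated on base genotypic values."""
    s2 = calibrate_environmental_variance(base_g, target_H2)
    return TraitModel(qtn=qtn, sigma_e2=s2, target_H2=target_H2)
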