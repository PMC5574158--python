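"""Synthetic founder panels emulating a Drosophila-like inbred reference panel.

The simulated base material mimics three properties of a panel of fully
inbred sequenced lines that drive selection dynamics downstream:

* founders are (close to) fully homozygous, so heterozygosity only appears
  after random mating;
* the site frequency spectrum is U-shaped (most variants rare);
* long-range linkage disequilibrium in the panel is near zero, because
  sites are drawn independently given their frequencies.

Real phased haplotypes can be ingested from a VCF instead
(:func:`load_haplotypes_vcf`).

Genetic maps are sex specific: the female map interpolates cumulative cM
linearly in physical position, while the male map is identically zero
(male Drosophila do not recombine).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SiteTable",
    "HaplotypePanel",
    "CHROMOSOME_DEFAULTS",
    "draw_site_frequencies",
    "make_genetic_map",
    "make_founder_panel",
    "load_haplotypes_vcf",
]

#: Default chromosome geometry: (label, length in bp, female map length in cM).
#: X ~22 Mb / 70 cM, chr2 ~48 Mb / 107 cM, chr3 ~52 Mb / 110 cM.
CHROMOSOME_DEFAULTS: tuple[tuple[str, int, float], ...] = (
    ("X", 22_000_000, 70.0),
    ("2", 48_000_000, 107.0),
    ("3", 52_000_000, 110.0),
)


@dataclass
class SiteTable:
    """Per-site metadata: chromosome, physical position and sex-specific map.

    Positions are 1-based (VCF convention) and strictly increasing within a
    chromosome; ``cm_male`` is zero at every site.
    """

    chromosome: np.ndarray  # dtype object/str, shape (k,)
    position_bp: np.ndarray  # int64, shape (k,)
    cm_female: np.ndarray  # float64, shape (k,)
    cm_male: np.ndarray  # float64, shape (k,)
    ref_allele: np.ndarray | None = None
    alt_allele: np.ndarray | None = None
    site_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.cm_female = np.asarray(self.cm_female, dtype=np.float64)
        self.cm_male = np.asarray(self.cm_male, dtype=np.float64)
        if self.site_id is None:
            self.site_id = np.arange(self.n_sites, dtype=np.int64)
        if self.ref_allele is None:
            self.ref_allele = np.full(self.n_sites, "A", dtype=object)
        if self.alt_allele is None:
            self.alt_allele = np.full(self.n_sites, "T", dtype=object)
        self._validate()

    def _validate(self) -> None:
        k = self.n_sites
        for arr, name in ((self.position_bp, "position_bp"), (self.cm_female, "cm_female"),
                          (self.cm_male, "cm_male"), (self.site_id, "site_id")):
            if len(arr) != k:
                raise ValueError(f"{name} length {len(arr)} != {k}")
        if len(np.unique(self.site_id)) != k:
            raise ValueError("site_ids must be unique")
        if np.any(self.cm_male != 0.0):
            raise ValueError("male map must be zero everywhere")
        for chrom in self.chromosomes:
            m = self.chromosome == chrom
            pos = self.position_bp[m]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
            if np.any(np.diff(self.cm_female[m]) < 0):
                raise ValueError(f"cm_female decreasing on chromosome {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.chromosome)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(str(c), None)
        return list(seen)

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous column slice per chromosome (sites are stored grouped)."""
        out: dict[str, slice] = {}
        chrom = np.asarray([str(c) for c in self.chromosome])
        for c in self.chromosomes:
            idx = np.flatnonzero(chrom == c)
            if len(idx) and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError("sites of one chromosome must be stored contiguously")
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1) if len(idx) else slice(0, 0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "cm_female": self.cm_female,
                "cm_male": self.cm_male,
                "ref_allele": self.ref_allele,
                "alt_allele": self.alt_allele,
            }
        )

    def subset(self, index: np.ndarray) -> "SiteTable":
        index = np.asarray(index)
        return SiteTable(
            chromosome=self.chromosome[index],
            position_bp=self.position_bp[index],
            cm_female=self.cm_female[index],
            cm_male=self.cm_male[index],
            ref_allele=np.asarray(self.ref_allele, dtype=object)[index],
            alt_allele=np.asarray(self.alt_allele, dtype=object)[index],
            site_id=self.site_id[index],
        )


@dataclass
class HaplotypePanel:
    """Phased founder haplotypes: two rows per line, one column per site."""

    sites: SiteTable
    haplotypes: np.ndarray  # uint8 {0,1}, shape (2*n_lines, k)
    line_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.sites.n_sites:
            raise ValueError("haplotype matrix shape does not match site table")
        if self.haplotypes.shape[0] != 2 * len(self.line_ids):
            raise ValueError("expected two haplotype rows per line")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("alleles must be 0/1")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_sites(self) -> int:
        return self.sites.n_sites

    def line_haplotypes(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.haplotypes[2 * i], self.haplotypes[2 * i + 1]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele 1 over the 2*n_lines haplotypes."""
        return self.haplotypes.mean(axis=0)

    def line_heterozygosity(self) -> np.ndarray:
        """Fraction of heterozygous sites per line (0 for fully inbred lines)."""
        a = self.haplotypes[0::2]
        b = self.haplotypes[1::2]
        return (a != b).mean(axis=1)


def draw_site_frequencies(
    n_sites: int,
    sfs_shape: float = 0.2,
    seed: int | np.random.Generator = 0,
    n_lines: int | None = None,
) -> np.ndarray:
    """Draw i.i.d. allele-1 frequencies from a symmetric Beta(shape, shape).

    With ``sfs_shape < 1`` the spectrum is U-shaped: most mass near 0 and 1,
    as observed for sequence variants in natural populations.  When
    ``n_lines`` is given, frequencies so extreme that the expected panel
    would be monomorphic (p < 1/(2*n_lines) or p > 1 - 1/(2*n_lines)) are
    redrawn so every retained site can segregate.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not sfs_shape > 0:
        raise ValueError("sfs_shape must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.beta(sfs_shape, sfs_shape, size=n_sites)
    if n_lines is not None:
        lo = 1.0 / (2 * n_lines)
        for _ in range(1000):
            bad = (p < lo) | (p > 1 - lo)
            if not bad.any():
                break
            p[bad] = rng.beta(sfs_shape, sfs_shape, size=int(bad.sum()))
        else:  # pragma: no cover - pathological shape
            p = np.clip(p, lo, 1 - lo)
    return p


def make_genetic_map(
    n_sites: int,
    chromosome_specs: Sequence[tuple[str, int, float]] = CHROMOSOME_DEFAULTS,
    seed: int | np.random.Generator = 0,
    breakpoints: dict[str, np.ndarray] | None = None,
) -> SiteTable:
    """Place ``n_sites`` uniformly over the chromosomes and build the maps.

    Sites are allocated to chromosomes proportionally to physical length,
    positions drawn uniformly (1-based, deduplicated), and ``cm_female``
    assigned by linear interpolation of cumulative map length against bp.
    ``cm_male`` is zero everywhere.  An optional per-chromosome breakpoint
    table (columns bp, cM) overrides the linear interpolation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [c[0] for c in chromosome_specs]
    lens = np.array([c[1] for c in chromosome_specs], dtype=float)
    cms = np.array([c[2] for c in chromosome_specs], dtype=float)
    if np.any(lens <= 0) or np.any(cms < 0):
        raise ValueError("chromosome lengths must be positive")
    counts = np.maximum(1, np.round(n_sites * lens / lens.sum()).astype(int))
    # fix rounding so the total is exactly n_sites
    while counts.sum() > n_sites:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_sites:
        counts[np.argmin(counts)] += 1

    chrom_col, pos_col, cmf_col = [], [], []
    for label, L, cM, cnt in zip(labels, lens, cms, counts):
        pos = np.sort(rng.choice(np.int64(L), size=cnt, replace=False)) + 1
        if breakpoints is not None and label in breakpoints:
            bp_tab = np.asarray(breakpoints[label], dtype=float)
            cmf = np.interp(pos, bp_tab[:, 0], bp_tab[:, 1])
        else:
            cmf = cM * pos / L
        chrom_col.append(np.full(cnt, label, dtype=object))
        pos_col.append(pos)
        cmf_col.append(cmf)
    return SiteTable(
        chromosome=np.concatenate(chrom_col),
        position_bp=np.concatenate(pos_col),
        cm_female=np.concatenate(cmf_col),
        cm_male=np.zeros(n_sites),
    )


def interpolate_map(sites: SiteTable, chromosome_specs=CHROMOSOME_DEFAULTS) -> SiteTable:
    """Fill cm_female on an existing site table by linear interpolation."""
    spec = {c[0]: (c[1], c[2]) for c in chromosome_specs}
    cmf = np.empty(sites.n_sites)
    for chrom, sl in sites.chromosome_slices().items():
        if chrom not in spec:
            raise ValueError(f"unknown chromosome label {chrom!r}")
        L, cM = spec[chrom]
        cmf[sl] = cM * sites.position_bp[sl] / L
    return SiteTable(
        chromosome=sites.chromosome,
        position_bp=sites.position_bp,
        cm_female=cmf,
        cm_male=np.zeros(sites.n_sites),
        ref_allele=sites.ref_allele,
        alt_allele=sites.alt_allele,
        site_id=sites.site_id,
    )


def make_founder_panel(
    freqs: np.ndarray,
    n_lines: int = 205,
    inbred: bool = True,
    seed: int | np.random.Generator = 0,
    sites: SiteTable | None = None,
    redraw_monomorphic: bool = True,
) -> HaplotypePanel:
    """Sample founder lines given per-site allele-1 frequencies.

    When ``inbred`` each line's allele at each site is a single
    Bernoulli(p_j) draw copied to both haplotypes, giving fully homozygous
    lines; otherwise the two haplotypes are drawn independently.  Sites are
    mutually independent given frequencies, so long-range LD in the panel
    is ~1/n_lines in r^2 terms.  Sites that come out monomorphic across the
    sampled lines are redrawn (keeping their frequency) so the panel is
    polymorphic everywhere.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 founder lines")
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(freqs)
    if inbred:
        lines = (rng.random((n_lines, k)) < freqs).astype(np.uint8)
        if redraw_monomorphic:
            fixable = (freqs > 0) & (freqs < 1)
            for _ in range(200):
                colsum = lines.sum(axis=0)
                mono = ((colsum == 0) | (colsum == n_lines)) & fixable
                if not mono.any():
                    break
                lines[:, mono] = (
                    rng.random((n_lines, int(mono.sum()))) < freqs[mono]
                ).astype(np.uint8)
        haps = np.repeat(lines, 2, axis=0)
    else:
        haps = (rng.random((2 * n_lines, k)) < freqs).astype(np.uint8)
    if sites is None:
        sites = make_genetic_map(k, seed=rng)
    line_ids = [f"line_{i:04d}" for i in range(n_lines)]
    return HaplotypePanel(sites=sites, haplotypes=haps, line_ids=line_ids)


def load_haplotypes_vcf(
    path: str,
    map_source: SiteTable | None = None,
    chromosome_specs=CHROMOSOME_DEFAULTS,
    strict: bool = True,
) -> HaplotypePanel:
    """Load phased biallelic SNPs from a VCF into a haplotype panel.

    Indels and non-biallelic records are skipped (count logged).  Unphased
    or missing genotypes raise an error under ``strict``, otherwise the
    site is dropped.  Map positions come from ``map_source`` (joined by
    chromosome+position) or by linear interpolation of the default
    chromosome geometry.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises OSError subclasses
        raise FileNotFoundError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    chrom_l, pos_l, ref_l, alt_l, gt_l = [], [], [], [], []
    n_skipped = 0
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        if any(g[0] < 0 or g[1] < 0 for g in gts):
            if strict:
                raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}")
            n_dropped += 1
            continue
        if not all(g[2] for g in gts):
            if strict:
                raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
            n_dropped += 1
            continue
        chrom_l.append(rec.CHROM)
        pos_l.append(rec.POS)
        ref_l.append(rec.REF)
        alt_l.append(rec.ALT[0])
        gt_l.append([a for g in gts for a in (g[0], g[1])])
    if n_skipped:
        logger.info("skipped %d indel/multiallelic records", n_skipped)
    if n_dropped:
        logger.info("dropped %d sites with missing/unphased genotypes", n_dropped)
    if not pos_l:
        raise ValueError("no usable phased biallelic SNP records in VCF")

    order = np.lexsort((np.asarray(pos_l), np.asarray(chrom_l, dtype=object)))
    chrom = np.asarray(chrom_l, dtype=object)[order]
    pos = np.asarray(pos_l, dtype=np.int64)[order]
    # column-per-site haplotype matrix, alternating hap0/hap1 per sample
    gt = np.asarray(gt_l, dtype=np.uint8)[order]  # (k, 2n)
    haps = np.ascontiguousarray(gt.T)  # (2n, k)

    if map_source is not None:
        key = {(str(c), int(b)): i for i, (c, b) in
               enumerate(zip(map_source.chromosome, map_source.position_bp))}
        idx = []
        keep = []
        for j, (c, b) in enumerate(zip(chrom, pos)):
            hit = key.get((str(c), int(b)))
            if hit is None:
                n_dropped += 1
                continue
            idx.append(hit)
            keep.append(j)
        if not keep:
            raise ValueError("no VCF sites matched the map source")
        sites = map_source.subset(np.asarray(idx))
        haps = haps[:, keep]
    else:
        sites = interpolate_map(
            SiteTable(
                chromosome=chrom,
                position_bp=pos,
                cm_female=np.zeros(len(pos)),
                cm_male=np.zeros(len(pos)),
                ref_allele=np.asarray(ref_l, dtype=object)[order],
                alt_allele=np.asarray(alt_l, dtype=object)[order],
            ),
            chromosome_specs,
        )
    return HaplotypePanel(sites=sites, haplotypes=haps, line_ids=samples)
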