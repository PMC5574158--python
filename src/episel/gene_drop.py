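"""Meiosis and reproduction: gene-dropping founder haplotypes through pedigrees.

Crossovers follow a Poisson process on the sex-specific cM map (no
interference): the count is Poisson in the female map length in Morgans
and positions are uniform on the cM scale.  Males do not recombine (their
map is zero), so a male gamete carries one intact haplotype per
chromosome.  X transmission: sons receive their single X from the dam;
daughters receive the sire's X intact plus a recombined maternal X.

Storage convention: every individual carries an (2, k) haplotype array.
For males the single X haplotype is stored duplicated in both rows, so
X dosage is automatically "doubled" (0/2) in genotype matrices and the
male X genotype class is homozygous — the default hemizygote coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .founders import HaplotypePanel, SiteTable
from .traits import TraitModel, genotypic_value, qtn_allele1_dosage

__all__ = [
    "FEMALE",
    "MALE",
    "ChromosomeMap",
    "Individual",
    "Population",
    "population_from_lines",
    "sample_gamete",
    "sample_gametes_batch",
    "mate",
    "random_mating_generation",
]

FEMALE, MALE = 0, 1


@dataclass
class ChromosomeMap:
    """Per-chromosome site slices and female cM coordinates."""

    labels: list[str]
    slices: list[slice]
    cm: list[np.ndarray]
    x_label: str = "X"

    @classmethod
    def from_sites(cls, sites: SiteTable, x_label: str = "X") -> "ChromosomeMap":
        sl = sites.chromosome_slices()
        labels = list(sl)
        return cls(
            labels=labels,
            slices=[sl[c] for c in labels],
            cm=[np.ascontiguousarray(sites.cm_female[sl[c]]) for c in labels],
            x_label=x_label,
        )

    @property
    def x_slice(self) -> slice | None:
        if self.x_label in self.labels:
            return self.slices[self.labels.index(self.x_label)]
        return None

    def length_cm(self, label: str) -> float:
        cm = self.cm[self.labels.index(label)]
        return float(cm.max()) if len(cm) else 0.0


@dataclass
class Individual:
    """Read-only view of one individual in a population."""

    id: int
    sex: int
    haplotypes: np.ndarray  # (2, k); male X duplicated across rows
    genotypic_value: float
    phenotype: float
    generation: int


@dataclass
class Population:
    """All individuals of one generation, stored columnar."""

    generation: int
    sites: SiteTable
    haplotypes: np.ndarray  # (n, 2, k) uint8
    sex: np.ndarray  # (n,) {0 female, 1 male}
    gv: np.ndarray
    phen: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    cmap: ChromosomeMap = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ids is None:
            self.ids = np.arange(len(self.sex), dtype=np.int64)
        if self.cmap is None:
            self.cmap = ChromosomeMap.from_sites(self.sites)

    @property
    def n(self) -> int:
        return len(self.sex)

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def individual(self, i: int) -> Individual:
        return Individual(
            id=int(self.ids[i]), sex=int(self.sex[i]), haplotypes=self.haplotypes[i],
            genotypic_value=float(self.gv[i]), phenotype=float(self.phen[i]),
            generation=self.generation,
        )

    def dosage(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Allele-1 dosage matrix (n x k or n x len(columns)), int16."""
        h = self.haplotypes if columns is None else self.haplotypes[:, :, columns]
        return h[:, 0].astype(np.int16) + h[:, 1]


def population_from_lines(
    panel: HaplotypePanel,
    trait: TraitModel | None,
    rng: np.random.Generator,
    generation: int = 0,
) -> Population:
    """One individual per founder line (both haplotypes = the line's), with
    sexes assigned half/half at random."""
    n = panel.n_lines
    haps = panel.haplotypes.reshape(n, 2, panel.n_sites).copy()
    sex = np.zeros(n, dtype=np.int8)
    sex[: n // 2] = MALE
    rng.shuffle(sex)
    cmap = ChromosomeMap.from_sites(panel.sites)
    # males: keep only one X (rows are identical for inbred lines anyway,
    # but enforce the duplicated-X convention for non-inbred input)
    xs = cmap.x_slice
    if xs is not None:
        m = sex == MALE
        haps[m, 1, xs] = haps[m, 0, xs]
    gv, phen = _evaluate_trait(haps, trait, rng)
    return Population(generation=generation, sites=panel.sites, haplotypes=haps,
                      sex=sex, gv=gv, phen=phen, cmap=cmap)


def _evaluate_trait(
    haps: np.ndarray, trait: TraitModel | None, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = haps.shape[0]
    if trait is None:
        z = np.zeros(n)
        return z, z.copy()
    dos = qtn_allele1_dosage(haps, trait.qtn)
    g = genotypic_value(trait.qtn.dominant_dosage(dos), trait.qtn)
    return g, trait.phenotypes(g, rng)


def _recombine_chrom(
    haps: np.ndarray,  # (n, 2, kc) parental haplotypes for this chromosome
    cm: np.ndarray,  # (kc,) site positions in cM
    n_xo: np.ndarray,  # (n,) crossover counts
    start: np.ndarray,  # (n,) starting haplotype 0/1
    rng: np.random.Generator,
    chunk: int = 1024,
) -> np.ndarray:
    """Gametes for one chromosome given crossover counts and start rows."""
    n, _, kc = haps.shape
    length = float(cm.max()) if kc else 0.0
    out = np.empty((n, kc), dtype=np.uint8)
    cmax = int(n_xo.max()) if n else 0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        if cmax == 0 or length == 0.0:
            choice = np.broadcast_to(start[lo:hi, None], (m, kc))
        else:
            pos = rng.uniform(0.0, length, size=(m, cmax))
            pos[np.arange(cmax)[None, :] >= n_xo[lo:hi, None]] = np.inf
            # crossovers strictly before each site flip the source haplotype
            n_before = (pos[:, :, None] < cm[None, None, :]).sum(axis=1)
            choice = (start[lo:hi, None] + n_before) % 2
        h = haps[lo:hi]
        out[lo:hi] = np.where(choice == 0, h[:, 0], h[:, 1])
    return out


def sample_gametes_batch(
    haplotypes: np.ndarray,  # (m, 2, k) parental pool
    parent_index: np.ndarray,  # (n,) rows of the pool, one per gamete
    parent_sex: np.ndarray,  # (n,)
    cmap: ChromosomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one whole-genome gamete per entry of ``parent_index``.

    Female parents recombine (Poisson crossovers on the cM map); male
    parents transmit one intact haplotype per chromosome (independent
    assortment across chromosomes, no recombination).
    """
    parent_index = np.asarray(parent_index)
    n = len(parent_index)
    k = haplotypes.shape[2]
    out = np.empty((n, k), dtype=np.uint8)
    female = np.asarray(parent_sex)[parent_index] == FEMALE
    for label, sl, cm in zip(cmap.labels, cmap.slices, cmap.cm):
        L_morgan = (cm.max() / 100.0) if len(cm) else 0.0
        n_xo = np.where(female, rng.poisson(L_morgan, size=n), 0)
        start = rng.integers(0, 2, size=n)
        out[:, sl] = _recombine_chrom(
            haplotypes[parent_index][:, :, sl], cm, n_xo, start, rng
        )
    return out


def sample_gamete(
    pop: Population,
    parent: int,
    chromosome: str,
    rng: np.random.Generator,
    destined_sex: int | None = None,
) -> np.ndarray:
    """One gamete haplotype for a single chromosome of one parent.

    A male parent's X is destined for daughters only; requesting it for a
    son violates the transmission contract and raises.
    """
    if chromosome not in pop.cmap.labels:
        raise ValueError(f"unknown chromosome {chromosome!r}")
    if (
        chromosome == pop.cmap.x_label
        and pop.sex[parent] == MALE
        and destined_sex == MALE
    ):
        raise ValueError("a sire's X cannot be transmitted to a son")
    ci = pop.cmap.labels.index(chromosome)
    sl = pop.cmap.slices[ci]
    whole = sample_gametes_batch(
        pop.haplotypes, np.asarray([parent]), pop.sex, pop.cmap, rng
    )
    return whole[0, sl]


def _offspring_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly balanced sexes (n even), order shuffled."""
    sex = np.zeros(n, dtype=np.int8)
    sex[: n // 2] = MALE
    rng.shuffle(sex)
    return sex


def _assemble_offspring(
    pop: Population,
    sires: np.ndarray,
    dams: np.ndarray,
    sexes: np.ndarray,
    trait: TraitModel | None,
    rng: np.random.Generator,
    generation: int,
) -> Population:
    pat = sample_gametes_batch(pop.haplotypes, sires, pop.sex, pop.cmap, rng)
    mat = sample_gametes_batch(pop.haplotypes, dams, pop.sex, pop.cmap, rng)
    xs = pop.cmap.x_slice
    if xs is not None:
        sons = sexes == MALE
        # sons carry only the maternal X; keep it duplicated in both rows
        pat[sons, xs] = mat[sons, xs]
    haps = np.stack([pat, mat], axis=1)
    gv, phen = _evaluate_trait(haps, trait, rng)
    return Population(generation=generation, sites=pop.sites, haplotypes=haps,
                      sex=sexes, gv=gv, phen=phen, cmap=pop.cmap)


def mate(
    pop: Population,
    sire: int,
    dam: int,
    n_offspring: int,
    trait: TraitModel | None,
    rng: np.random.Generator,
) -> Population:
    """Offspring of one sire x dam mating, with an equal sex ratio."""
    if pop.sex[sire] != MALE or pop.sex[dam] != FEMALE:
        raise ValueError("mate() needs a male sire and a female dam")
    sexes = _offspring_sexes(n_offspring, rng)
    sires = np.full(n_offspring, sire)
    dams = np.full(n_offspring, dam)
    return _assemble_offspring(pop, sires, dams, sexes, trait, rng,
                               pop.generation + 1)


def random_mating_generation(
    pop: Population,
    N: int,
    trait: TraitModel | None,
    rng: np.random.Generator,
) -> Population:
    """Next generation of N offspring from uniformly drawn male x female pairs.

    Sire and dam are sampled independently (with replacement) for every
    offspring, which maximizes the effective size of the mating scheme.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    males, females = pop.males, pop.females
    if len(males) == 0 or len(females) == 0:
        raise ValueError("random mating requires both sexes")
    sires = rng.choice(males, size=N, replace=True)
    dams = rng.choice(females, size=N, replace=True)
    sexes = _offspring_sexes(N, rng)
    return _assemble_offspring(pop, sires, dams, sexes, trait, rng,
                               pop.generation + 1)
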