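"""Neutral historical population and genome simulation.

The study genome is an abstract diploid map: ``n_chromosomes`` chromosomes of
``chr_length`` centimorgans, each carrying biallelic SNP and QTL loci placed
uniformly at random on the genetic map.  A closed historical population of
constant size is bred forward for hundreds of discrete generations under
random selection and random mating, letting drift, recombination and recurrent
mutation shape linkage disequilibrium and the allele-frequency spectrum, after
which a small base population (G0) of prospective sires and dams is drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeConfig",
    "GenomeMap",
    "HistoricalConfig",
    "Population",
    "simulate_historical",
    "sample_base_population",
]


@dataclass(frozen=True)
class GenomeConfig:
    """Layout parameters of the simulated genome.

    Defaults mirror a penaeid-shrimp-like design: 44 chromosomes of 100 cM,
    1200 SNPs and 85 QTLs per chromosome (52,800 SNPs, 3,740 QTLs genome-wide)
    and a per-locus, per-gamete mutation rate of 2.5e-8.
    """

    n_chromosomes: int = 44
    chr_length: float = 100.0
    snps_per_chr: int = 1200
    qtls_per_chr: int = 85
    mutation_rate: float = 2.5e-8

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.snps_per_chr < 1 or self.qtls_per_chr < 0:
            raise ValueError("genome must have >= 1 chromosome with >= 1 SNP each")
        if self.chr_length < 0:
            raise ValueError("chr_length must be non-negative")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chr

    @property
    def n_qtls(self) -> int:
        return self.n_chromosomes * self.qtls_per_chr

    @property
    def n_loci(self) -> int:
        return self.n_snps + self.n_qtls

    def build_map(self, rng: np.random.Generator | int) -> "GenomeMap":
        """Draw uniform map positions for every SNP and QTL.

        SNP and QTL positions are drawn independently within each chromosome;
        loci are then stored sorted by (chromosome, position).
        """
        rng = np.random.default_rng(rng)
        per_chr = self.snps_per_chr + self.qtls_per_chr
        chrom = np.repeat(np.arange(self.n_chromosomes), per_chr)
        pos = np.empty(self.n_loci)
        is_qtl = np.empty(self.n_loci, dtype=bool)
        for c in range(self.n_chromosomes):
            p = rng.uniform(0.0, self.chr_length, size=per_chr)
            q = np.zeros(per_chr, dtype=bool)
            q[self.snps_per_chr:] = True
            order = np.argsort(p, kind="stable")
            sl = slice(c * per_chr, (c + 1) * per_chr)
            pos[sl] = p[order]
            is_qtl[sl] = q[order]
        return GenomeMap(config=self, chrom=chrom, pos_cm=pos, is_qtl=is_qtl)


@dataclass(frozen=True)
class GenomeMap:
    """A realized locus map: chromosome, position (cM) and type per locus."""

    config: GenomeConfig
    chrom: np.ndarray
    pos_cm: np.ndarray
    is_qtl: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.pos_cm.size

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def chromosome_slices(self) -> list[slice]:
        """Contiguous locus index ranges, one per chromosome."""
        bounds = np.searchsorted(self.chrom, np.arange(self.config.n_chromosomes + 1))
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": np.arange(self.n_loci),
                "chrom": self.chrom + 1,
                "pos_cm": self.pos_cm,
                "type": np.where(self.is_qtl, "QTL", "SNP"),
            }
        )


@dataclass(frozen=True)
class HistoricalConfig:
    """Historical-population parameters: 400 generations of constant size 1000
    (500 males, 500 females) under random selection and random mating."""

    n_generations: int = 400
    pop_size: int = 1000
    n_males: int = 500
    n_females: int = 500
    init_allele_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.n_males + self.n_females != self.pop_size:
            raise ValueError("n_males + n_females must equal pop_size")
        if self.pop_size < 2 or self.n_males == 0 or self.n_females == 0:
            raise ValueError("population needs at least one male and one female")
        if not 0.0 <= self.init_allele_freq <= 1.0:
            raise ValueError("init_allele_freq must lie in [0, 1]")


@dataclass
class Population:
    """One discrete generation: identifiers, sexes, parents and diplotypes.

    ``haplotypes`` has shape (n, 2, n_loci) over the full (SNP + QTL)
    interleaved locus map; ``sire``/``dam`` are 0 for unknown parents.
    Trait fields are attached once the generation enters the breeding program.
    """

    ids: np.ndarray
    sex: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    haplotypes: np.ndarray
    genome_map: GenomeMap
    generation_label: str
    qtl_bv: np.ndarray | None = None
    poly_bv: np.ndarray | None = None
    tbv: np.ndarray | None = None
    phenotype: np.ndarray | None = None
    ebv_selection: np.ndarray | None = None
    inbreeding: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == "M"

    def dosage(self, locus_indices: np.ndarray) -> np.ndarray:
        """Allele-count (0/1/2) genotypes at the given loci."""
        return self.haplotypes[:, :, locus_indices].sum(axis=1).astype(np.int8)

    def snp_dosage(self) -> np.ndarray:
        return self.dosage(self.genome_map.snp_indices)

    def qtl_dosage(self) -> np.ndarray:
        return self.dosage(self.genome_map.qtl_indices)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "sire": self.sire,
                "dam": self.dam,
                "sex": self.sex,
                "generation": self.generation_label,
            }
        )
        for name in ("qtl_bv", "poly_bv", "tbv", "phenotype", "ebv_selection"):
            val = getattr(self, name)
            if val is not None:
                df[name] = val
        return df


def _mutate(gametes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Recurrent per-locus allele flips, in place.

    Exact Bernoulli mask for appreciable rates; for tiny rates (the default
    2.5e-8) a binomial draw of the flip count with uniform placement, which is
    equivalent up to vanishing collision probability.
    """
    if rate <= 0.0:
        return
    if rate >= 1e-4:
        mask = rng.random(gametes.shape) < rate
        gametes[mask] ^= 1
        return
    n_mut = rng.binomial(gametes.size, rate)
    if n_mut:
        idx = np.unique(rng.integers(0, gametes.size, size=n_mut))
        flat = gametes.reshape(-1)
        flat[idx] ^= 1


def gametes_from_parents(
    haplotypes: np.ndarray,
    parent_idx: np.ndarray,
    genome_map: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete per entry of ``parent_idx`` by meiosis.

    Per chromosome the crossover count is Poisson with mean equal to the map
    length in Morgans, crossover positions are uniform on the map (Haldane, no
    interference) and the starting parental strand is chosen fairly.  Recurrent
    mutation is applied per locus at the configured rate.
    """
    n_gam = parent_idx.size
    out = np.empty((n_gam, genome_map.n_loci), dtype=np.uint8)
    lam = genome_map.config.chr_length / 100.0
    for sl in genome_map.chromosome_slices():
        pos = genome_map.pos_cm[sl]
        hap = haplotypes[parent_idx][:, :, sl]  # (n_gam, 2, L)
        start = rng.integers(0, 2, size=n_gam)
        n_cx = rng.poisson(lam, size=n_gam) if lam > 0 else np.zeros(n_gam, dtype=int)
        plain = n_cx == 0
        if plain.any():
            out[plain, sl] = hap[plain, start[plain], :]
        for g in np.flatnonzero(~plain):
            cx = np.sort(rng.uniform(0.0, genome_map.config.chr_length, size=n_cx[g]))
            source = (start[g] + np.searchsorted(cx, pos, side="right")) % 2
            out[g, sl] = np.where(source == 0, hap[g, 0], hap[g, 1])
    _mutate(out, genome_map.config.mutation_rate, rng)
    return out


def simulate_historical(
    genome: GenomeConfig, hist: HistoricalConfig, seed: int
) -> Population:
    """Breed the historical population forward and return its final generation.

    Founders start with every locus segregating at ``init_allele_freq``
    (independent Bernoulli alleles); each later generation is produced by
    drawing, per offspring, a sire uniformly among males and a dam uniformly
    among females, with gametes formed by meiosis and recurrent mutation.
    Generations are discrete and non-overlapping; offspring sexes are assigned
    to hit exactly ``n_males``/``n_females``.
    """
    rng = np.random.default_rng(seed)
    gmap = genome.build_map(rng)
    n = hist.pop_size
    sex = np.array(["M"] * hist.n_males + ["F"] * hist.n_females)
    haplos = (
        rng.random((n, 2, gmap.n_loci)) < hist.init_allele_freq
    ).astype(np.uint8)
    ids = np.arange(1, n + 1, dtype=np.int64)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    next_id = n + 1
    for _ in range(hist.n_generations):
        males = np.flatnonzero(sex == "M")
        females = np.flatnonzero(sex == "F")
        sire_pick = males[rng.integers(0, males.size, size=n)]
        dam_pick = females[rng.integers(0, females.size, size=n)]
        pat = gametes_from_parents(haplos, sire_pick, gmap, rng)
        mat = gametes_from_parents(haplos, dam_pick, gmap, rng)
        new = np.stack([pat, mat], axis=1)
        sire = ids[sire_pick]
        dam = ids[dam_pick]
        ids = np.arange(next_id, next_id + n, dtype=np.int64)
        next_id += n
        haplos = new
    return Population(
        ids=ids,
        sex=sex.copy(),
        sire=sire,
        dam=dam,
        haplotypes=haplos,
        genome_map=gmap,
        generation_label="historical",
    )


def sample_base_population(
    hist_pop: Population, n_sires: int, n_dams: int, seed: int
) -> Population:
    """Draw the base generation G0: ``n_sires`` males and ``n_dams`` females
    sampled uniformly without replacement, haplotypes copied unchanged."""
    rng = np.random.default_rng(seed)
    males = np.flatnonzero(hist_pop.is_male)
    females = np.flatnonzero(~hist_pop.is_male)
    if males.size < n_sires or females.size < n_dams:
        raise ValueError(
            f"need {n_sires} males and {n_dams} females; population has "
            f"{males.size} males and {females.size} females"
        )
    pick = np.concatenate(
        [
            rng.choice(males, size=n_sires, replace=False),
            rng.choice(females, size=n_dams, replace=False),
        ]
    )
    return Population(
        ids=hist_pop.ids[pick].copy(),
        sex=hist_pop.sex[pick].copy(),
        sire=np.zeros(pick.size, dtype=np.int64),
        dam=np.zeros(pick.size, dtype=np.int64),
        haplotypes=hist_pop.haplotypes[pick].copy(),
        genome_map=hist_pop.genome_map,
        generation_label="G0",
    )
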