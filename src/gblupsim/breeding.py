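"""Selective breeding over full-sib families with a QTL + polygenic trait.

Five generations (G01..G05) of 50 full-sib families are produced from a base
population by truncation selection of sires and dams on estimated breeding
values.  The trait has mean 0 and phenotypic variance 1, decomposed into a QTL
component (additive allele-substitution effects summed over QTL genotypes), a
pedigree polygenic component, and a normal residual:

    phenotype = qtl_bv + poly_bv + e,   tbv = qtl_bv + poly_bv.

Family contributions are either equal (scenario S1, a fixed family size) or
unequal (S2, family sizes drawn from a categorical distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import (
    GenomeConfig,
    GenomeMap,
    HistoricalConfig,
    Population,
    gametes_from_parents,
    sample_base_population,
    simulate_historical,
)
from .relmat import tabular_extend

__all__ = [
    "TraitArchitecture",
    "FamilyContribution",
    "BreedingResult",
    "assign_qtl_effects",
    "meiosis",
    "draw_family_sizes",
    "advance_generation",
    "run_breeding",
]

# h2 -> (QTL additive variance, polygenic additive variance); residual is the
# complement to a phenotypic variance of 1.  At h2 = 0.3 the polygenic share
# is one third of the additive variance; the same 2:1 split is applied at the
# low and high heritabilities.
VARIANCE_PARTITION: dict[float, tuple[float, float]] = {
    0.05: (0.03, 0.02),
    0.3: (0.2, 0.1),
    0.5: (0.3, 0.2),
}


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive trait variance partition and (once assigned) QTL effects."""

    h2: float
    var_qtl: float
    var_poly: float
    mean: float = 0.0
    qtl_effects: np.ndarray | None = None
    qtl_offset: float = 0.0  # centers base-generation QTL breeding values at 0

    def __post_init__(self) -> None:
        if self.var_qtl < 0 or self.var_poly < 0:
            raise ValueError("variance components must be non-negative")
        if self.var_qtl + self.var_poly > 1.0 + 1e-12:
            raise ValueError("additive variance exceeds the phenotypic variance of 1")

    @property
    def var_error(self) -> float:
        return 1.0 - self.var_qtl - self.var_poly

    @property
    def var_additive(self) -> float:
        return self.var_qtl + self.var_poly

    @classmethod
    def from_h2(cls, h2: float) -> "TraitArchitecture":
        if h2 not in VARIANCE_PARTITION:
            raise ValueError(f"no variance partition defined for h2={h2}")
        vq, vp = VARIANCE_PARTITION[h2]
        return cls(h2=h2, var_qtl=vq, var_poly=vp)


@dataclass(frozen=True)
class FamilyContribution:
    """Family-size rule: equal (S1) or a categorical distribution (S2)."""

    kind: str
    equal_size: int = 100
    sizes: tuple[int, ...] = (5, 25, 50, 75, 100, 125, 150, 175, 200)
    probs: tuple[float, ...] = (0.05, 0.10, 0.12, 0.14, 0.18, 0.14, 0.12, 0.10, 0.05)

    def __post_init__(self) -> None:
        if self.kind not in ("equal", "unequal"):
            raise ValueError("kind must be 'equal' or 'unequal'")
        if self.kind == "unequal":
            if len(self.sizes) != len(self.probs):
                raise ValueError("sizes and probs must have equal length")
            if abs(sum(self.probs) - 1.0) > 1e-12:
                raise ValueError("probs must sum to 1 within 1e-12")
            if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
                raise ValueError("sizes must be strictly increasing")

    @classmethod
    def equal(cls, size: int = 100) -> "FamilyContribution":
        return cls(kind="equal", equal_size=size)

    @classmethod
    def unequal(
        cls,
        sizes: tuple[int, ...] | None = None,
        probs: tuple[float, ...] | None = None,
    ) -> "FamilyContribution":
        kw: dict = {}
        if sizes is not None:
            kw["sizes"] = tuple(sizes)
        if probs is not None:
            kw["probs"] = tuple(probs)
        return cls(kind="unequal", **kw)

    @property
    def mean_size(self) -> float:
        if self.kind == "equal":
            return float(self.equal_size)
        return float(np.dot(self.sizes, self.probs))


def assign_qtl_effects(
    population: Population, arch: TraitArchitecture, seed: int
) -> TraitArchitecture:
    """Draw and scale QTL allele-substitution effects on the base generation.

    One effect per QTL is drawn from a standard normal and all effects are
    rescaled by a single constant so that the sample variance of per-individual
    QTL breeding values in the base generation equals ``arch.var_qtl``.  The
    effects are then fixed for all later generations.
    """
    rng = np.random.default_rng(seed)
    n_qtl = population.genome_map.qtl_indices.size
    raw = rng.standard_normal(n_qtl)
    bv = population.qtl_dosage() @ raw
    v = float(np.var(bv, ddof=1))
    if v <= 0.0:
        raise ValueError("QTL breeding values are degenerate (zero variance)")
    effects = raw * np.sqrt(arch.var_qtl / v)
    offset = -float(np.mean(population.qtl_dosage() @ effects))
    return replace(arch, qtl_effects=effects, qtl_offset=offset)


def meiosis(
    parent_haplotypes: np.ndarray,
    genome_map: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete from a parent's (2, n_loci) haplotype pair.

    Crossovers per chromosome are Poisson with mean chr_length/100 (Haldane,
    no interference); the starting strand is chosen fairly; mutation flips
    alleles at the configured rate.
    """
    haps = parent_haplotypes[np.newaxis]
    return gametes_from_parents(haps, np.zeros(1, dtype=int), genome_map, rng)[0]


def draw_family_sizes(
    contribution: FamilyContribution, n_families: int, seed: int
) -> np.ndarray:
    """Progeny counts for ``n_families`` matings under the contribution rule."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if contribution.kind == "equal":
        return np.full(n_families, contribution.equal_size, dtype=np.int64)
    rng = np.random.default_rng(seed)
    return rng.choice(
        np.asarray(contribution.sizes, dtype=np.int64),
        size=n_families,
        p=np.asarray(contribution.probs),
    )


def _select_top(
    pop: Population, mask: np.ndarray, k: int
) -> np.ndarray:
    """Positions of the top-k individuals of ``mask`` by selection EBV,
    ties broken by ascending id for reproducibility."""
    cand = np.flatnonzero(mask)
    if cand.size < k:
        raise ValueError(f"only {cand.size} candidates available, need {k}")
    ebv = pop.ebv_selection[cand]
    order = np.lexsort((pop.ids[cand], -ebv))
    return cand[order[:k]]


def advance_generation(
    parents: Population,
    arch: TraitArchitecture,
    contribution: FamilyContribution,
    n_families: int,
    seed: int,
    *,
    start_id: int | None = None,
    generation_label: str = "G",
) -> Population:
    """Produce the next generation from truncation-selected parents.

    The top ``n_families`` males and females by ``ebv_selection`` are paired
    randomly 1:1 into full-sib matings; each mating yields a family of size
    drawn from the contribution rule.  Offspring sex is Bernoulli(0.5).  The
    polygenic value of an offspring is the mid-parent value plus a Mendelian
    sampling deviation N(0, var_poly/2 * (1 - (F_s + F_d)/2)), with parental
    inbreeding F taken from the pedigree; the phenotype adds a
    N(0, var_error) residual to the total breeding value.
    """
    if arch.qtl_effects is None:
        raise ValueError("trait architecture has no QTL effects assigned")
    if parents.ebv_selection is None:
        raise ValueError("parents carry no selection EBVs")
    rng = np.random.default_rng(seed)
    gmap = parents.genome_map

    sires = _select_top(parents, parents.is_male, n_families)
    dams = _select_top(parents, ~parents.is_male, n_families)
    dams = dams[rng.permutation(n_families)]
    sizes = draw_family_sizes(
        contribution, n_families, int(rng.integers(0, 2**31 - 1))
    )
    n_off = int(sizes.sum())

    sire_pos = np.repeat(sires, sizes)
    dam_pos = np.repeat(dams, sizes)
    pat = gametes_from_parents(parents.haplotypes, sire_pos, gmap, rng)
    mat = gametes_from_parents(parents.haplotypes, dam_pos, gmap, rng)
    haplos = np.stack([pat, mat], axis=1)

    if start_id is None:
        start_id = int(parents.ids.max()) + 1
    ids = np.arange(start_id, start_id + n_off, dtype=np.int64)
    sex = np.where(rng.random(n_off) < 0.5, "M", "F")

    qtl_bv = haplos[:, :, gmap.qtl_indices].sum(axis=1) @ arch.qtl_effects + arch.qtl_offset
    f_par = (
        parents.inbreeding
        if parents.inbreeding is not None
        else np.zeros(parents.n)
    )
    ms_var = 0.5 * arch.var_poly * (1.0 - 0.5 * (f_par[sire_pos] + f_par[dam_pos]))
    mid = 0.5 * (parents.poly_bv[sire_pos] + parents.poly_bv[dam_pos])
    poly_bv = mid + rng.standard_normal(n_off) * np.sqrt(np.maximum(ms_var, 0.0))
    tbv = qtl_bv + poly_bv
    phenotype = arch.mean + tbv + rng.standard_normal(n_off) * np.sqrt(arch.var_error)

    return Population(
        ids=ids,
        sex=sex,
        sire=parents.ids[sire_pos],
        dam=parents.ids[dam_pos],
        haplotypes=haplos,
        genome_map=gmap,
        generation_label=generation_label,
        qtl_bv=qtl_bv,
        poly_bv=poly_bv,
        tbv=tbv,
        phenotype=phenotype,
        inbreeding=None,
    )


@dataclass
class BreedingResult:
    """A complete simulated dataset: G0 plus the selection generations."""

    genome_map: GenomeMap
    arch: TraitArchitecture
    contribution: FamilyContribution
    generations: dict[str, Population]
    pedigree: pd.DataFrame
    nrm: np.ndarray
    nrm_ids: np.ndarray

    def generation_labels(self) -> list[str]:
        return [k for k in self.generations if k != "G0"]


def run_breeding(
    genome: GenomeConfig,
    hist: HistoricalConfig,
    arch: TraitArchitecture,
    contribution: FamilyContribution,
    seed: int,
    n_families: int = 50,
    n_generations: int = 5,
) -> BreedingResult:
    """Simulate the full dataset: history, base population and selection.

    Chains ``simulate_historical`` -> ``sample_base_population`` ->
    ``advance_generation`` x ``n_generations``.  G01 is produced by random
    mating of all G0 parents (uniform EBVs); from G02 onward, parents are the
    top ``n_families`` of each sex by pedigree-BLUP EBVs computed from all
    phenotypes recorded so far with the true simulated variance components.
    The numerator relationship matrix over the whole pedigree (G0 treated as
    unrelated founders) is accumulated alongside and returned.
    """
    from .prediction import blup_known_variance  # deferred: avoids cycle

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + n_generations)]
    hist_pop = simulate_historical(genome, hist, seeds[0])
    g0 = sample_base_population(hist_pop, n_families, n_families, seeds[1])
    del hist_pop
    arch = assign_qtl_effects(g0, arch, seeds[2])
    rng0 = np.random.default_rng(seeds[3])
    g0.qtl_bv = g0.qtl_dosage() @ arch.qtl_effects + arch.qtl_offset
    g0.poly_bv = rng0.standard_normal(g0.n) * np.sqrt(arch.var_poly)
    g0.tbv = g0.qtl_bv + g0.poly_bv
    g0.ebv_selection = np.zeros(g0.n)
    g0.inbreeding = np.zeros(g0.n)

    # cumulative NRM over the pedigree, G0 as founders
    nrm = np.eye(g0.n)
    nrm_ids = g0.ids.copy()
    id_to_pos = {int(i): p for p, i in enumerate(g0.ids)}

    generations: dict[str, Population] = {"G0": g0}
    ped_frames = [g0.to_frame()[["id", "sire", "dam", "sex", "generation"]]]
    current = g0
    next_id = int(g0.ids.max()) + 1
    pheno_pos: list[np.ndarray] = []  # NRM positions of phenotyped individuals
    pheno_y: list[np.ndarray] = []

    for g in range(1, n_generations + 1):
        label = f"G{g:02d}"
        off = advance_generation(
            current,
            arch,
            contribution,
            n_families,
            seeds[3 + g],
            start_id=next_id,
            generation_label=label,
        )
        next_id = int(off.ids.max()) + 1
        sire_pos = np.array([id_to_pos[int(s)] for s in off.sire])
        dam_pos = np.array([id_to_pos[int(d)] for d in off.dam])
        nrm = tabular_extend(nrm, sire_pos, dam_pos)
        base = nrm_ids.size
        nrm_ids = np.concatenate([nrm_ids, off.ids])
        id_to_pos.update({int(i): base + p for p, i in enumerate(off.ids)})
        off.inbreeding = np.diag(nrm)[base : base + off.n] - 1.0

        off_pos = np.arange(base, base + off.n)
        pheno_pos.append(off_pos)
        pheno_y.append(off.phenotype)
        if g < n_generations:
            obs = np.concatenate(pheno_pos)
            y = np.concatenate(pheno_y)
            ebv_all = blup_known_variance(
                y, obs, nrm, arch.var_additive, arch.var_error
            )
            off.ebv_selection = ebv_all[off_pos]
        else:
            off.ebv_selection = np.zeros(off.n)

        generations[label] = off
        ped_frames.append(off.to_frame()[["id", "sire", "dam", "sex", "generation"]])
        current = off

    pedigree = pd.concat(ped_frames, ignore_index=True)
    return BreedingResult(
        genome_map=g0.genome_map,
        arch=arch,
        contribution=contribution,
        generations=generations,
        pedigree=pedigree,
        nrm=nrm,
        nrm_ids=nrm_ids,
    )
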