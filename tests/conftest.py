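import numpy as np
import pytest

import gblupsim as gs


def make_population(n, seed=0, n_loci=1, label="G01"):
    """A light Population with dummy haplotypes, for split/selection tests."""
    rng = np.random.default_rng(seed)
    config = gs.GenomeConfig(n_chromosomes=1, snps_per_chr=n_loci, qtls_per_chr=0)
    gmap = gs.GenomeMap(
        config=config,
        chrom=np.zeros(n_loci, dtype=np.int64),
        pos_cm=np.linspace(0, config.chr_length, n_loci),
        is_qtl=np.zeros(n_loci, dtype=bool),
    )
    return gs.Population(
        ids=np.arange(1, n + 1, dtype=np.int64),
        sex=np.where(rng.random(n) < 0.5, "M", "F"),
        sire=np.zeros(n, dtype=np.int64),
        dam=np.zeros(n, dtype=np.int64),
        haplotypes=rng.integers(0, 2, size=(n, 2, n_loci)).astype(np.uint8),
        genome_map=gmap,
        generation_label=label,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """One tiny-profile breeding simulation shared across module tests."""
    cfg = gs.ScenarioConfig.tiny(master_seed=7)
    return gs.run_breeding(
        genome=cfg.genome,
        hist=cfg.historical,
        arch=gs.TraitArchitecture.from_h2(0.3),
        contribution=cfg.contribution("S1"),
        seed=11,
        n_families=cfg.n_families,
        n_generations=cfg.n_generations,
    )


@pytest.fixture(scope="session")
def tiny_grid():
    """Full tiny-profile factorial: accuracy and concordance records."""
    cfg = gs.ScenarioConfig.tiny(master_seed=3)
    return gs.run_grid(cfg)
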