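"""Scenario-grid orchestration: configuration, seeding and execution.

One breeding simulation is run per (scenario, heritability, replicate) base
dataset; every SNP-density x error-rate cell reuses that simulation, with
smaller panels nested inside the largest and errors injected after panel
sampling.  GBLUP is fitted per cell and generation, pedigree BLUP once per
base dataset and generation.  Per-cell seeds are derived deterministically
from the master seed and the cell's factor levels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .breeding import (
    BreedingResult,
    FamilyContribution,
    TraitArchitecture,
    run_breeding,
)
from .evaluation import accuracy, grm_concordance
from .genome import GenomeConfig, HistoricalConfig
from .genotyping import (
    GenotypeMatrix,
    build_transition_matrix,
    inject_errors,
    maf_filter,
    sample_panel,
)
from .relmat import RelationshipMatrix, compute_grm
from .prediction import fit_mixed_model, predict_ebv, split_train_test

__all__ = [
    "ScenarioConfig",
    "DatasetDescriptor",
    "derive_seed",
    "enumerate_grid",
    "run_base_dataset",
    "run_grid",
]

log = logging.getLogger("gblupsim")


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic sub-seed from the master seed and factor levels."""
    tag = "|".join(str(k) for k in (master_seed, *keys))
    digest = hashlib.sha256(tag.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class ScenarioConfig:
    """The full factorial the pipeline executes.

    The ``full`` profile reproduces the study configuration (a 960-cell grid:
    2 scenarios x 3 heritabilities x 10 replicates x 4 densities x 4 error
    rates); the ``desk`` profile is a reduced-genome, reduced-population
    version of the same design sized for a single workstation, and ``tiny``
    is the test-suite profile.
    """

    scenarios: tuple[str, ...] = ("S1", "S2")
    heritabilities: tuple[float, ...] = (0.05, 0.3, 0.5)
    n_replicates: int = 10
    panel_sizes: tuple[int, ...] = (500, 3000, 10000, 20000)
    error_rates: tuple[float, ...] = (0.0, 0.01, 0.05, 0.10)
    methods: tuple[str, ...] = ("GBLUP", "PBLUP")
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    historical: HistoricalConfig = field(default_factory=HistoricalConfig)
    n_families: int = 50
    n_generations: int = 5
    equal_family_size: int = 100
    unequal_sizes: tuple[int, ...] = (5, 25, 50, 75, 100, 125, 150, 175, 200)
    unequal_probs: tuple[float, ...] = (
        0.05, 0.10, 0.12, 0.14, 0.18, 0.14, 0.12, 0.10, 0.05,
    )
    test_fraction: float = 0.30
    maf_threshold: float = 0.01
    profile: str = "full"
    master_seed: int = 2024

    def __post_init__(self) -> None:
        for name in ("scenarios", "heritabilities", "panel_sizes", "error_rates"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        unknown = set(self.scenarios) - {"S1", "S2"}
        if unknown:
            raise ValueError(f"unknown scenarios {unknown}")

    @classmethod
    def full(cls, master_seed: int = 2024) -> "ScenarioConfig":
        return cls(master_seed=master_seed)

    @classmethod
    def desk(cls, master_seed: int = 2024) -> "ScenarioConfig":
        """Workstation-scale profile: 4 chromosomes of 300 SNPs + 20 QTLs,
        100 historical generations of 200, families of ~20, 3 replicates."""
        return cls(
            n_replicates=3,
            panel_sizes=(200, 1000),
            error_rates=(0.0, 0.10),
            genome=GenomeConfig(
                n_chromosomes=4, snps_per_chr=300, qtls_per_chr=20
            ),
            historical=HistoricalConfig(
                n_generations=100, pop_size=200, n_males=100, n_females=100
            ),
            equal_family_size=20,
            unequal_sizes=(1, 5, 10, 15, 20, 25, 30, 35, 40),
            profile="desk",
            master_seed=master_seed,
        )

    @classmethod
    def tiny(cls, master_seed: int = 2024) -> "ScenarioConfig":
        """Minimal profile for fast property checks."""
        return cls(
            scenarios=("S1",),
            heritabilities=(0.05, 0.5),
            n_replicates=3,
            panel_sizes=(100, 300),
            error_rates=(0.0, 0.05, 0.10),
            genome=GenomeConfig(
                n_chromosomes=2, snps_per_chr=250, qtls_per_chr=15
            ),
            historical=HistoricalConfig(
                n_generations=40, pop_size=100, n_males=50, n_females=50
            ),
            n_families=20,
            equal_family_size=10,
            unequal_sizes=(1, 3, 5, 8, 10, 13, 15, 18, 20),
            profile="tiny",
            master_seed=master_seed,
        )

    def contribution(self, scenario: str) -> FamilyContribution:
        if scenario == "S1":
            return FamilyContribution.equal(self.equal_family_size)
        return FamilyContribution.unequal(self.unequal_sizes, self.unequal_probs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class DatasetDescriptor:
    """One analysis cell of the factorial."""

    scenario: str
    h2: float
    replicate: int
    panel_size: int
    error_rate: float

    @property
    def base_key(self) -> tuple[str, float, int]:
        return (self.scenario, self.h2, self.replicate)


def enumerate_grid(config: ScenarioConfig) -> list[DatasetDescriptor]:
    """All panel x error cells of the factorial, replicate-major, so that all
    cells of one base dataset (one breeding simulation) are adjacent."""
    return [
        DatasetDescriptor(s, h, r, k, e)
        for s in config.scenarios
        for h in config.heritabilities
        for r in range(1, config.n_replicates + 1)
        for k in config.panel_sizes
        for e in config.error_rates
    ]


def _snp_genotypes(population) -> GenotypeMatrix:
    return GenotypeMatrix(
        dosage=population.snp_dosage(),
        locus_ids=population.genome_map.snp_indices,
        individual_ids=population.ids,
    )


def run_base_dataset(
    config: ScenarioConfig, scenario: str, h2: float, replicate: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one base dataset and analyse every panel x error cell.

    Returns (accuracy records, GRM concordance records) as long-format
    frames.  PBLUP rows carry no panel size or error rate.
    """
    t0 = time.perf_counter()
    seed = derive_seed(config.master_seed, "base", scenario, h2, replicate)
    result = run_breeding(
        genome=config.genome,
        hist=config.historical,
        arch=TraitArchitecture.from_h2(h2),
        contribution=config.contribution(scenario),
        seed=seed,
        n_families=config.n_families,
        n_generations=config.n_generations,
    )
    nrm = RelationshipMatrix(values=result.nrm, ids=result.nrm_ids, kind="pedigree")
    log.info(
        "base dataset %s h2=%s rep=%d simulated in %.1fs",
        scenario, h2, replicate, time.perf_counter() - t0,
    )

    records: list[dict] = []
    concordance: list[dict] = []
    keys = {"scenario": scenario, "h2": h2, "replicate": replicate}
    for gen_label in result.generation_labels():
        pop = result.generations[gen_label]
        generation = int(gen_label.lstrip("G"))
        split = split_train_test(
            pop,
            config.test_fraction,
            derive_seed(config.master_seed, "split", scenario, h2, replicate, gen_label),
        )
        test_tbv = pd.Series(pop.tbv, index=pop.ids).loc[split.test_ids]

        if "PBLUP" in config.methods:
            fit = predict_ebv(pop, result.pedigree, split, nrm=nrm)
            records.append(
                keys
                | {
                    "generation": generation,
                    "method": "PBLUP",
                    "panel_size": np.nan,
                    "error_rate": np.nan,
                    "accuracy": accuracy(
                        test_tbv.to_numpy(), fit.ebv.loc[split.test_ids].to_numpy()
                    ),
                }
            )

        if "GBLUP" not in config.methods:
            continue
        qc = maf_filter(_snp_genotypes(pop), config.maf_threshold)
        largest = max(config.panel_sizes)
        # at reduced scale the post-QC SNP count can fall below the nominal
        # largest density; the cell keeps its nominal label
        top_panel = sample_panel(
            qc,
            min(largest, qc.n_loci),
            derive_seed(config.master_seed, "panel", scenario, h2, replicate, gen_label, largest),
        )
        for k in sorted(config.panel_sizes, reverse=True):
            if k == largest:
                panel = top_panel
            else:
                panel = sample_panel(
                    top_panel,
                    min(k, top_panel.n_loci),
                    derive_seed(config.master_seed, "panel", scenario, h2, replicate, gen_label, k),
                )
            grm_clean = compute_grm(panel)
            train_phe = pd.Series(pop.phenotype, index=pop.ids).loc[split.train_ids]
            for rate in config.error_rates:
                if rate == 0.0:
                    observed = panel
                    grm = grm_clean
                else:
                    tm = build_transition_matrix(rate)
                    observed = inject_errors(
                        panel,
                        tm,
                        derive_seed(
                            config.master_seed, "err", scenario, h2, replicate,
                            gen_label, k, rate,
                        ),
                    )
                    grm = compute_grm(observed)
                fit = fit_mixed_model(train_phe, grm)
                records.append(
                    keys
                    | {
                        "generation": generation,
                        "method": "GBLUP",
                        "panel_size": k,
                        "error_rate": rate,
                        "accuracy": accuracy(
                            test_tbv.to_numpy(), fit.ebv.loc[split.test_ids].to_numpy()
                        ),
                    }
                )
                conc = grm_concordance(grm_clean, grm)
                concordance.append(
                    keys
                    | {
                        "generation": generation,
                        "panel_size": k,
                        "error_rate": rate,
                        "pearson_r": conc.pearson_r,
                        "lin_ccc": conc.lin_ccc,
                        "n_pairs": conc.n_pairs,
                    }
                )
    log.info(
        "base dataset %s h2=%s rep=%d analysed in %.1fs",
        scenario, h2, replicate, time.perf_counter() - t0,
    )
    return pd.DataFrame(records), pd.DataFrame(concordance)


def run_grid(
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    resume: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the whole factorial; optionally persist results and manifest.

    With ``out_dir`` set, per-base-dataset shards are written under
    ``shards/`` as they complete, so an interrupted grid can be resumed with
    ``resume=True``; the concatenated ``results.csv`` / ``concordance.csv``
    and a run manifest are written at the end.
    """
    grid = enumerate_grid(config)
    base_keys = sorted({d.base_key for d in grid}, key=str)
    log.info(
        "grid: %d cells over %d base datasets (profile=%s, seed=%d)",
        len(grid), len(base_keys), config.profile, config.master_seed,
    )
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "shards").mkdir(parents=True, exist_ok=True)

    res_frames, conc_frames = [], []
    for scenario, h2, replicate in base_keys:
        tag = f"{scenario}_h{h2}_r{replicate}"
        shard_res = out / "shards" / f"results_{tag}.csv" if out else None
        shard_con = out / "shards" / f"concordance_{tag}.csv" if out else None
        if resume and shard_res is not None and shard_res.exists():
            log.info("resuming: %s already done", tag)
            res_frames.append(pd.read_csv(shard_res))
            if shard_con.exists():
                conc_frames.append(pd.read_csv(shard_con))
            continue
        res, conc = run_base_dataset(config, scenario, h2, replicate)
        if shard_res is not None:
            res.to_csv(shard_res, index=False)
            if not conc.empty:
                conc.to_csv(shard_con, index=False)
        res_frames.append(res)
        conc_frames.append(conc)

    results = pd.concat(res_frames, ignore_index=True)
    concordance = (
        pd.concat([f for f in conc_frames if not f.empty], ignore_index=True)
        if any(not f.empty for f in conc_frames)
        else pd.DataFrame()
    )
    if out is not None:
        results.to_csv(out / "results.csv", index=False)
        if not concordance.empty:
            concordance.to_csv(out / "concordance.csv", index=False)
        manifest = {
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "n_cells": len(grid),
            "n_base_datasets": len(base_keys),
            "files": ["results.csv"] + (["concordance.csv"] if not concordance.empty else []),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return results, concordance
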