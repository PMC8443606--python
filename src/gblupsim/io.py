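"""Plain-text readers and writers for the pipeline's artifacts.

Formats:

* pedigree — whitespace-delimited columns ``id sire dam sex generation``
  with 0 for unknown parents;
* genotypes — headered CSV, first column ``id`` then one 0/1/2 dosage column
  per locus named ``snp_<locus>``;
* loci sidecar — CSV ``locus, chrom, pos_cm, type``;
* phenotypes — CSV ``id, generation, phenotype, tbv, qtl_bv, poly_bv``;
* relationship matrices — full symmetric CSV or long triplets;
* panel manifest — JSON mapping panel label -> locus ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Population
from .genotyping import GenotypeMatrix
from .relmat import RelationshipMatrix

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_genotypes",
    "read_genotypes",
    "write_loci",
    "write_phenotypes",
    "read_phenotypes",
    "write_matrix",
    "write_matrix_triplets",
    "write_panel_manifest",
    "read_panel_manifest",
]


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    cols = ["id", "sire", "dam", "sex", "generation"]
    pedigree[cols].to_csv(path, sep=" ", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+")


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        g.dosage,
        index=pd.Index(g.individual_ids, name="id"),
        columns=[f"snp_{int(l)}" for l in g.locus_ids],
    )
    df.to_csv(path)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="id")
    locus_ids = np.array([int(c.removeprefix("snp_")) for c in df.columns])
    return GenotypeMatrix(
        dosage=df.to_numpy(dtype=np.int8),
        locus_ids=locus_ids,
        individual_ids=df.index.to_numpy(dtype=np.int64),
    )


def write_loci(population: Population, path: str | Path) -> None:
    population.genome_map.to_frame().to_csv(path, index=False)


def write_phenotypes(populations: list[Population], path: str | Path) -> None:
    frames = []
    for pop in populations:
        if pop.phenotype is None:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "id": pop.ids,
                    "generation": pop.generation_label,
                    "phenotype": pop.phenotype,
                    "tbv": pop.tbv,
                    "qtl_bv": pop.qtl_bv,
                    "poly_bv": pop.poly_bv,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(m: RelationshipMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index_label="id")


def write_matrix_triplets(m: RelationshipMatrix, path: str | Path) -> None:
    m.to_triplets().to_csv(path, index=False)


def write_panel_manifest(panels: dict[int, np.ndarray], path: str | Path) -> None:
    payload = {str(k): [int(x) for x in v] for k, v in panels.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_panel_manifest(path: str | Path) -> dict[int, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    return {int(k): np.array(v, dtype=np.int64) for k, v in payload.items()}
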