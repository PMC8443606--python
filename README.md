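# gblupsim

Simulation framework for asking how **genotyping errors**, **SNP density**,
**trait heritability** and **family-contribution structure** affect the
accuracy of genomic versus pedigree prediction of breeding values in a
full-sib aquaculture breeding program (a design patterned on black tiger
prawn, *Penaeus monodon*: 44 chromosomes, 50 full-sib families per
generation, selection over five generations).

It is aimed at breeding-program designers who need to know, before paying
for genotyping, how many SNPs are enough and how much assay error can be
tolerated — and at quantitative geneticists who want a transparent,
fully-seeded forward simulator for sib-training GBLUP experiments.

## What it simulates

1. **Genome and history** — an abstract genetic map (by default 44 × 100 cM
   chromosomes carrying 52,800 SNPs and 3,740 QTLs placed uniformly at
   random) evolves through 400 discrete historical generations of 1000
   randomly mating individuals (recurrent mutation rate 2.5 × 10⁻⁸),
   building up drift and linkage disequilibrium; 50 sires and 50 dams are
   then drawn as the base population G0.
2. **Breeding program** — five generations G01–G05 of 50 full-sib families
   under truncation selection of 50 sires and 50 dams on pedigree-BLUP EBVs.
   Family sizes are equal (S1: 100 progeny each) or drawn from a categorical
   distribution (S2: sizes 5–200 with probabilities 5–18 %). The trait has
   phenotypic variance 1 and heritability 0.05, 0.3 or 0.5, split into a QTL
   component, a pedigree polygenic component and a normal residual:
   `y = μ + u_qtl + u_poly + e`, `TBV = u_qtl + u_poly`.
3. **Genotyping** — per-generation MAF > 0.01 QC, nested SNP panels
   (0.5 K ⊂ 3 K ⊂ 10 K ⊂ 20 K), and genotype miscalls drawn from 3×3
   row-stochastic transition probability matrices at 0/1/5/10 % error.
4. **Prediction** — within each generation, 30 % of progeny are masked as
   selection candidates and predicted from their sibs' phenotypes by GBLUP,

   `G = WW′/c`, `W_ij = X_ij + 1 − 2p_j`, `c = 2 Σ_j p_j(1 − p_j)`,

   or by pedigree BLUP with the numerator relationship matrix **A** (tabular
   method). Variance components are re-estimated by spectral REML for every
   fit. Accuracy is the Pearson correlation of (G)EBV with TBV on the test
   set; the effect of error on **G** itself is measured by Pearson's r and
   Lin's concordance correlation coefficient on the off-diagonal
   relationships.

## Worked example

```python
import pandas as pd
import gblupsim as gs
from gblupsim.pipeline import _snp_genotypes

# a small self-contained study: 2 chromosomes, 20 families, 5 generations
cfg = gs.ScenarioConfig.tiny(master_seed=3)
result = gs.run_breeding(
    genome=cfg.genome,
    hist=cfg.historical,
    arch=gs.TraitArchitecture.from_h2(0.3),
    contribution=cfg.contribution("S1"),
    seed=11,
    n_families=cfg.n_families,
)

pop = result.generations["G03"]
split = gs.split_train_test(pop, 0.30, seed=5)
qc = gs.maf_filter(_snp_genotypes(pop))
panel = gs.sample_panel(qc, 300, seed=6)
tbv = pd.Series(pop.tbv, index=pop.ids).loc[split.test_ids].to_numpy()

clean_grm = gs.compute_grm(panel)
for rate in (0.0, 0.05, 0.10):
    tm = None if rate == 0.0 else gs.build_transition_matrix(rate)
    fit = gs.predict_gebv(pop, panel, split, transition=tm, seed=7)
    acc = gs.accuracy(tbv, fit.ebv.loc[split.test_ids].to_numpy())
    grm = clean_grm if tm is None else gs.compute_grm(gs.inject_errors(panel, tm, 7))
    ccc = gs.grm_concordance(clean_grm, grm).lin_ccc
    print(f"GBLUP 300-SNP panel, {rate:4.0%} error: accuracy={acc:.3f}  GRM CCC={ccc:.3f}")

pfit = gs.predict_ebv(pop, result.pedigree, split)
pacc = gs.accuracy(tbv, pfit.ebv.loc[split.test_ids].to_numpy())
print(f"PBLUP (pedigree only):          accuracy={pacc:.3f}")
```

Output:

```
GBLUP 300-SNP panel,   0% error: accuracy=0.553  GRM CCC=1.000
GBLUP 300-SNP panel,   5% error: accuracy=0.558  GRM CCC=0.962
GBLUP 300-SNP panel,  10% error: accuracy=0.553  GRM CCC=0.892
PBLUP (pedigree only):          accuracy=0.504
```

Genomic prediction beats pedigree prediction (it separates sibs within a
family, which **A** cannot), and at this density a 5–10 % genotyping error
barely moves the test-set accuracy even though the relationship matrix
itself has visibly degraded (CCC 1.00 → 0.89) — errors partly average out in
`WW′/c` while the concordance of individual pairwise relationships suffers.

## Command line

`gblupsim run-grid --profile desk --seed 1 --out runs/desk` executes the
whole scenario factorial (profiles: `full` — the complete 960-cell design;
`desk` — a reduced genome/population for a single workstation; `tiny` — the
test profile) and writes `results.csv`, `concordance.csv` and a run
manifest; interrupted grids resume with `--resume`. `simulate`, `genotype`,
`predict`, `evaluate` and `summarize` expose the individual pipeline stages
over plain CSV/text files. Defaults can be overridden with a YAML file via
`--config`.

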