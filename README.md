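# syndromevo

Correlated evolution of **trait syndromes** on phylogenies.

Comparative biologists often summarize many covarying species traits —
ecological specialization, life-history pace (the r–K gradient), sexual
dimorphism, dispersal and social behaviour — into a handful of synthetic
axes ("syndromes"), ask which end of each axis is ancestral, and test whether
different syndromes evolved together along the tree. `syndromevo` packages
that entire workflow for species × trait tables (with missing data) and a
rooted, branch-length-bearing phylogeny:

1. **Trait coding & imputation** — qualitative records coded 1 / 0.5 / 0,
   ordinal modalities collapsed to specialization indices
   (1 − weighted variance), coverage filtering, Gower nearest-neighbour
   imputation.
2. **Syndrome construction** — PCA on the Spearman rank-correlation matrix of
   each (disjoint) trait set; species split into ancestral (A) / derived (B)
   levels by *exact* 1-D 2-means, i.e. the breakpoint maximizing the
   between/within variance ratio.
3. **Mk models** — pruning likelihood for k-state continuous-time Markov
   characters, ML transition rates q_ij with arbitrary zero/tying
   constraints, exact marginal ancestral states at every node.
4. **Pagel's correlated-evolution test** — for binary characters x, y, the
   4-state product chain with simultaneous transitions forbidden; the
   independent model (4 free rates) versus the dependent model (8 free
   rates), LRT = 2(lnL_D − lnL_I) ~ χ²(4).
5. **Phylogenetic structure** — Abouheif proximity and Cmean permutation
   test, phylogenetic PCA (eigenanalysis of (1/n)Xᵀ((W+Wᵀ)/2)X), three-way
   strategy clustering, phylogenetic ANOVA with a Brownian-simulation null,
   and a mean-pairwise-distance (MPD) null model for sample
   representativeness.
6. **Synthetic data** — Yule trees, forward CTMC and Brownian simulators,
   and a full trait-table generator with known ground truth, so every stage
   is testable without any external download.

Modelling follows a Model → Results pattern: `MkModel(...).fit()` returns
`MkResults` with rates, log-likelihood, ancestral states and a `summary()`;
likewise `PagelModel`, `PhyloPCA`, `PhyloANOVA`, `SpearmanPCA`.

## Worked example

```python
import syndromevo as sv

# a synthetic dataset with known truth: 81 species x 53 traits, 20% missing
ds = sv.simulate_trait_matrix(sv.SimulationConfig(seed=1))
report = sv.run_analysis(ds.matrix, ds.tree, ds.definitions)

spec = report.syndromes["ecological_specialization"]
print(round(spec["variance_fraction_pc1"], 3))
from collections import Counter
print(Counter(spec["states"].values()))
for row in report.pagel[:2]:
    print(row["pair"], round(row["lrt_statistic"], 3),
          round(row["p_value"], 4))
print(report.strategies["counts"])
```

prints

```
0.757
Counter({'A': 50, 'B': 31})
['ecological_specialization', 'rK_gradient'] 3.958 0.4117
['ecological_specialization', 'sexual_dimorphism'] 0.425 0.9804
{'A': 38, 'B1': 26, 'B2': 17}
```

PC1 of the specialization block carries 75.7% of the rank-correlation
variance; the exact 2-means split labels 50 species ancestral (generalist)
and 31 derived (specialist). Both displayed syndrome pairs are consistent
with independent evolution (p ≫ 0.05), as they should be under this
generator scenario, and k-means in the 3-D phylogenetic-PC space divides the
species into three strategy classes.

The same pipeline runs from files:

```bash
syndromevo simulate --seed 1 --out data/
syndromevo run-all --config config.yaml --seed 1 --out results/
```

with subcommands (`impute`, `syndromes`, `ancestral`, `pagel`, `ppca`,
`anova`, `mpd`) for individual stages.

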