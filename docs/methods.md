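# Methods

`syndromevo` implements a complete comparative analysis of *trait syndromes*
— suites of covarying species traits summarized by a single synthetic axis —
on a time-calibrated phylogeny. This note documents the models, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Trait coding and imputation

Raw natural-history observations arrive as a species × trait table mixing
three kinds of variables:

* **Qualitative** records ("Yes" / "Yes minus" / "No") are coded 1 / 0.5 / 0
  and averaged across literature records, weighted by occurrence, so a trait
  reported present in three sources and absent in one scores 0.75.
* **Ordinal multi-modality** traits (e.g. foraging height scored ground = 1,
  shrubs = 2, trees = 3) are summarized per species by a *specialization
  index*: one minus the occurrence-weighted population variance of the
  modality scores. A species always observed in one modality scores 1; a
  species split between extreme modalities scores near 0. Because a wide
  modality scale can push the weighted variance above 1, the index is clipped
  to [0, 1] with a warning. Population (not sample) variance is used because
  the weights are literature frequencies, not random draws.
* **Altitudinal specialization** is 1 − (altitudinal range / dataset-wide
  maximum altitude, default 4,950 m). The constant can be overridden to
  recompute from a user dataset.

Missingness is carried as an explicit boolean mask, never a sentinel value.
Species documented for less than half their traits (configurable) are dropped
before analysis. Remaining holes are filled by a nearest-neighbour rule: the
donor is the species minimizing the Gower distance (range-normalized absolute
differences averaged over co-observed traits); ties among equally close
donors are averaged. The rule is deterministic, scale-free and idempotent.
Tropical affinity is a strict-majority rule: a species is tropical iff more
than half its distribution area lies in the tropics.

## Syndrome construction

Each syndrome (ecological specialization, r–K gradient, sexual dimorphism,
dispersal/social behaviour) is defined by a disjoint set of traits. The
syndrome score is the first principal component of a PCA on the *Spearman*
rank-correlation matrix of those traits: column ranks are standardized
(population scaling) and projected onto the eigenvectors of the rank
correlation matrix. With this construction the reported loadings are rank
correlations between each variable and the axis scores, and the whole
analysis is invariant to monotone transforms of any input column. PC1's sign
is oriented so a declared *derived pole* subset of variables loads
net-positive, removing the eigenvector sign ambiguity.

Species are discretized into ancestral (A) / derived (B) levels by 1-D
2-means, solved *exactly* by scanning the n − 1 sorted breakpoints for the
split minimizing within-group variance (equivalently maximizing the
between/within variance ratio). This removes any seed dependence. One
consequence of the rank-based scores deserves emphasis: ranks erase the size
of gaps, so the exact 2-means split is biased toward balanced groups, and a
character whose true minority state occupies only a few species cannot be
recovered reliably by this construction (see the generator notes below).

The three-way strategy classes (A / B1 / B2) come from k-means (k = 3, best
of 100 seeded restarts) in the space of the first three phylogenetic-PC axes,
used unstandardized by default (a `standardize` switch exists). Cluster labels
are made deterministic by convention: A is the cluster containing the most
species whose four binary syndrome states are all ancestral; of the remaining
two, B1 has the higher mean sexual-dimorphism score.

## Mk models, ancestral states, and the correlated-evolution test

A discrete character with k states evolves along branches as a
continuous-time Markov chain with generator Q; the kernel over a branch of
length t is expm(Qt) (closed form for k = 2, eigendecomposition vectorized
over branches otherwise, per-branch `expm` as a fallback). The likelihood is
computed by the pruning algorithm with per-node rescaling; on strictly binary
trees the pass is vectorized over level-grouped node "waves". Missing or
ambiguous tips enter as all-ones (or arbitrary) partial-likelihood vectors.
Zero-length branches are legal (identity kernel).

Rates are estimated by bounded L-BFGS-B on log rates, constrained to
[1e-8, 100] per unit branch length, with multi-restart initialization
(default 10 restarts; the first start is 1/mean tip depth, the rest are
seeded log-uniform perturbations). Arbitrary tying and structural-zero
constraints are supported through an integer parameter map. The root prior is
uniform by default, with a stationary-distribution option; every fit records
which was used. Profile-likelihood 95% intervals re-maximize the remaining
free rates on a bisection grid.

Marginal ancestral states are exact: inside (upward) partials from pruning
are combined with outside (downward) partials so each node's distribution
conditions on all tips; every row of the reported table sums to 1.

The correlated-evolution test for two binary characters builds the 4-state
product chain over (x, y) with simultaneous double transitions forbidden. The
*independent* model has 4 free rates (each character's gain and loss shared
across the partner's state); the *dependent* model frees all 8 single-step
rates. The statistic is LRT = 2(lnL_dep − lnL_indep), referred to chi-square
with **df = 4** (8 − 4 free rates); this df reproduces published p-values for
all six worked likelihood pairs to at least six significant digits. The
dependent optimization always includes the independent optimum (duplicated
appropriately) among its starts, so nesting holds up to optimizer tolerance.
Calibration: under independent-model simulation (200 tips) the empirical
type-I error at α = 0.05 is close to nominal (pooled estimate ≈ 0.06 over
several hundred replicates — very mildly liberal, as expected of the
chi-square approximation at this sample size). Known
fragilities inherited from the method itself: characters with only a handful
of (especially irreversible) origins on one tree inflate the LRT (the
few-origins pseudoreplication problem), and misclassified tip states act as
measurement error with the same effect.

## Phylogenetically structured statistics

* **Abouheif proximity**: 1 / product of direct-descendant counts over the
  interior nodes on the tip-to-tip path (endpoints excluded, MRCA included);
  zero diagonal, entries in (0, 1]. The signal test is the Moran-style Cmean
  with row-normalized proximity; permutation p = (1 + #{null ≥ obs}) /
  (n_perm + 1), 999 permutations by default. The diagonal-corrected proximity
  variant is not implemented.
* **Phylogenetic PCA**: eigenanalysis of H = (1/n) Xᵀ((W + Wᵀ)/2)X on
  centered, population-scaled columns, W the row-normalized proximity.
  Symmetrizing W guarantees real eigenvalues. Positive eigenvalues flag
  global (clade-level) structure, negative ones local (tip-contrast)
  structure; on a star tree a single standardized trait has eigenvalue
  −1/(n − 1) exactly. Axes are reported up to sign with a net-positive
  loading convention.
* **Phylogenetic ANOVA**: the F statistic is the classical one-way value;
  its null distribution is built from trait simulations under Brownian
  motion on the tree (rate fitted by ML via the GLS quadratic form, 1000
  simulations by default, drawn through a Cholesky factor of rate × C with C
  the shared-path-length matrix), group labels held fixed;
  p = #{F_sim ≥ F_obs}/n_sim. On a star tree this converges to the
  parametric F test; for clade-confounded groups it is properly more
  conservative.
* **MPD null model**: mean pairwise patristic distance of a focal species
  set, compared with 1000 equal-size subsets drawn without replacement from
  the pool tree; the reported quantile is the proportion of null MPDs
  *strictly below* the observed value, so ties count against clustering.
  Low quantiles mean phylogenetic clustering; mid-range values mean the
  focal set is a representative sample.

## Synthetic data generator

No compiled trait table can be redistributed, so the generator produces
tables with the same statistical skeleton, and its defaults are the study
conditions for every test here:

* **Tree**: Yule, 81 species, birth rate 0.45 — root height ≈ 9 in rate
  units, the scale at which the per-syndrome transition rates used below
  yield derived-state fractions of roughly 25–45%, matching the group sizes
  such analyses report.
* **Binary syndrome states** (default, `independent` scenario): each
  syndrome evolves as its own 2-state chain from an ancestral root, with
  gain/loss rates (0.087, 0.097), (0.031, 0), (0.041, 0), (0.077, 0.033) —
  the magnitudes fitted for, respectively, ecological specialization, r–K
  gradient, sexual dimorphism and dispersal/social behaviour on comparable
  time-calibrated trees. A `strategy` scenario instead evolves a 3-state
  A/B1/B2 chain (rates A→B1 = 0.067, A→B2 = 0.027, B2→B1 = 0.014, reversals
  structurally zero) and maps strategies to syndrome-state profiles; a
  `dependent_pair` scenario plants one strongly correlated pair
  (x flips at 0.12; y's gain/loss rates swap between 0.5 and 0.05 with x's
  state) while the remaining syndromes evolve reversibly at (0.05, 0.02) so
  the non-planted pairs are calibrated nulls.
* **Balance floor**: state histories are redrawn until every syndrome's
  minority state covers ≥ 15% of species. This emulates the balanced splits
  real compiled tables show and keeps the two-group recovery problem
  well-posed (see the rank-score remark above).
* **Latent scores and traits**: the latent syndrome score is ±1.5 by state
  (offset 3.0) plus Brownian noise with tip standard deviation 0.5 — a
  separation large enough that the two-group split is essentially
  unambiguous, as it is when states are defined by the split itself. Each of
  the 53 traits is a signed loading (|b| ∈ [0.7, 1], one third negative)
  times its block's latent score plus Gaussian noise (sd 0.5); one third of
  traits are discretized at terciles to the qualitative codes {0, 0.5, 1};
  cells are deleted completely at random at rate 0.20 (an MNAR switch links
  missingness to trait index instead). Block sizes are 14/13/13/13.

What the generator does **not** emulate: literature-weighted multi-source
records per cell (each cell is a single draw), non-ultrametric trees or
calibration uncertainty, correlated missingness between related species,
and trait distributions with heavy tails or counts. Passing recovery tests
therefore demonstrates the pipeline's statistical machinery, not robustness
to every idiosyncrasy of real compiled data.

## Validation experiments and the scales used

`syndromevo.experiments` packages the self-checks; each is seeded and
returns its inputs' sizes. Scales were chosen to make each check sharp while
keeping a full run of the suite and the acceptance script within ordinary
desk time: 200 random 3–6 tip trees for the enumeration oracle (agreement to
1e-10); 50 replicates of 500-tip rate recovery (simulated at birth rate 0.3,
about four mixing times of the 0.09/0.10 chain, where both rates are
identifiable; at much shorter heights the loss rate is too weakly identified
for any estimator to meet a factor-1.5 contract); 200 replicates of 200-tip
type-I calibration; 1000 random vectors for the exact-split check; 500
replicates for MPD-quantile uniformity; and 20 pipeline seeds each for
syndrome-state recovery and the planted-pair positive control.

## Known limitations

* Pagel-test p-values rely on the chi-square approximation; for characters
  with very few transitions a simulation-based null would be preferable.
* The imputation donor search couples trait blocks (a donor is chosen on all
  co-observed traits), which can leak weak cross-syndrome correlation into
  downstream tests when missingness is high.
* pPCA eigenvector signs, and hence species-score signs, are conventional.
* Polytomies are accepted (likelihood falls back to the generic pruning
  loop) but k-means strategy labels and the balance floor assume the
  binary-tree simulators.
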