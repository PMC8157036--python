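# Methods

## Rate decomposition

Input is a genes × branches matrix of per-gene branch lengths
b_{g,j} ≥ 0 (substitutions/site), mapped onto a canonical branch indexing
of a rooted species tree (terminal branches are named by their leaf,
internal branches by a hash of their sorted descendant leaf set, so
identifiers do not depend on newick rotation).  The model is

    b_{g,j} = R_j · r_g · e_{g,j}

fitted additively on the log scale: log(b_{g,j} + ε) = μ + α_g + β_j + γ_{g,j}.
For complete matrices the least-squares solution is row/column means; for
incomplete matrices we iterate alternating row and column centering
(Gauss–Seidel on the normal equations) to a parameter change ≤ 1e-10,
capped at 500 sweeps.  The fitted values are the unique least-squares fit;
the split into gene and branch effects is identified by mean_g log r_g = 0
and mean_j log R_j = grand mean of log(b + ε).  For complete data this
leaves the interactions doubly centered (row and column means of log e are
zero); for incomplete data the interactions are the observed-cell
residuals under the same identification.

* **Pseudocount ε** (default 1e-9) keeps zero-length branches — common in
  gene trees — inside the log.  It is recorded in the output; analyses that
  need exact recovery of a noiseless simulation should lower it (the log
  distortion is ≈ ε / b).
* **Median polish** is available as a robust alternative; it is not the
  default because it does not satisfy the least-squares oracle property.
* Genes lacking any observed entry, or branches lacking any, are an error:
  their effects are undefined.

Features for regression are the log interactions arranged branches × genes.
Missing cells are filled before standardization — default `zero-log`
(log e = 0, "no deviation", unbiased under the centering constraint),
optionally the gene's observed mean.  Per-gene standardization constants
(mean, population sd) are computed on the *fitting* branches only and
applied to all branches, so internal branches are scored on the terminal
scale.  Genes with zero variance on the fitting subset cannot be
standardized and are dropped with a warning.

## Trait models

Continuous traits are fitted as natural-log response with squared-error
LASSO; binary traits with L1-penalized logistic regression (0/1 response,
hard calls at probability 0.5, probabilities always retained).  Branches
with a missing trait value are excluded from fitting and retain their
feature rows for later imputation.  The penalty is chosen by k-fold
cross-validation (default k = 10, shuffled folds with a required seed).
The default applies the **one-standard-error rule**: the strongest penalty
whose mean CV error is within one standard error of the minimum.  We chose
this over the raw CV minimum because the minimum-MSE rule routinely admits
dozens of spurious genes when no real signal exists, while on signal-bearing
data the two rules select nearly identical causal sets and indistinguishable
predictive accuracy; a sparse, stable predictor-gene list is the scientific
product here.  `CVConfig(one_se=False)` restores the plain minimum.

Coefficients are reported on the standardized-feature scale (unitless);
`selected_genes` returns the non-zero ones ordered by |coefficient| with
ties broken by gene id.  Predictions at any branch are
exp(intercept + x·β) for continuous traits (hence always positive) and the
logistic probability for binary traits.  No post-selection inference is
attempted: with p ≫ n and CV-chosen penalties, naive p-values on selected
coefficients would be meaningless.

## Trait network

All traits enter numerically: continuous traits as natural logs, binary
traits as 0/1.  Pairwise Pearson correlations use pairwise-complete rows;
partial correlations use complete cases across the selected traits and the
inverse-correlation formula ρ_{ij·rest} = −P_ij / √(P_ii P_jj).  A
condition number above 1e12 is treated as singular and reported as an
error naming the remedy (drop collinear traits).

The dependence graph is selected by BIC over Gaussian graphical models:
adding edge (i, j) to the empty model improves BIC by
w_ij = −n·log(1 − r_ij²) − log n (one extra parameter), and the
minimum-BIC model within the forest class is the maximum-weight spanning
forest over positive-weight edges (Kruskal, ties broken by the
lexicographic trait-name pair, so the result is independent of input
order).  Restricting to forests keeps the model decomposable and matches
the sparse networks this analysis is meant to produce; general decomposable
model search is out of scope.  Predicted-ancestral rows participate as
ordinary rows — this mirrors the analysis the package reimplements and
reduces phylogenetic pseudo-replication only in the heuristic sense claimed
there; no independent-contrasts correction is applied, and users should
treat edge strengths accordingly.  Treating binary traits as 0/1 in a
Gaussian model is a documented approximation; recoding a binary trait flips
signs but not magnitudes.

## Correlated evolution of binary trait pairs

A joint 4-state CTMC over (00, 01, 10, 11) with the four dual-transition
entries fixed to zero.  The independent model has 4 rates (each trait's
gain and loss, blind to the other trait); the dependent model gives each of
the 8 allowed transitions its own rate.  Rates are events per Myr; the
tree must be time-calibrated.  Likelihood is Felsenstein pruning with
per-branch transition matrices expm(Q·t), computed for all branches at
once by eigendecomposition (falling back to scaling-and-squaring `expm`
when the eigenvector matrix is ill-conditioned, and pinning zero-duration
branches to the exact identity so impossible configurations yield
likelihood exactly zero).  Tips with missing states are marginalized
(all-ones partial likelihood), which equals pruning them from the tree.
The root is averaged over a uniform distribution by default (a
stationary-distribution option is provided); rates this small leave deep
trees insensitive to the choice.

ML estimation runs L-BFGS-B on log rates from multi-start points drawn
log-uniformly in [1e-3, 10] events/Myr.  The dependent-vs-independent
comparison is a likelihood-ratio test against χ²(df = 4).  The MCMC option
is a fixed-dimension Metropolis–Hastings sampler: independent Exponential
priors on the rates (mean 1 by default), per-rate log-normal random-walk
proposals, and proposal scales adapted toward ~30 % acceptance during
burn-in only, so the post-burn-in kernel is fixed and the whole chain is
reproducible from its seed.  We deliberately use fixed-dimension MCMC
rather than a reversible-jump sampler over rate groupings: the scientific
question — which transitions are asymmetric — is answerable from the
8-rate model directly, and trans-dimensional moves add tuning burden
without changing that answer.  Harmonic-mean marginal likelihoods are
deliberately not offered (they are notoriously unstable); model comparison
goes through the LRT.  Output headers label all priors and chain defaults
as package choices.

## Synthetic data

The generators emulate a mammal-scale comparative dataset and are the
package's test bed:

* **Trees**: birth–death simulation conditioned on the number of extant
  tips (dendropy), rescaled to a target depth; the "paper-like" preset is
  89 taxa, 1204 genes, depth 180 Myr; the "test" preset is 20 taxa, 60
  genes, depth 100 Myr.
* **Continuous traits**: Brownian motion of the log trait along the tree
  (default σ² = 0.03 per Myr, roughly the cross-species spread of log life
  history traits over a 180-Myr tree).  The branch-level value is the
  Brownian path at the branch's temporal midpoint (trait values belong to
  branches here, not nodes), so the tip variance is σ²·(depth − t/2) for a
  terminal branch of length t.
* **Interactions**: log e_{g,j} = γ_g·z̃_j + N(0, σ_e²) for causal genes
  (z̃ the standardized latent trait, effect magnitudes uniform in
  [0.3, 0.8] with random sign, σ_e = 0.3 ≈ 30 % rate fluctuation),
  pure noise otherwise, then double-centered to satisfy the
  decomposition's identification exactly.  Branch and gene effects are
  log-normal (branch effects around 0.02 substitutions/site).
* **Binary pairs**: exact Gillespie simulation of the 4-state chain down
  the tree, so recorded event lists can never contain dual transitions.
* **Trait tables**: tree-structured Gaussian samples for a declared forest
  of edge correlations; binary columns are median-thresholded.

Everything is reproducible bit-for-bit from (config, seed); numpy's PCG64
drives all draws except the tree shape, which uses a seeded
`random.Random` through dendropy.

What the generators do *not* emulate: heavy-tailed interaction noise (a
Student-t option exists for sensitivity checks), gene-tree estimation
error and topology conflicts, correlated noise between genes, and
measurement error in tip traits.  Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated generative model,
not robustness to every pathology of real comparative data.

## Simulation conditions behind the reported numbers

Problem sizes were chosen to exercise study-scale structure while keeping
a full run to minutes on one CPU:

* decomposition exactness: 40-taxon trees, 100 genes, complete and
  25 %-missing matrices;
* pruning oracle: 4-taxon trees (3 internal nodes, 4³ enumerable
  assignments), random rates in [0.05, 2] /Myr;
* LRT calibration and power: 200-taxon, 180-Myr trees at base rate
  0.05 /Myr — about nine expected transitions per lineage and trait, the
  regime where the χ²(4) reference is well calibrated (at much shallower
  depths the statistic is visibly inflated); power uses q(01→11) scaled
  5×; rate recovery uses 500-taxon, 100-Myr trees at 1 event/Myr and is
  summarized by the geometric mean of the four estimated rates;
* LASSO recovery: 100 taxa, 300 genes, 20 causal at signal-to-noise 2
  (γ = 0.6, σ_e = 0.3); the null uses the same sizes with no causal genes;
* network: residual-regression oracle at n = 400, chain recovery at
  n = 1000.

## Numerical notes and edge cases

* Empty gene/branch rows, unrooted trees, duplicate taxa, negative rates,
  non-normalized root distributions, zero MCMC iterations, and unknown
  config keys are hard errors with actionable messages.
* Constant responses yield an intercept-only model with a warning rather
  than an error; class imbalance beyond 9:1 warns.
* Fewer usable branches than CV folds reduces the fold count with a
  warning (never below 2).
* LASSO active sets are not strictly nested along the penalty path; the
  sparsity-vs-penalty property is asserted as an overall trend, not
  pointwise monotonicity.
* The two-way fit is identified only up to a constant; oracle comparisons
  are made on centered fitted values, and the exported effects follow the
  identification above.

## Known limitations

* No phylogenetic GLS / independent-contrasts correction in the trait
  regression or the network — by design, to mirror the reimplemented
  analysis; correlations computed over tips plus predicted ancestors are
  not formally independent samples.
* The gene–branch mapping for genes with missing taxa assigns a gene-tree
  branch to the lowest matching species branch and leaves the rest of the
  collapsed path missing; no length-splitting rule is attempted.
* Forest-structured networks cannot represent cycles of genuine partial
  dependence; edges absent from the forest are not evidence of
  conditional independence.
* The coevolution model covers exactly two binary traits; multi-state or
  hidden-rate extensions are out of scope.
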