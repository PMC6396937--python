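# coac

Localized gene co-expression subnetwork inference from single-cell
RNA-seq, with per-cell and per-sample subnetwork scoring.

Single-cell expression matrices are sparse (60–95% zeros from dropout)
and heterogeneous: a gene module may be tightly co-expressed inside one
cell subpopulation and silent everywhere else, so whole-matrix
correlation analysis washes it out. `coac` finds such **localized
co-expression subnetworks** by combining matrix factorization with closed
frequent-pattern mining, then turns each subnetwork into a scalar
feature that scores any cell — or any bulk RNA-seq sample — for how
coordinately it expresses that subnetwork. The features support
cell-type separation, case/control feature selection, survival-style
sample stratification, and drug-response labelling for downstream
regression.

## Method

Given a cells × genes matrix *A* (log(TPM+1)), the workflow is:

1. **Factorization.** Truncated SVD, *A = UΣVᵀ*. Each gene profile is a
   weighted sum of components *P_j = U[:, j]*: *A[:, i] = Σ_j w_ij P_j*
   with *w_ij = σ_j V(i, j)*. A robust rank *r* (permutation null,
   cumulative-energy, or spectral-gap rule) picks the retained
   components.
2. **Projection and ternarization.** The normalized loading
   *D(i, j) = w_ij / ‖A[:, i]‖ ∈ [−1, 1]* measures how much component
   *j* organizes gene *i*. Per component, the collection {*D(i, j)*} has
   mean *m* and variance *s²*; a gene is an outlier when
   *(x − m)²/s²* exceeds the (1 − α) quantile of *F(1, N−1)*
   (α ∈ [0.01, 0.05]). Outliers are coded +1 (Gain) above
   *m + √(s²·F_crit)*, −1 (Loss) below *m − √(s²·F_crit)*, else 0.
3. **Closed association rules.** On the presence matrix (|ternary|),
   each rule pairs a gene collection with the *full* set of components
   marking every one of those genes (the Cartesian product is all-ones);
   only closed rules survive — no gene can be added without shrinking
   the component set, and among rules with the same components only the
   maximal gene set is kept. Enumeration is LCM-style and exact.
4. **Subnetworks and filters.** A rule's genes form a co-expression
   graph (edges where |Pearson r| of their profiles passes a threshold);
   the subnetwork is its largest connected component. Two filter
   metrics: *average correlation* — mean pairwise correlation of the
   genes' reconstructions restricted to the rule's components — and
   *average component ratio* — mean fraction Σ_{j∈rule} w_ij² / Σ_j w_ij²
   of component-space energy the rule captures.
5. **Features.** Each subnetwork is represented by the leading
   eigenvectors *F_t* (eigenvalues σ_1 ≥ σ_2 ≥ …) of its gene–gene
   correlation matrix. A cell or sample with expression *S* over the
   subnetwork genes scores
   *feature = Σ_t (σ_t/σ_1) · S·F_t / ‖S‖₂* — scale-invariant, so the
   same score applies to single cells and bulk profiles. Features are
   selected by F-score (one-way ANOVA F by default, threshold 2.4) or
   ranked by group differences of means and variances; samples are
   stratified into top-*k*/bottom-*k* groups (default 32), and IC50
   values above 10 μM label drug-resistant lines.

A first-class synthetic generator plants modules with known gene sets,
active-cell fractions, within-module correlation, and expression-level
dropout, so the whole chain is testable without external data.

## Worked example

`examples/simulate_and_recover.py` plants three 20-gene modules, each
co-expressed (ρ = 0.8) in a 30% cell subpopulation of a 500-cell ×
200-gene matrix with 60% dropout, and mines them back:

```
simulated 500 cells x 200 genes, 60% zeros
mined 76 filtered subnetworks (rank 30 factorization)
module 0 (20 genes): best Jaccard = 1.00
module 1 (20 genes): best Jaccard = 1.00
module 2 (20 genes): best Jaccard = 1.00
```

A Jaccard of 1.00 means some filtered subnetwork's gene set equals the
planted module exactly. `examples/score_features.py` abolishes one
module's co-expression in a case group and scores every subnetwork
feature on case/control labels:

```
188 subnetwork features scored on control vs case labels
top feature overlap with the perturbed module: Jaccard 1.00
top F-score = 145.4 (matched feature F = 145.4, threshold 2.4)
```

The perturbed module's feature ranks first by a wide margin over intact
modules (null features sit near F ≈ 1). See also
`examples/mine_subnetworks.py` (the ternary matrix and closed rules on a
small input) and `examples/stratify_bulk.py` (bulk-sample scoring,
top/bottom stratification and IC50 labelling).

## Command line

A thin CLI wraps the library: `coac simulate`, `coac decompose`,
`coac run` (full pipeline with a JSON config and reproducible manifest),
`coac select`, `coac stratify`. Run `coac --help` for options.

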