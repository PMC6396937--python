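# Methods

This note records the model, the numerical choices, and the design
decisions behind `coac`, in the order the pipeline runs.

## Factorization and robust rank

The expression matrix is held cells × genes; all math is stated in that
frame (components are directions in cell space, genes project onto
them). The SVD is computed dense (LAPACK) for dense input or when
centering is requested, and with ARPACK (`svds`, deterministic start
vector from the seed) for large sparse matrices.

Centering is off by default: zeros are the dominant feature of
single-cell data and the uncentered factorization preserves them. It
matters, though, that the uncentered spectrum is led by a large
all-positive "mean" component, and every other component's loading
collection is shifted by its interaction with that mean. In regimes
where strong localized modules coexist (such as the synthetic
benchmark), that shift pushes unrelated strong genes past the *Loss*
threshold of other components and glues foreign genes into their rules —
so the benchmark analyses set `center=True`, which removes the mean
component and leaves module spikes clean. Both paths are exposed;
`Decomposition.col_norms` records the gene norms of the matrix actually
factored so projections stay consistent.

Three robust-rank rules are provided because the exact published
definition is not available to us:

* **permutation** (default, n_perm = 10): each gene column is shuffled
  and the observed spectrum is compared with the shuffled one. The
  shuffle for a column is seeded from the master seed, the permutation
  index and a hash of the column's *sorted* values, which makes the
  whole estimate invariant to row and column permutations of the input
  (duplicate columns collide on the same shuffle; with continuous data
  this is immaterial). Two comparisons are offered: `max` counts
  singular values above the largest shuffled singular value — note that
  shuffling preserves column norms and the shared positive mean, so for
  nonnegative data this floor sits at the level of the leading
  component and the variant is deliberately conservative (rarely r > 1);
  `per_rank` is standard parallel analysis (longest prefix with
  σ_j above the j-th shuffled value) and is the variant that can
  certify multi-component structure.
* **energy**: smallest r with Σ_{j≤r} σ_j² ≥ 0.9 of the total (fraction
  configurable).
* **elbow**: largest relative gap in the spectrum.

## Ternarization

Thresholds are solved in closed form, x = m ± √(s²·F_crit(1−α; 1, N−1)),
rather than scanning elements; s² is the sample variance (ddof = 1) of
the loading collection, N counts non-degenerate genes only
(zero-expression genes are excluded from the collection and from N, and
get all-zero loading rows). Ties at a threshold map to 0 — the
inequalities are strict. Components whose loading collection is
numerically constant (variance ≤ 1e−24; loadings are bounded by 1) are
flagged inert and never mark a gene. A Gaussian null collection at
α = 0.05 is marked at 0.050 ± 0.01 (checked at N = 2000 over 100
components), confirming the calibration.

α is restricted to [0.01, 0.05] by default (`strict_alpha_bounds`
lifts the restriction deliberately).

## Mining

Mining runs on the presence matrix (Gain and Loss collapsed to 1), with
the per-pair signs retained in each rule's `sign_profile` for reporting.
Enumeration is an LCM-style prefix-preserving closure extension over
component-set bitmasks; a brute-force enumeration over all gene subsets
defines correctness and the two are set-identical on randomized inputs
(50 seeds in the acceptance checks). Output order is deterministic
(gene-set size descending, then lexicographic).

The subnetwork graph connects rule genes whose **full expression
profiles** correlate with |r| ≥ `edge_threshold`; the subnetwork is the
largest connected component (ties broken toward the component containing
the lexicographically smallest gene). An alternative edge source — the
correlations of the component-restricted reconstructions — is available,
but for a single-component rule those reconstructions are all collinear,
every pair correlates at ±1, and the largest-connected-component step
degenerates to the whole rule; the full-profile graph is therefore the
default. The restricted correlations are still what the *average
correlation* metric reports, since that metric is defined as homogeneity
*given* the rule's components. The *component ratio* denominator runs
over all k computed components.

Defaults: min_genes = 2, min_components = 1, edge_threshold = 0.5,
filter thresholds 0.5/0.5 with an optional top-fraction cut by average
correlation. The benchmark uses edge_threshold = 0.15 and
min_avg_comp_ratio = 0.1: with 60% dropout both genes of a pair must
survive for an entry to co-vary, which attenuates a planted
within-module correlation of 0.8 to roughly 0.2 in observable profiles,
and with k = 30 retained components a module's one or two own components
carry a minority share of each gene's squared norm (0.1 is still well
above the 1/k ≈ 0.03 uniform baseline).

## Features and selection

Subnetwork eigensystems come from the Pearson correlation matrix of the
giant-component genes' full training profiles. Eigenvector signs are
fixed by making each vector's largest-magnitude loading positive.
`v="auto"` keeps all eigenvalues ≥ 1 (Kaiser-style, at least one); the
attenuation coefficients σ_t/σ_1 weight the per-eigenvector cosines.
A zero expression vector scores 0 by convention and is the only
degenerate input.

The F-score has three forms. The default is the classic one-way ANOVA F
(between-group mean square over within-group mean square): it is
F(1, n−2)-distributed under the null, so a fixed critical point (2.4 by
default) is meaningful regardless of scale. The bounded form
(between-group variance over merged population variance, `mode="ratio"`)
is retained, but note it cannot exceed 1 by the law of total variance —
a 2.4 threshold under that form would select nothing, which is why it is
not the default. `mode="var_diff"` (|var₁ − var₂| over merged variance)
captures pure dispersion changes. All forms are shift- and
scale-invariant.

Group-difference ranking combines the rank of |Δmean| and the rank of
|Δvariance| by rank product (rank sum available). Stratification sorts
by value with ties broken by sample id, making the top-k/bottom-k groups
reproducible. IC50 labelling is strict: exactly 10 μM is sensitive.

## Synthetic data

The generator emulates a droplet scRNA-seq matrix as the pipeline sees
it: values are exp(mean_log + noise_sd·z) — log-normal with a wide
dynamic range (mean_log = −2, noise_sd = 1, i.e. most background entries
sub-TPM), an optional rank-1 global nuisance factor (strength 0.1), K
planted modules, and dropout.

Each module has a gene count, an active-cell fraction, a target
within-module Pearson correlation ρ, and an **activation**: a log-scale
up-shift (defaults 3.5/4.0/4.5 across the three default modules) of the
module genes in their active cells. The activation is what localizes
the module — a cell-type program's genes are expressed where the program
runs and near-silent elsewhere — and it is deliberately heterogeneous
across modules: identical program strengths would make the three
factorization spikes exactly degenerate, and degenerate eigenvectors mix
arbitrarily in any spectral method, which would test numerical
coincidence rather than the algorithm. The activation does not enter
the within-active-cell correlation (it is constant there): correlation
is planted by a shared factor per active cell on the log layer, with the
latent correlation solved in closed form from the log-normal identity so
the *value-scale* correlation among active cells hits ρ (realized within
±0.1 at the default sizes).

Dropout is Bernoulli per entry with probability logistic in log
expression (steepness 1; intercept calibrated by bisection so the mean
dropout probability equals `dropout_rate`; steepness 0 recovers uniform
dropout). Expression-dependent dropout is the standard model for
droplet data, and it matters here: with uniform dropout the zero
pattern is pure noise, and since the feature score normalizes ‖S‖ away,
a co-expression perturbation would be nearly invisible in the features.

The two-group generator draws matched control and case groups and, in
the case group, shuffles the designated module's latent values
*independently per gene* across its active cells — a single shared
shuffle would preserve within-cell co-expression and abolish nothing.
Marginals are exactly preserved; only the co-fluctuation is destroyed.

What the generator does **not** model: library-size variation beyond the
global factor, batch effects, expression-dependent noise families
(negative binomial counts), doublets, or gene-gene correlation outside
planted modules. Passing the benchmarks therefore demonstrates the
machinery under the stated localization premise, not performance on any
particular real dataset.

## Benchmark problem sizes

The recovery benchmark uses 500 cells × 200 genes, three disjoint
20-gene modules (ρ = 0.8, 30% active cells, 60% dropout), five seeds;
the discrimination benchmark replaces the middle module with a globally
active program (active fraction 1.0, activation 2.0) and perturbs it —
with a 30%-active target, both groups share ~70% identical background
cells and no feature of any kind can separate the labels; perturbing a
global program is the regime where co-expression loss is visible in
every cell. Subnetworks are always mined from the control cells only
and all cells are scored. These sizes keep each experiment in the
seconds range while leaving the module-detection problem genuinely hard
(the modules sit close to the spiked-matrix detection edge at these
dropout levels).

## Pipeline

`run_pipeline` executes load → transform → decompose → ternarize → mine
→ filter → featurize, writes every intermediate as text (MTX, TSV,
JSON-lines), and records a manifest with SHA-256 checksums per stage;
reruns with the same config and seed are byte-identical. A stage
failure aborts with the stage name and keeps completed artifacts.
Config round-trips through JSON and rejects unknown keys and
out-of-range constants before any stage runs.
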