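# Methods

## The model

`mcia` integrates K nonnegative feature-by-sample tables **M**₁, …, **M**_K
that share their samples (cell lines, patients) but not their features (probes,
genes, proteins).  Each table is first turned into a *statistical triplet*
(**X**_k, **Q**_k, **D**) by non-symmetric correspondence analysis (NSC): with
marginals r_i = m_{i+}/m_{++}, c_j = m_{+j}/m_{++} and cell proportions
p_{ij} = m_{ij}/m_{++}, the centered row profile is

    x_ij = p_ij / r_i − c_j ,

with samples as rows.  Rows of **X** sum to zero exactly and columns are
centered under the row weights; the whole construction is invariant to a
global rescaling of **M**, so tables on different measurement scales become
comparable.  **Q**_k is a diagonal metric on features, **D** a diagonal weight
on samples shared by all tables.

Multiple co-inertia analysis (MCIA) then finds, order by order, a synthetic
sample-space axis **v** (the *reference structure*) and per-table auxiliary
feature-space axes **u**_k maximizing

    f(u₁, …, u_K, v) = Σ_k ω_k · cov²(X_k Q_k u_k, v) ,
    cov(a, b) = aᵀ D b,   vᵀ D v = 1,   u_kᵀ Q_k u_k = 1 .

The optimum **v** is the dominant eigenvector of
S = Σ_k ω_k X_k Q_k X_kᵀ D and **u**_k = X_kᵀ D v / ‖X_kᵀ D v‖_{Q_k}.
Table k's sample scores are X_k Q_k u_k; its *pseudo-eigenvalue*
ω_k·cov²(X_k Q_k u_k, v) measures how much that platform drives the axis and
sums over tables to the global eigenvalue λ_h exactly (this identity is
re-verified at 1e−8 in the tests and reported by the acceptance script).

### Deflation and orthogonality

After each order every table is deflated by the Q-orthogonal projection of its
sample rows onto the complement of the extracted axis:

    X_k ← X_k − (X_k Q_k u_k) u_kᵀ        (u_k Q-normalized).

This is the metric-folded SVD deflation (D^{1/2} X Q^{1/2} (I − ũũᵀ) in
Euclidean coordinates).  It annihilates the extracted score direction
(X_k Q_k u_k = 0 afterwards), is idempotent, drops the numeric rank by exactly
one, and by induction forces u_kʲᵀ Q_k u_kˢ = 0 across orders.  Synthetic axes
are automatically D-orthogonal because each previous **v** lies in the kernel
of the deflated operator.  A table whose profile rank is exhausted before the
requested number of axes contributes zero auxiliary axes and zero scores for
the remaining orders.

### Eigen-solution strategy

The shared dimension n (samples) is small in omics, so S is formed explicitly
as an n×n matrix and solved with a dense symmetric eigendecomposition of the
similarity transform D^{1/2} S D^{−1/2} at every order.  No iterative or
randomized solver is involved; together with a fixed sign rule (the
largest-magnitude entry of **v** is made positive, with all u_k and scores
flipping consistently) the whole pipeline is bit-reproducible.

## Parameters and conventions

| parameter | default | meaning / rationale |
|---|---|---|
| `n_axes` (H) | min(10, n−1) | number of extracted orders; hard-bounded by n−1 |
| `weighting_scheme` ω_k | `uniform` | table weights in the criterion; `inverse_first_eigenvalue` (ω_k = 1/λ1_k) equalizes each table's leading inertia and is the right choice when one platform's variance scale would otherwise dominate the reference structure |
| `metric_convention` **Q**_k | `col_weights` (diag c_j) | feature metric; `identity` gives the classical unweighted NSC metric.  The underlying convention is genuinely ambiguous in the duality-diagram literature, so both are implemented and the choice is recorded in every result |
| `sample_weight_convention` **D** | `uniform` (1/n·I) | `identity` (I) differs only by a global eigenvalue factor n; uniform weights keep eigenvalues comparable across sample sizes — axes, scores and variance proportions are unchanged |
| `eig_tol` | 1e−10 | threshold below which an eigenvalue counts as "no variance left" |

Variance-explained proportions divide each λ_h by the sum of the **full**
spectrum of the first-order operator (computed once, independent of H), so
they do not depend on how many axes were extracted.

The RV coefficient between two analyzed configurations is
trace(W_a W_b)/√(trace(W_a²)·trace(W_b²)) with W_t = X_t Q_t X_tᵀ D — the
matrix generalization of a squared Pearson correlation, in [0, 1].  It is
computed on the triplet metrics, not the raw matrices, so it measures
co-structure of the configurations as analyzed.

### Per-sample divergence and projection plots

Each sample has one point per table plus a common reference point; the segment
length measures cross-platform discordance for that sample.  Two variants:

* **normalized** (default): table score columns scaled to unit D-norm,
  reference = the unit synthetic axis **v**.  Identical tables give exactly
  zero divergence; the statistic is scale-free.
* **raw**: untouched table scores against **v**·√λ_h (the reference moved to
  the score scale).  Homogeneous of degree one in the score scale.

The projection plot uses the same convention and always writes its plotted
coordinates as TSV next to the image; the figure content is therefore
numerically testable.  Note that only the raw coordinates coincide with the
stored `table_scores` columns.

### Feature selection and consensus

A feature's coordinate on axis h is its covariance with the synthetic axis,
(X_kᵀ D v^h)_j, computed under the sequential (deflated) construction — it is
proportional to its auxiliary-axis entry with a positive per-(table, axis)
factor, so rankings coincide with **u**_k while staying comparable across
tables; an optional flag rescales by √λ_h.  `top_features` takes the n most
positive and n most negative coordinates per (table, axis); zero scores belong
to neither end and ties break lexicographically on feature id.  A *consensus
call* is a feature selected at the same axis end in at least `min_tables`
tables; output is ordered by (axis, end — positive first, descending support,
feature id).

Scores for axis h are computed from the (h−1)-times deflated matrix, matching
the sequential construction; they differ from projecting the original X_k onto
all axes at once whenever a table's axes are not exactly Q-orthogonal in its
column space.

## The synthetic generator

`generate_bundle` emulates the regime the method targets: K nonnegative
tables, same samples, private feature sets, a shared sample-level group
structure.  Samples are assigned to `n_clusters` groups round-robin
(deterministic, balanced).  Per table, feature baselines are lognormal(1,
0.25), measurement noise lognormal(0, `noise_sd` = 0.5), and a disjoint
`informative_fraction` = 10% of features per cluster is multiplied by
`effect_size` = 3 in that cluster's samples (fold-change semantics).  The
modest baseline spread reflects that triplets are built from
post-normalization (log-scale) intensities whose feature-to-feature dynamic
range is compressed; a heavy-tailed baseline would let a handful of
high-abundance features monopolize the NSC inertia, which is outside the
method's intended regime — with no planted effect the leading spectral gap
stays below λ1/λ2 = 3 across seeds under these settings.

What the generator does **not** emulate: platform-specific probe effects,
count distributions and library-size biases of sequencing assays, batch
structure, partially overlapping feature spaces, or missingness mechanisms
other than completely-at-random (`inject_missingness` is i.i.d. Bernoulli).
Passing recovery tests therefore demonstrates correctness of the algorithm
under clean planted structure, not robustness to those real-data artifacts.

Reference conditions used by the tests and the acceptance script: 30 samples,
3 tables of 200/150/300 features, 3 clusters, effect size 3, noise sd 0.5.
Random-instance oracle checks use n ≤ 12 samples, q_k ≤ 20 features, K ≤ 4
tables — sizes at which dense brute-force eigendecomposition is exact and
instant.

## Numerical choices and degenerate inputs

* Duplicate feature ids collapse to the row with the highest mean over
  non-missing entries; exact ties keep the first-occurring row.
* Zero-total features carry no inertia and are dropped with a warning listing
  them; a zero-total sample is a hard error naming the sample.
* Negative values are a hard error pointing to the explicit
  `shift_to_nonnegative` step; the shift is never applied silently.
* Near-degenerate eigenvalues: the solver's ordering is accepted; axes within
  a numerically degenerate eigenspace are arbitrary up to rotation.
* A requested axis beyond the pooled rank raises a rank error rather than
  returning noise axes.
* All TSV output uses 12 significant digits and round-trips within 1e−12.

## Known limitations

* Only the NSC triplet is implemented; PCA- or COA-based single-table
  transforms, and the RGCCA/SGCCA/CPCA criteria, are out of scope.
* Missing data must be resolved upstream (filter + impute); the decomposition
  itself is not missingness-aware.
* Identifier harmonization across platforms (probe-to-symbol mapping) is
  assumed done; consensus calls match feature ids verbatim.
* No significance testing (e.g. permutation p-values for RV) is provided.
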