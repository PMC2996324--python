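# Methods

## Model

A directed (possibly cyclic) regulatory network over `p` expression
phenotypes with `q` genotyped perturbations is parametrized as a completely
observed linear Gaussian SEM: `y = By + Wx + e`, `e ~ N(0, Σ)` with `Σ`
diagonal and `diag(B) = 0`. The zero diagonal is an identifiability
constraint — a self-loop is confounded with the error variance of the same
gene — and the diagonal error covariance is the standard assumption of
graphical network inference. `I − B` must be invertible so the system has a
proper stationary joint distribution; for cyclic `B` the simulator
additionally enforces a spectral radius below 0.95, a stricter margin that
keeps implied covariances well conditioned.

Genotypes are treated as exogenous with covariance `R` purely for algebraic
convenience: dosages of an F2 intercross are discrete (1:2:1 over
{0, 1, 2}), not Gaussian, but only the *support* of the joint precision
matters for structure recovery, and that support is a function of `(B, W,
Σ, R)` alone. The default `R` is the unlinked F2 dosage covariance
`0.5·I`.

The joint precision factorizes as `Ω = B̃ᵀB̃` with the block
upper-triangular model matrix `B̃ = [[Λ^{1/2}(I−B), −Λ^{1/2}W], [0,
R^{−1/2}]]`. This identity is verified to 1e−10 on random models as a
standing test. Nonzeros of `Ω` are the moral graph: phenotype pairs that
regulate each other or share a child, each locus with its cis gene and with
every phenotype parent of that gene. The latter — induced dependencies —
carry the directionality signal: an edge between locus `k` and a phenotype
`i ≠ g(k)` can only mean `i → g(k)`.

### Equivalence

Two parametrizations are distribution-equivalent iff their model matrices
differ by an orthonormal left factor. With a unique cis perturbation per
phenotype, the only admissible factors are signed permutations of phenotype
rows whose nontrivial orbits trace directed cycles of `B`. Hence DAGs are
uniquely identified, and cyclic models are identified up to reversals of
directed cycles, each reversal also permuting the eQTL-to-gene assignment
along the cycle. `reverse_cycle` implements the construction explicitly
(row permutation, sign renormalization to a positive diagonal,
re-extraction of `B`, `W`, `Σ`); preservation of the implied covariance and
of the data log-likelihood is asserted to 1e−8, and the evaluation module
enumerates equivalence classes by closing the set of simple-cycle reversals
under breadth-first search. When the perturbation topology (which locus
feeds which gene) is *known* — as it is once the cis screen has assigned
loci to genes — the class collapses to a single model, which is why the
recovery step returns one directed network rather than a class.

The likelihood is the joint Gaussian log-density of the centered data under
`Ω`, computed as `(n/2)(log|Ω| − tr(SΩ) − (p+q)log 2π)` with `S` the
empirical covariance using denominator `n` (so the expression equals the
exact sum of per-row log-densities, which the tests check against a direct
density evaluation).

## Synthetic data

The generator reproduces the benchmark regime the method targets: small
networks with strong, independent cis perturbations.

- **Topology.** DAG mode draws a random node order and includes each
  unordered pair with probability `d/(p−1)` oriented consistently with the
  order; DCG mode includes each *ordered* pair with probability
  `d/(2(p−1))`. Both give expected total degree `d` per node (1, 2 or 3 in
  the study classes).
- **Effects.** Nonzero entries of `B` have magnitude `Uniform(0.4, 1.0)`
  and random sign; each gene's cis effect is constant (1.0) and error
  variance 0.25. These numeric defaults are this package's choices of a
  strong-signal regime (effect magnitudes comfortably above the noise
  floor at the benchmark sample sizes); they are exposed in
  `SimulationConfig`, and a randomized-parameter mode draws variances and
  cis effects per gene instead, which measurably lowers power.
- **Faithfulness.** Exact parameter cancellations in `Ω` are measure-zero
  under continuous effect distributions; a sampled parametrization whose
  population precision support disagrees with combinatorial moralization is
  nevertheless rejected and redrawn (a numerical near-cancellation guard).
- **Genotypes.** F2 dosages, iid 1:2:1 per marker in unlinked mode; in
  linked mode each of the two gametes per individual is a two-state Markov
  chain along the chromosome with switch probability `r` (the recombination
  fraction), giving adjacent-marker dosage correlation `1 − 2r`.
- **Trans contamination.** A configurable fraction of loci receive one
  extra trans target of cis-scale effect, exercising the permutation
  filter; the benchmark classes themselves have none, and the replicate
  harness accordingly skips the filter when `trans_fraction = 0`.

What the generator does *not* emulate: unobserved confounders, non-linear
or non-Gaussian regulation, measurement-specific noise structure,
pleiotropic cis variants, or realistic LD beyond a single per-chromosome
recombination fraction. Passing tests therefore demonstrate correctness of
the machinery and finite-sample behavior under the model's own
assumptions, not robustness to their violation on real data.

## Estimation choices

- **Screen.** The cis window is `[start − window_bp, start + window_bp]`
  (1-based inclusive) around the gene start; the best marker per gene is
  kept, with ties broken by distance to the start and then marker index.
  The Bonferroni denominator is the total test count across genes
  (conservative); BH and permutation corrections are options. LD pruning is
  greedy in ascending p-value order under a pairwise `r² ≤ r2_max`
  constraint, default 0.01.
- **Neighborhood regressions.** All columns standardized to mean 0,
  variance 1 so penalties act evenly. Stage 1 is a plain lasso over all
  other columns; stage 2 re-solves with penalties `λ₂/|β̂_j|` (adaptive
  weight exponent 1, the canonical choice), realized by rescaling active
  columns — predictors zeroed in stage 1 are excluded outright (the
  infinite-weight limit). Each stage's penalty minimizes 5-fold
  cross-validated mean-squared prediction error over a log-spaced grid
  (coordinate descent, tolerance 1e−7, up to 1e5 passes); fold assignment
  seeds are recorded in every fit. A `joint_cv` flag instead scores the
  stage-2 grid by refitting both stages within each fold, for the protocol
  reading in which one error is minimized across both steps; both variants
  give closely similar graphs.
- **Symmetrization.** Phenotype–phenotype edges use the AND rule by default
  (edge only if each gene's regression selects the other), the conservative
  choice favoring a low false-discovery rate; OR is exposed. Locus–
  phenotype edges come from a single regression (responses are phenotypes
  only, so locus–locus edges are never estimated).
- **Directed read-off.** Each induced edge `(k, i)`, `i ≠ g(k)`, yields
  `i → g(k)` with effect equal to the stage-2 coefficient of `i` in
  `g(k)`'s regression — the coefficient that estimates the regulatory
  effect `B[g(k), i]` up to standardization (the locus coefficient
  estimates the perturbation effect instead). By default a directed edge is
  emitted only when the graph also contains the corroborating phenotype
  edge `(i, g(k))`: the moral graph of any model containing `i → g(k)`
  necessarily has that edge, so an induced edge without it is inconsistent
  with every directed interpretation. Empirically nearly all such orphans
  are selection noise, and requiring corroboration cuts the directed FDR by
  roughly a factor of three at the benchmark conditions without costing
  power; `require_skeleton=False` restores the raw rule. Population-level
  graphs are always consistent, so oracle behavior is unchanged.
- **Permutation filter.** Exceedance is the fraction of `n_perm` genotype
  permutations whose null `|cor|` *strictly* exceeds the observed value
  (ties, possible with discrete dosages, count as non-exceeding); an edge
  passes iff exceedance `> 0.90`, also strict. Under independence the
  exceedance is uniform, so the threshold deliberately sacrifices ~10% of
  genuine induced edges for strong protection against trans effects; a
  dropped edge is demoted to an undirected phenotype edge rather than
  deleted.

## Evaluation

Directed power = TP/(number of true edges); directed FDR = FP/max(1,
predictions), defined as 0 when nothing is predicted. Strict scoring
demands exact orientation matches; equivalence-aware scoring credits any
member of the cycle-reversal class (enumerated exactly for the small
networks used). Undirected predictions matching the true skeleton earn
half credit in a supplementary column only. The replicate harness
re-samples topology *and* parameters for each replicate and records every
seed, so any cell of the study reruns exactly. The bundled study sizes —
10-gene networks, five replicates, sample sizes 120–960 — are desk-scale
choices that keep the full benchmark in the tens of seconds while showing
the qualitative behavior (power rising toward 1 and FDR falling below 0.1
by n = 960 on sparse DAGs).

## Degenerate inputs and numerics

Zero-variance columns are rejected by name at standardization; fully
missing columns fail imputation; non-invertible `I − B` (condition number
above 1e12) and non-PD genotype covariances fail model construction with a
diagnostic. Population support extraction thresholds at `1e−9·max|Ω|` to
separate structural zeros from floating-point dust. Pipeline outputs embed
the master seed and a hash of the analysis configuration (output paths
excluded), and identical configurations reproduce byte-identical tables.

## Known limitations

The unique-cis assumption is load-bearing: trans-acting or pleiotropic
perturbations enlarge the equivalence class, and the permutation filter
only screens induced edges, it cannot re-orient them. CV-selected penalties
are tuned for prediction rather than support recovery, so some
overselection survives into the undirected graph (mitigated, not
eliminated, by the adaptive second stage, the AND rule and skeleton
corroboration). Performance degrades for dense topologies and for networks
much larger than the tens-of-genes regime the method was designed around,
where the asymptotic selection guarantees require sample sizes beyond
typical expression panels.
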