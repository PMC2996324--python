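# eqtlnet

Directed gene-regulatory network reconstruction from gene expression and
unique *cis*-eQTL genotypes, by adaptive-lasso neighborhood selection on the
joint expression/genotype conditional-independence graph.

## The problem and who this is for

Expression data alone cannot orient regulatory relationships: distinct
directed networks — including whole reversed pathways — imply identical
multivariate-normal distributions over the observed expression levels.
Genetic perturbations break these ties. When every gene in an analysis set
carries its own strong, independent *cis*-acting variant (a unique
*cis*-eQTL), the undirected conditional-independence graph over genes *and*
genotypes contains enough information to read off a unique directed network
among the genes — cyclic topologies included, up to reversals of whole
cycles, and exactly when the eQTL-to-gene map is known. This package is for
statistical geneticists and systems biologists working with expression +
genotype panels (experimental crosses or natural populations) who want
directed, possibly cyclic, regulatory networks with explicit statistical
guarantees, plus a full synthetic benchmark to validate the procedure
without any external data.

## The model and the algorithm

Expression of `p` genes in each sample follows a linear structural equation
model with observed genetic perturbations:

    y = B y + W x + e,     e ~ N(0, Σ),  Σ diagonal,

where `B[i,j]` is the regulatory effect of gene *j* on gene *i* (zero
diagonal, `I − B` invertible; cycles allowed), `x` holds eQTL dosages, and
`W` has one nonzero per column under the unique-*cis* assumption. The joint
precision matrix of `(y, x)` factorizes as `Ω = B̃ᵀB̃` with

    B̃ = [ Λ^{1/2}(I−B)   −Λ^{1/2}W ]        Λ = Σ^{-1},
        [ 0               R^{-1/2}  ]

so the support of `Ω` is the moral graph: genes are linked to their
regulators and co-parents, and eQTL *k* is linked to its *cis* gene `g(k)`
and — the key signal — to every *parent* of `g(k)` (an induced dependency).
Each such induced edge `(k, i)` therefore orients a regulatory edge
`i → g(k)`.

The estimator has three steps:

1. **Screen** — per-gene *cis*-window association scan (linear or Spearman;
   Bonferroni/BH/permutation correction), then greedy LD pruning so selected
   eQTL genotypes have pairwise `r² ≤ r2_max` (default 0.01).
2. **Recover** — standardize all columns; regress every gene on all other
   genes and all eQTL with a two-stage adaptive lasso (lasso, then lasso
   re-weighted by `1/|β̂|`, each penalty chosen by 5-fold CV on mean-squared
   prediction error); assemble the interaction graph (AND/OR
   symmetrization) and orient edges through the induced dependencies.
3. **Filter** — for each putative induced edge, permute the genotype 10,000
   times and require the null `|cor|` to exceed the observed `|cor|` more
   than 90% of the time (marginal independence, the collider signature);
   edges failing the screen are demoted to undirected.

## Worked example

Simulate an 8-gene sparse acyclic network with 480 F2 samples, then run the
recovery step (genotype column *k* is the known unique *cis*-eQTL of gene
*k*, so the screen is not needed):

```bash
eqtlnet simulate --p 8 --n 480 --seed 42 --out-dir demo
eqtlnet infer --expression demo/expression.tsv \
              --genotypes demo/genotypes.tsv --seed 42 --out demo/network.tsv
# -> 5 directed, 3 undirected edges
```

Recovered edge table (`demo/network.tsv`):

```
source target  edge_type    effect  provenance_eqtl
  G000   G006 undirected       NaN               -1
  G001   G000   directed  0.474577                0
  G001   G005 undirected       NaN               -1
  G002   G006 undirected       NaN               -1
  G003   G002   directed -0.389550                2
  G004   G002   directed  0.043350                2
  G004   G006   directed  0.363669                6
  G005   G000   directed -0.494637                0
```

The generating network had four directed edges (`G001→G000`, `G003→G002`,
`G004→G006`, `G005→G000`); all four are recovered with the correct
orientation and sign (the `effect` column is the standardized adaptive-lasso
coefficient of the regulator in the target's regression, `provenance_eqtl`
the locus whose induced dependency oriented the edge), alongside one false
positive (`G004→G002`, the small-effect entry) and three unoriented
dependencies. The `run` subcommand chains screen → recover → filter from a
JSON/YAML config; `evaluate` reruns the replicate benchmark
(power/false-discovery rate per topology class and sample size).

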