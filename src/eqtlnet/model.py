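"""Structural-equation model of a gene-regulatory network with eQTL perturbations.

The network over ``p`` expression phenotypes and ``q`` genotyped loci is a
completely observed linear Gaussian SEM.  Writing one sample as a pair of
column vectors ``y`` (expression) and ``x`` (genotype dosages),

    y = B y + W x + e,        e ~ N(0, Sigma),  Sigma diagonal,

where ``B[i, j]`` is the regulatory effect of phenotype *j* on phenotype *i*
(the "child, parent" convention, used everywhere in this package), ``W[g, k]``
is the effect of locus *k* on phenotype *g*, and the zero diagonal of ``B``
rules out self-loops (those would be confounded with the error variances).
``B`` may contain directed cycles; the only structural requirement is that
``I - B`` is invertible so the system has a proper stationary solution.

Treating genotypes as exogenous with covariance ``R`` (for algebra purposes;
only the support of the joint precision matters for structure recovery), the
joint precision of ``(y, x)`` factorizes through the model matrix

    Btilde = [ L^{1/2} (I - B)   -L^{1/2} W ]
             [ 0                  R^{-1/2}  ],      L = Sigma^{-1},

with ``Btilde' Btilde = Omega``, the joint precision.  Zeros of ``Omega`` are
exactly the non-edges of the moral (conditional-independence) graph, and when
every phenotype carries a unique cis perturbation the directed graph can be
read back off that undirected graph — the machinery the rest of the package
estimates from data.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg


__all__ = [
    "NetworkModel",
    "FullModelMatrix",
    "PrecisionMatrix",
    "JointDataset",
    "EquivalenceTransform",
    "InteractionGraph",
    "DirectedNetwork",
    "f2_genotype_covariance",
    "build_model_matrix",
    "implied_precision",
    "implied_covariance",
    "moral_support",
    "moral_graph_from_structure",
    "conditional_log_likelihood",
    "reverse_cycle",
]


def f2_genotype_covariance(q: int) -> np.ndarray:
    """Marginal dosage covariance of ``q`` unlinked F2 markers.

    Dosages segregate 1:2:1 over {0, 1, 2}, so each marker has variance 1/2
    and unlinked markers are independent.
    """
    return 0.5 * np.eye(q)


@dataclasses.dataclass(frozen=True)
class NetworkModel:
    """A parametrized directed (possibly cyclic) expression network.

    Parameters
    ----------
    b : (p, p) array
        Regulatory effects, ``b[i, j]`` = effect of phenotype ``j`` on ``i``.
        Diagonal must be zero; ``I - b`` must be invertible.
    w : (p, q) array
        eQTL effects.  Under the unique-cis assumption column ``k`` has a
        single nonzero entry at row ``assignment[k]``.
    sigma : (p,) array
        Strictly positive error variances (diagonal error covariance).
    assignment : (q,) int array
        ``assignment[k]`` is the cis gene of locus ``k``.
    genotype_cov : (q, q) array, optional
        Symmetric positive-definite genotype covariance.  Defaults to the
        unlinked F2 dosage model (``0.5 * I``).
    unique_cis : bool
        Assert the one-nonzero-per-column structure of ``w`` at construction.
    """

    b: np.ndarray
    w: np.ndarray
    sigma: np.ndarray
    assignment: np.ndarray
    genotype_cov: np.ndarray | None = None
    unique_cis: bool = True

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        w = np.asarray(self.w, dtype=float)
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        assignment = np.asarray(self.assignment, dtype=int)
        p = b.shape[0]
        if b.shape != (p, p):
            raise ValueError(f"b must be square, got {b.shape}")
        q = w.shape[1] if w.ndim == 2 else 0
        if w.shape != (p, q):
            raise ValueError(f"w must be (p, q) = ({p}, {q}), got {w.shape}")
        if sigma.shape != (p,):
            raise ValueError(f"sigma must have length p={p}, got {sigma.shape}")
        if assignment.shape != (q,):
            raise ValueError(f"assignment must have length q={q}")
        if np.any(np.diagonal(b) != 0.0):
            raise ValueError("diagonal of b must be zero (no self-loops)")
        if np.any(sigma <= 0.0):
            raise ValueError("error variances must be strictly positive")
        gc = self.genotype_cov
        if gc is None:
            gc = f2_genotype_covariance(q)
        gc = np.asarray(gc, dtype=float)
        if gc.shape != (q, q):
            raise ValueError(f"genotype_cov must be ({q}, {q}), got {gc.shape}")
        if not np.allclose(gc, gc.T, atol=1e-10):
            raise ValueError("genotype_cov must be symmetric")
        if q and np.min(scipy.linalg.eigvalsh(gc)) <= 0.0:
            raise ValueError("genotype_cov must be positive-definite")
        # invertibility of I - B, with an explicit conditioning guard
        eye_b = np.eye(p) - b
        if p and 1.0 / np.linalg.cond(eye_b) < 1e-12:
            raise ValueError("I - b is singular or numerically singular")
        if self.unique_cis and q:
            if len(set(assignment.tolist())) != q:
                raise ValueError("unique_cis requires an injective assignment")
            rows, cols = np.nonzero(w)
            expected = assignment[cols]
            if not np.array_equal(rows, expected) or len(cols) != q or set(
                cols.tolist()
            ) != set(range(q)):
                raise ValueError(
                    "unique_cis requires support(w) == {(assignment[k], k)}"
                )
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "assignment", assignment)
        object.__setattr__(self, "genotype_cov", gc)

    @property
    def p(self) -> int:
        return self.b.shape[0]

    @property
    def q(self) -> int:
        return self.w.shape[1]

    def directed_edges(self, tol: float = 0.0) -> set[tuple[int, int]]:
        """True regulatory edges as (parent, child) phenotype index pairs."""
        rows, cols = np.nonzero(np.abs(self.b) > tol)
        return {(int(j), int(i)) for i, j in zip(rows, cols)}

    def is_dag(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.p))
        g.add_edges_from(self.directed_edges())
        return nx.is_directed_acyclic_graph(g)


@dataclasses.dataclass(frozen=True)
class FullModelMatrix:
    """Upper-triangular-by-blocks square root of the implied joint precision."""

    btilde: np.ndarray
    p: int
    q: int

    def __post_init__(self) -> None:
        m = self.p + self.q
        if self.btilde.shape != (m, m):
            raise ValueError("btilde has inconsistent block dimensions")
        if np.any(np.diagonal(self.btilde) <= 0.0):
            raise ValueError("btilde diagonal must be strictly positive")


@dataclasses.dataclass(frozen=True)
class PrecisionMatrix:
    """Joint precision over phenotypes (first ``p`` rows) then loci."""

    omega: np.ndarray
    p: int
    q: int

    def __post_init__(self) -> None:
        m = self.p + self.q
        if self.omega.shape != (m, m):
            raise ValueError("omega has inconsistent dimensions")
        if not np.allclose(self.omega, self.omega.T, atol=1e-8):
            raise ValueError("omega must be symmetric")

    @property
    def yy(self) -> np.ndarray:
        return self.omega[: self.p, : self.p]

    @property
    def yx(self) -> np.ndarray:
        return self.omega[: self.p, self.p :]

    @property
    def xx(self) -> np.ndarray:
        return self.omega[self.p :, self.p :]


@dataclasses.dataclass
class JointDataset:
    """Expression and genotype data on a common set of samples.

    ``sample_cov`` is the empirical covariance of the column-centered joint
    matrix ``[Y X]`` with denominator ``n`` (so the Gaussian log-likelihood
    written in terms of it equals the exact sum of log-densities of the
    centered rows).  NaN marks missing values prior to imputation.
    """

    expression: np.ndarray
    genotypes: np.ndarray
    gene_ids: list[str]
    marker_ids: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.expression.ndim != 2 or self.genotypes.ndim != 2:
            raise ValueError("expression and genotypes must be 2-D")
        if self.expression.shape[0] != self.genotypes.shape[0]:
            raise ValueError(
                "expression and genotypes must have equal sample counts: "
                f"{self.expression.shape[0]} vs {self.genotypes.shape[0]}"
            )
        if len(self.gene_ids) != self.expression.shape[1]:
            raise ValueError("gene_ids length does not match expression columns")
        if len(self.marker_ids) != self.genotypes.shape[1]:
            raise ValueError("marker_ids length does not match genotype columns")

    @property
    def n(self) -> int:
        return self.expression.shape[0]

    @property
    def p(self) -> int:
        return self.expression.shape[1]

    @property
    def q(self) -> int:
        return self.genotypes.shape[1]

    def joint(self) -> np.ndarray:
        return np.hstack([self.expression, self.genotypes])

    def centered(self) -> np.ndarray:
        z = self.joint()
        return z - z.mean(axis=0, keepdims=True)

    @property
    def sample_cov(self) -> np.ndarray:
        z = self.centered()
        return z.T @ z / self.n

    def has_missing(self) -> bool:
        return bool(
            np.isnan(self.expression).any() or np.isnan(self.genotypes).any()
        )


@dataclasses.dataclass(frozen=True)
class EquivalenceTransform:
    """Orthonormal row action mapping one model matrix onto an equivalent one.

    ``a`` acts on the full (p+q)-row model matrix; its phenotype block ``ps``
    is a signed permutation (one entry of magnitude one per row and column).
    """

    a: np.ndarray
    ps: np.ndarray
    cycle: tuple[int, ...]

    def __post_init__(self) -> None:
        m = self.a.shape[0]
        if not np.allclose(self.a.T @ self.a, np.eye(m), atol=1e-10):
            raise ValueError("transform must be orthonormal")
        ps = self.ps
        if not (
            np.all(np.sum(np.abs(ps) > 0.5, axis=0) == 1)
            and np.all(np.sum(np.abs(ps) > 0.5, axis=1) == 1)
            and np.allclose(np.abs(ps[np.abs(ps) > 0.5]), 1.0)
        ):
            raise ValueError("ps must be a signed permutation matrix")


class InteractionGraph:
    """Undirected conditional-independence graph over phenotypes and loci.

    Nodes are integers: phenotypes ``0..p-1``, loci ``p..p+q-1``.  Edges are
    stored as frozensets of node pairs; ``bd(v)`` is the boundary (neighbor
    set) of ``v``.
    """

    def __init__(self, p: int, q: int, edges: Iterable[tuple[int, int]] = ()):
        self.p = int(p)
        self.q = int(q)
        self.edges: set[frozenset[int]] = set()
        for a, b in edges:
            self.add_edge(a, b)

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        n = self.p + self.q
        if not (0 <= a < n and 0 <= b < n):
            raise ValueError(f"node out of range: ({a}, {b})")
        self.edges.add(frozenset((int(a), int(b))))

    def has_edge(self, a: int, b: int) -> bool:
        return frozenset((a, b)) in self.edges

    def boundary(self, v: int) -> set[int]:
        return {next(iter(e - {v})) for e in self.edges if v in e}

    def phenotype_edges(self) -> set[frozenset[int]]:
        return {e for e in self.edges if max(e) < self.p}

    def eqtl_phenotype_edges(self) -> set[tuple[int, int]]:
        """Pairs (locus index k in 0..q-1, phenotype index)."""
        out = set()
        for e in self.edges:
            a, b = sorted(e)
            if a < self.p <= b:
                out.add((b - self.p, a))
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InteractionGraph)
            and (self.p, self.q) == (other.p, other.q)
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (
            f"InteractionGraph(p={self.p}, q={self.q}, "
            f"n_edges={len(self.edges)})"
        )


@dataclasses.dataclass
class DirectedNetwork:
    """Recovered network: directed edges among phenotypes plus leftovers.

    ``directed_edges`` entries are ``(source, target, effect, provenance)``
    where provenance is the locus index whose induced dependency oriented the
    edge; ``undirected_edges`` holds phenotype pairs whose dependency could
    not be oriented.
    """

    p: int
    directed_edges: list[tuple[int, int, float, int]] = dataclasses.field(
        default_factory=list
    )
    undirected_edges: set[frozenset[int]] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        for s, t, _, _ in self.directed_edges:
            if s == t:
                raise ValueError("directed self-edges are not allowed")
            if not (0 <= s < self.p and 0 <= t < self.p):
                raise ValueError("directed edges must join phenotypes")

    def directed_pairs(self) -> set[tuple[int, int]]:
        return {(s, t) for s, t, _, _ in self.directed_edges}

    def parents(self, i: int) -> set[int]:
        return {s for s, t, _, _ in self.directed_edges if t == i}


def build_model_matrix(model: NetworkModel) -> FullModelMatrix:
    """Assemble the block model matrix whose Gram matrix is the precision.

    Blocks: ``[[L^{1/2}(I - B), -L^{1/2} W], [0, R^{-1/2}]]`` with
    ``L = diag(1/sigma)`` and ``R`` the genotype covariance (symmetric
    inverse square root).
    """
    p, q = model.p, model.q
    lam_half = np.diag(1.0 / np.sqrt(model.sigma))
    top_left = lam_half @ (np.eye(p) - model.b)
    top_right = -lam_half @ model.w
    if q:
        r_inv_half = _sym_inv_sqrt(model.genotype_cov)
    else:
        r_inv_half = np.zeros((0, 0))
    btilde = np.block(
        [[top_left, top_right], [np.zeros((q, p)), r_inv_half]]
    )
    return FullModelMatrix(btilde=btilde, p=p, q=q)


def _sym_inv_sqrt(m: np.ndarray) -> np.ndarray:
    vals, vecs = scipy.linalg.eigh(m)
    if np.min(vals) <= 0.0:
        raise ValueError("matrix is not positive-definite")
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T


def implied_precision(model: NetworkModel) -> PrecisionMatrix:
    """Joint precision of (phenotypes, genotypes) implied by the model.

    Blockwise: ``O_yy = (I-B)' L (I-B)``, ``O_yx = -(I-B)' L W``,
    ``O_xx = W' L W + R^{-1}``.
    """
    p, q = model.p, model.q
    lam = np.diag(1.0 / model.sigma)
    ib = np.eye(p) - model.b
    o_yy = ib.T @ lam @ ib
    o_yx = -ib.T @ lam @ model.w
    if q:
        o_xx = model.w.T @ lam @ model.w + np.linalg.inv(model.genotype_cov)
    else:
        o_xx = np.zeros((0, 0))
    omega = np.block([[o_yy, o_yx], [o_yx.T, o_xx]])
    omega = 0.5 * (omega + omega.T)
    return PrecisionMatrix(omega=omega, p=p, q=q)


def implied_covariance(model: NetworkModel) -> np.ndarray:
    """Joint covariance of (phenotypes, genotypes): inverse implied precision."""
    omega = implied_precision(model).omega
    try:
        cov = np.linalg.inv(omega)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ValueError("implied precision is singular") from exc
    return 0.5 * (cov + cov.T)


def moral_support(
    precision: PrecisionMatrix, tol: float | None = None
) -> InteractionGraph:
    """Read the moral graph off the nonzero support of a precision matrix.

    ``tol`` defaults to ``1e-9 * max|omega|``, separating structural zeros
    from floating-point noise in population-level matrices.
    """
    omega = precision.omega
    if tol is None:
        tol = 1e-9 * np.max(np.abs(omega)) if omega.size else 0.0
    graph = InteractionGraph(precision.p, precision.q)
    n = omega.shape[0]
    for a in range(n):
        for b in range(a + 1, n):
            if abs(omega[a, b]) > tol:
                graph.add_edge(a, b)
    return graph


def moral_graph_from_structure(
    b_support: np.ndarray,
    assignment: Sequence[int],
    genotype_prec_support: np.ndarray | None = None,
) -> InteractionGraph:
    """Combinatorial moralization of a directed network with eQTL parents.

    Rules: phenotypes i, j are joined if either regulates the other or they
    share a child; locus k is joined to its cis gene ``g(k)`` and to every
    phenotype parent of ``g(k)``; two loci are joined only through off-
    diagonal support of the genotype precision (never under unlinked loci).
    Serves as the independent structural oracle for ``moral_support``.
    """
    b_support = np.asarray(b_support) != 0
    p = b_support.shape[0]
    q = len(assignment)
    graph = InteractionGraph(p, q)
    parents = [set(np.nonzero(b_support[i])[0].tolist()) for i in range(p)]
    for child in range(p):
        par = sorted(parents[child])
        for j in par:
            graph.add_edge(j, child)
        for a_idx in range(len(par)):
            for b_idx in range(a_idx + 1, len(par)):
                graph.add_edge(par[a_idx], par[b_idx])
    for k in range(q):
        g = int(assignment[k])
        graph.add_edge(p + k, g)
        for j in parents[g]:
            graph.add_edge(p + k, j)
    if genotype_prec_support is not None:
        gp = np.asarray(genotype_prec_support) != 0
        for a in range(q):
            for b in range(a + 1, q):
                if gp[a, b]:
                    graph.add_edge(p + a, p + b)
    return graph


def conditional_log_likelihood(data: JointDataset, model: NetworkModel) -> float:
    """Gaussian log-likelihood of the centered joint data under the model.

    Equals ``(n/2) (log det Omega - tr(S Omega) - (p+q) log 2 pi)`` with
    ``S`` the empirical covariance (denominator ``n``) of the centered data,
    i.e. the exact sum of joint-normal log-densities of the centered rows.
    """
    if data.p != model.p or data.q != model.q:
        raise ValueError(
            f"dimension mismatch: data is (p={data.p}, q={data.q}), "
            f"model is (p={model.p}, q={model.q})"
        )
    omega = implied_precision(model).omega
    s = data.sample_cov
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise ValueError("implied precision is not positive-definite")
    m = model.p + model.q
    n = data.n
    return 0.5 * n * (logdet - float(np.sum(s * omega)) - m * np.log(2.0 * np.pi))


def reverse_cycle(
    model: NetworkModel, cycle: Sequence[int]
) -> tuple[NetworkModel, EquivalenceTransform]:
    """Construct the distribution-equivalent model with ``cycle`` reversed.

    Only directed cyclic graphs admit non-trivial equivalent models under
    unique cis perturbations; the transform is a signed permutation of the
    phenotype rows of the model matrix (rows of cycle children move to their
    cycle parents, signs chosen to keep the diagonal positive), followed by
    re-extraction of ``(B, W, sigma)`` from the transformed matrix.  The
    perturbation assignment is permuted along the cycle, so the returned
    model is a genuinely different directed graph with an identical implied
    joint distribution.

    Raises ``ValueError`` if ``cycle`` is not a directed cycle of the model,
    including the DAG case where no equivalent alternative model exists.
    """
    if not model.unique_cis:
        raise ValueError("cycle reversal requires the unique-cis structure")
    cycle = [int(v) for v in cycle]
    if len(cycle) < 2 or len(set(cycle)) != len(cycle):
        raise ValueError("cycle must list at least two distinct phenotypes")
    p, q = model.p, model.q
    for v in cycle:
        if not 0 <= v < p:
            raise ValueError(f"cycle node {v} out of range")
    succ = {cycle[i]: cycle[(i + 1) % len(cycle)] for i in range(len(cycle))}
    for v, nxt in succ.items():
        if model.b[nxt, v] == 0.0:
            raise ValueError(
                f"({v} -> {nxt}) is not an edge: argument is not a directed "
                "cycle of the model (a DAG has no equivalent alternative)"
            )

    full = build_model_matrix(model)
    btilde = full.btilde
    # Row sigma(i) of the phenotype block moves to position i, where sigma is
    # the cycle-successor map; off-cycle rows stay put.
    perm = np.arange(p)
    for v in cycle:
        perm[v] = succ[v]
    pmat = np.zeros((p, p))
    pmat[np.arange(p), perm] = 1.0
    permuted = pmat @ btilde[:p, :]
    signs = np.where(np.diagonal(permuted[:, :p]) > 0, 1.0, -1.0)
    ps = np.diag(signs) @ pmat
    a = np.block(
        [[ps, np.zeros((p, q))], [np.zeros((q, p)), np.eye(q)]]
    )
    new_top = ps @ btilde[:p, :]

    lam_half_new = np.diagonal(new_top[:, :p]).copy()
    if np.any(lam_half_new <= 0):  # pragma: no cover - signs force positivity
        raise RuntimeError("failed to renormalize to a positive diagonal")
    inv_lh = np.diag(1.0 / lam_half_new)
    new_b = np.eye(p) - inv_lh @ new_top[:, :p]
    np.fill_diagonal(new_b, 0.0)
    new_w = -inv_lh @ new_top[:, p:]
    new_sigma = 1.0 / lam_half_new**2
    new_assignment = model.assignment.copy()
    # locus k previously cis to succ(v) now feeds v
    inv_succ = {v2: v1 for v1, v2 in succ.items()}
    for k in range(q):
        g = int(model.assignment[k])
        if g in inv_succ:
            new_assignment[k] = inv_succ[g]
    # prune numerical dust so the support is exact
    new_b[np.abs(new_b) < 1e-12] = 0.0
    new_w[np.abs(new_w) < 1e-12] = 0.0
    new_model = NetworkModel(
        b=new_b,
        w=new_w,
        sigma=new_sigma,
        assignment=new_assignment,
        genotype_cov=model.genotype_cov,
        unique_cis=model.unique_cis,
    )
    transform = EquivalenceTransform(a=a, ps=ps, cycle=tuple(cycle))
    return new_model, transform
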