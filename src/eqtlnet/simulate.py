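"""Generative simulator for the network model and an F2 cross.

Emulates the benchmark design the recovery algorithm is validated on:
random sparse directed topologies (acyclic or cyclic) with a target
expected degree, regulatory effects drawn uniformly in magnitude with
random sign, one strong independent cis-eQTL of constant effect per gene,
F2 genotype dosages (1:2:1 segregation, optionally linked markers on
chromosomes with a fixed recombination fraction), and Gaussian SEM
expression.  Each replicate of a study re-samples both the topology and
its parametrization.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import (
    JointDataset,
    NetworkModel,
    implied_precision,
    moral_graph_from_structure,
    moral_support,
)

__all__ = [
    "SimulationConfig",
    "sample_topology",
    "sample_effects",
    "sample_f2_genotypes",
    "sample_expression",
    "simulate_dataset",
]

#: Spectral-radius cap on cyclic B so the SEM has a proper joint distribution.
STABILITY_BOUND = 0.95


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults describe the regime the method targets: strong cis
    perturbations (``eqtl_effect`` 1.0) against low error variance (0.25),
    regulatory effect magnitudes uniform on (0.4, 1.0) with random sign, and
    sparse topologies of expected degree 1–3.
    """

    p: int = 10
    n: int = 200
    expected_degree: float = 1.0
    allow_cycles: bool = False
    effect_low: float = 0.4
    effect_high: float = 1.0
    eqtl_effect: float = 1.0
    error_var: float = 0.25
    randomize_params: bool = False
    trans_fraction: float = 0.0
    trans_effect: float | None = None
    linkage_r: float | None = None
    markers_per_chrom: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.expected_degree > self.p - 1:
            raise ValueError("expected_degree must be at most p - 1")
        if not 0.0 < self.effect_low < self.effect_high:
            raise ValueError("need 0 < effect_low < effect_high")
        if self.eqtl_effect <= 0:
            raise ValueError("eqtl_effect must be positive")
        if self.error_var <= 0:
            raise ValueError("error_var must be positive")
        if not 0.0 <= self.trans_fraction <= 1.0:
            raise ValueError("trans_fraction must lie in [0, 1]")


def sample_topology(
    p: int,
    expected_degree: float,
    allow_cycles: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random directed support with a target expected (total) degree.

    DAG mode: draw a random node order, include each unordered pair
    independently with probability ``expected_degree / (p - 1)`` and orient
    it consistently with the order (guaranteeing acyclicity).  DCG mode:
    include each ordered pair independently with probability
    ``expected_degree / (2 (p - 1))``, so the expected number of incident
    edges per node matches the DAG mode.
    """
    if expected_degree >= p:
        raise ValueError("expected_degree must be < p")
    support = np.zeros((p, p), dtype=bool)
    if p < 2 or expected_degree <= 0:
        return support
    if allow_cycles:
        prob = expected_degree / (2.0 * (p - 1))
        mask = rng.random((p, p)) < prob
        np.fill_diagonal(mask, False)
        support = mask
    else:
        order = rng.permutation(p)
        rank = np.empty(p, dtype=int)
        rank[order] = np.arange(p)
        prob = expected_degree / (p - 1)
        for a in range(p):
            for b in range(a + 1, p):
                if rng.random() < prob:
                    parent, child = (a, b) if rank[a] < rank[b] else (b, a)
                    support[child, parent] = True
    return support


def sample_effects(
    support: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_retries: int = 200,
) -> NetworkModel:
    """Parametrize a topology: uniform-magnitude signed effects, unique cis W.

    Cyclic supports are re-drawn until the spectral radius of B falls below
    the stability bound; sampled models whose population precision support
    disagrees with combinatorial moralization (a measure-zero faithfulness
    violation, possible only through numerical near-cancellation) are
    rejected and re-sampled likewise.
    """
    support = np.asarray(support, dtype=bool)
    if np.any(np.diagonal(support)):
        raise ValueError("support must have a zero diagonal")
    p = support.shape[0]
    assignment = np.arange(p)
    for _ in range(max_retries):
        mag = rng.uniform(config.effect_low, config.effect_high, size=(p, p))
        sign = rng.choice([-1.0, 1.0], size=(p, p))
        b = np.where(support, mag * sign, 0.0)
        if np.count_nonzero(b):
            rho = np.max(np.abs(np.linalg.eigvals(b)))
            if rho >= STABILITY_BOUND:
                continue
        if config.randomize_params:
            sigma = rng.uniform(0.1, 1.0, size=p)
            w_eff = rng.uniform(0.5, 1.5, size=p)
        else:
            sigma = np.full(p, config.error_var)
            w_eff = np.full(p, config.eqtl_effect)
        w = np.zeros((p, p))
        w[assignment, np.arange(p)] = w_eff
        model = NetworkModel(
            b=b, w=w, sigma=sigma, assignment=assignment, unique_cis=True
        )
        oracle = moral_support(implied_precision(model))
        expected = moral_graph_from_structure(b != 0.0, assignment)
        if oracle == expected:
            return model
    raise RuntimeError(
        "could not sample a stable, faithful parametrization "
        f"after {max_retries} attempts"
    )


def add_trans_effects(
    model: NetworkModel,
    trans_fraction: float,
    rng: np.random.Generator,
    trans_effect: float | None = None,
) -> NetworkModel:
    """Give a fraction of loci an extra trans target (contaminated W).

    Breaks the unique-cis structure deliberately, to exercise the
    permutation filter; the returned model has ``unique_cis=False``.
    """
    p, q = model.p, model.q
    w = model.w.copy()
    n_trans = int(round(trans_fraction * q))
    if n_trans == 0:
        return model
    loci = rng.choice(q, size=n_trans, replace=False)
    effect = trans_effect if trans_effect is not None else float(
        np.max(np.abs(w))
    )
    for k in loci:
        g = int(model.assignment[k])
        others = [i for i in range(p) if i != g]
        target = int(rng.choice(others))
        w[target, k] = effect * rng.choice([-1.0, 1.0])
    return NetworkModel(
        b=model.b,
        w=w,
        sigma=model.sigma,
        assignment=model.assignment,
        genotype_cov=model.genotype_cov,
        unique_cis=False,
    )


def sample_f2_genotypes(
    n: int,
    q: int,
    rng: np.random.Generator,
    linkage_r: float | None = None,
    markers_per_chrom: int | None = None,
) -> np.ndarray:
    """Dosage genotypes of an F2 intercross.

    Unlinked mode (``linkage_r`` None): iid dosages with P(0) = 1/4,
    P(1) = 1/2, P(2) = 1/4.  Linked mode: markers are grouped into
    chromosomes of ``markers_per_chrom`` loci; each of the two gametes per
    individual is an independent two-state Markov chain along the
    chromosome whose transition (allele switch) probability is the
    recombination fraction ``r``; the dosage is the gamete sum, giving
    adjacent-marker dosage correlation ``(1 - 2 r)``.
    """
    if n < 1 or q < 1:
        raise ValueError("n and q must be at least 1")
    if linkage_r is None:
        return rng.choice([0, 1, 2], size=(n, q), p=[0.25, 0.5, 0.25]).astype(
            float
        )
    r = float(linkage_r)
    if not 0.0 < r <= 0.5:
        raise ValueError(f"recombination fraction must be in (0, 0.5], got {r}")
    m_per = markers_per_chrom or q
    x = np.empty((n, q), dtype=float)
    col = 0
    while col < q:
        block = min(m_per, q - col)
        gametes = np.empty((2, n, block))
        for g in range(2):
            chain = np.empty((n, block))
            chain[:, 0] = rng.random(n) < 0.5
            for j in range(1, block):
                switch = rng.random(n) < r
                chain[:, j] = np.where(switch, 1 - chain[:, j - 1], chain[:, j - 1])
            gametes[g] = chain
        x[:, col : col + block] = gametes.sum(axis=0)
        col += block
    return x


def sample_expression(
    model: NetworkModel, x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw expression rows from the SEM given genotype rows.

    Each sample solves ``y = B y + W x + e`` with ``e ~ N(0, Sigma)``;
    vectorized over samples, ``Y = (X W' + E) (I - B)^{-T}``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.q:
        raise ValueError(
            f"x must be (n, q={model.q}), got {x.shape}"
        )
    n = x.shape[0]
    e = rng.normal(0.0, np.sqrt(model.sigma), size=(n, model.p))
    rhs = x @ model.w.T + e
    ib = np.eye(model.p) - model.b
    # Y^T = (I - B)^{-1} (W X^T + E^T), i.e. Y = (X W' + E) (I - B)^{-T}
    return np.linalg.solve(ib, rhs.T).T


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[JointDataset, NetworkModel]:
    """Sample topology, parameters, genotypes and expression in one call.

    Returns the dataset together with the generating model (the truth for
    scoring).  Locus ``k`` is the cis perturbation of gene ``k``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    support = sample_topology(
        config.p, config.expected_degree, config.allow_cycles, rng
    )
    model = sample_effects(support, config, rng)
    if config.trans_fraction > 0:
        model = add_trans_effects(
            model, config.trans_fraction, rng, config.trans_effect
        )
    x = sample_f2_genotypes(
        config.n,
        model.q,
        rng,
        linkage_r=config.linkage_r,
        markers_per_chrom=config.markers_per_chrom,
    )
    y = sample_expression(model, x, rng)
    gene_ids = [f"G{i:03d}" for i in range(config.p)]
    marker_ids = [f"M{i:03d}" for i in range(model.q)]
    sample_ids = [f"S{i:04d}" for i in range(config.n)]
    data = JointDataset(
        expression=y,
        genotypes=x,
        gene_ids=gene_ids,
        marker_ids=marker_ids,
        sample_ids=sample_ids,
    )
    return data, model
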