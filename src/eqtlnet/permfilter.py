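"""Step 3: permutation screen for marginal independence of induced edges.

A directed edge ``i -> g(k)`` is trusted only if locus ``k`` and the
upstream phenotype ``i`` are marginally uncorrelated — the signature of a
genuine induced (collider) dependency rather than a trans effect of the
locus.  The screen permutes the genotype vector and measures how often the
null absolute marginal correlation exceeds the observed one; edges whose
exceedance probability is not greater than a conservative threshold (0.90
by default) are demoted to undirected.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model import DirectedNetwork, JointDataset

__all__ = ["EdgeTest", "permutation_exceedance", "filter_directed_edges"]


@dataclasses.dataclass
class EdgeTest:
    """Permutation-null summary for one locus-phenotype pair."""

    eqtl: int
    phenotype: int
    obs_abs_cor: float
    n_perm: int
    exceedance: float
    passed: bool


def permutation_exceedance(
    y: np.ndarray,
    x: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    eqtl: int = -1,
    phenotype: int = -1,
    threshold: float = 0.90,
) -> EdgeTest:
    """Fraction of genotype permutations whose |correlation| exceeds observed.

    The count uses strict inequality, so ties (possible with discrete
    dosages) count as non-exceeding.  Deterministic under a fixed generator
    state.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length vectors")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if np.std(y) == 0.0 or np.std(x) == 0.0:
        raise ValueError("constant vector: correlation undefined")
    yc = (y - y.mean()) / (y.std() * np.sqrt(y.size))
    xc = (x - x.mean()) / (x.std() * np.sqrt(x.size))
    obs = abs(float(yc @ xc))
    count = 0
    for _ in range(n_perm):
        if abs(float(yc @ rng.permutation(xc))) > obs:
            count += 1
    exceed = count / n_perm
    return EdgeTest(
        eqtl=eqtl,
        phenotype=phenotype,
        obs_abs_cor=obs,
        n_perm=n_perm,
        exceedance=exceed,
        passed=exceed > threshold,
    )


def filter_directed_edges(
    network: DirectedNetwork,
    data: JointDataset,
    rng: np.random.Generator,
    threshold: float = 0.90,
    n_perm: int = 10_000,
) -> tuple[DirectedNetwork, list[EdgeTest]]:
    """Keep directed edges whose provenance locus passes the marginal screen.

    For each directed edge ``i -> g(k)``, the upstream phenotype ``i`` and
    genotype ``k`` are tested; the edge survives iff the exceedance
    probability strictly exceeds ``threshold``.  Dropped edges are demoted
    to undirected phenotype edges.  All test records are returned.
    """
    tests: list[EdgeTest] = []
    kept: list[tuple[int, int, float, int]] = []
    demoted: set[frozenset[int]] = set()
    for s, t, eff, k in network.directed_edges:
        test = permutation_exceedance(
            data.expression[:, s],
            data.genotypes[:, k],
            n_perm=n_perm,
            rng=rng,
            eqtl=k,
            phenotype=s,
            threshold=threshold,
        )
        tests.append(test)
        if test.passed:
            kept.append((s, t, eff, k))
        else:
            demoted.add(frozenset((s, t)))
    implied = {frozenset((s, t)) for s, t, _, _ in kept}
    undirected = set(network.undirected_edges) | (demoted - implied)
    filtered = DirectedNetwork(
        p=network.p, directed_edges=kept, undirected_edges=undirected
    )
    return filtered, tests


def tests_to_frame(tests: list[EdgeTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "eqtl": t.eqtl,
                "phenotype": t.phenotype,
                "obs_abs_cor": t.obs_abs_cor,
                "n_perm": t.n_perm,
                "exceedance": t.exceedance,
                "pass": t.passed,
            }
            for t in tests
        ],
        columns=["eqtl", "phenotype", "obs_abs_cor", "n_perm", "exceedance", "pass"],
    )
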