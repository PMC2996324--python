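"""Step 1: selection of expression phenotypes with strong, independent cis-eQTL.

Each gene is scanned for association against every marker inside a cis
window centered on the gene start; the best marker per gene is kept,
multiplicity-corrected, and the surviving (gene, eQTL) pairs are greedily
pruned so that no two selected genotypes exceed a pairwise r² ceiling —
ensuring each retained locus is an effectively independent perturbation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .model import JointDataset

__all__ = [
    "ScreenConfig",
    "CandidateHit",
    "ScreenResult",
    "impute_missing",
    "cis_scan",
    "ld_prune",
    "run_screen",
]


@dataclasses.dataclass
class ScreenConfig:
    """Settings for the cis scan and LD pruning.

    ``window_bp`` is the half-width of the cis window around the gene start
    (both maps use 1-based inclusive coordinates).  ``r2_max`` defaults to a
    very conservative 0.01 so selected genotypes are nearly uncorrelated.
    """

    window_bp: int = 25_000
    test: str = "linear"
    correction: str = "bonferroni"
    alpha: float = 0.05
    r2_max: float = 0.01
    n_perm_assoc: int = 1000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.test not in ("linear", "spearman"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.correction not in ("bonferroni", "bh", "permutation"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must lie in (0, 1]")


@dataclasses.dataclass
class CandidateHit:
    gene: str
    gene_index: int
    marker: str
    marker_index: int
    statistic: float
    pvalue: float
    n_tests: int
    distance_bp: int
    passed: bool


@dataclasses.dataclass
class ScreenResult:
    """Per-gene best cis hits plus the pruned selection."""

    hits: list[CandidateHit]
    selected: list[CandidateHit] = dataclasses.field(default_factory=list)
    pruning_log: list[str] = dataclasses.field(default_factory=list)
    total_tests: int = 0

    def passing(self) -> list[CandidateHit]:
        return [h for h in self.hits if h.passed]

    def to_frame(self) -> pd.DataFrame:
        sel = {(h.gene, h.marker) for h in self.selected}
        rows = [
            {
                "gene": h.gene,
                "marker": h.marker,
                "statistic": h.statistic,
                "pvalue": h.pvalue,
                "n_tests": h.n_tests,
                "distance_bp": h.distance_bp,
                "passed": h.passed,
                "selected": (h.gene, h.marker) in sel,
            }
            for h in self.hits
        ]
        return pd.DataFrame(rows)


def impute_missing(data: JointDataset) -> JointDataset:
    """Replace missing expression/genotype values by their column means.

    Column means over observed entries are unchanged by the fill.  A fully
    missing column has no mean to impute and raises.
    """
    def fill(mat: np.ndarray, ids: list[str], what: str) -> np.ndarray:
        mat = np.array(mat, dtype=float, copy=True)
        mask = np.isnan(mat)
        if not mask.any():
            return mat
        n_obs = (~mask).sum(axis=0)
        if np.any(n_obs == 0):
            bad = [ids[j] for j in np.nonzero(n_obs == 0)[0]]
            raise ValueError(f"fully missing {what} column(s): {bad}")
        col_means = np.nansum(mat, axis=0) / n_obs
        idx = np.nonzero(mask)
        mat[idx] = col_means[idx[1]]
        return mat

    return JointDataset(
        expression=fill(data.expression, data.gene_ids, "expression"),
        genotypes=fill(data.genotypes, data.marker_ids, "genotype"),
        gene_ids=list(data.gene_ids),
        marker_ids=list(data.marker_ids),
        sample_ids=list(data.sample_ids) if data.sample_ids else None,
    )


def _assoc_pvalue(
    y: np.ndarray,
    x: np.ndarray,
    test: str,
    n_perm: int,
    rng: np.random.Generator | None,
) -> tuple[float, float]:
    """Single-marker association: statistic (|correlation|) and p-value."""
    if test == "linear":
        r, pval = scipy.stats.pearsonr(x, y)
    else:
        r, pval = scipy.stats.spearmanr(x, y)
    stat = abs(float(r))
    if rng is not None:  # permutation p-value replaces the analytic one
        obs = stat
        count = 0
        for _ in range(n_perm):
            xp = rng.permutation(x)
            if test == "linear":
                rp = scipy.stats.pearsonr(xp, y)[0]
            else:
                rp = scipy.stats.spearmanr(xp, y)[0]
            if abs(rp) >= obs:
                count += 1
        pval = (count + 1) / (n_perm + 1)
    return stat, float(pval)


def cis_scan(
    data: JointDataset,
    gene_map: pd.DataFrame,
    marker_map: pd.DataFrame,
    config: ScreenConfig,
    rng: np.random.Generator | None = None,
) -> ScreenResult:
    """Scan every gene's cis window, keep its best marker, correct for tests.

    ``gene_map`` needs columns (gene_id, chrom, start_bp); ``marker_map``
    needs (marker_id, chrom, pos_bp).  The window is the closed interval
    ``[start - window_bp, start + window_bp]`` on the gene's chromosome.
    Ties in significance break by genomic distance to the gene start, then
    by marker index.  Genes with no cis marker are flagged (not failed).
    The Bonferroni denominator is the total number of tests across genes.
    """
    if data.has_missing():
        raise ValueError("impute missing values before scanning")
    gmap = gene_map.set_index("gene_id")
    mmap = marker_map.set_index("marker_id")
    missing_genes = [g for g in data.gene_ids if g not in gmap.index]
    if missing_genes:
        raise ValueError(f"gene map does not cover: {missing_genes[:5]}")
    missing_markers = [m for m in data.marker_ids if m not in mmap.index]
    if missing_markers:
        raise ValueError(f"marker map does not cover: {missing_markers[:5]}")
    if config.correction == "permutation" and rng is None:
        rng = np.random.default_rng(0)

    marker_chrom = np.array([mmap.loc[m, "chrom"] for m in data.marker_ids])
    marker_pos = np.array(
        [int(mmap.loc[m, "pos_bp"]) for m in data.marker_ids]
    )

    raw: list[CandidateHit] = []
    total_tests = 0
    for gi, gene in enumerate(data.gene_ids):
        chrom = gmap.loc[gene, "chrom"]
        start = int(gmap.loc[gene, "start_bp"])
        in_window = (marker_chrom == chrom) & (
            np.abs(marker_pos - start) <= config.window_bp
        )
        idx = np.nonzero(in_window)[0]
        if idx.size == 0:
            raw.append(
                CandidateHit(
                    gene=gene,
                    gene_index=gi,
                    marker="",
                    marker_index=-1,
                    statistic=np.nan,
                    pvalue=np.nan,
                    n_tests=0,
                    distance_bp=-1,
                    passed=False,
                )
            )
            continue
        y = data.expression[:, gi]
        best = None
        for mi in idx:
            perm_rng = rng if config.correction == "permutation" else None
            stat, pval = _assoc_pvalue(
                y,
                data.genotypes[:, mi],
                config.test,
                config.n_perm_assoc,
                perm_rng,
            )
            dist = int(abs(marker_pos[mi] - start))
            key = (pval, dist, mi)
            if best is None or key < best[0]:
                best = (key, mi, stat, pval, dist)
        total_tests += idx.size
        _, mi, stat, pval, dist = best
        raw.append(
            CandidateHit(
                gene=gene,
                gene_index=gi,
                marker=data.marker_ids[mi],
                marker_index=int(mi),
                statistic=stat,
                pvalue=pval,
                n_tests=int(idx.size),
                distance_bp=dist,
                passed=False,
            )
        )

    tested = [h for h in raw if h.n_tests > 0]
    if tested:
        pvals = np.array([h.pvalue for h in tested])
        if config.correction == "bonferroni":
            passed = pvals * max(total_tests, 1) <= config.alpha
        elif config.correction == "bh":
            passed = multipletests(pvals, alpha=config.alpha, method="fdr_bh")[0]
        else:  # permutation p-values are already empirical
            passed = pvals <= config.alpha
        for h, ok in zip(tested, passed):
            h.passed = bool(ok)
    return ScreenResult(hits=raw, total_tests=total_tests)


def ld_prune(
    result: ScreenResult, genotypes: np.ndarray, r2_max: float
) -> ScreenResult:
    """Greedy pruning of passing hits to a pairwise-independent eQTL set.

    Candidates are visited in ascending p-value order; one is kept iff its
    genotype's squared Pearson correlation with every already-kept genotype
    does not exceed ``r2_max``.
    """
    candidates = sorted(
        result.passing(), key=lambda h: (h.pvalue, h.distance_bp, h.marker_index)
    )
    kept: list[CandidateHit] = []
    log: list[str] = []
    for hit in candidates:
        x = genotypes[:, hit.marker_index]
        ok = True
        for other in kept:
            xo = genotypes[:, other.marker_index]
            r = np.corrcoef(x, xo)[0, 1]
            if r * r > r2_max:
                log.append(
                    f"drop {hit.gene}/{hit.marker}: r2={r * r:.4f} with "
                    f"{other.gene}/{other.marker} exceeds {r2_max}"
                )
                ok = False
                break
        if ok:
            kept.append(hit)
    return ScreenResult(
        hits=result.hits,
        selected=kept,
        pruning_log=log,
        total_tests=result.total_tests,
    )


def run_screen(
    data: JointDataset,
    gene_map: pd.DataFrame,
    marker_map: pd.DataFrame,
    config: ScreenConfig,
    rng: np.random.Generator | None = None,
) -> ScreenResult:
    """Convenience wrapper: impute (if needed), scan, prune."""
    if data.has_missing():
        data = impute_missing(data)
    result = cis_scan(data, gene_map, marker_map, config, rng=rng)
    return ld_prune(result, data.genotypes, config.r2_max)
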