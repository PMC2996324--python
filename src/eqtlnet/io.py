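"""Tabular file formats and the end-to-end pipeline.

All tables are sample-major TSV (rows = samples, first column = sample ID)
with a header row; map files use 1-based bp coordinates.  Every output
written by the pipeline carries the master seed and a hash of the resolved
configuration in ``#``-prefixed header comments, so a run can be verified
and reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .model import DirectedNetwork, JointDataset
from .permfilter import filter_directed_edges, tests_to_frame
from .recover import fit_all_neighborhoods, interaction_graph, recover_directed
from .screen import ScreenConfig, run_screen
from .recover import standardize

__all__ = [
    "PipelineConfig",
    "read_dataset",
    "write_dataset",
    "write_network",
    "read_network",
    "run_pipeline",
]


VALID_GENOTYPES = {0.0, 1.0, 2.0}


@dataclasses.dataclass
class PipelineConfig:
    """Paths and stage settings for a full screen-recover-filter run."""

    expression: str
    genotypes: str
    gene_map: str
    marker_map: str
    out_dir: str
    screen: ScreenConfig = dataclasses.field(default_factory=ScreenConfig)
    rule: str = "AND"
    joint_cv: bool = False
    n_perm: int = 10_000
    perm_threshold: float = 0.90
    run_filter: bool = True
    seed: int = 0
    impute: bool = True

    def config_hash(self) -> str:
        """Fingerprint of the analysis settings (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        text = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str, **overrides: Any) -> "PipelineConfig":
        text = pathlib.Path(path).read_text()
        raw = yaml.safe_load(text)
        screen = ScreenConfig(**raw.pop("screen", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(screen=screen, **raw)


def _read_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        comment="#",
        index_col=0,
        na_values=["NA", "nan", ""],
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dups[:5]}")
    return df


def read_dataset(
    expression_path: str,
    genotype_path: str,
    impute: bool = True,
) -> JointDataset:
    """Load expression and genotype TSVs, aligning samples by ID.

    Genotype entries must be dosages in {0, 1, 2} or missing.  Mean
    imputation is applied when requested; otherwise NaN entries survive
    into the returned dataset.
    """
    expr = _read_table(expression_path)
    geno = _read_table(genotype_path)
    if set(expr.index) != set(geno.index):
        only_e = sorted(set(expr.index) - set(geno.index))[:5]
        only_g = sorted(set(geno.index) - set(expr.index))[:5]
        raise ValueError(
            f"sample ID mismatch between files (expression-only {only_e}, "
            f"genotype-only {only_g})"
        )
    geno = geno.loc[expr.index]  # realign rows by sample ID
    gvals = geno.to_numpy(dtype=float)
    bad = ~(np.isnan(gvals) | np.isin(gvals, list(VALID_GENOTYPES)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {gvals[r, c]!r} at sample "
            f"{geno.index[r]!r}, marker {geno.columns[c]!r}"
        )
    data = JointDataset(
        expression=expr.to_numpy(dtype=float),
        genotypes=gvals,
        gene_ids=list(expr.columns),
        marker_ids=list(geno.columns),
        sample_ids=list(expr.index.astype(str)),
    )
    if impute and data.has_missing():
        from .screen import impute_missing

        data = impute_missing(data)
    return data


def _header_lines(meta: dict[str, Any] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_dataset(
    data: JointDataset,
    expression_path: str,
    genotype_path: str,
    meta: dict[str, Any] | None = None,
) -> None:
    samples = data.sample_ids or [f"S{i:04d}" for i in range(data.n)]
    for path, values, cols in (
        (expression_path, data.expression, data.gene_ids),
        (genotype_path, data.genotypes, data.marker_ids),
    ):
        df = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"),
                          columns=cols)
        with open(path, "w") as fh:
            fh.write(_header_lines(meta))
            df.to_csv(fh, sep="\t")


def network_to_frame(network: DirectedNetwork,
                     labels: list[str] | None = None) -> pd.DataFrame:
    """Edge table with deterministic (source, target) lexicographic order."""
    lab = labels or [f"G{i:03d}" for i in range(network.p)]
    rows = [
        {
            "source": lab[s],
            "target": lab[t],
            "edge_type": "directed",
            "effect": eff,
            "provenance_eqtl": k,
        }
        for s, t, eff, k in network.directed_edges
    ]
    for e in network.undirected_edges:
        a, b = sorted(e)
        rows.append(
            {
                "source": lab[a],
                "target": lab[b],
                "edge_type": "undirected",
                "effect": np.nan,
                "provenance_eqtl": -1,
            }
        )
    df = pd.DataFrame(
        rows, columns=["source", "target", "edge_type", "effect", "provenance_eqtl"]
    )
    return df.sort_values(["source", "target"], kind="stable").reset_index(drop=True)


def write_network(
    network: DirectedNetwork,
    path: str,
    fmt: str = "tsv",
    labels: list[str] | None = None,
    meta: dict[str, Any] | None = None,
) -> None:
    """Write a recovered network as TSV, GraphML or SIF."""
    lab = labels or [f"G{i:03d}" for i in range(network.p)]
    if fmt == "tsv":
        df = network_to_frame(network, lab)
        with open(path, "w") as fh:
            fh.write(_header_lines(meta))
            df.to_csv(fh, sep="\t", index=False)
    elif fmt == "graphml":
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(lab)
        for s, t, eff, k in sorted(network.directed_edges):
            g.add_edge(lab[s], lab[t], edge_type="directed", effect=float(eff),
                       provenance_eqtl=int(k))
        for e in sorted(network.undirected_edges, key=sorted):
            a, b = sorted(e)
            g.add_edge(lab[a], lab[b], edge_type="undirected")
        for k, v in (meta or {}).items():
            g.graph[k] = str(v)
        nx.write_graphml(g, path)
    elif fmt == "sif":
        lines = [_header_lines(meta)] if meta else []
        for s, t, _, _ in sorted(network.directed_edges):
            lines.append(f"{lab[s]}\tregulates\t{lab[t]}\n")
        for e in sorted(network.undirected_edges, key=sorted):
            a, b = sorted(e)
            lines.append(f"{lab[a]}\tassoc\t{lab[b]}\n")
        pathlib.Path(path).write_text("".join(lines))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path: str, labels: list[str]) -> DirectedNetwork:
    """Parse a TSV edge table back into a network (inverse of tsv writing)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    index = {g: i for i, g in enumerate(labels)}
    directed = []
    undirected = set()
    for _, row in df.iterrows():
        s, t = index[row["source"]], index[row["target"]]
        if row["edge_type"] == "directed":
            directed.append((s, t, float(row["effect"]), int(row["provenance_eqtl"])))
        else:
            undirected.add(frozenset((s, t)))
    return DirectedNetwork(p=len(labels), directed_edges=directed,
                           undirected_edges=undirected)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Screen, recover, filter and write the output bundle.

    Stages: cis-eQTL screen with LD pruning; adaptive-lasso neighborhood
    selection on the reduced gene/eQTL set; directed recovery; permutation
    filter of the induced edges.  Failures surface with a stage label; no
    partial outputs are written before the failing stage completes.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    rng = np.random.default_rng(config.seed)

    try:
        data = read_dataset(config.expression, config.genotypes,
                            impute=config.impute)
        gene_map = pd.read_csv(config.gene_map, sep="\t", comment="#")
        marker_map = pd.read_csv(config.marker_map, sep="\t", comment="#")
    except Exception as exc:
        raise RuntimeError(f"[stage: input] {exc}") from exc

    try:
        screen_result = run_screen(data, gene_map, marker_map, config.screen,
                                   rng=rng)
    except Exception as exc:
        raise RuntimeError(f"[stage: screen] {exc}") from exc
    selected = screen_result.selected
    if not selected:
        raise RuntimeError("[stage: screen] no genes passed the cis screen")

    gene_idx = [h.gene_index for h in selected]
    marker_idx = [h.marker_index for h in selected]
    sub = JointDataset(
        expression=data.expression[:, gene_idx],
        genotypes=data.genotypes[:, marker_idx],
        gene_ids=[data.gene_ids[i] for i in gene_idx],
        marker_ids=[data.marker_ids[i] for i in marker_idx],
        sample_ids=data.sample_ids,
    )
    assignment = np.arange(len(selected))  # locus k is cis to selected gene k

    try:
        z = standardize(sub)
        fits = fit_all_neighborhoods(z, sub.p, rng=rng,
                                     joint_cv=config.joint_cv)
        graph = interaction_graph(fits, sub.p, sub.q, rule=config.rule)
        network = recover_directed(graph, assignment, fits)
    except Exception as exc:
        raise RuntimeError(f"[stage: recover] {exc}") from exc

    tests = []
    if config.run_filter:
        try:
            network, tests = filter_directed_edges(
                network, sub, rng, threshold=config.perm_threshold,
                n_perm=config.n_perm,
            )
        except Exception as exc:
            raise RuntimeError(f"[stage: filter] {exc}") from exc

    screen_path = out / "screen.tsv"
    with open(screen_path, "w") as fh:
        fh.write(_header_lines(meta))
        screen_result.to_frame().to_csv(fh, sep="\t", index=False)
    edges_path = out / "network.tsv"
    write_network(network, str(edges_path), fmt="tsv", labels=sub.gene_ids,
                  meta=meta)
    write_network(network, str(out / "network.graphml"), fmt="graphml",
                  labels=sub.gene_ids, meta=meta)
    if tests:
        with open(out / "permfilter.tsv", "w") as fh:
            fh.write(_header_lines(meta))
            tests_to_frame(tests).to_csv(fh, sep="\t", index=False)
    manifest = {
        **meta,
        "n_samples": sub.n,
        "n_genes_screened": data.p,
        "n_genes_selected": sub.p,
        "n_directed_edges": len(network.directed_edges),
        "n_undirected_edges": len(network.undirected_edges),
        "stages": ["screen", "recover"] + (["filter"] if config.run_filter else []),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {"network": network, "screen": screen_result, "tests": tests,
            "manifest": manifest, "dataset": sub}
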