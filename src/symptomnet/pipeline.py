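"""End-to-end analysis orchestration: config, run, artifact writers.

``run_pipeline`` executes polychoric estimation → EBIC glasso → centrality
→ bootstrap diagnostics from a single :class:`RunConfig`, writes every
artifact file (TSV edge list / adjacency / node metrics / CIs / difference
matrices, GraphML, consolidated JSON report), and returns the report as a
plain dict.  All defaults are echoed into the report, so a report alone
fully specifies its run, and rerunning the same config + seed reproduces
the JSON byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import (DEFAULT_DROP_GRID, StabilityReport,
                        stability_analysis)
from .centrality import (centrality_table, network_descriptors, rank_nodes)
from .data import (Item, ItemResponseMatrix, MISSING, read_metadata,
                   validate_input)
from .errors import ValidationError
from .glasso import NetworkModel, estimate_network

log = logging.getLogger("symptomnet")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    input: str | None = None            # responses CSV
    metadata: str | None = None         # item metadata YAML
    gamma: float = 0.5
    n_lambda: int = 100
    min_ratio: float = 0.01
    bootstraps: int = 1000
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    b_per_level: int | None = None      # defaults to ``bootstraps``
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"
    cutoffs: dict[str, int] = field(default_factory=dict)
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        self.drop_grid = tuple(float(q) for q in self.drop_grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ValidationError(f"cannot read config {path}: {exc}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        d = asdict(self)
        d["drop_grid"] = list(self.drop_grid)
        # worker count is an execution detail: results are identical for
        # any n_jobs, and the echoed config must be too
        d.pop("n_jobs")
        return d


@dataclass
class ScaleScores:
    """Row-sum scale scores for one community of items."""

    sums: np.ndarray
    mean: float
    sd: float
    n_complete: int
    n_excluded: int
    cutoff: int | None
    proportion_at_or_above: float | None


def scale_scores(data: ItemResponseMatrix, community: str,
                 cutoff: int | None = None) -> ScaleScores:
    """Per-respondent sum score over one community's items, with
    descriptive statistics and an optional proportion meeting a cutoff.
    Respondents missing any item of the scale are excluded listwise within
    the scale, with a count."""
    cols = [j for j, it in enumerate(data.items) if it.community == community]
    if not cols:
        raise ValidationError(f"no items in community {community!r}")
    block = data.values[:, cols]
    complete = np.all(block != MISSING, axis=1)
    sums = block[complete].sum(axis=1)
    n_complete = int(complete.sum())
    if n_complete == 0:
        raise ValidationError(
            f"no complete respondents for community {community!r}")
    mean = float(sums.mean())
    sd = float(sums.std(ddof=1)) if n_complete > 1 else 0.0
    prop = None
    if cutoff is not None:
        prop = float((sums >= cutoff).mean())
    return ScaleScores(sums, mean, sd, n_complete,
                       int(data.n - n_complete), cutoff, prop)


# ---------------------------------------------------------------------------
# artifact writers

def write_edge_list(net: NetworkModel, path: Path) -> None:
    rows = []
    comm = net.communities
    iu = np.triu_indices(net.p, k=1)
    for i, j in zip(*iu):
        rows.append((net.node_labels[i], net.node_labels[j],
                     net.weights[i, j], comm[i] == comm[j]))
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight",
                                "same_community"]
                 ).to_csv(path, sep="\t", index=False)


def write_adjacency(net: NetworkModel, path: Path) -> None:
    pd.DataFrame(net.weights, index=net.node_labels,
                 columns=net.node_labels).to_csv(path, sep="\t")


def write_graphml(net: NetworkModel, path: Path) -> None:
    G = nx.Graph()
    for label, comm in zip(net.node_labels, net.communities):
        G.add_node(label, community=comm)
    iu = np.triu_indices(net.p, k=1)
    for i, j in zip(*iu):
        w = net.weights[i, j]
        if w != 0.0:
            G.add_edge(net.node_labels[i], net.node_labels[j],
                       weight=float(w))
    nx.write_graphml(G, path)


def write_ebic_path(net: NetworkModel, path: Path) -> None:
    pd.DataFrame(net.ebic_path, columns=["lambda", "ebic", "n_edges"]
                 ).to_csv(path, sep="\t", index=False)


def write_node_metrics(table: pd.DataFrame, path: Path) -> None:
    out = table.copy()
    out["ei_rank"] = out["ei"].rank(ascending=False, method="min").astype(int)
    out["bei_rank"] = out["bei"].rank(ascending=False,
                                      method="min").astype(int)
    out.to_csv(path, sep="\t")


def write_diff_matrix(sig: np.ndarray, names: list[str], path: Path) -> None:
    pd.DataFrame(sig.astype(int), index=names, columns=names
                 ).to_csv(path, sep="\t")


def write_pair_n(pair_n: np.ndarray, labels: list[str], path: Path) -> None:
    pd.DataFrame(pair_n, index=labels, columns=labels
                 ).to_csv(path, sep="\t")


def _py(x):
    """Recursively convert numpy scalars/arrays for JSON."""
    if isinstance(x, dict):
        return {k: _py(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_py(v) for v in x]
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_py(v) for v in x.tolist()]
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def report_json(report: dict) -> str:
    return json.dumps(_py(report), sort_keys=True, indent=2) + "\n"


# ---------------------------------------------------------------------------

def _descriptor_block(net: NetworkModel) -> dict:
    desc = network_descriptors(net.weights)
    labels = net.node_labels

    def _edge(e):
        if e is None:
            return None
        (i, j), w = e
        return {"nodes": [labels[i], labels[j]], "weight": w}

    return {
        "density": desc.density,
        "mean_weight": desc.mean_weight,
        "mean_abs_weight": desc.mean_abs_weight,
        "n_edges": desc.n_edges,
        "n_positive": desc.n_positive,
        "n_negative": desc.n_negative,
        "strongest_positive_edge": _edge(desc.strongest_positive),
        "strongest_negative_edge": _edge(desc.strongest_negative),
        "selected_penalty": net.selected_penalty,
        "gamma": net.gamma,
        "n_effective": net.n_effective,
    }


def run_pipeline(config: RunConfig,
                 data: ItemResponseMatrix | None = None) -> dict:
    """Execute the full analysis and write all artifacts to
    ``config.out_dir``.  ``data`` may be passed directly (e.g. freshly
    simulated); otherwise it is read from ``config.input`` and validated
    against ``config.metadata``."""
    t0 = time.time()
    if data is None:
        if config.input is None or config.metadata is None:
            raise ValidationError("config must name input and metadata files")
        items = read_metadata(config.metadata)
        data = validate_input(config.input, items)
    if len(set(data.communities)) < 2:
        raise ValidationError(
            "bridge expected influence requires >= 2 communities; "
            f"got {sorted(set(data.communities))}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: n=%d p=%d seed=%d", data.n, data.p,
             config.seed)

    # scale scores per community
    scales = {}
    for comm in sorted(set(data.communities)):
        s = scale_scores(data, comm, config.cutoffs.get(comm))
        scales[comm] = {
            "mean": s.mean, "sd": s.sd, "n_complete": s.n_complete,
            "n_excluded": s.n_excluded, "cutoff": s.cutoff,
            "proportion_at_or_above": s.proportion_at_or_above,
        }

    t = time.time()
    net = estimate_network(data, gamma=config.gamma,
                           n_lambda=config.n_lambda,
                           min_ratio=config.min_ratio)
    log.info("network estimated in %.1fs: %d edges, lambda=%.4g",
             time.time() - t, _descriptor_block(net)["n_edges"],
             net.selected_penalty)

    table = centrality_table(net.weights, net.node_labels, net.communities)
    ei_order, ei_ties = rank_nodes(table, "ei")
    bei_order, bei_ties = rank_nodes(table, "bei")

    t = time.time()
    stab = stability_analysis(
        data, net, B=config.bootstraps, drop_grid=config.drop_grid,
        B_per_level=config.b_per_level, seed=config.seed,
        alpha=config.alpha, gamma=config.gamma, n_lambda=config.n_lambda,
        min_ratio=config.min_ratio, n_jobs=config.n_jobs)
    log.info("bootstrap finished in %.1fs: CS=%.4g", time.time() - t,
             stab.cs_coefficient)

    _write_artifacts(out, net, table, stab)

    report = {
        "software": {"package": "symptomnet", "version": __version__},
        "config": config.echo(),
        "sample": {"n": data.n, "p": data.p, "scales": scales},
        "network": _descriptor_block(net),
        "centrality": {
            "nodes": {
                lb: {"community": table.loc[lb, "community"],
                     "ei": float(table.loc[lb, "ei"]),
                     "bei": float(table.loc[lb, "bei"])}
                for lb in net.node_labels
            },
            "ei_order": ei_order, "ei_ties": ei_ties,
            "bei_order": bei_order, "bei_ties": bei_ties,
        },
        "stability": {
            "cs_coefficient": stab.cs_coefficient,
            "cs_ci": stab.cs_ci,
            "B": stab.B,
            "alpha": stab.alpha,
            "drop_grid": list(stab.drop_grid),
            "n_failures_nonparametric": stab.n_failures_nonparametric,
            "n_failures_case_drop": stab.n_failures_case_drop,
            "n_significant_edge_pairs":
                int(stab.edge_diff_significant.sum()) // 2,
            "n_significant_ei_pairs":
                int(stab.ei_diff_significant.sum()) // 2,
        },
    }
    (out / "report.json").write_text(report_json(report))
    log.info("pipeline done in %.1fs", time.time() - t0)
    return report


def _write_artifacts(out: Path, net: NetworkModel, table: pd.DataFrame,
                     stab: StabilityReport) -> None:
    write_edge_list(net, out / "edges.tsv")
    write_adjacency(net, out / "adjacency.tsv")
    write_graphml(net, out / "network.graphml")
    write_ebic_path(net, out / "ebic_path.tsv")
    write_node_metrics(table, out / "node_metrics.tsv")
    if net.correlation is not None:
        write_adjacency_matrix(net.correlation.matrix, net.node_labels,
                               out / "polychoric.tsv")
        write_pair_n(net.correlation.pair_n, net.node_labels,
                     out / "pair_n.tsv")
    stab.edge_ci.to_csv(out / "edge_ci.tsv", sep="\t", index=False)
    stab.cor_by_drop.to_csv(out / "ei_correlation_by_drop.tsv", sep="\t",
                            index=False)
    edge_names = [f"{a}--{b}" for a, b in
                  zip(stab.edge_ci["node_a"], stab.edge_ci["node_b"])]
    write_diff_matrix(stab.edge_diff_significant, edge_names,
                      out / "edge_diff_significant.tsv")
    write_diff_matrix(stab.ei_diff_significant, net.node_labels,
                      out / "ei_diff_significant.tsv")


def write_adjacency_matrix(matrix: np.ndarray, labels: list[str],
                           path: Path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")
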