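"""Interaction-network partition statistics for two differential gene sets.

Given the subtype-preferential gene sets A and B (which may share genes, as
CDH1/RHOA-like drivers do) and a scored interaction edge table, the induced
subgraph over A ∪ B is split into:

* in-A edges — both endpoints exclusive to A;
* in-B edges — both endpoints exclusive to B;
* inter edges — one exclusive-A and one exclusive-B endpoint;
* shared-incident edges — edges touching a gene in A ∩ B.

For each exclusive gene the fractions of its incident edges that are
within-set (f_in) vs. cross-set (f_inter) are computed; edges to shared genes
count as within-set for the exclusive endpoint, so f_in + f_inter = 1 for any
gene with at least one edge. A paired t-test on d_g = f_in - f_inter per set
asks whether each set is more internally connected than cross-connected.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "induce_subgraph",
    "classify_edges",
    "paired_edge_test",
    "PartitionStats",
    "NetworkPartition",
    "NetworkPartitionResults",
]


def _as_graph(edges) -> nx.Graph:
    if isinstance(edges, nx.Graph):
        return edges
    graph = nx.Graph()
    df = edges
    cols = [c for c in ("gene_a", "gene_b", "score") if c in df.columns]
    if len(cols) != 3:
        raise ValueError("edge frame needs columns gene_a, gene_b, score")
    for u, v, s in zip(df["gene_a"].astype(str), df["gene_b"].astype(str), df["score"]):
        if u == v:
            continue
        if graph.has_edge(u, v):
            graph[u][v]["score"] = max(graph[u][v]["score"], float(s))
        else:
            graph.add_edge(u, v, score=float(s))
    return graph


def induce_subgraph(
    edges: nx.Graph | pd.DataFrame,
    set_a: Iterable[str],
    set_b: Iterable[str],
    min_score: float = 0.4,
) -> nx.Graph:
    """Edges with both endpoints in A ∪ B and score >= ``min_score``."""
    graph = _as_graph(edges)
    keep = set(set_a) | set(set_b)
    sub = nx.Graph()
    sub.add_nodes_from(n for n in graph.nodes if n in keep)
    for u, v, data in graph.edges(data=True):
        if u in keep and v in keep and data.get("score", 1.0) >= min_score:
            sub.add_edge(u, v, **data)
    return sub


@dataclass
class PartitionStats:
    """Edge-class counts, per-gene fractions, and the paired tests."""

    n_inter: int
    n_in_a: int
    n_in_b: int
    n_shared_incident: int
    per_gene: pd.DataFrame
    labels: tuple[str, str] = ("A", "B")
    t_a: float = math.nan
    p_a: float = math.nan
    t_b: float = math.nan
    p_b: float = math.nan

    @property
    def n_shared_edges(self) -> int:
        """Edges bridging the two exclusive sets (the 'between' count)."""
        return self.n_inter

    @property
    def n_total(self) -> int:
        return self.n_inter + self.n_in_a + self.n_in_b + self.n_shared_incident


def classify_edges(
    sub: nx.Graph, set_a: Iterable[str], set_b: Iterable[str]
) -> PartitionStats:
    """Classify induced-subgraph edges and compute per-gene edge fractions.

    Counters are disjoint: an edge touching a shared (A ∩ B) gene is counted
    only in ``n_shared_incident``. In the per-gene fraction series, however,
    an exclusive gene's edge to a shared gene counts as a within-set edge
    (shared genes are the connectors of the two sub-networks); shared genes
    themselves contribute no fraction row.
    """
    set_a, set_b = set(set_a), set(set_b)
    shared = set_a & set_b
    only_a = set_a - shared
    only_b = set_b - shared
    n_in_a = n_in_b = n_inter = n_shared_inc = 0
    in_edges: dict[str, int] = {}
    inter_edges: dict[str, int] = {}
    degree: dict[str, int] = {}

    def _bump(gene: str, kind: str) -> None:
        degree[gene] = degree.get(gene, 0) + 1
        if kind == "in":
            in_edges[gene] = in_edges.get(gene, 0) + 1
        else:
            inter_edges[gene] = inter_edges.get(gene, 0) + 1

    for u, v in sub.edges():
        u_sh, v_sh = u in shared, v in shared
        if u_sh or v_sh:
            n_shared_inc += 1
            # shared-gene policy: within-set for the exclusive endpoint
            if not u_sh:
                _bump(u, "in")
            if not v_sh:
                _bump(v, "in")
            continue
        if u in only_a and v in only_a:
            n_in_a += 1
            _bump(u, "in")
            _bump(v, "in")
        elif u in only_b and v in only_b:
            n_in_b += 1
            _bump(u, "in")
            _bump(v, "in")
        else:
            n_inter += 1
            _bump(u, "inter")
            _bump(v, "inter")

    rows = []
    for gene in sorted(only_a | only_b):
        deg = degree.get(gene, 0)
        if deg == 0:
            continue
        f_in = in_edges.get(gene, 0) / deg
        f_inter = inter_edges.get(gene, 0) / deg
        rows.append(
            {
                "gene": gene,
                "set_label": "A" if gene in only_a else "B",
                "degree": deg,
                "f_in": f_in,
                "f_inter": f_inter,
            }
        )
    per_gene = pd.DataFrame(
        rows, columns=["gene", "set_label", "degree", "f_in", "f_inter"]
    ).set_index("gene")
    return PartitionStats(
        n_inter=n_inter,
        n_in_a=n_in_a,
        n_in_b=n_in_b,
        n_shared_incident=n_shared_inc,
        per_gene=per_gene,
    )


def paired_edge_test(
    f_in: Iterable[float], f_inter: Iterable[float]
) -> tuple[float, float]:
    """Two-sided paired t-test on d_g = f_in - f_inter across genes.

    Genes enter one pair each; the caller excludes zero-degree genes. When
    every d_g is identical the t statistic is degenerate: p = 0 (with a
    warning) if the common difference is non-zero, else (t, p) = (0, 1).
    """
    d = np.asarray(list(f_in), dtype=float) - np.asarray(list(f_inter), dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired test needs at least two genes with counted edges")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean != 0.0:
            logger.warning(
                "all per-gene differences identical (%.3g); p reported as 0", mean
            )
            return (math.inf if mean > 0 else -math.inf, 0.0)
        return (0.0, 1.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return (float(t), float(min(p, 1.0)))


class NetworkPartition:
    """Model: two differential gene sets against a scored interaction graph.

    ``fit()`` induces the subgraph at ``min_score``, classifies edges,
    computes per-gene fractions, and runs the paired t-test per set.
    """

    def __init__(
        self,
        edges: nx.Graph | pd.DataFrame,
        set_a: Iterable[str],
        set_b: Iterable[str],
        min_score: float = 0.4,
        labels: tuple[str, str] = ("A", "B"),
    ) -> None:
        self.edges = _as_graph(edges)
        self.set_a = set(set_a)
        self.set_b = set(set_b)
        self.min_score = min_score
        self.labels = labels

    def fit(self) -> "NetworkPartitionResults":
        if not self.set_a or not self.set_b:
            logger.warning("one or both gene sets are empty; statistics will be empty")
        sub = induce_subgraph(self.edges, self.set_a, self.set_b, self.min_score)
        stats_ = classify_edges(sub, self.set_a, self.set_b)
        stats_.labels = self.labels
        for side, label in (("a", "A"), ("b", "B")):
            rows = stats_.per_gene[stats_.per_gene["set_label"] == label]
            if len(rows) >= 2:
                t, p = paired_edge_test(rows["f_in"], rows["f_inter"])
                setattr(stats_, f"t_{side}", t)
                setattr(stats_, f"p_{side}", p)
        return NetworkPartitionResults(stats_, sub, self)


class NetworkPartitionResults:
    """Fitted partition: counts, per-gene fractions, paired-t results."""

    def __init__(
        self, stats_: PartitionStats, subgraph: nx.Graph, model: NetworkPartition
    ) -> None:
        self.stats = stats_
        self.subgraph = subgraph
        self.model = model

    # convenience pass-throughs
    @property
    def per_gene(self) -> pd.DataFrame:
        return self.stats.per_gene

    def to_dict(self) -> dict:
        s = self.stats
        la, lb = s.labels
        return {
            "labels": list(s.labels),
            "n_inter_edges": s.n_inter,
            f"n_in_{la}": s.n_in_a,
            f"n_in_{lb}": s.n_in_b,
            "n_shared_incident_edges": s.n_shared_incident,
            "n_edges_total": s.n_total,
            f"t_{la}": None if math.isnan(s.t_a) else s.t_a,
            f"p_{la}": None if math.isnan(s.p_a) else s.p_a,
            f"t_{lb}": None if math.isnan(s.t_b) else s.t_b,
            f"p_{lb}": None if math.isnan(s.p_b) else s.p_b,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def export_graphml(self, path: str | Path) -> None:
        """Write the induced subgraph (with set membership attributes) as GraphML."""
        g = self.subgraph.copy()
        shared = self.model.set_a & self.model.set_b
        for node in g.nodes:
            if node in shared:
                g.nodes[node]["set"] = "shared"
            elif node in self.model.set_a:
                g.nodes[node]["set"] = self.stats.labels[0]
            else:
                g.nodes[node]["set"] = self.stats.labels[1]
        nx.write_graphml(g, path)

    def summary(self) -> str:
        s = self.stats
        la, lb = s.labels
        lines = [
            "Network partition statistics",
            "=" * 48,
            f"sets:                  {la} (n={len(self.model.set_a)}), "
            f"{lb} (n={len(self.model.set_b)}), "
            f"shared {len(self.model.set_a & self.model.set_b)}",
            f"min edge score:        {self.model.min_score}",
            f"edges in subgraph:     {s.n_total}",
            f"in-{la} edges:            {s.n_in_a}",
            f"in-{lb} edges:            {s.n_in_b}",
            f"inter edges:           {s.n_inter}",
            f"shared-incident edges: {s.n_shared_incident}",
            "-" * 48,
            f"paired t ({la}): t = {s.t_a:.4g}, p = {s.p_a:.4g}",
            f"paired t ({lb}): t = {s.t_b:.4g}, p = {s.p_b:.4g}",
        ]
        return "\n".join(lines)
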