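"""Centrality analysis and tie-aware TOP-k pivotal-node calling.

Three exact (non-sampled) centralities are computed for every node of the
ceRNA network:

* degree — number of incident edges;
* betweenness — for each unordered pair (s, t), the fraction of shortest
  s-t paths passing through the node (endpoints excluded), summed over
  pairs; reported unnormalized by default;
* closeness — the Wasserman-Faust component-scaled form
  ((reachable-1)/(n-1)) * (reachable-1)/sum(dist), which stays comparable
  across components of a disconnected graph; isolated nodes score 0.

A node is *pivotal* when it lies in the TOP-k sets of all three metrics
simultaneously.  TOP-k is tie-inclusive: every node whose value ties the
k-th largest is kept, so results are deterministic and never depend on an
arbitrary tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

METRICS = ("degree", "betweenness", "closeness")


class TopologyError(ValueError):
    pass


def centralities(network: nx.Graph, normalized: bool = False) -> pd.DataFrame:
    """Exact degree / betweenness / closeness per node.

    ``normalized=True`` divides betweenness by the number of ordered node
    pairs excluding the node (the usual rescaling); degree and closeness
    are unaffected (closeness is already on [0, 1]).
    """
    if network.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node_id", "type", *METRICS])
    deg = dict(network.degree())
    btw = nx.betweenness_centrality(network, normalized=normalized)
    clo = nx.closeness_centrality(network, wf_improved=True)
    rows = [
        {
            "node_id": n,
            "type": network.nodes[n].get("type", ""),
            "degree": deg[n],
            "betweenness": btw[n],
            "closeness": clo[n],
        }
        for n in network.nodes
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["degree", "node_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def topk(report: pd.DataFrame, metric: str, k: int = 100) -> set[str]:
    """Tie-inclusive top-k node set for one metric.

    Every node with value >= the k-th largest value is included, so the
    set has at least min(k, n) members and may exceed k on ties.
    """
    if metric not in METRICS:
        raise TopologyError(f"unknown metric {metric!r}")
    if k < 1:
        raise TopologyError("k must be >= 1")
    if len(report) == 0:
        return set()
    values = report[metric].sort_values(ascending=False).to_numpy()
    threshold = values[min(k, len(values)) - 1]
    return set(report.loc[report[metric] >= threshold, "node_id"])


@dataclass
class PivotalSet:
    """TOP-k sets per metric, their triple intersection, and Venn regions."""

    k: int
    top_sets: dict[str, set[str]]
    intersection: set[str]
    venn_regions: dict[str, int]
    members_by_type: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "top_set_sizes": {m: len(s) for m, s in self.top_sets.items()},
            "intersection": sorted(self.intersection),
            "venn_regions": self.venn_regions,
            "members_by_type": self.members_by_type,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def pivotal_nodes(report: pd.DataFrame, k: int = 100) -> PivotalSet:
    """Intersect the three tie-inclusive TOP-k sets and count Venn regions.

    The seven regions are keyed by the metrics a node belongs to
    (e.g. ``degree_only``, ``degree+betweenness``, ``all_three``); their
    counts sum to the size of the union of the three sets.
    """
    d = topk(report, "degree", k)
    b = topk(report, "betweenness", k)
    c = topk(report, "closeness", k)
    inter = d & b & c
    regions = {
        "degree_only": len(d - b - c),
        "betweenness_only": len(b - d - c),
        "closeness_only": len(c - d - b),
        "degree+betweenness": len((d & b) - c),
        "degree+closeness": len((d & c) - b),
        "betweenness+closeness": len((b & c) - d),
        "all_three": len(inter),
    }
    types = dict(zip(report["node_id"], report["type"]))
    by_type: dict[str, list[str]] = {}
    for node in sorted(inter):
        by_type.setdefault(types.get(node, ""), []).append(node)
    return PivotalSet(
        k=k,
        top_sets={"degree": d, "betweenness": b, "closeness": c},
        intersection=inter,
        venn_regions=regions,
        members_by_type=by_type,
    )


def write_centralities(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.8g")
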