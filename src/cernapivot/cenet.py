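"""ceRNA network construction: co-expression plus miRNA-target support.

The competing-endogenous-RNA hypothesis predicts that a lncRNA sponging
shared miRNAs is positively correlated with the mRNAs it de-represses.  The
network is therefore built in three passes:

1. ``correlation_edges`` — Pearson correlation of every (lncRNA, mRNA) pair
   on log2(fpkm + 1) across all samples, with the exact t-transform p-value
   (t = r * sqrt(n-2) / sqrt(1-r^2), two-sided, n-2 df);
2. ``filter_correlation`` — keep p < 0.05 and r >= 0.6 (inclusive on r;
   an absolute-value mode admits negative correlations);
3. ``cross_reference`` — keep only pairs supported by at least
   ``min_shared`` miRNAs targeting both partners in the interaction table,
   recording the shared miRNA ids on the edge.

``build_cerna`` expands the surviving lncRNA-mRNA edges into the
mRNA-lncRNA-miRNA network: shared miRNAs become nodes with targeting edges
to both partners.  The result is an undirected simple graph exportable as
SIF / edge-list TSV for Cytoscape.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expr import ExpressionError, ExpressionMatrix

EDGE_COLUMNS = ["lncrna_id", "mrna_id", "r", "p_value", "n_samples", "shared_mirnas"]


def correlation_edges(
    matrix: ExpressionMatrix,
    lnc_ids: Sequence[str],
    mrna_ids: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlation of every (lncRNA, mRNA) pair on log2(fpkm + 1).

    Pools all samples (tumor + control).  Pairs where either gene is
    constant get r = NaN and are excluded by the downstream filter.
    """
    if matrix.unit not in ("fpkm", "log2fpkm"):
        raise ExpressionError("correlation_edges expects fpkm or log2fpkm")
    n = matrix.values.shape[1]
    if n < 3:
        raise ExpressionError("need >= 3 samples for a correlation p-value")
    missing = (set(lnc_ids) | set(mrna_ids)) - set(matrix.gene_ids)
    if missing:
        raise ExpressionError(f"gene ids absent from matrix: {sorted(missing)[:5]}")

    x = matrix.values.loc[list(lnc_ids)].to_numpy(dtype=float)
    y = matrix.values.loc[list(mrna_ids)].to_numpy(dtype=float)
    if matrix.unit == "fpkm":
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)  # exact collinearity

    li = np.repeat(np.arange(len(lnc_ids)), len(mrna_ids))
    mi = np.tile(np.arange(len(mrna_ids)), len(lnc_ids))
    return pd.DataFrame(
        {
            "lncrna_id": np.asarray(lnc_ids, dtype=object)[li],
            "mrna_id": np.asarray(mrna_ids, dtype=object)[mi],
            "r": r.ravel(),
            "p_value": p.ravel(),
            "n_samples": n,
            "shared_mirnas": [None] * (len(lnc_ids) * len(mrna_ids)),
        }
    )


def filter_correlation(
    edges: pd.DataFrame,
    alpha: float = 0.05,
    r_min: float = 0.6,
    sign_mode: str = "positive",
) -> pd.DataFrame:
    """Keep edges with p < alpha and r >= r_min (or |r| >= r_min).

    ``sign_mode='positive'`` (the ceRNA default) requires r >= r_min;
    ``'absolute'`` requires |r| >= r_min.  NaN correlations (constant
    genes) are always dropped.
    """
    if not 0.0 < r_min <= 1.0:
        raise ExpressionError("r_min must lie in (0, 1]")
    if sign_mode not in ("positive", "absolute"):
        raise ExpressionError(f"unknown sign_mode {sign_mode!r}")
    r = edges["r"]
    ok = edges["p_value"].lt(alpha) & r.notna()
    ok &= r.ge(r_min) if sign_mode == "positive" else r.abs().ge(r_min)
    return edges.loc[ok].reset_index(drop=True)


def cross_reference(
    edges: pd.DataFrame, table: pd.DataFrame, min_shared: int = 1
) -> pd.DataFrame:
    """Keep edges whose endpoints share >= min_shared targeting miRNAs.

    ``table`` is an interaction table with columns mirna_id, target_id.
    Shared miRNA ids are recorded (sorted) in the shared_mirnas column.
    """
    targets: dict[str, set[str]] = {}
    for mir, tgt in zip(table["mirna_id"], table["target_id"]):
        targets.setdefault(tgt, set()).add(mir)
    keep, shared_col = [], []
    for row in edges.itertuples(index=False):
        shared = sorted(
            targets.get(row.lncrna_id, set()) & targets.get(row.mrna_id, set())
        )
        if len(shared) >= min_shared:
            keep.append(True)
            shared_col.append(shared)
        else:
            keep.append(False)
    out = edges.loc[keep].reset_index(drop=True)
    out["shared_mirnas"] = shared_col
    return out


def build_cerna(edges: pd.DataFrame, table: pd.DataFrame | None = None) -> nx.Graph:
    """Expand cross-referenced edges into the mRNA-lncRNA-miRNA network.

    Nodes are the lncRNAs/mRNAs of surviving correlation edges plus every
    shared miRNA; edges are the correlation edges (kind='correlation') plus
    miRNA targeting edges to both partners (kind='targeting').  Undirected,
    no self-loops, no duplicates.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.lncrna_id, type="lncRNA")
        g.add_node(row.mrna_id, type="mRNA")
        g.add_edge(row.lncrna_id, row.mrna_id, kind="correlation",
                   r=float(row.r), p_value=float(row.p_value))
        for mir in row.shared_mirnas or []:
            g.add_node(mir, type="miRNA")
            g.add_edge(mir, row.lncrna_id, kind="targeting")
            g.add_edge(mir, row.mrna_id, kind="targeting")
    return g


# -- export / import -------------------------------------------------------

def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Cytoscape SIF: one 'a <kind> b' line per edge."""
    with open(path, "w") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{data.get('kind', 'link')}\t{b}\n")
        for node in sorted(n for n in g.nodes if g.degree(n) == 0):
            fh.write(f"{node}\n")


def write_network(g: nx.Graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Edge-list TSV plus a node-attribute TSV (Cytoscape-loadable)."""
    rows = [
        {"source": a, "target": b, "kind": d.get("kind", "link"),
         "r": d.get("r", ""), "p_value": d.get("p_value", "")}
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "kind", "r", "p_value"]).to_csv(
        edges_path, sep="\t", index=False
    )
    nodes = [{"node_id": n, "type": d.get("type", "")} for n, d in
             sorted(g.nodes(data=True))]
    pd.DataFrame(nodes, columns=["node_id", "type"]).to_csv(
        nodes_path, sep="\t", index=False
    )


def read_network(edges_path: str | Path, nodes_path: str | Path) -> nx.Graph:
    g = nx.Graph()
    nodes = pd.read_csv(nodes_path, sep="\t")
    for row in nodes.itertuples(index=False):
        g.add_node(row.node_id, type=row.type)
    edges = pd.read_csv(edges_path, sep="\t")
    for row in edges.itertuples(index=False):
        attrs = {"kind": row.kind}
        if pd.notna(row.r) and row.r != "":
            attrs["r"] = float(row.r)
        if pd.notna(row.p_value) and row.p_value != "":
            attrs["p_value"] = float(row.p_value)
        g.add_edge(row.source, row.target, **attrs)
    return g


def write_edges_table(edges: pd.DataFrame, path: str | Path) -> None:
    out = edges.copy()
    out["shared_mirnas"] = [
        ",".join(s) if isinstance(s, (list, tuple)) else ""
        for s in out["shared_mirnas"]
    ]
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")
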