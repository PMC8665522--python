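"""Over-representation analysis of DE genes with expression-trend scoring.

Each gene set is tested with the one-sided hypergeometric (Fisher upper
tail) test: with a universe of N genes of which n are differentially
expressed, a term of K universe members showing k DE genes has

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

Benjamini-Hochberg adjustment is applied across the collection.  Each term
also receives the trend z-score

    z_trend = (up - down) / sqrt(up + down)

over its DE members, summarizing whether the term's signal is up- or
downregulated; the enrichment score is -log10 p.  The universe defaults to
the genes actually tested for DE, guarding against detection bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit universe."""

    terms: dict[str, list[str]]                  # term_id -> member gene ids
    names: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for tid, members in self.terms.items():
            if len(members) != len(set(members)):
                self.terms[tid] = sorted(set(members))


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    k = overlap, K = term size in the universe, n = DE genes in the
    universe, N = universe size.  k = 0 gives p = 1 exactly.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise EnrichmentError(
            f"inconsistent margins k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_collection(
    de_status: Mapping[str, str] | pd.DataFrame,
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every term of a collection for DE-gene over-representation.

    ``de_status`` maps gene_id -> status ('up'/'down'), or is a DEResult
    table from which up/down rows are taken.  Terms and DE genes are
    intersected with the universe first; only terms with overlap k >= 1 are
    reported.  Returns a table sorted by raw p with BH-adjusted p-values,
    enrichment score and trend z-score.
    """
    if isinstance(de_status, pd.DataFrame):
        sub = de_status[de_status["status"].isin(["up", "down"])]
        de_status = dict(zip(sub["gene_id"], sub["status"]))
    if universe is None:
        universe = collection.universe
    if universe is None:
        raise EnrichmentError("a universe is required (none on the collection)")
    universe_set = set(universe)
    if not universe_set:
        raise EnrichmentError("empty universe")
    de_in_universe = {g: s for g, s in de_status.items() if g in universe_set}
    N = len(universe_set)
    n = len(de_in_universe)

    rows = []
    for tid, members in collection.terms.items():
        term = set(members) & universe_set
        K = len(term)
        overlap = [g for g in term if g in de_in_universe]
        k = len(overlap)
        if K == 0 or k == 0:
            continue
        up = sum(1 for g in overlap if de_in_universe[g] == "up")
        down = k - up
        p = hypergeom_p(k, K, n, N)
        rows.append(
            {
                "term_id": tid,
                "term_name": collection.names.get(tid, tid),
                "N": N, "K": K, "n": n, "k": k,
                "p_value": p,
                "enrichment_score": -np.log10(max(p, 1e-300)),
                "z_trend": (up - down) / np.sqrt(up + down),
                "up": up, "down": down,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "N", "K", "n", "k", "p_value",
                 "enrichment_score", "z_trend", "up", "down"],
    )
    if len(table):
        table["adj_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values(
            ["p_value", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["adj_p"] = pd.Series(dtype=float)
    return table


# -- GMT I/O ---------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file: term, description, member genes."""
    terms: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(f"malformed GMT line: {line[:60]!r}")
            tid, desc, members = parts[0], parts[1], parts[2:]
            if tid in terms:
                raise EnrichmentError(f"duplicate term {tid}")
            terms[tid] = [m for m in members if m]
            names[tid] = desc
    return GeneSetCollection(terms=terms, names=names)


def write_gmt(collection: GeneSetCollection | Mapping[str, list[str]],
              path: str | Path) -> None:
    if not isinstance(collection, GeneSetCollection):
        collection = GeneSetCollection(terms=dict(collection))
    with open(path, "w") as fh:
        for tid, members in collection.terms.items():
            desc = collection.names.get(tid, tid)
            fh.write("\t".join([tid, desc, *members]) + "\n")
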