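"""Differential-expression screening and figure-ready summaries.

Genes are tested tumor vs control with Welch's two-sample t-test on
log2(fpkm + 1); the fold change is log2((mean_tumor + 1)/(mean_control + 1))
on FPKM means.  A gene is called differentially expressed when p < 0.05 and
|log2FC| > 1 (both strict), the usual screening rule for small paired
case-control bulk studies; Benjamini-Hochberg adjusted p-values are reported
alongside but do not enter the default call.

Degenerate genes with zero variance in both groups get p = 1 when the group
means agree and p = 0 (flagged ``degenerate``) when they differ, so that
constant genes never propagate NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .expr import ExpressionError, ExpressionMatrix

DE_COLUMNS = [
    "gene_id", "biotype", "mean_control", "mean_tumor", "base_mean",
    "log2fc", "p_value", "adj_p", "degenerate", "status",
]


def test_differential(
    matrix: ExpressionMatrix, grouping: pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs control on log2(fpkm + 1).

    ``grouping`` overrides the sample sheet's condition column (a Series of
    'tumor'/'control' indexed by sample_id).  Requires at least two samples
    per group.  Returns an unclassified DEResult table (status 'ns').
    """
    if matrix.unit != "fpkm":
        raise ExpressionError(f"test_differential expects fpkm, got {matrix.unit}")
    if len(matrix.gene_ids) == 0:
        raise ExpressionError("empty expression matrix")
    cond = matrix.samples["condition"] if grouping is None else grouping
    tumor = [s for s in matrix.sample_ids if cond[s] == "tumor"]
    control = [s for s in matrix.sample_ids if cond[s] == "control"]
    if len(tumor) < 2 or len(control) < 2:
        raise ExpressionError("need >= 2 samples per group (variance undefined)")

    fpkm = matrix.values
    mean_t = fpkm[tumor].mean(axis=1)
    mean_c = fpkm[control].mean(axis=1)
    base_mean = fpkm.mean(axis=1)
    log2fc = np.log2((mean_t + 1.0) / (mean_c + 1.0))

    x = np.log2(fpkm[tumor].to_numpy() + 1.0)
    y = np.log2(fpkm[control].to_numpy() + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)

    var_zero = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    means_equal = np.isclose(x.mean(axis=1), y.mean(axis=1))
    degenerate = var_zero & ~means_equal
    p = np.where(var_zero & means_equal, 1.0, p)
    p = np.where(degenerate, 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)  # residual ties, e.g. single-value groups

    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "biotype": matrix.biotypes.to_numpy(),
            "mean_control": mean_c.to_numpy(),
            "mean_tumor": mean_t.to_numpy(),
            "base_mean": base_mean.to_numpy(),
            "log2fc": np.asarray(log2fc, dtype=float),
            "p_value": p,
            "adj_p": adj_p,
            "degenerate": degenerate,
            "status": "ns",
        }
    ).reset_index(drop=True)


def classify_de(
    results: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Apply the strict 'p < alpha and |log2FC| > lfc_min' call.

    Boundary values (p == alpha or |log2fc| == lfc_min) are not significant.
    ``use_adjusted`` switches the p column to the BH-adjusted one.
    """
    out = results.copy()
    p = out["adj_p"] if use_adjusted else out["p_value"]
    sig = p < alpha
    out["status"] = np.where(
        sig & (out["log2fc"] > lfc_min), "up",
        np.where(sig & (out["log2fc"] < -lfc_min), "down", "ns"),
    )
    return out


def de_gene_ids(results: pd.DataFrame) -> list[str]:
    """Gene ids with status up or down, in table order."""
    return list(results.loc[results["status"] != "ns", "gene_id"])


@dataclass
class ClusteringResult:
    linkage: np.ndarray                 # scipy linkage matrix over samples
    sample_ids: list[str]
    partition: dict[str, int]           # sample_id -> cluster label of the 2-cut


def summarize_plots(
    results: pd.DataFrame, matrix: ExpressionMatrix
) -> dict[str, object]:
    """Figure-ready tables: MA, volcano, and a sample dendrogram on DE genes.

    The MA table carries log10(base_mean + 1) as x; the volcano table carries
    -log10 p (capped at 300 for p = 0).  Hierarchical clustering uses
    Euclidean distance with average linkage on per-gene z-scores of
    log2(fpkm + 1) restricted to DE genes, and reports the 2-cluster cut of
    the sample dendrogram.  With no DE genes the clustering is skipped with
    a warning.
    """
    ma = pd.DataFrame(
        {
            "gene_id": results["gene_id"],
            "log10_base_mean": np.log10(results["base_mean"] + 1.0),
            "log2fc": results["log2fc"],
            "status": results["status"],
        }
    )
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(results["p_value"])
    volcano = pd.DataFrame(
        {
            "gene_id": results["gene_id"],
            "log2fc": results["log2fc"],
            "neg_log10_p": np.minimum(neg_log10_p, 300.0),
            "status": results["status"],
        }
    )
    de_ids = de_gene_ids(results)
    clustering = None
    if len(de_ids) < 2:
        warnings.warn("fewer than 2 DE genes; hierarchical clustering skipped")
    else:
        sub = matrix.subset_genes(de_ids)
        x = np.log2(sub.values.to_numpy(dtype=float) + 1.0)
        sd = x.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        lk = linkage(z.T, method="average", metric="euclidean")
        labels = fcluster(lk, t=2, criterion="maxclust")
        clustering = ClusteringResult(
            linkage=lk,
            sample_ids=list(matrix.sample_ids),
            partition={s: int(l) for s, l in zip(matrix.sample_ids, labels)},
        )
    return {"ma": ma, "volcano": volcano, "clustering": clustering}


def write_de_table(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
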