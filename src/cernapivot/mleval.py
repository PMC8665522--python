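"""Sample-separation evaluation of a DE gene panel (PCA, K-means, GMM).

Measures how well a panel of differentially expressed genes distinguishes
tumor from control samples, in the unsupervised style of exploratory bulk
studies: PCA of the z-scored log2(fpkm + 1) profile, K-means with k = 2, and
a two-component Gaussian mixture with a single diagonal covariance shared by
both components (a deliberately rigid model — with a dozen samples and
hundreds of features anything richer is unidentifiable).

Cluster labels are aligned to the true conditions by majority before the
concordance (fraction of correctly grouped samples) is computed, so
concordance lives in [0.5, 1] for two balanced groups.  The mixture's EM
iterations are recorded; the log-likelihood trace is non-decreasing, which
the test suite asserts per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .expr import ExpressionError, ExpressionMatrix


@dataclass
class SeparationReport:
    pca_coords: pd.DataFrame            # samples x [pc1, pc2]
    explained_variance: np.ndarray      # fractions, all components
    kmeans_labels: pd.Series            # sample_id -> {0, 1}
    gmm_labels: pd.Series
    gmm_posteriors: pd.DataFrame        # samples x components
    max_posterior: pd.Series            # per sample, for its assigned component
    concordance: float                  # K-means vs condition, majority-aligned
    gmm_concordance: float
    high_posterior_fraction: float      # tumor samples with max posterior > thr
    posterior_threshold: float
    log_likelihood_trace: np.ndarray

    def to_dict(self) -> dict:
        return {
            "explained_variance": [float(v) for v in self.explained_variance[:2]],
            "concordance": self.concordance,
            "gmm_concordance": self.gmm_concordance,
            "high_posterior_fraction": self.high_posterior_fraction,
            "posterior_threshold": self.posterior_threshold,
            "min_max_posterior": float(self.max_posterior.min()),
            "em_iterations": int(len(self.log_likelihood_trace)),
        }


def _zscore_log_features(matrix: ExpressionMatrix, gene_ids: Sequence[str]) -> np.ndarray:
    sub = matrix.subset_genes(gene_ids)
    x = sub.values.to_numpy(dtype=float)
    if matrix.unit == "fpkm":
        x = np.log2(x + 1.0)
    elif matrix.unit != "log2fpkm":
        raise ExpressionError("separation evaluation expects fpkm or log2fpkm")
    sd = x.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ExpressionError("constant feature matrix")
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return z.T  # samples x genes


def _gmm_shared_diag(
    x: np.ndarray,
    k: int,
    init_labels: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """EM for a k-component Gaussian mixture with one shared diagonal covariance.

    Returns (posteriors n x k, log-likelihood trace).  Initialized from hard
    labels; the shared variance is floored at 1e-9 per dimension.
    """
    n, d = x.shape
    resp = np.zeros((n, k))
    resp[np.arange(n), init_labels] = 1.0
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # M-step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        var = np.zeros(d)
        for j in range(k):
            diff = x - means[j]
            var += resp[:, j] @ (diff**2)
        var = np.maximum(var / n, 1e-9)
        # E-step
        log_det = np.sum(np.log(var))
        log_p = np.empty((n, k))
        for j in range(k):
            maha = np.sum((x - means[j]) ** 2 / var, axis=1)
            log_p[:, j] = (
                np.log(weights[j]) - 0.5 * (d * np.log(2 * np.pi) + log_det + maha)
            )
        norm = logsumexp(log_p, axis=1)
        resp = np.exp(log_p - norm[:, None])
        ll = float(norm.sum())
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return resp, np.asarray(trace)


def _majority_concordance(labels: np.ndarray, truth: np.ndarray) -> float:
    """Fraction correctly grouped after the best binary label alignment."""
    acc = float(np.mean(labels == truth))
    return max(acc, 1.0 - acc)


def evaluate_separation(
    matrix: ExpressionMatrix,
    de_genes: Sequence[str],
    grouping: pd.Series | None = None,
    k: int = 2,
    posterior_threshold: float = 0.8,
    seed: int = 0,
) -> SeparationReport:
    """Evaluate tumor/control separability of a gene panel.

    Features are z-scored log2(fpkm + 1) values of ``de_genes``; PCA is the
    SVD of the centered sample matrix; K-means uses 10 k-means++ restarts
    with a fixed seed; the GMM is fit by EM (shared diagonal covariance,
    tolerance 1e-6, max 500 iterations) initialized from the K-means labels.
    """
    if len(de_genes) < 2:
        raise ExpressionError("need >= 2 DE genes to evaluate separation")
    z = _zscore_log_features(matrix, de_genes)
    n = z.shape[0]
    if n < k:
        raise ExpressionError(f"fewer samples ({n}) than components ({k})")
    cond = matrix.samples["condition"] if grouping is None else grouping
    truth = (cond.loc[list(matrix.sample_ids)] == "tumor").to_numpy().astype(int)

    # PCA by SVD of the centered sample matrix
    centered = z - z.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    coords = centered @ vt[:2].T
    evr = s**2 / max(np.sum(s**2), 1e-300)

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)
    km_labels = km.labels_.astype(int)

    resp, trace = _gmm_shared_diag(z, k, km_labels)
    gmm_labels = resp.argmax(axis=1)
    max_post = resp.max(axis=1)

    samples = list(matrix.sample_ids)
    tumor_mask = truth.astype(bool)
    high_frac = float(np.mean(max_post[tumor_mask] > posterior_threshold))
    return SeparationReport(
        pca_coords=pd.DataFrame(coords, index=samples, columns=["pc1", "pc2"]),
        explained_variance=evr,
        kmeans_labels=pd.Series(km_labels, index=samples),
        gmm_labels=pd.Series(gmm_labels, index=samples),
        gmm_posteriors=pd.DataFrame(resp, index=samples),
        max_posterior=pd.Series(max_post, index=samples),
        concordance=_majority_concordance(km_labels, truth),
        gmm_concordance=_majority_concordance(gmm_labels, truth),
        high_posterior_fraction=high_frac,
        posterior_threshold=posterior_threshold,
        log_likelihood_trace=trace,
    )
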