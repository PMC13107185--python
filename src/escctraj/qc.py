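"""Sample-level quality control: housekeeping-protein PCA and
correlation-based sample similarity clustering."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix


@dataclass(eq=False)
class QCReport:
    """PCA coordinates plus a sample dendrogram.

    ``pc_coordinates``: samples x components.  ``variance_explained``:
    non-negative fractions, non-increasing, summing to <= 1.  ``linkage``:
    scipy linkage matrix over samples (Euclidean distance, complete
    linkage).  ``correlation``: sample x sample Pearson matrix when the
    report came from correlation clustering.  ``flags``: sample-level
    warnings (degenerate PCA, excluded samples, ...).
    """

    pc_coordinates: pd.DataFrame
    variance_explained: np.ndarray
    linkage: np.ndarray
    sample_order: list[str]
    correlation: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)


def _pca(x: np.ndarray, n_components: int):
    """Centered, unscaled PCA via SVD with a deterministic sign convention
    (largest-magnitude loading of each component is positive)."""
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, len(s))
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    coords = u[:, :k] * s[:k]
    total = float((xc ** 2).sum())
    if total <= 0:
        var = np.zeros(k)
    else:
        var = (s[:k] ** 2) / total
    return coords, var


def qc_housekeeping(m: ExpressionMatrix, hk_proteins, n_components: int = 2) -> QCReport:
    """PCA and hierarchical clustering of samples restricted to
    housekeeping proteins (stable across tissues, so structure here points
    at technical rather than biological variation)."""
    hk = [p for p in hk_proteins if p in m.data.index]
    missing = sorted(set(hk_proteins) - set(hk))
    if len(hk) < 2:
        raise ValueError(
            f"need >=2 housekeeping proteins in matrix; missing: {missing}")
    sub = m.data.loc[hk]
    x = sub.fillna(sub.mean(axis=1).fillna(0.0), axis=0).to_numpy().T
    coords, var = _pca(x, n_components)
    flags = [f"housekeeping proteins absent from matrix: {missing}"] if missing else []
    if var.sum() == 0:
        flags.append("PCA degenerate: all samples identical")
    z = hierarchy.linkage(x, method="complete", metric="euclidean")
    pcs = pd.DataFrame(coords, index=m.sample_ids,
                       columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    return QCReport(pcs, var, z, m.sample_ids, flags=flags)


def sample_correlation_clustering(m: ExpressionMatrix, min_shared: int = 3) -> QCReport:
    """Pairwise-complete Pearson correlation between samples, then
    hierarchical clustering of the correlation matrix rows (Euclidean
    distance, complete linkage)."""
    if m.shape[1] < 3:
        raise ValueError("need >=3 samples")
    flags = []
    data = m.data
    sds = data.std(axis=0, skipna=True)
    constant = sds[(sds == 0) | sds.isna()].index.tolist()
    all_missing = [s for s in data.columns if data[s].notna().sum() == 0]
    drop = sorted(set(constant) | set(all_missing))
    if drop:
        flags.append(f"excluded constant/empty samples: {drop}")
        data = data.drop(columns=drop)
    if data.shape[1] < 3:
        raise ValueError("fewer than 3 usable samples after exclusions")
    # pairwise-complete Pearson; pairs sharing < min_shared proteins are an error
    notna = data.notna().to_numpy().astype(int)
    shared = notna.T @ notna
    if (shared < min_shared).any():
        raise ValueError(
            f"sample pairs share fewer than {min_shared} quantified proteins")
    corr = data.corr(method="pearson", min_periods=min_shared)
    z = hierarchy.linkage(corr.to_numpy(), method="complete", metric="euclidean")
    coords, var = _pca(data.fillna(data.mean(axis=1).fillna(0.0), axis=0).to_numpy().T, 2)
    pcs = pd.DataFrame(coords, index=data.columns, columns=["PC1", "PC2"])
    return QCReport(pcs, var, z, list(data.columns), correlation=corr, flags=flags)


def dendrogram_leaf_order(report: QCReport) -> list[str]:
    """Sample IDs in dendrogram leaf order."""
    order = hierarchy.leaves_list(report.linkage)
    return [report.sample_order[i] for i in order]


def cut_dendrogram(report: QCReport, k: int) -> pd.Series:
    """Cut the QC dendrogram into k flat clusters."""
    labels = hierarchy.fcluster(report.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=report.sample_order, name="cluster")
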