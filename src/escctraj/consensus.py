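"""Resampling-based consensus clustering and subtype association tests.

Monti-style consensus clustering: repeatedly subsample the samples,
cluster each subsample, and record for every sample pair how often it
co-clusters among the resamples where both were drawn.  The consensus
matrix (co-clustered / co-sampled) is then itself clustered
(hierarchical, complete linkage on 1 - consensus) to produce the final
labels, and silhouette widths on the same 1 - consensus distance guide
the choice of k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .matrix import ExpressionMatrix


def select_variable_features(m: ExpressionMatrix, fraction: float = 0.25,
                             measure: str = "sd") -> list[str]:
    """Top ``ceil(fraction * n)`` proteins by dispersion (default sd; "mad"
    for median absolute deviation).  Ties break by protein ID so the
    selection is deterministic."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if measure == "sd":
        disp = m.data.std(axis=1, skipna=True)
    elif measure == "mad":
        med = m.data.sub(m.data.median(axis=1, skipna=True), axis=0).abs()
        disp = med.median(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown dispersion measure {measure!r}")
    disp = disp.fillna(0.0)
    n_keep = math.ceil(fraction * len(disp))
    order = sorted(disp.index, key=lambda p: (-disp[p], p))
    return order[:n_keep]


@dataclass(eq=False)
class ConsensusResult:
    """Consensus matrices, labels and silhouettes for each k."""

    consensus: dict[int, pd.DataFrame]
    labels: dict[int, pd.Series]          # sample -> 1..k
    silhouette: dict[int, pd.Series]      # per-sample widths
    avg_silhouette: dict[int, float]
    chosen_k: int
    feature_ids: list[str]
    params: dict = field(default_factory=dict)


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1, skipna=True)
    sd = df.std(axis=1, skipna=True).replace(0.0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def _inner_labels(x: np.ndarray, k: int, inner: str, n_init: int,
                  seed: int) -> np.ndarray:
    if inner == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        return km.fit_predict(x)
    if inner == "hclust":
        z = hierarchy.linkage(x, method="complete", metric="euclidean")
        return hierarchy.fcluster(z, t=k, criterion="maxclust")
    raise ValueError(f"unknown inner algorithm {inner!r}")


def consensus_cluster(m: ExpressionMatrix, features, k_range=range(2, 7),
                      n_resamples: int = 1000, subsample_frac: float = 0.8,
                      inner: str = "kmeans", n_init: int = 10,
                      seed: int = 0, zscore: bool = True) -> ConsensusResult:
    """Monti consensus clustering of samples on the given protein features.

    The feature matrix is protein-wise z-scored by default.  Per resample,
    ``subsample_frac`` of the samples are drawn without replacement and
    clustered with the inner algorithm (k-means with ``n_init`` restarts,
    or complete-linkage hierarchical clustering).  Deterministic under
    ``seed``.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k must be >= 2")
    samples = m.sample_ids
    n = len(samples)
    if n < 2 * max(k_range):
        raise ValueError("need at least 2*max(k) samples")
    sub = m.data.loc[list(features)]
    if zscore:
        sub = _zscore_rows(sub)
    x = sub.fillna(0.0).to_numpy().T  # samples x features
    rng = np.random.default_rng(seed)
    n_sub = max(max(k_range), int(round(subsample_frac * n)))

    consensus, labels, sil, avg_sil = {}, {}, {}, {}
    for k in k_range:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=n_sub, replace=False)
            lab = _inner_labels(x[idx], k, inner, n_init,
                                int(rng.integers(0, 2**31 - 1)))
            tog[np.ix_(idx, idx)] += 1.0
            for c in np.unique(lab):
                members = idx[lab == c]
                co[np.ix_(members, members)] += 1.0
        if (tog == 0).any():
            raise ValueError("some sample pair never co-sampled; "
                             "increase n_resamples")
        cons = co / tog
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        dist = 1.0 - cons
        z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
        lab_k = hierarchy.fcluster(z, t=k, criterion="maxclust")
        widths = silhouette_samples(dist, lab_k, metric="precomputed")
        consensus[k] = pd.DataFrame(cons, index=samples, columns=samples)
        labels[k] = pd.Series(lab_k, index=samples, name="cluster")
        sil[k] = pd.Series(widths, index=samples, name="silhouette")
        avg_sil[k] = float(np.mean(widths))
    chosen_k = max(k_range, key=lambda k: (avg_sil[k], -k))
    return ConsensusResult(consensus, labels, sil, avg_sil, chosen_k,
                           list(features),
                           params={"n_resamples": n_resamples,
                                   "subsample_frac": subsample_frac,
                                   "inner": inner, "n_init": n_init,
                                   "seed": seed, "zscore": zscore})


def silhouette_widths(labels, distance: np.ndarray) -> tuple[pd.Series, float]:
    """Standard silhouette widths s(i) = (b-a)/max(a,b) on a precomputed
    distance matrix; members of singleton clusters get 0."""
    labels = pd.Series(labels)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    widths = silhouette_samples(np.asarray(distance, dtype=float),
                                labels.to_numpy(), metric="precomputed")
    s = pd.Series(widths, index=labels.index, name="silhouette")
    return s, float(np.mean(widths))


def subtype_association(labels, clinical_values) -> dict:
    """Pearson chi-squared (no continuity correction) between subtype
    labels and a categorical/ordinal clinical variable."""
    table = pd.crosstab(pd.Series(labels, name="subtype"),
                        pd.Series(clinical_values, name="variable"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                    correction=False)
    if (expected < 5).any():
        warnings.warn("some expected counts < 5; chi-squared approximate")
    return {"chi2": float(chi2), "df": int(dof), "p": float(p),
            "table": table,
            "expected": pd.DataFrame(expected, index=table.index,
                                     columns=table.columns)}


def subtype_concordance(labels_a, labels_b) -> dict:
    """Best-matching agreement between two labelings of the same samples.

    Labels are aligned by maximum-agreement matching (Hungarian algorithm
    on the contingency table); agreement is the fraction of samples whose
    labels correspond under that matching.  Also returns Sankey-ready
    flow counts.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("labelings share no samples")
    a, b = a.loc[shared], b.loc[shared]
    table = pd.crosstab(a, b)
    cost = -table.to_numpy()
    ri, ci = linear_sum_assignment(cost)
    matched = int(table.to_numpy()[ri, ci].sum())
    mapping = {table.index[i]: table.columns[j] for i, j in zip(ri, ci)}
    flows = table.stack().reset_index()
    flows.columns = ["label_a", "label_b", "n"]
    return {"agreement": matched / len(shared), "mapping": mapping,
            "table": table, "flows": flows[flows["n"] > 0]}


def write_consensus_result(res: ConsensusResult, outdir, prefix: str = "subtype") -> None:
    import os
    rows = []
    for k, lab in res.labels.items():
        for s, c in lab.items():
            rows.append((s, k, int(c)))
    pd.DataFrame(rows, columns=["sample_id", "k", "cluster"]).to_csv(
        os.path.join(outdir, f"{prefix}_labels.tsv"), sep="\t", index=False)
    for k, cons in res.consensus.items():
        cons.to_csv(os.path.join(outdir, f"{prefix}_consensus_k{k}.tsv"),
                    sep="\t", float_format="%.6g")
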