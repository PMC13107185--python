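"""Per-sample signature scoring (ssGSEA-style) and derived analyses.

The scorer implements the single-sample rank-based running-sum enrichment
statistic: per sample, proteins are ranked by descending abundance; the
enrichment score is the sum over the ranked list of the weighted in-set
cumulative fraction minus the out-of-set cumulative fraction.  It scores
any user-supplied signature collection (cell types, expression-mode sets,
hallmark sets alike) — scores are rank statistics, invariant to any
strictly monotone transform of a sample's values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusResult, consensus_cluster
from .differential import bh_adjust
from .matrix import ExpressionMatrix


@dataclass(eq=False)
class ScoreMatrix:
    """Signature x sample score matrix plus the scoring parameters."""

    scores: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _sample_ssgsea(values: pd.Series, sets: dict[str, list[str]],
                   weight: float) -> dict[str, float]:
    v = values.dropna()
    n = len(v)
    order = v.sort_values(ascending=False, kind="mergesort").index
    # rank value = n for the most abundant protein; average ranks for ties
    rank_val = pd.Series(stats.rankdata(v.to_numpy(), method="average"),
                         index=v.index).loc[order].to_numpy()
    out = {}
    member_mask = np.zeros(n, dtype=bool)
    for name, ids in sets.items():
        member_mask[:] = False
        idx = order.get_indexer(pd.Index(ids))
        member_mask[idx[idx >= 0]] = True
        m = int(member_mask.sum())
        w = np.abs(rank_val) ** weight
        w_in = np.where(member_mask, w, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~member_mask) / (n - m)
        out[name] = float(np.sum(p_in - p_out))
    return out


def ssgsea_score(m: ExpressionMatrix, sets: dict[str, list[str]],
                 weight: float = 0.25, normalize: bool = False,
                 min_size: int = 3) -> ScoreMatrix:
    """ssGSEA-style enrichment scores for each set in each sample.

    Sets with fewer than ``min_size`` measured members, or spanning the
    full measured universe of a sample, are skipped with a warning.
    ``normalize`` applies per-set min-max scaling across samples.
    """
    measured = set(m.protein_ids)
    usable: dict[str, list[str]] = {}
    for name, ids in sets.items():
        members = sorted(set(ids) & measured)
        if len(members) < min_size:
            warnings.warn(f"set {name!r}: <{min_size} measured members; skipped")
            continue
        if len(members) >= len(measured):
            warnings.warn(f"set {name!r} spans the full universe; skipped")
            continue
        usable[name] = members
    if not usable:
        raise ValueError("no scorable sets")
    cols = {}
    for s in m.sample_ids:
        cols[s] = _sample_ssgsea(m.data[s], usable, weight)
    scores = pd.DataFrame(cols).loc[list(usable)]
    if normalize:
        rng_ = scores.max(axis=1) - scores.min(axis=1)
        rng_ = rng_.replace(0.0, 1.0)
        scores = scores.sub(scores.min(axis=1), axis=0).div(rng_, axis=0)
    return ScoreMatrix(scores, params={"weight": weight, "normalize": normalize,
                                       "min_size": min_size})


def aggregate_scores(scores: ScoreMatrix, immune_sets, stroma_sets) -> pd.DataFrame:
    """Per-sample ImmuneScore / StromaScore: sums of the designated
    signature scores.  Which signatures count as immune or stromal is user
    configuration, not asserted truth."""
    for name in list(immune_sets) + list(stroma_sets):
        if name not in scores.scores.index:
            raise KeyError(f"signature {name!r} not in score matrix")
    return pd.DataFrame({
        "ImmuneScore": scores.scores.loc[list(immune_sets)].sum(axis=0),
        "StromaScore": scores.scores.loc[list(stroma_sets)].sum(axis=0),
    })


def immune_subtype_cluster(scores: ScoreMatrix, k_range=range(2, 7),
                           **consensus_params) -> ConsensusResult:
    """Consensus clustering of samples on their signature scores (same
    contract as :func:`escctraj.consensus.consensus_cluster`)."""
    m = ExpressionMatrix(scores.scores.copy())
    return consensus_cluster(m, features=scores.set_names, k_range=k_range,
                             **consensus_params)


def score_survival_split(score: pd.Series, clinical: pd.DataFrame,
                         endpoint: str = "OS", rule: str = "median",
                         min_per_arm: int = 10) -> dict:
    """Dichotomize patients at the score median (ties go to the low arm)
    and compare survival with a two-sided log-rank test."""
    from .survival import logrank_test
    if rule != "median":
        raise ValueError("only the median split rule is implemented")
    clin = clinical.set_index("patient_id")
    shared = score.index.intersection(clin.index)
    score = score.loc[shared]
    if score.nunique() < 2:
        raise ValueError("degenerate split: score is constant")
    cut = float(score.median())
    groups = pd.Series(np.where(score <= cut, "low", "high"),
                       index=score.index, name="group")
    n_low, n_high = int((groups == "low").sum()), int((groups == "high").sum())
    if min(n_low, n_high) < min_per_arm:
        raise ValueError(f"degenerate split: arms {n_low}/{n_high} below "
                         f"min_per_arm={min_per_arm}")
    col = {"OS": ("os_time", "os_event"), "DFS": ("dfs_time", "dfs_event")}[endpoint]
    time = clin.loc[shared, col[0]].to_numpy(dtype=float)
    event = clin.loc[shared, col[1]].to_numpy(dtype=int)
    chi2, df, p = logrank_test(time, event, groups.to_numpy())
    return {"groups": groups, "cutpoint": cut, "chi2": chi2, "df": df, "p": p}


def correlate_scores(a: ScoreMatrix, b: ScoreMatrix,
                     method: str = "spearman") -> pd.DataFrame:
    """Pairwise Spearman correlation between two score matrices over their
    shared samples, with BH-adjusted p across all pairs (long format)."""
    if method != "spearman":
        raise ValueError("only Spearman correlation is implemented")
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if len(shared) < 5:
        raise ValueError("need >= 5 shared samples")
    rows = []
    for sa in a.set_names:
        va = a.scores.loc[sa, shared].to_numpy(dtype=float)
        for sb in b.set_names:
            vb = b.scores.loc[sb, shared].to_numpy(dtype=float)
            if np.std(va) == 0 or np.std(vb) == 0:
                warnings.warn(f"constant score vector in pair ({sa}, {sb})")
                rows.append((sa, sb, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(va, vb)
            rows.append((sa, sb, float(rho), float(p)))
    df = pd.DataFrame(rows, columns=["set_a", "set_b", "rho", "p"])
    df["p_adj"] = bh_adjust(df["p"])
    return df


def write_score_matrix(scores: ScoreMatrix, path) -> None:
    scores.scores.to_csv(path, sep="\t", float_format="%.6g",
                         index_label="set_name")
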