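"""Two-group nonparametric differential expression and set enrichment.

The differential test is the two-sided Wilcoxon rank-sum (Mann-Whitney U)
test: exact enumeration when both groups are small (min(nA, nB) <= 8) and
the pooled values carry no ties, otherwise the normal approximation with
tie and continuity correction.  Effect size is the difference of group
means on the log2 scale (fold change = 2**log2fc).  Multiplicity control is
Benjamini-Hochberg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

DE_COLUMNS = ["u", "p", "p_adj", "log2fc", "direction", "n_a", "n_b"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order preserving, monotone; NaN entries are propagated and do not count
    toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def classify_de(p_adj, log2fc, alpha: float = 0.01, fc_min: float = 1.5,
                require_fc: bool = False) -> np.ndarray:
    """Label proteins U (up), D (down) or S (stable).

    U requires adjusted p < alpha, positive log2fc, and — when
    ``require_fc`` — a fold change 2**|log2fc| > fc_min.  D is symmetric;
    everything else (including untestable NaN rows) is S.
    """
    p_adj = np.asarray(p_adj, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    sig = (p_adj < alpha) & ~np.isnan(log2fc)
    if require_fc:
        with np.errstate(invalid="ignore"):
            sig &= np.power(2.0, np.abs(log2fc)) > fc_min
    out = np.full(p_adj.shape, "S", dtype=object)
    out[sig & (log2fc > 0)] = "U"
    out[sig & (log2fc < 0)] = "D"
    return out


def _rank_sum_row(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Single-protein two-sided rank-sum test (U of group A, p)."""
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if min(len(a), len(b)) <= 8 and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_de(m: ExpressionMatrix, group_a, group_b,
                alpha: float = 0.01, fc_min: float = 1.5,
                require_fc: bool = False) -> pd.DataFrame:
    """Per-protein rank-sum differential expression, group A vs group B.

    Returns a DataFrame indexed by protein ID with columns ``u, p, p_adj,
    log2fc, direction, n_a, n_b``; proteins with fewer than two quantified
    values in either group get NaN statistics and direction S.  Thresholds
    used for the direction label are recorded in ``df.attrs``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    for g in (group_a, group_b):
        absent = set(g) - set(m.sample_ids)
        if absent:
            raise KeyError(f"samples not in matrix: {sorted(absent)}")
    a_all = m.data[group_a].to_numpy(dtype=float)
    b_all = m.data[group_b].to_numpy(dtype=float)
    n_a = (~np.isnan(a_all)).sum(axis=1)
    n_b = (~np.isnan(b_all)).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)

    u = np.full(m.shape[0], np.nan)
    p = np.full(m.shape[0], np.nan)
    with np.errstate(invalid="ignore"):
        log2fc = np.nanmean(np.where(np.isnan(a_all), np.nan, a_all), axis=1) - \
            np.nanmean(np.where(np.isnan(b_all), np.nan, b_all), axis=1)
    log2fc[~testable] = np.nan

    complete = testable & (n_a == len(group_a)) & (n_b == len(group_b))
    # fast vectorized path: complete rows in the large-sample regime
    if min(len(group_a), len(group_b)) > 8 and complete.any():
        res = stats.mannwhitneyu(a_all[complete], b_all[complete], axis=1,
                                 alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        u[complete] = res.statistic
        p[complete] = res.pvalue
        rest = testable & ~complete
    else:
        rest = testable
    for i in np.flatnonzero(rest):
        a = a_all[i][~np.isnan(a_all[i])]
        b = b_all[i][~np.isnan(b_all[i])]
        u[i], p[i] = _rank_sum_row(a, b)

    if (~testable).any():
        warnings.warn(f"{int((~testable).sum())} proteins untestable "
                      "(<2 quantified values in a group)")
    p_adj = bh_adjust(p)
    direction = classify_de(p_adj, log2fc, alpha, fc_min, require_fc)
    df = pd.DataFrame({"u": u, "p": p, "p_adj": p_adj, "log2fc": log2fc,
                       "direction": direction, "n_a": n_a, "n_b": n_b},
                      index=pd.Index(m.protein_ids, name="protein_id"))
    df.attrs.update({"alpha": alpha, "fc_min": fc_min, "require_fc": require_fc,
                     "group_a": group_a, "group_b": group_b})
    return df


@dataclass(eq=False)
class FisherResult:
    odds_ratio: float
    odds_ratio_haldane: float | None
    p_two_sided: float
    p_enrich: float
    table: np.ndarray


def fisher_overlap(set_a, set_b, universe) -> FisherResult:
    """Fisher's exact test for overlap of two sets within a universe.

    Table rows split the universe by membership in A, columns by membership
    in B.  The odds ratio is the plain cross-product ratio; when a cell is
    zero a Haldane (+0.5) corrected ratio is reported alongside.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    haldane = None
    if (table == 0).any():
        haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    p_two = float(stats.fisher_exact(table, alternative="two-sided")[1])
    p_gr = float(stats.fisher_exact(table, alternative="greater")[1])
    return FisherResult(odds, haldane, p_two, p_gr, table)


def _set_score(values: pd.Series, members: list[str]) -> tuple[float, float]:
    """Rank-biserial enrichment score s = 2*AUC - 1 and its two-sided
    rank-sum p for one set (members vs non-members)."""
    member_vals = values.loc[members].to_numpy()
    other_vals = values.drop(index=members).to_numpy()
    res = stats.mannwhitneyu(member_vals, other_vals, alternative="two-sided")
    auc = res.statistic / (len(member_vals) * len(other_vals))
    return 2.0 * auc - 1.0, float(res.pvalue)


def annotation_enrichment_1d(values: pd.Series, sets: dict[str, list[str]],
                             min_members: int = 10) -> pd.DataFrame:
    """1D annotation enrichment of per-protein values over a set collection.

    For each set, members' values are compared to non-members' with a
    two-sided rank-sum test; the score s = 2*AUC - 1 lies in [-1, 1]
    (positive: members rank higher).  BH FDR across sets.
    """
    values = values.dropna()
    rows = []
    for name, ids in sets.items():
        members = sorted(set(ids) & set(values.index))
        if not members:
            warnings.warn(f"set {name!r} has no members in universe; skipped")
            continue
        if len(members) < min_members or len(values) - len(members) < 2:
            continue
        s, p = _set_score(values, members)
        rows.append((name, s, p, len(members)))
    df = pd.DataFrame(rows, columns=["set_name", "score_s", "p_raw",
                                     "n_members_in_universe"]).set_index("set_name")
    df["fdr"] = bh_adjust(df["p_raw"])
    return df[["score_s", "p_raw", "fdr", "n_members_in_universe"]]


def annotation_enrichment_2d(values_x: pd.Series, values_y: pd.Series,
                             sets: dict[str, list[str]],
                             min_members: int = 10) -> pd.DataFrame:
    """2D annotation enrichment: one score per dimension, set-level p as the
    conservative max of the two dimension p-values, then BH."""
    common = values_x.dropna().index.intersection(values_y.dropna().index)
    vx, vy = values_x.loc[common], values_y.loc[common]
    rows = []
    for name, ids in sets.items():
        members = sorted(set(ids) & set(common))
        if not members:
            warnings.warn(f"set {name!r} has no members in universe; skipped")
            continue
        if len(members) < min_members or len(common) - len(members) < 2:
            continue
        sx, px = _set_score(vx, members)
        sy, py = _set_score(vy, members)
        rows.append((name, sx, sy, max(px, py), len(members)))
    df = pd.DataFrame(rows, columns=["set_name", "score_x", "score_y", "p_raw",
                                     "n_members_in_universe"]).set_index("set_name")
    df["fdr"] = bh_adjust(df["p_raw"])
    return df[["score_x", "score_y", "p_raw", "fdr", "n_members_in_universe"]]


def write_de_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="", float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")
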