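"""Planted-truth recovery benchmarks.

Each routine sets up a synthetic scenario with known ground truth, runs the
corresponding pipeline component, and measures how well the truth is
recovered (or how exactly an implementation matches its independent
definition).  They back both the validation test suite and the
``scripts/acceptance.py`` reproduction script.

Problem sizes follow the study conditions (20 Healthy donors, 124
patients, mode effect 1.0 log2 units, noise sd 0.5); replicate counts and
resampling depths are stated per routine.
"""

from __future__ import annotations

import filecmp
import os
import tempfile
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .consensus import consensus_cluster, select_variable_features
from .differential import bh_adjust, wilcoxon_de
from .evaluate import compare_mode_models, patient_feature_table
from .matrix import ExpressionMatrix
from .modes import assign_modes
from .pipeline import run_pipeline
from .simulate import SimConfig, generate_cohort, simulate_survival
from .survival import (cindex, cox_fit, ridge_cox_fit, staging_3c, td_auc,
                       train_test_split)


def _tissue(meta, t):
    return meta.loc[meta["tissue"] == t, "sample_id"].tolist()


# ---------------------------------------------------------------------------
# exactness of the statistical primitives
# ---------------------------------------------------------------------------

def _enumeration_p(a, b):
    pooled = np.r_[a, b]
    n_a, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    center = len(a) * len(b) / 2.0
    obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    hits = total = 0
    for comb in combinations(range(n), n_a):
        u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2.0
        hits += abs(u - center) >= abs(obs - center) - 1e-12
        total += 1
    return hits / total


def wilcoxon_exact_vs_enumeration(max_n: int = 7, seeds=(0, 1, 2)) -> float:
    """Largest |p_implementation - p_enumeration| over every group-size pair
    (2..max_n squared) and several tie-free datasets per pair."""
    worst = 0.0
    for n_a in range(2, max_n + 1):
        for n_b in range(2, max_n + 1):
            for s in seeds:
                rng = np.random.default_rng(100 * n_a + 10 * n_b + s)
                a = rng.normal(size=n_a)
                b = rng.normal(0.5, size=n_b)
                cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
                m = ExpressionMatrix(pd.DataFrame(np.r_[a, b].reshape(1, -1),
                                                  index=["P"], columns=cols))
                de = wilcoxon_de(m, cols[:n_a], cols[n_a:])
                worst = max(worst, abs(de.loc["P", "p"] - _enumeration_p(a, b)))
    return worst


def bh_vs_brute_force(n_vectors: int = 1000, seed: int = 0) -> float:
    """Largest deviation from the literal step-up definition over random
    p-value vectors of mixed lengths."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=rng.integers(1, 60))
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        worst = max(worst, float(np.max(np.abs(bh_adjust(p) - adj))))
    return worst


# ---------------------------------------------------------------------------
# mode taxonomy recovery
# ---------------------------------------------------------------------------

def _assigned_vs_truth(cfg: SimConfig):
    m, meta, _, truth = generate_cohort(cfg)
    de_hn = wilcoxon_de(m, _tissue(meta, "NAT"), _tissue(meta, "Healthy"))
    de_nt = wilcoxon_de(m, _tissue(meta, "Tumor"), _tissue(meta, "NAT"))
    am = assign_modes(de_hn, de_nt)
    return am.table.join(truth.mode_label.rename("true"))


def mode_recovery(seed: int = 42) -> dict:
    """Fraction of planted non-SS proteins assigned their planted mode and
    of planted SS proteins assigned SS, on one default cohort."""
    tab = _assigned_vs_truth(SimConfig(seed=seed))
    nonss = tab[tab["true"] != "SS"]
    ss = tab[tab["true"] == "SS"]
    return {"nonss_fraction": float((nonss["mode"] == nonss["true"]).mean()),
            "ss_fraction": float((ss["mode"] == "SS").mean()),
            "n_proteins": len(tab)}


def null_mode_calls(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Worst-case fraction of proteins called non-SS when every planted
    effect is zero (type-I behaviour of the whole mode pipeline)."""
    fracs = []
    for k in range(n_seeds):
        cfg = SimConfig(seed=base_seed + k, effect_size=0.0,
                        subtype_shift=0.0, cell_signature_shift=0.0,
                        risk_loading=0.0)
        tab = _assigned_vs_truth(cfg)
        fracs.append(float((tab["mode"] != "SS").mean()))
    return {"max_fraction": max(fracs), "mean_fraction": float(np.mean(fracs)),
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# subtype discovery
# ---------------------------------------------------------------------------

def subtype_recovery(n_runs: int = 20, base_seed: int = 0,
                     n_resamples: int = 100, n_init: int = 5) -> dict:
    """Consensus clustering of NAT samples on planted two-subtype cohorts.

    A run succeeds when k=2 recovers the planted labels with ARI >= 0.9 and
    attains the maximal average silhouette among k in 2..6.
    """
    successes, aris = 0, []
    for k in range(n_runs):
        cfg = SimConfig(seed=base_seed + 7 * k + 1)
        m, meta, _, truth = generate_cohort(cfg)
        nat = m.subset_samples(_tissue(meta, "NAT"))
        feats = select_variable_features(nat, 0.25)
        res = consensus_cluster(nat, feats, k_range=range(2, 7),
                                n_resamples=n_resamples, n_init=n_init,
                                seed=base_seed + 7 * k + 2)
        pid = meta.set_index("sample_id").loc[nat.sample_ids, "patient_id"]
        ari = adjusted_rand_score(truth.subtype_label.loc[pid].to_numpy(),
                                  res.labels[2].to_numpy())
        aris.append(ari)
        successes += (ari >= 0.9) and (res.chosen_k == 2)
    return {"success_rate": successes / n_runs,
            "median_ari": float(np.median(aris)), "n_runs": n_runs}


# ---------------------------------------------------------------------------
# survival parameter recovery and metric anchors
# ---------------------------------------------------------------------------

def subtype_hr_coverage(n_reps: int = 50, base_seed: int = 1000,
                        n_proteins: int = 200) -> dict:
    """How often the 95% Wald CI of a subtype Cox fit covers the planted
    hazard ratio of 2 (exponential baseline, ~30% censoring, n=124)."""
    covered = 0
    for k in range(n_reps):
        cfg = SimConfig(seed=base_seed + k, n_proteins=n_proteins)
        _, _, clin, truth = generate_cohort(cfg)
        X = pd.DataFrame(
            {"subtype2": (truth.subtype_label.to_numpy() == 2).astype(float)})
        m = cox_fit(X, clin["os_time"], clin["os_event"])
        lo = m.summary["hr_ci_low"].iloc[0]
        hi = m.summary["hr_ci_high"].iloc[0]
        covered += lo <= 2.0 <= hi
    return {"coverage": covered / n_reps, "n_reps": n_reps}


def ridge_limit_equivalence(seed: int = 0, n: int = 300) -> float:
    """Max |coefficient difference| between the ridge path at lambda = 0 and
    the unpenalized Newton fit on a well-conditioned problem."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": rng.standard_normal(n),
                      "b": rng.binomial(1, 0.5, n).astype(float),
                      "c": rng.standard_normal(n)})
    lp = 0.7 * X["a"].to_numpy() - 0.5 * X["b"].to_numpy()
    t, e = simulate_survival(lp, 0.01, 0.3, rng)
    full = cox_fit(X, t, e)
    ridge = ridge_cox_fit(X, t, e, lambda_grid=[0.0], nfolds=3, seed=seed)
    return float(np.max(np.abs(full.coefficients.to_numpy()
                               - ridge.coefficients.to_numpy())))


def metric_anchors(seed: int = 0) -> dict:
    """Closed-form anchors of the evaluation metrics."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(100, size=50)
    e = np.ones(50, dtype=int)
    out = {
        "cindex_perfect": cindex(-t, t, e),
        "cindex_constant": cindex(np.zeros(50), t, e),
        "cindex_toy": cindex([3.0, 1.0, 2.0], [1.0, 2.0, 3.0], [1, 1, 1]),
    }
    s = rng.standard_normal(200)
    t2 = rng.exponential(100, size=200)
    worst = 0.0
    for th in (30.0, 80.0, 150.0):
        cases, controls = s[t2 <= th], s[t2 > th]
        u = stats.mannwhitneyu(cases, controls).statistic
        binary = u / (len(cases) * len(controls))
        worst = max(worst, abs(float(td_auc(s, t2, np.ones(200, dtype=int),
                                            [th]).iloc[0]) - binary))
    out["tdauc_vs_static_auc_max_diff"] = worst
    return out


def staging_recovery(seed: int = 5, n: int = 124) -> dict:
    """3-class k-means staging on a 3-component score mixture
    (means 0/3/6, sd 0.5)."""
    rng = np.random.default_rng(seed)
    comp = rng.integers(0, 3, size=n)
    scores = pd.Series(comp * 3.0 + rng.normal(0, 0.5, size=n),
                       index=[f"p{i}" for i in range(n)])
    st = staging_3c(scores, seed=seed)
    mapping = {"low": 0, "medium": 1, "high": 2}
    acc = float(np.mean([mapping[g] == c for g, c in zip(st.groups, comp)]))
    gm = st.group_means
    return {"accuracy": acc,
            "means_ascending": bool(gm["low"] < gm["medium"] < gm["high"]),
            "n": n}


def us_model_selection(n_reps: int = 20, base_seed: int = 5000,
                       lambda_grid=(1.0, 10.0, 100.0, 1000.0),
                       nfolds: int = 5) -> dict:
    """On cohorts where only US-mode proteins express the latent survival
    risk, how often the US-restricted ridge model attains a test C-index at
    least as high as every other single-mode model."""
    wins = 0
    for k in range(n_reps):
        seed = base_seed + k
        cfg = SimConfig(seed=seed, subtype_hr=1.0, risk_beta=0.7)
        m, meta, clin, _ = generate_cohort(cfg)
        de_hn = wilcoxon_de(m, _tissue(meta, "NAT"), _tissue(meta, "Healthy"))
        de_nt = wilcoxon_de(m, _tissue(meta, "Tumor"), _tissue(meta, "NAT"))
        am = assign_modes(de_hn, de_nt)
        feats = patient_feature_table(m, meta, "NAT")
        train, test, _ = train_test_split(clin, seed=seed)
        res = compare_mode_models(feats, am, clin, train, test,
                                  endpoint="OS",
                                  modes=["SU", "SD", "US", "UD", "UU",
                                         "DU", "DS", "DD"],
                                  lambda_grid=list(lambda_grid),
                                  nfolds=nfolds, seed=seed)
        others = res.drop(index="US")["cindex_test"]
        wins += res.loc["US", "cindex_test"] >= others.max()
    return {"us_best_rate": wins / n_reps, "n_reps": n_reps}


def pipeline_determinism(config_path=None) -> dict:
    """Run the bundled end-to-end config twice and byte-compare every
    artifact."""
    if config_path is None:
        config_path = os.path.join(os.path.dirname(__file__), "..", "..",
                                   "configs", "default.yaml")
    cfg_text = open(config_path).read()
    with tempfile.TemporaryDirectory() as tmp:
        out1 = run_pipeline(cfg_text, outdir=os.path.join(tmp, "a"))
        out2 = run_pipeline(cfg_text, outdir=os.path.join(tmp, "b"))
        names = sorted(os.listdir(out1))
        identical = all(filecmp.cmp(os.path.join(out1, n),
                                    os.path.join(out2, n), shallow=False)
                        for n in names)
    return {"byte_identical": bool(identical), "n_artifacts": len(names)}
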