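"""Mode-restricted prognostic model comparison.

Mirrors the model-selection logic of the trajectory analysis: for each
expression-mode protein set (and their union "All"), fit a ridge-Cox model
on the training cohort using the patients' NAT protein profiles as
predictors, score the held-out test cohort, and compare test C-indices
(plus time-dependent AUC at chosen horizons).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ptnm_ordinal
from .modes import MODES, NON_SS_MODES, ModeAssignment, mode_set
from .survival import SurvivalModel, cindex, ridge_cox_fit, risk_score, td_auc


def patient_feature_table(m: ExpressionMatrix, meta: pd.DataFrame,
                          tissue: str = "NAT") -> pd.DataFrame:
    """Patients x proteins feature table from one tissue's samples."""
    sub = meta[meta["tissue"] == tissue]
    df = m.data[sub["sample_id"].to_list()].T
    df.index = sub["patient_id"].to_list()
    return df


def fit_mode_model(features: pd.DataFrame, proteins, clinical: pd.DataFrame,
                   train_ids, endpoint: str = "OS", lambda_grid=None,
                   nfolds: int = 10, seed: int = 0) -> SurvivalModel:
    """Ridge-Cox on the given protein set for the training patients."""
    cols = [p for p in proteins if p in features.columns]
    if not cols:
        raise ValueError("no model proteins present in feature table")
    clin = clinical.set_index("patient_id")
    tcol, ecol = ("os_time", "os_event") if endpoint == "OS" else ("dfs_time", "dfs_event")
    X = features.loc[list(train_ids), cols].fillna(0.0)
    return ridge_cox_fit(X, clin.loc[list(train_ids), tcol],
                         clin.loc[list(train_ids), ecol],
                         lambda_grid=lambda_grid, nfolds=nfolds, seed=seed)


def compare_mode_models(features: pd.DataFrame, assignment: ModeAssignment,
                        clinical: pd.DataFrame, train_ids, test_ids,
                        endpoint: str = "OS", modes=None, lambda_grid=None,
                        nfolds: int = 10, seed: int = 0,
                        t_eval=None) -> pd.DataFrame:
    """Test-cohort C-index (and optional tdAUC) per mode-restricted model.

    ``modes`` defaults to the eight non-SS modes plus "All".  Modes with
    fewer than 2 proteins are skipped with a warning.
    """
    if modes is None:
        modes = list(NON_SS_MODES) + ["All"]
    clin = clinical.set_index("patient_id")
    tcol, ecol = ("os_time", "os_event") if endpoint == "OS" else ("dfs_time", "dfs_event")
    rows = []
    models = {}
    for mo in modes:
        prots = [p for p in mode_set(assignment, mo) if p in features.columns]
        if len(prots) < 2:
            warnings.warn(f"mode {mo}: <2 proteins; skipped")
            continue
        model = fit_mode_model(features, prots, clinical, train_ids,
                               endpoint, lambda_grid, nfolds, seed)
        models[mo] = model
        row = {"mode": mo, "n_proteins": len(prots), "lam": model.lam}
        for cohort, ids in (("train", list(train_ids)), ("test", list(test_ids))):
            scores = risk_score(model, features.loc[ids].fillna(0.0))
            t = clin.loc[ids, tcol].to_numpy(dtype=float)
            e = clin.loc[ids, ecol].to_numpy(dtype=int)
            row[f"cindex_{cohort}"] = cindex(scores.to_numpy(), t, e)
            if t_eval is not None:
                auc = td_auc(scores.to_numpy(), t, e, t_eval)
                for th, v in auc.items():
                    row[f"auc_{cohort}_t{th:g}"] = v
        rows.append(row)
    df = pd.DataFrame(rows).set_index("mode")
    df.attrs["models"] = models
    df.attrs["endpoint"] = endpoint
    return df


def subtype_ptnm_model(clinical: pd.DataFrame, subtype: pd.Series,
                       endpoint: str = "OS"):
    """Cox model on {subtype indicator, ordinal pTNM} — the integrated
    subtype + staging model; returns (model, risk scores)."""
    from .survival import cox_fit
    clin = clinical.set_index("patient_id")
    shared = clin.index.intersection(subtype.index)
    X = pd.DataFrame({
        "subtype2": (subtype.loc[shared].to_numpy() ==
                     np.max(subtype.to_numpy())).astype(float),
        "ptnm": ptnm_ordinal(clin.loc[shared, "ptnm"]).to_numpy(dtype=float),
    }, index=shared)
    tcol, ecol = ("os_time", "os_event") if endpoint == "OS" else ("dfs_time", "dfs_event")
    model = cox_fit(X, clin.loc[shared, tcol], clin.loc[shared, ecol])
    return model, risk_score(model, X, name="risk")
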