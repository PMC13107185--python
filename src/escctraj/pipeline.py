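"""Stage-wise analysis pipeline and its configuration.

``run_pipeline`` chains the full trajectory analysis: simulate (or load) ->
normalize/filter -> QC -> differential expression (NAT vs Healthy, Tumor vs
Healthy, Tumor vs NAT) -> expression modes -> NAT subtype discovery ->
cell-composition scoring -> survival models -> evaluation.  Every stage
reads its inputs from, and writes its TSV/JSON artifacts into, the output
directory, so any stage can be re-run alone once its predecessors' files
exist.  With a fixed config and seed the whole bundle is byte-identical
(all floats are written with one fixed format and no timestamps are
recorded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time as _time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellscore import aggregate_scores, ssgsea_score, write_score_matrix
from .consensus import consensus_cluster, select_variable_features, write_consensus_result
from .differential import wilcoxon_de, write_de_table, read_de_table
from .evaluate import compare_mode_models, patient_feature_table, subtype_ptnm_model
from .gmt import read_gmt, write_gmt
from .matrix import (ExpressionMatrix, filter_by_quantification,
                     normalize_to_reference, read_clinical_table,
                     read_expression_matrix, read_sample_metadata,
                     write_expression_matrix)
from .modes import assign_modes, write_mode_table
from .qc import sample_correlation_clustering
from .simulate import SimConfig, generate_cohort, make_signature_sets
from .survival import (cindex, decision_curve, logrank_test, predict_survprob,
                       risk_score, staging_3c, td_auc, train_test_split)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"

_DEFAULTS: dict = {
    "seed": 0,
    "outdir": "escctraj_out",
    "simulate": None,        # dict of SimConfig overrides, or None to load inputs
    "inputs": None,          # dict of file paths for user data
    "normalize": {"center": "none", "min_fraction": 0.5},
    "de": {"alpha": 0.01, "fc_min": 1.5, "require_fc": False},
    "subtype": {"feature_fraction": 0.25, "k_range": [2, 6],
                "n_resamples": 100, "subsample_frac": 0.8, "n_init": 5,
                "inner": "kmeans"},
    "cellscore": {"weight": 0.25, "min_size": 3,
                  "immune_sets": ["immune_cells"],
                  "stroma_sets": ["stroma_cells"]},
    "survival": {"endpoint": "OS", "train_fraction": 82 / 124,
                 "nfolds": 5, "lambda_grid": [1.0, 10.0, 100.0, 1000.0],
                 "mode_models": ["US", "All"], "t_eval_years": [3, 5],
                 "dca_horizon_years": 5},
}

_RANGES = {
    ("de", "alpha"): (0.0, 1.0),
    ("de", "fc_min"): (1.0, float("inf")),
    ("normalize", "min_fraction"): (0.0, 1.0),
    ("subtype", "feature_fraction"): (0.0, 1.0),
    ("subtype", "subsample_frac"): (0.0, 1.0),
    ("survival", "train_fraction"): (0.0, 1.0),
}


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""


def validate_config(source) -> dict:
    """Load and schema-check a pipeline config (path, YAML string or dict).

    Unknown keys are rejected; defaults are materialized so the returned
    dict is complete.  All problems are reported in one pass.
    """
    if isinstance(source, dict):
        raw = source
    else:
        text = source if "\n" in str(source) else open(source).read()
        raw = yaml.safe_load(text) or {}
    errors: list[str] = []
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in _DEFAULTS.items()}
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for key, val in raw.items():
        if key not in _DEFAULTS:
            errors.append(f"unknown top-level key {key!r}")
            continue
        if key == "simulate":
            if val is None:
                cfg["simulate"] = None
                continue
            unknown = set(val) - sim_fields
            if unknown:
                errors.append(f"simulate: unknown keys {sorted(unknown)}")
            cfg["simulate"] = dict(val)
        elif key == "inputs":
            cfg["inputs"] = dict(val) if val else None
        elif isinstance(_DEFAULTS[key], dict):
            unknown = set(val) - set(_DEFAULTS[key])
            if unknown:
                errors.append(f"{key}: unknown keys {sorted(unknown)}")
            cfg[key].update({k: v for k, v in val.items()
                             if k in _DEFAULTS[key]})
        else:
            cfg[key] = val
    for (sec, name), (lo, hi) in _RANGES.items():
        v = cfg[sec][name]
        if not (lo < v <= hi) and not (lo < v < hi):
            errors.append(f"{sec}.{name}={v} outside ({lo}, {hi}]")
    if cfg["simulate"] is None and cfg["inputs"] is None:
        errors.append("either 'simulate' or 'inputs' must be given")
    if cfg["inputs"]:
        for k, path in cfg["inputs"].items():
            if k in ("reference_column",):
                continue
            if not os.path.exists(path):
                errors.append(f"inputs.{k}: file not found: {path}")
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _path(outdir, name):
    return os.path.join(outdir, name)


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg, outdir):
    sim = SimConfig(seed=cfg["seed"], **(cfg["simulate"] or {}))
    m, meta, clin, truth = generate_cohort(sim)
    write_expression_matrix(m, _path(outdir, "expression.tsv"))
    meta.to_csv(_path(outdir, "metadata.tsv"), sep="\t", index=False)
    clin.to_csv(_path(outdir, "clinical.tsv"), sep="\t", index=False)
    make_signature_sets(truth, _path(outdir, "signatures.gmt"))
    _write_json({
        "mode_label": truth.mode_label.to_dict(),
        "subtype_label": {k: int(v) for k, v in truth.subtype_label.items()},
        "subtype_signature": truth.subtype_signature,
        "risk_proteins": truth.risk_beta[truth.risk_beta != 0].index.tolist(),
    }, _path(outdir, "truth.json"))


def _load_inputs(cfg, outdir):
    if cfg["simulate"] is not None:
        m = read_expression_matrix(_path(outdir, "expression.tsv"))
        meta = read_sample_metadata(_path(outdir, "metadata.tsv"))
        clin = read_clinical_table(_path(outdir, "clinical.tsv"))
        sets = read_gmt(_path(outdir, "signatures.gmt"))
        return m, meta, clin, sets
    inp = cfg["inputs"]
    if "raw" in inp:
        raw = pd.read_csv(inp["raw"], sep="\t", index_col=0)
        m = normalize_to_reference(raw, inp["reference_column"],
                                   center=cfg["normalize"]["center"])
    else:
        m = read_expression_matrix(inp["expression"])
    meta = read_sample_metadata(inp["metadata"])
    clin = read_clinical_table(inp["clinical"])
    sets = read_gmt(inp["signatures"]) if "signatures" in inp else {}
    return m, meta, clin, sets


def stage_normalize(cfg, outdir):
    m, meta, clin, sets = _load_inputs(cfg, outdir)
    if cfg["simulate"] is None and cfg["normalize"]["center"] != "none" \
            and "raw" not in (cfg["inputs"] or {}):
        # pre-normalized input matrices can still be re-centered
        m = normalize_to_reference(
            pd.concat([2.0 ** m.data, pd.Series(1.0, index=m.data.index,
                                                name="__ref__")], axis=1),
            "__ref__", center=cfg["normalize"]["center"])
    m = filter_by_quantification(m, cfg["normalize"]["min_fraction"])
    write_expression_matrix(m, _path(outdir, "normalized.tsv"))


def _norm_matrix(outdir):
    return read_expression_matrix(_path(outdir, "normalized.tsv"))


def _meta(cfg, outdir):
    if cfg["simulate"] is not None:
        return read_sample_metadata(_path(outdir, "metadata.tsv"))
    return read_sample_metadata(cfg["inputs"]["metadata"])


def _clin(cfg, outdir):
    if cfg["simulate"] is not None:
        return read_clinical_table(_path(outdir, "clinical.tsv"))
    return read_clinical_table(cfg["inputs"]["clinical"])


def stage_qc(cfg, outdir):
    m = _norm_matrix(outdir)
    rep = sample_correlation_clustering(m)
    rep.correlation.to_csv(_path(outdir, "qc_correlation.tsv"), sep="\t",
                           float_format=FLOAT_FMT)
    _write_json({"flags": rep.flags,
                 "variance_explained": [round(float(v), 6)
                                        for v in rep.variance_explained]},
                _path(outdir, "qc_summary.json"))


def _tissue_samples(meta, tissue):
    return meta.loc[meta["tissue"] == tissue, "sample_id"].tolist()


def stage_de(cfg, outdir):
    m = _norm_matrix(outdir)
    meta = _meta(cfg, outdir)
    d = cfg["de"]
    pairs = {
        "de_nat_vs_healthy.tsv": ("NAT", "Healthy"),
        "de_tumor_vs_healthy.tsv": ("Tumor", "Healthy"),
        "de_tumor_vs_nat.tsv": ("Tumor", "NAT"),
    }
    for fname, (a, b) in pairs.items():
        de = wilcoxon_de(m, _tissue_samples(meta, a), _tissue_samples(meta, b),
                         alpha=d["alpha"], fc_min=d["fc_min"],
                         require_fc=d["require_fc"])
        write_de_table(de, _path(outdir, fname))


def stage_modes(cfg, outdir):
    d = cfg["de"]
    de_hn = read_de_table(_path(outdir, "de_nat_vs_healthy.tsv"))
    de_nt = read_de_table(_path(outdir, "de_tumor_vs_nat.tsv"))
    am = assign_modes(de_hn, de_nt, alpha=d["alpha"], fc_min=d["fc_min"],
                      require_fc=d["require_fc"])
    write_mode_table(am, _path(outdir, "mode_table.tsv"),
                     _path(outdir, "mode_summary.json"))


def stage_subtype(cfg, outdir):
    m = _norm_matrix(outdir)
    meta = _meta(cfg, outdir)
    s = cfg["subtype"]
    nat = m.subset_samples(_tissue_samples(meta, "NAT"))
    feats = select_variable_features(nat, s["feature_fraction"])
    res = consensus_cluster(nat, feats,
                            k_range=range(s["k_range"][0], s["k_range"][1] + 1),
                            n_resamples=s["n_resamples"],
                            subsample_frac=s["subsample_frac"],
                            inner=s["inner"], n_init=s["n_init"],
                            seed=cfg["seed"])
    write_consensus_result(res, outdir, prefix="subtype")
    _write_json({"chosen_k": res.chosen_k,
                 "avg_silhouette": {str(k): round(v, 6)
                                    for k, v in res.avg_silhouette.items()}},
                _path(outdir, "subtype_summary.json"))


def stage_cellscore(cfg, outdir):
    m = _norm_matrix(outdir)
    _, _, _, sets = _load_inputs(cfg, outdir)
    if not sets:
        log.info("cellscore: no signature sets; stage skipped")
        return
    c = cfg["cellscore"]
    scores = ssgsea_score(m, sets, weight=c["weight"], min_size=c["min_size"])
    write_score_matrix(scores, _path(outdir, "cell_scores.tsv"))
    immune = [x for x in c["immune_sets"] if x in scores.scores.index]
    stroma = [x for x in c["stroma_sets"] if x in scores.scores.index]
    if immune and stroma:
        agg = aggregate_scores(scores, immune, stroma)
        agg.to_csv(_path(outdir, "aggregate_scores.tsv"), sep="\t",
                   float_format=FLOAT_FMT, index_label="sample_id")


def _patient_subtypes(cfg, outdir, meta):
    labs = pd.read_csv(_path(outdir, "subtype_labels.tsv"), sep="\t")
    labs = labs[labs["k"] == 2].set_index("sample_id")["cluster"]
    nat = meta[meta["tissue"] == "NAT"].set_index("sample_id")
    return pd.Series(labs.reindex(nat.index).to_numpy(),
                     index=nat["patient_id"].to_numpy(), name="subtype").dropna()


def stage_survive(cfg, outdir):
    meta = _meta(cfg, outdir)
    clin = _clin(cfg, outdir)
    sv = cfg["survival"]
    m = _norm_matrix(outdir)
    subtype = _patient_subtypes(cfg, outdir, meta)
    # orient discovered labels so subtype "2" is the higher-risk cluster
    model, scores = subtype_ptnm_model(clin, subtype, endpoint=sv["endpoint"])
    st = staging_3c(scores, seed=cfg["seed"])
    out = pd.DataFrame({"risk": scores, "group": st.groups})
    out.to_csv(_path(outdir, "staging.tsv"), sep="\t",
               float_format=FLOAT_FMT, index_label="patient_id")

    train, test, report = train_test_split(clin, sv["train_fraction"],
                                           seed=cfg["seed"])
    feats = patient_feature_table(m, meta, "NAT")
    am_tab = pd.read_csv(_path(outdir, "mode_table.tsv"), sep="\t",
                         index_col="protein_id")
    from .modes import ModeAssignment
    am = ModeAssignment(am_tab, list(am_tab.index), 0)
    cmp = compare_mode_models(feats, am, clin, train, test,
                              endpoint=sv["endpoint"],
                              modes=sv["mode_models"],
                              lambda_grid=sv["lambda_grid"],
                              nfolds=sv["nfolds"], seed=cfg["seed"])
    models = cmp.attrs["models"]
    risk_rows = {}
    for mo, mod in models.items():
        risk_rows[f"{mo}score"] = risk_score(mod, feats.fillna(0.0))
    pd.DataFrame(risk_rows).to_csv(_path(outdir, "risk_scores.tsv"), sep="\t",
                                   float_format=FLOAT_FMT,
                                   index_label="patient_id")
    cmp.drop(columns=[], inplace=False).to_csv(
        _path(outdir, "mode_models.tsv"), sep="\t", float_format=FLOAT_FMT)
    _write_json({
        "subtype_ptnm": {
            "coef": {k: round(float(v), 6)
                     for k, v in model.coefficients.items()},
            "hr": {k: round(float(v), 6) for k, v in model.summary["hr"].items()},
            "p": {k: round(float(v), 6) for k, v in model.summary["p"].items()},
        },
        "split": {"train": list(train), "test": list(test),
                  "seed": int(report.attrs["seed"])},
        "mode_model_lambdas": {mo: float(mod.lam) for mo, mod in models.items()},
    }, _path(outdir, "survival_models.json"))
    # persist fitted ridge models for the evaluation stage
    blob = {}
    for mo, mod in models.items():
        blob[mo] = {"coef": {k: float(v) for k, v in mod.coefficients.items()},
                    "lam": float(mod.lam),
                    "baseline_times": [float(t) for t in mod.baseline_times],
                    "baseline_h0": [float(h) for h in mod.baseline_h0]}
    _write_json(blob, _path(outdir, "model_params.json"))


def stage_evaluate(cfg, outdir):
    meta = _meta(cfg, outdir)
    clin = _clin(cfg, outdir).set_index("patient_id")
    sv = cfg["survival"]
    tcol, ecol = (("os_time", "os_event") if sv["endpoint"] == "OS"
                  else ("dfs_time", "dfs_event"))
    split = json.load(open(_path(outdir, "survival_models.json")))["split"]
    risks = pd.read_csv(_path(outdir, "risk_scores.tsv"), sep="\t",
                        index_col="patient_id")
    rows = []
    t_evals = [y * 365.25 for y in sv["t_eval_years"]]
    for col in risks.columns:
        for cohort, ids in (("train", split["train"]), ("test", split["test"])):
            s = risks.loc[ids, col].to_numpy()
            t = clin.loc[ids, tcol].to_numpy(dtype=float)
            e = clin.loc[ids, ecol].to_numpy(dtype=int)
            rows.append((col, sv["endpoint"], cohort, "cindex", "",
                         cindex(s, t, e)))
            auc = td_auc(s, t, e, t_evals)
            for (th, v), y in zip(auc.items(), sv["t_eval_years"]):
                rows.append((col, sv["endpoint"], cohort, "td_auc", y, v))
    # staging separation
    stag = pd.read_csv(_path(outdir, "staging.tsv"), sep="\t",
                       index_col="patient_id")
    chi2, df_, p = logrank_test(clin.loc[stag.index, tcol],
                                clin.loc[stag.index, ecol],
                                stag["group"])
    rows.append(("subtype_ptnm_3c", sv["endpoint"], "all", "logrank_chi2", "", chi2))
    rows.append(("subtype_ptnm_3c", sv["endpoint"], "all", "logrank_p", "", p))
    ev = pd.DataFrame(rows, columns=["model", "endpoint", "cohort", "metric",
                                     "t_years", "value"])
    ev.to_csv(_path(outdir, "evaluation.tsv"), sep="\t", index=False,
              float_format=FLOAT_FMT)

    # decision curve for the first mode model at the DCA horizon
    params = json.load(open(_path(outdir, "model_params.json")))
    first = sv["mode_models"][0]
    if first in params:
        from .survival import SurvivalModel
        pm = params[first]
        model = SurvivalModel(pd.Series(pm["coef"]), pm["lam"], None,
                              np.asarray(pm["baseline_times"]),
                              np.asarray(pm["baseline_h0"]), 0, 0.0, 0.0)
        m = _norm_matrix(outdir)
        feats = patient_feature_table(m, meta, "NAT").fillna(0.0)
        horizon = sv["dca_horizon_years"] * 365.25
        ids = split["test"]
        surv = predict_survprob(model, feats.loc[ids], horizon)
        risk_at_t = 1.0 - surv
        t = clin.loc[ids, tcol]
        e = clin.loc[ids, ecol]
        observed = pd.Series(np.where(t > horizon, 0.0,
                                      np.where(e == 1, 1.0, np.nan)),
                             index=ids)
        dca = decision_curve(risk_at_t, observed, np.arange(0.05, 0.96, 0.05))
        dca.to_csv(_path(outdir, "decision_curve.tsv"), sep="\t", index=False,
                   float_format=FLOAT_FMT)


STAGES = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "qc": stage_qc,
    "de": stage_de,
    "modes": stage_modes,
    "subtype": stage_subtype,
    "cellscore": stage_cellscore,
    "survive": stage_survive,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: dict, outdir=None, stages=None) -> str:
    """Run the configured stages in order; returns the output directory.

    A stage failure aborts with the stage name attached.  The manifest
    records the package version, seed and per-stage parameters (no
    timestamps, so reruns are byte-identical).
    """
    cfg = validate_config(cfg)
    outdir = outdir or cfg["outdir"]
    todo = list(STAGES) if stages is None else list(stages)
    if cfg["simulate"] is None and "simulate" in todo:
        todo.remove("simulate")
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    os.makedirs(outdir, exist_ok=True)
    for name in todo:
        t0 = _time.time()
        try:
            STAGES[name](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs", name, _time.time() - t0)
    manifest = {"package": "escctraj", "version": __version__,
                "seed": cfg["seed"], "stages": todo,
                "config": {k: v for k, v in cfg.items() if k != "outdir"}}
    _write_json(manifest, _path(outdir, "manifest.json"))
    return outdir
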