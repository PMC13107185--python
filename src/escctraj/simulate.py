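"""Synthetic Healthy/NAT/Tumor cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:

* 20 Healthy donors plus 124 patients with paired NAT and Tumor samples;
* log2-ratio protein values with i.i.d. Gaussian noise (optionally
  heavier-tailed t, df=5) around mode-specific group means — each protein's
  mean steps by +/- ``effect_size`` at the Healthy->NAT and NAT->Tumor
  transitions according to its planted nine-way mode;
* a two-subtype NAT signature: ``subtype_signature_size`` SS-mode proteins
  separated by ``subtype_shift`` between NAT samples of subtype-2 and
  subtype-1 patients.  The shift is applied mean-centered across the NAT
  group (subtype 2 up, subtype 1 down, weighted by the subtype fractions)
  so the NAT group mean — and hence the proteins' planted SS mode — is
  preserved while the between-subtype contrast equals ``subtype_shift``;
* planted cell-type signatures whose context shift is directionally
  consistent with the planted modes: an immune signature (SS proteins,
  subtype-linked and mean-centered within NAT like the subtype signature),
  a stroma signature (DS proteins additionally elevated in Healthy
  samples) and an epithelial signature (SU proteins additionally elevated
  in Tumor samples);
* exponential survival whose hazard is ``baseline_hazard *
  exp(log(subtype_hr) * [subtype 2] + risk_beta * z)`` with a patient-level
  latent factor z expressed in designated risk proteins, and independent
  exponential censoring calibrated to a target censoring fraction.

All randomness flows from one NumPy ``default_rng(seed)`` (PCG64), so a
fixed seed gives bit-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .matrix import ExpressionMatrix
from .modes import MODES

#: Mode frequencies used as generator defaults: the nine-way mode counts
#: observed in the esophageal Healthy/NAT/Tumor proteome (universe 6873),
#: normalized to proportions.
DEFAULT_MODE_COUNTS = {
    "SS": 3621, "SU": 235, "SD": 383, "US": 1164, "UU": 151,
    "UD": 160, "DU": 88, "DS": 964, "DD": 107,
}


def _default_proportions() -> dict[str, float]:
    total = sum(DEFAULT_MODE_COUNTS.values())
    return {m: DEFAULT_MODE_COUNTS[m] / total for m in MODES}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort (defaults = study conditions)."""

    seed: int
    n_healthy: int = 20
    n_patients: int = 124
    n_proteins: int = 2000
    mode_proportions: dict[str, float] = field(default_factory=_default_proportions)
    effect_size: float = 1.0          # log2 units per transition step
    noise_sd: float = 0.5             # log2 units, within-group
    patient_sd: float = 0.2           # shared NAT/Tumor patient intercept
    baseline_sd: float = 0.3          # per-protein baseline spread
    heavy_tails: bool = False         # t(df=5) noise instead of Gaussian
    subtype2_fraction: float = 79 / 124
    subtype_signature_size: int = 300
    subtype_shift: float = 1.0        # log2 shift in subtype-2 NAT samples
    subtype_hr: float = 2.0           # hazard ratio of subtype 2 vs 1
    n_risk_proteins: int = 50         # US-mode proteins expressing the latent risk
    risk_loading: float = 0.5         # log2 shift per unit latent risk
    risk_beta: float = 0.0            # log-hazard per unit latent risk
    cell_signature_size: int = 40
    cell_signature_shift: float = 0.8
    baseline_hazard: float = 1.0 / 1500.0   # events/day at linpred 0
    baseline_hazard_dfs: float = 1.4 / 1500.0
    censor_rate: float = 0.30

    def validate(self) -> None:
        props = self.mode_proportions
        if set(props) != set(MODES):
            raise ValueError(f"mode_proportions must cover exactly {MODES}")
        if abs(sum(props.values()) - 1.0) > 1e-8:
            raise ValueError("mode_proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(eq=False)
class CohortTruth:
    """Planted ground truth of a synthetic cohort."""

    mode_label: pd.Series                 # protein -> mode
    subtype_label: pd.Series              # patient -> 1 or 2
    subtype_signature: list[str]
    cell_signatures: dict[str, list[str]]
    risk_beta: pd.Series                  # protein -> expression loading (0 off risk set)
    latent_risk: pd.Series                # patient -> z
    linpred: pd.Series                    # patient -> log-hazard offset
    baseline_hazard: float
    censor_rate: float


def _largest_remainder_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    raw = {m: proportions[m] * n for m in MODES}
    counts = {m: int(np.floor(raw[m])) for m in MODES}
    short = n - sum(counts.values())
    order = sorted(MODES, key=lambda m: (-(raw[m] - counts[m]), m))
    for m in order[:short]:
        counts[m] += 1
    return counts


_STEP = {"U": 1.0, "D": -1.0, "S": 0.0}


def solve_censor_rate(event_rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate achieving the target censoring fraction.

    With event rate lambda_i and censor rate c, P(censored) for patient i is
    c / (c + lambda_i); the mean over patients is matched to ``target``.
    """
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, 1e6 * float(np.max(event_rates))

    def frac(c):
        return float(np.mean(c / (c + event_rates))) - target

    return float(brentq(frac, lo, hi, xtol=1e-14, rtol=1e-12))


def simulate_survival(linpred: np.ndarray, baseline_rate: float,
                      censor_rate: float, rng: np.random.Generator):
    """Exponential event times with exponential censoring.

    Event time ~ Exp(baseline_rate * exp(linpred)); the censoring rate is
    solved so the expected censored fraction equals ``censor_rate``.
    Returns (time, event) arrays; event = 1 when the event precedes censoring.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    linpred = np.asarray(linpred, dtype=float)
    rates = baseline_rate * np.exp(linpred)
    t_event = rng.exponential(1.0 / rates)
    if censor_rate == 0:
        return t_event, np.ones(len(t_event), dtype=int)
    c = solve_censor_rate(rates, censor_rate)
    t_cens = rng.exponential(1.0 / c, size=len(t_event))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    achieved = 1.0 - event.mean()
    if abs(achieved - censor_rate) > 0.20:
        warnings.warn(f"achieved censoring fraction {achieved:.2f} far from "
                      f"target {censor_rate:.2f}")
    return time, event


def generate_cohort(cfg: SimConfig):
    """Generate (ExpressionMatrix, sample metadata, clinical table, truth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_prot, n_pat, n_h = cfg.n_proteins, cfg.n_patients, cfg.n_healthy
    width = max(4, len(str(n_prot)))
    proteins = [f"PR{i:0{width}d}" for i in range(1, n_prot + 1)]
    patients = [f"P{i:03d}" for i in range(1, n_pat + 1)]
    healthy_ids = [f"H{i:03d}" for i in range(1, n_h + 1)]
    nat_ids = [f"N_{p}" for p in patients]
    tum_ids = [f"T_{p}" for p in patients]

    # --- planted modes ---------------------------------------------------
    counts = _largest_remainder_counts(cfg.mode_proportions, n_prot)
    order = rng.permutation(n_prot)
    mode_arr = np.empty(n_prot, dtype=object)
    pos = 0
    for m in MODES:
        mode_arr[order[pos:pos + counts[m]]] = m
        pos += counts[m]
    mode_label = pd.Series(mode_arr, index=proteins, name="mode")
    step_hn = np.array([_STEP[m[0]] for m in mode_arr]) * cfg.effect_size
    step_nt = np.array([_STEP[m[1]] for m in mode_arr]) * cfg.effect_size

    # --- planted subtype & signatures ------------------------------------
    n_sub2 = int(round(cfg.subtype2_fraction * n_pat))
    sub2 = np.zeros(n_pat, dtype=bool)
    sub2[rng.choice(n_pat, size=n_sub2, replace=False)] = True
    subtype_label = pd.Series(np.where(sub2, 2, 1), index=patients, name="subtype")

    ss_idx = rng.permutation(np.flatnonzero(mode_arr == "SS"))
    n_sig = min(cfg.subtype_signature_size, len(ss_idx))
    sig_idx = ss_idx[:n_sig]
    remaining_ss = ss_idx[n_sig:]
    cell_idx: dict[str, np.ndarray] = {}
    k = min(cfg.cell_signature_size, len(remaining_ss))
    cell_idx["immune_cells"] = remaining_ss[:k]
    ds_idx = rng.permutation(np.flatnonzero(mode_arr == "DS"))
    cell_idx["stroma_cells"] = ds_idx[:min(cfg.cell_signature_size, len(ds_idx))]
    su_idx = rng.permutation(np.flatnonzero(mode_arr == "SU"))
    cell_idx["epithelial_cells"] = su_idx[:min(cfg.cell_signature_size, len(su_idx))]
    cell_signatures = {name: [proteins[i] for i in idx]
                       for name, idx in cell_idx.items()}

    us_idx = np.flatnonzero(mode_arr == "US")
    n_risk = min(cfg.n_risk_proteins, len(us_idx))
    risk_idx = rng.choice(us_idx, size=n_risk, replace=False) if n_risk else np.array([], int)
    risk_beta = pd.Series(0.0, index=proteins, name="risk_beta")
    risk_beta.iloc[risk_idx] = cfg.risk_loading
    z = rng.standard_normal(n_pat)

    # --- expression matrix ------------------------------------------------
    base = rng.normal(0.0, cfg.baseline_sd, size=n_prot)
    mu_h = base
    mu_n = base + step_hn
    mu_t = base + step_hn + step_nt

    n_samples = n_h + 2 * n_pat
    mu = np.empty((n_prot, n_samples))
    mu[:, :n_h] = mu_h[:, None]
    mu[:, n_h:n_h + n_pat] = mu_n[:, None]
    mu[:, n_h + n_pat:] = mu_t[:, None]

    # subtype contrast, mean-centered across NAT so group means (and hence
    # planted modes) are untouched: sub2 += shift*(1-f2), sub1 -= shift*f2
    nat_cols = np.arange(n_h, n_h + n_pat)
    tum_cols = np.arange(n_h + n_pat, n_samples)
    f2 = sub2.mean()
    if len(sig_idx):
        mu[np.ix_(sig_idx, nat_cols[sub2])] += cfg.subtype_shift * (1 - f2)
        mu[np.ix_(sig_idx, nat_cols[~sub2])] -= cfg.subtype_shift * f2
    # cell-signature context shifts (directionally consistent with modes)
    imm = cell_idx["immune_cells"]
    if len(imm):
        mu[np.ix_(imm, nat_cols[sub2])] += cfg.cell_signature_shift * (1 - f2)
        mu[np.ix_(imm, nat_cols[~sub2])] -= cfg.cell_signature_shift * f2
    mu[np.ix_(cell_idx["stroma_cells"], np.arange(n_h))] += cfg.cell_signature_shift
    mu[np.ix_(cell_idx["epithelial_cells"], tum_cols)] += cfg.cell_signature_shift
    # latent risk expressed in risk proteins of both patient samples
    if len(risk_idx):
        shift = cfg.risk_loading * z
        mu[np.ix_(risk_idx, nat_cols)] += shift
        mu[np.ix_(risk_idx, tum_cols)] += shift

    # shared patient intercept for NAT/Tumor of the same patient
    u_pat = rng.normal(0.0, cfg.patient_sd, size=(n_prot, n_pat))
    mu[:, nat_cols] += u_pat
    mu[:, tum_cols] += u_pat

    if cfg.heavy_tails:
        df = 5
        noise = rng.standard_t(df, size=mu.shape) * (cfg.noise_sd / np.sqrt(df / (df - 2)))
    else:
        noise = rng.normal(0.0, cfg.noise_sd, size=mu.shape)
    values = mu + noise

    sample_ids = healthy_ids + nat_ids + tum_ids
    matrix = ExpressionMatrix(pd.DataFrame(values, index=proteins, columns=sample_ids))

    # --- metadata ---------------------------------------------------------
    h_batch = ["HB1" if i < n_h // 2 else "HB2" for i in range(n_h)]
    pat_batch = [f"B{(i // 9) + 1:02d}" for i in range(n_pat)]
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": [""] * n_h + patients + patients,
        "tissue": ["Healthy"] * n_h + ["NAT"] * n_pat + ["Tumor"] * n_pat,
        "batch": h_batch + pat_batch + pat_batch,
    })

    # --- clinical table ---------------------------------------------------
    linpred = np.log(cfg.subtype_hr) * sub2.astype(float) + cfg.risk_beta * z
    os_time, os_event = simulate_survival(linpred, cfg.baseline_hazard,
                                          cfg.censor_rate, rng)
    dfs_time, dfs_event = simulate_survival(linpred, cfg.baseline_hazard_dfs,
                                            cfg.censor_rate, rng)
    ptnm = rng.choice(["I", "II", "III", "IV"], size=n_pat,
                      p=[0.15, 0.35, 0.40, 0.10])
    t_stage = rng.choice(["T1", "T2", "T3", "T4"], size=n_pat,
                         p=[0.10, 0.25, 0.50, 0.15])
    n_stage = rng.choice(["N0", "N1", "N2", "N3"], size=n_pat,
                         p=[0.40, 0.30, 0.20, 0.10])
    sex = rng.choice(["F", "M"], size=n_pat, p=[0.2, 0.8])
    age = np.clip(np.round(rng.normal(60, 8, size=n_pat)), 30, 85).astype(int)
    clinical = pd.DataFrame({
        "patient_id": patients,
        "os_time": np.round(os_time, 2), "os_event": os_event,
        "dfs_time": np.round(dfs_time, 2), "dfs_event": dfs_event,
        "ptnm": ptnm, "t_stage": t_stage, "n_stage": n_stage,
        "sex": sex, "age": age,
    })

    truth = CohortTruth(
        mode_label=mode_label,
        subtype_label=subtype_label,
        subtype_signature=[proteins[i] for i in sig_idx],
        cell_signatures=cell_signatures,
        risk_beta=risk_beta,
        latent_risk=pd.Series(z, index=patients, name="latent_risk"),
        linpred=pd.Series(linpred, index=patients, name="linpred"),
        baseline_hazard=cfg.baseline_hazard,
        censor_rate=cfg.censor_rate,
    )
    return matrix, meta, clinical, truth


def make_signature_sets(truth: CohortTruth, path=None) -> dict[str, list[str]]:
    """Planted cell signatures as a GMT-ready collection (optionally written
    to ``path``); empty signatures are skipped with a warning."""
    if not truth.cell_signatures:
        raise ValueError("truth has no cell signatures")
    sets = {}
    for name, members in truth.cell_signatures.items():
        if not members:
            warnings.warn(f"planted signature {name!r} is empty; skipped")
            continue
        sets[name] = list(members)
    if path is not None:
        from .gmt import write_gmt
        write_gmt(sets, path, descriptions={n: "planted" for n in sets})
    return sets
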