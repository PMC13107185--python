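"""Survival estimation and prognostic model construction.

Implements the prognostic workflow: Kaplan-Meier / log-rank description,
Cox proportional hazards with Efron tie handling (Newton-Raphson on the
partial likelihood to a gradient norm below 1e-8), ridge-penalized Cox
with lambda chosen by cross-validated partial-likelihood deviance,
risk-score evaluation (Harrell C, IPCW time-dependent AUC), three-class
k-means risk staging, balanced train/test splitting, Breslow survival
prediction, and decision-curve net benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.cluster import KMeans


# ---------------------------------------------------------------------------
# Efron partial likelihood
# ---------------------------------------------------------------------------

def _efron_nll_grad_hess(beta, X, time, event, lam=0.0, want_hess=True):
    """Negative log partial likelihood (Efron ties) + ridge term, with
    gradient and (optionally) Hessian."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # numeric guard; partial likelihood is shift-invariant
    e = np.exp(eta)
    return _efron_core(eta, e, beta, X, time, event, lam, want_hess)


def _efron_core(eta, e, beta, X, time, event, lam, want_hess):
    n, p = X.shape
    order = np.argsort(-time, kind="mergesort")
    ts, es, Xs, ws = time[order], event[order], X[order], e[order]

    nll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if want_hess else None
    S_R = 0.0
    F_R = np.zeros(p)
    H_R = np.zeros((p, p)) if want_hess else None

    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        blk = slice(i, j)
        wX = Xs[blk] * ws[blk, None]
        S_R += ws[blk].sum()
        F_R += wX.sum(axis=0)
        if want_hess:
            H_R += Xs[blk].T @ wX
        d_idx = np.flatnonzero(es[blk] == 1) + i
        d = len(d_idx)
        if d:
            S_D = ws[d_idx].sum()
            F_D = (Xs[d_idx] * ws[d_idx, None]).sum(axis=0)
            if want_hess:
                H_D = Xs[d_idx].T @ (Xs[d_idx] * ws[d_idx, None])
            nll -= eta[order][d_idx].sum()
            grad -= Xs[d_idx].sum(axis=0)
            for l in range(d):
                f = l / d
                denom = S_R - f * S_D
                num = F_R - f * F_D
                nll += np.log(denom)
                mu = num / denom
                grad += mu
                if want_hess:
                    hess += (H_R - f * H_D) / denom - np.outer(mu, mu)
        i = j
    if lam > 0:
        nll += 0.5 * lam * float(beta @ beta)
        grad = grad + lam * beta
        if want_hess:
            hess = hess + lam * np.eye(p)
    return nll, grad, hess


def _newton_cox(X, time, event, lam=0.0, tol=1e-8, max_iter=100):
    n, p = X.shape
    beta = np.zeros(p)
    nll, grad, hess = _efron_nll_grad_hess(beta, X, time, event, lam)
    for it in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            return beta, nll, grad, hess, it - 1
        try:
            delta = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(hess, -grad, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                nll_c, grad_c, hess_c = _efron_nll_grad_hess(cand, X, time,
                                                             event, lam)
            if np.isfinite(nll_c) and nll_c <= nll + 1e-12:
                beta, nll, grad, hess = cand, nll_c, grad_c, hess_c
                break
            step /= 2.0
        else:
            break
        if np.max(np.abs(beta)) > 30:
            warnings.warn("possible separation: |beta| growing unboundedly")
    gnorm = float(np.linalg.norm(grad))
    if gnorm >= tol:
        raise RuntimeError(
            f"Cox Newton-Raphson did not converge: grad norm {gnorm:.3g} "
            f"after {max_iter} iterations (nll={nll:.6g})")
    return beta, nll, grad, hess, max_iter


@dataclass(eq=False)
class SurvivalModel:
    """Fitted (possibly ridge-penalized) Cox model.

    Coefficients are on the original covariate scale (log-hazard units).
    ``baseline_times`` / ``baseline_h0`` give the Breslow cumulative
    baseline hazard step function evaluated at the training event times.
    """

    coefficients: pd.Series
    lam: float
    summary: pd.DataFrame | None          # HR, CI, Wald p (unpenalized fits)
    baseline_times: np.ndarray
    baseline_h0: np.ndarray
    n_iter: int
    grad_norm: float
    log_likelihood: float
    x_mean: pd.Series | None = None       # standardization record (ridge)
    x_sd: pd.Series | None = None
    cv_deviance: pd.DataFrame | None = None


def _breslow_baseline(X, time, event, beta):
    eta = X @ beta
    e = np.exp(eta - eta.mean())
    scale = np.exp(eta.mean())
    order = np.argsort(time, kind="mergesort")
    ts, es, ws = time[order], event[order], e[order]
    # risk-set sums: total minus prefix of samples with smaller time
    uniq = np.unique(ts[es == 1])
    h0 = np.zeros(len(uniq))
    for k, t in enumerate(uniq):
        at_risk = ws[ts >= t].sum()
        d = int(((ts == t) & (es == 1)).sum())
        h0[k] = d / (at_risk * scale)
    return uniq, np.cumsum(h0)


def cox_fit(X: pd.DataFrame, time, event, lam: float = 0.0,
            tol: float = 1e-8, max_iter: int = 100) -> SurvivalModel:
    """Cox proportional hazards fit (Efron ties) by Newton-Raphson.

    Returns hazard ratios with Wald confidence intervals from the observed
    information when unpenalized.  Constant covariates are an error;
    fewer events than covariates triggers a warning.
    """
    X = pd.DataFrame(X).astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("negative survival times")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    if event.sum() < X.shape[1]:
        warnings.warn("fewer events than covariates; estimates unstable")
    xv = X.to_numpy()
    beta, nll, grad, hess, n_iter = _newton_cox(xv, time, event, lam, tol, max_iter)
    coefs = pd.Series(beta, index=X.columns, name="coef")
    summary = None
    if lam == 0.0:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
        zsc = beta / se
        summary = pd.DataFrame({
            "coef": beta, "se": se, "hr": np.exp(beta),
            "hr_ci_low": np.exp(beta - 1.959963984540054 * se),
            "hr_ci_high": np.exp(beta + 1.959963984540054 * se),
            "p": 2 * stats.norm.sf(np.abs(zsc)),
        }, index=X.columns)
    bt, bh = _breslow_baseline(xv, time, event, beta)
    return SurvivalModel(coefs, lam, summary, bt, bh, n_iter,
                         float(np.linalg.norm(grad)), -float(nll))


def _partial_loglik(beta, X, time, event):
    nll, _, _ = _efron_nll_grad_hess(beta, X, time, event, 0.0, want_hess=False)
    return -nll


def _partial_loglik_eta(eta, time, event):
    """Efron log partial likelihood evaluated directly from the linear
    predictor (value is invariant to shifting eta)."""
    eta = np.asarray(eta, dtype=float)
    sh = eta - eta.max()
    nll, _, _ = _efron_core(sh, np.exp(sh), np.zeros(0),
                            np.zeros((len(eta), 0)), time, event, 0.0, False)
    return -nll


def _fit_ridge_reduced(Z, time, event, lam, tol, max_iter=100):
    """Ridge Cox fit via the row space of Z.

    For lam > 0 the penalized optimum lies in the row space of Z (any
    orthogonal component leaves the likelihood unchanged but raises the
    penalty), so Newton runs in min(n, p) dimensions: Z = U S V',
    beta = V gamma, eta = (U S) gamma, and ||beta|| = ||gamma||.
    """
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > 1e-10 * s[0]
    else:
        keep = np.zeros(s.shape, dtype=bool)
    m = u[:, keep] * s[keep]
    gamma, nll, grad, hess, n_iter = _newton_cox(m, time, event, lam, tol,
                                                 max_iter)
    beta = vt[keep].T @ gamma
    return beta, nll, grad, n_iter


def ridge_cox_fit(X: pd.DataFrame, time, event, lambda_grid=None,
                  nfolds: int = 10, seed: int = 0,
                  tol: float = 1e-8) -> SurvivalModel:
    """Ridge-penalized Cox: -loglik(beta) + (lambda/2)*||beta||^2.

    Features are standardized internally; coefficients are returned on the
    original scale.  Lambda is chosen from ``lambda_grid`` by minimizing
    the mean cross-validated partial-likelihood deviance (for fold k:
    -2 * [loglik_all(beta_-k) - loglik_-k(beta_-k)]), then the model is
    refit on the full data at the chosen lambda.
    """
    X = pd.DataFrame(X).astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if lambda_grid is None:
        lambda_grid = np.geomspace(0.01, 100.0, 10)
    lambda_grid = sorted(float(l) for l in lambda_grid)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((X - mean) / sd).to_numpy()
    n = len(time)
    rng = np.random.default_rng(seed)
    fold = np.array([i % nfolds for i in range(n)])
    rng.shuffle(fold)

    cv_rows = []
    for lam in lambda_grid:
        devs = []
        for k in range(nfolds):
            tr = fold != k
            beta_k, *_ = _fit_ridge_reduced(Z[tr], time[tr], event[tr], lam, tol)
            ll_all = _partial_loglik_eta(Z @ beta_k, time, event)
            ll_tr = _partial_loglik_eta(Z[tr] @ beta_k, time[tr], event[tr])
            devs.append(-2.0 * (ll_all - ll_tr))
        cv_rows.append((lam, float(np.mean(devs)), float(np.std(devs))))
    cv = pd.DataFrame(cv_rows, columns=["lam", "mean_deviance", "sd_deviance"])
    best = float(cv.loc[cv["mean_deviance"].idxmin(), "lam"])

    beta_std, nll, grad, n_iter = _fit_ridge_reduced(Z, time, event, best, tol)
    beta = beta_std / sd.to_numpy()
    coefs = pd.Series(beta, index=X.columns, name="coef")
    bt, bh = _breslow_baseline(X.to_numpy(), time, event, beta)
    return SurvivalModel(coefs, best, None, bt, bh, n_iter,
                         float(np.linalg.norm(grad)),
                         float(_partial_loglik_eta(Z @ beta_std, time, event)),
                         x_mean=mean, x_sd=sd, cv_deviance=cv)


# ---------------------------------------------------------------------------
# Descriptive estimators
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray          # Greenwood
    median: float                 # inf when S never reaches 0.5


def km_estimate(time, event) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with Greenwood variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    tab = kmf.event_table
    times = tab.index.to_numpy(dtype=float)
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
    var = surv ** 2 * np.cumsum(term)
    med = float(kmf.median_survival_time_)
    return KMEstimate(times, surv, var, med)


def logrank_test(time, event, groups) -> tuple[float, int, float]:
    """Mantel-Haenszel log-rank test; returns (chi2, df, p)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    res = multivariate_logrank_test(np.asarray(time, dtype=float), groups,
                                    np.asarray(event, dtype=int))
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Risk scores and metrics
# ---------------------------------------------------------------------------

def risk_score(model: SurvivalModel, X: pd.DataFrame, name: str = "risk") -> pd.Series:
    """Linear predictor x . beta-hat (higher = higher hazard)."""
    X = pd.DataFrame(X)
    missing = [c for c in model.coefficients.index if c not in X.columns]
    if missing:
        raise KeyError(f"missing covariates: {missing}")
    lp = X[list(model.coefficients.index)].astype(float).to_numpy() @ \
        model.coefficients.to_numpy()
    return pd.Series(lp, index=X.index, name=name)


def cindex(scores, time, event) -> float:
    """Harrell's concordance index.

    Permissible pairs: t_i < t_j with event_i = 1 (tied event times are not
    compared).  Concordant when the earlier-failing patient has the higher
    score; tied scores count 0.5.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = earlier.sum()
    if n_pairs == 0:
        raise ValueError("no permissible pairs")
    conc = (s[:, None] > s[None, :]) & earlier
    ties = (s[:, None] == s[None, :]) & earlier
    return float((conc.sum() + 0.5 * ties.sum()) / n_pairs)


def _censor_survival_left(time, event):
    """KM of the censoring distribution; returns a left-limit evaluator."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), 1 - np.asarray(event, dtype=int))
    tl = kmf.survival_function_.index.to_numpy(dtype=float)
    sv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def g_left(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(tl, t, side="left") - 1
        out = np.where(idx >= 0, sv[np.clip(idx, 0, len(sv) - 1)], 1.0)
        return out

    def g_at(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(tl, t, side="right") - 1
        return np.where(idx >= 0, sv[np.clip(idx, 0, len(sv) - 1)], 1.0)

    return g_left, g_at


def td_auc(scores, time, event, t_eval) -> pd.Series:
    """Cumulative-case / dynamic-control AUC(t) with inverse-probability-
    of-censoring (Kaplan-Meier) weighting of the cases.

    With no censoring this reduces exactly to the Mann-Whitney AUC of the
    binary outcome (T <= t) vs (T > t).  Horizons with no case or no
    control yield NaN with a warning.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g_left, _ = _censor_survival_left(t, e)
    out = {}
    for th in np.atleast_1d(np.asarray(t_eval, dtype=float)):
        cases = (t <= th) & (e == 1)
        controls = t > th
        if cases.sum() == 0 or controls.sum() == 0:
            warnings.warn(f"no cases or controls at t={th}; AUC undefined")
            out[float(th)] = np.nan
            continue
        g = g_left(t[cases])
        w = np.where(g > 0, 1.0 / np.where(g > 0, g, 1.0), 0.0)
        sc, sn = s[cases], s[controls]
        gt = (sc[:, None] > sn[None, :]).sum(axis=1)
        eq = (sc[:, None] == sn[None, :]).sum(axis=1)
        num = float((w * (gt + 0.5 * eq)).sum())
        den = float(w.sum() * controls.sum())
        out[float(th)] = num / den
    return pd.Series(out, name="auc")


@dataclass(eq=False)
class StagingResult:
    """Three-class risk staging from 1-D k-means on risk scores."""

    groups: pd.Series                     # patient -> low/medium/high
    group_means: pd.Series                # ascending
    inertia: float
    seed: int


def staging_3c(scores: pd.Series, seed: int = 0, n_restarts: int = 50) -> StagingResult:
    """k-means (k=3) on risk scores; clusters named low/medium/high by
    ascending mean risk."""
    scores = pd.Series(scores)
    if scores.nunique() < 3:
        raise ValueError("need >= 3 distinct score values")
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed)
    lab = km.fit_predict(scores.to_numpy(dtype=float).reshape(-1, 1))
    means = pd.Series(km.cluster_centers_.ravel())
    order = means.sort_values().index.to_list()
    names = {order[0]: "low", order[1]: "medium", order[2]: "high"}
    groups = pd.Series([names[l] for l in lab], index=scores.index, name="risk_group")
    gmeans = scores.groupby(groups).mean().loc[["low", "medium", "high"]]
    if not (gmeans.iloc[0] < gmeans.iloc[1] < gmeans.iloc[2]):
        raise AssertionError("risk group means not strictly ascending")
    return StagingResult(groups, gmeans, float(km.inertia_), seed)


def train_test_split(clinical: pd.DataFrame, train_fraction: float = 82 / 124,
                     seed: int = 0, balance_vars=None, alpha: float = 0.05,
                     max_redraws: int = 100):
    """Seeded random patient split with covariate balance checking.

    Categorical variables are compared between the arms with a chi-squared
    test, continuous ones with a rank-sum test; if any p < alpha the split
    is redrawn with an incremented seed (up to ``max_redraws``), and the
    final seed is reported.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if balance_vars is None:
        balance_vars = {"sex": "categorical", "ptnm": "categorical",
                        "age": "continuous"}
    ids = clinical["patient_id"].to_numpy()
    n = len(ids)
    n_train = int(round(train_fraction * n))
    clin = clinical.set_index("patient_id")
    for attempt in range(max_redraws + 1):
        cur = seed + attempt
        rng = np.random.default_rng(cur)
        perm = rng.permutation(n)
        train = sorted(ids[perm[:n_train]])
        test = sorted(ids[perm[n_train:]])
        rows = []
        ok = True
        for var, kind in balance_vars.items():
            a, b = clin.loc[train, var], clin.loc[test, var]
            if kind == "categorical":
                tab = pd.crosstab(
                    np.r_[np.repeat("train", len(a)), np.repeat("test", len(b))],
                    pd.concat([a, b]).to_numpy())
                if tab.shape[1] < 2:
                    p = 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p = float(stats.chi2_contingency(tab.to_numpy(),
                                                         correction=False)[1])
            else:
                p = float(stats.mannwhitneyu(a.astype(float), b.astype(float),
                                             alternative="two-sided").pvalue)
            rows.append((var, kind, p))
            ok &= p >= alpha
        report = pd.DataFrame(rows, columns=["variable", "kind", "p"])
        if ok:
            report.attrs["seed"] = cur
            report.attrs["n_redraws"] = attempt
            return train, test, report
    raise RuntimeError(
        f"no balanced split after {max_redraws} redraws; last report:\n{report}")


def predict_survprob(model: SurvivalModel, X: pd.DataFrame, t: float) -> pd.Series:
    """S(t | x) = exp(-H0(t) * exp(x . beta)) with the Breslow baseline."""
    if t < 0:
        raise ValueError("t must be non-negative")
    lp = risk_score(model, X).to_numpy()
    idx = np.searchsorted(model.baseline_times, t, side="right") - 1
    h0 = model.baseline_h0[idx] if idx >= 0 else 0.0
    return pd.Series(np.exp(-h0 * np.exp(lp)), index=pd.DataFrame(X).index,
                     name=f"survprob_t{t:g}")


def decision_curve(pred_risk: pd.Series, observed: pd.Series,
                   thresholds) -> pd.DataFrame:
    """Net benefit NB(p_t) = TP/n - (FP/n) * p_t/(1-p_t) across thresholds.

    ``observed`` is 1 (event by t), 0 (event-free at t) or NaN (censored
    before t, excluded; count in ``df.attrs['n_excluded']``).  Treat-all
    and treat-none reference strategies are included.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie in (0, 1)")
    pred = pd.Series(pred_risk).astype(float)
    obs = pd.Series(observed).astype(float).reindex(pred.index)
    keep = obs.notna()
    n_excluded = int((~keep).sum())
    pred, obs = pred[keep], obs[keep]
    n = len(pred)
    if n == 0:
        raise ValueError("no evaluable patients")
    prev = float(obs.mean())
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt)
        treated = pred >= pt
        tp = float((treated & (obs == 1)).sum())
        fp = float((treated & (obs == 0)).sum())
        nb = tp / n - (fp / n) * odds
        nb_all = prev - (1.0 - prev) * odds
        rows.append((pt, nb, nb_all, 0.0))
    df = pd.DataFrame(rows, columns=["threshold", "nb_model", "nb_all", "nb_none"])
    df.attrs["n_excluded"] = n_excluded
    df.attrs["prevalence"] = prev
    return df
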