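"""Outcome modelling: univariate screens and the bootstrap-LASSO
nested-CV framework.

Two lesion-level endpoints are supported:

* ``OR`` — binary overall response, logistic models scored by AUC;
* ``progression`` — right-censored time to progression, Cox models
  (Breslow ties) scored by Harrell's c-index.

Feature selection follows a bootstrap-stabilised LASSO: on each of N
stratified bootstrap resamples of a training set, the L1 penalty is
tuned by inner cross-validation and the support recorded; features are
ranked by selection frequency.  Model order (how many top-ranked
features enter the final unpenalised model) is chosen from M bootstrap
out-of-bag metric estimates with a one-standard-error parsimony rule.
Generalisation performance comes from an outer repeated stratified
K-fold loop in which all selection happens inside the training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "ModelingConfig",
    "spearman_univariate",
    "cox_univariate",
    "bonferroni_threshold",
    "univariate_screen",
    "bootstrap_lasso_rank",
    "model_order_select",
    "one_se_choice",
    "ModelOrderCurve",
    "nested_cv_evaluate",
    "CVPerformance",
    "adasyn_balance",
    "km_stratify",
    "calibration_curve",
    "fit_final_model",
    "FittedModel",
]

COEF_CAP = 10.0  # |beta| beyond this on standardized inputs flags monotone likelihood


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelingConfig:
    """Settings for the nested-CV bootstrap-LASSO framework.

    Defaults are the study conditions: 10x5-fold outer CV, N = M = 100
    bootstrap replicates, a 50-point geometric lambda grid spanning 3
    decades below the smallest all-zero penalty, inner 5-fold tuning,
    one-SE model-order rule.
    """

    endpoint: str = "OR"                  # 'OR' | 'progression'
    outer_repeats: int = 10
    outer_folds: int = 5
    n_bootstrap_rank: int = 100           # N
    n_bootstrap_order: int = 100          # M
    inner_folds: int = 5
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    one_se_rule: bool = True
    adasyn: bool = False
    adasyn_k: int = 5
    max_order: int | None = None
    n_ci_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.endpoint not in ("OR", "progression"):
            raise ValueError("endpoint must be 'OR' or 'progression'")
        if self.n_bootstrap_rank < 1 or self.n_bootstrap_order < 1:
            raise ValueError("bootstrap counts must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")


# ---------------------------------------------------------------------------
# univariate screens


def spearman_univariate(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) between a feature and a
    binary response, with its two-sided p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def cox_univariate(x, time, event) -> tuple[float, float, float]:
    """Univariate Cox regression of one feature (Breslow ties).

    Returns (Harrell c-index of the fitted risk direction, hazard ratio
    per unit feature, Wald p).  Monotone-likelihood fits are flagged by
    capping the coefficient at +/-10 with a warning.
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < 1:
        raise ValueError("no events; Cox model undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.PHReg(time, x[:, None], status=event, ties="breslow")
        try:
            res = model.fit(disp=False)
            beta = float(res.params[0])
            p = float(res.pvalues[0])
        except Exception:
            beta, p = np.inf, np.nan
    if not np.isfinite(beta) or abs(beta) > COEF_CAP:
        warnings.warn("monotone likelihood: coefficient capped", RuntimeWarning)
        if not np.isfinite(beta):
            # sign of the association from the concordance direction
            c_raw = concordance_index(time, -x, event)
            beta = COEF_CAP if c_raw >= 0.5 else -COEF_CAP
        beta = float(np.clip(beta, -COEF_CAP, COEF_CAP))
        p = np.nan if not np.isfinite(p) else p
    risk = beta * x
    cidx = concordance_index(time, -risk, event)
    return float(cidx), float(np.exp(beta)), p


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise corrected significance threshold alpha/k, rounded to
    3 decimals as conventionally reported."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return round(alpha / k, 3)


def univariate_screen(
    data: pd.DataFrame,
    features: list[str],
    or_col: str = "OR",
    time_col: str = "time",
    event_col: str = "event",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Spearman-vs-response and univariate-Cox summary with
    Bonferroni-corrected significance flags."""
    thr = bonferroni_threshold(alpha, len(features))
    rows = []
    for f in features:
        rho, p_or = spearman_univariate(data[f], data[or_col])
        cidx, hr, p_prog = cox_univariate(data[f], data[time_col], data[event_col])
        rows.append(
            {
                "feature": f, "spearman_OR": rho, "p_OR": p_or,
                "c_index": cidx, "hazard_ratio": hr, "p_progression": p_prog,
                "sig_OR": p_or < thr,
                "sig_progression": (p_prog < thr) if np.isfinite(p_prog) else False,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["bonferroni_threshold"] = thr
    return out


# ---------------------------------------------------------------------------
# standardization and resampling helpers


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _stratified_bootstrap(rng: np.random.Generator, strata: np.ndarray) -> np.ndarray:
    """Resample with replacement within each stratum, preserving sizes."""
    idx = []
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.sort(np.concatenate(idx))


def _is_degenerate(endpoint: str, y, time=None, event=None, idx=None) -> bool:
    if endpoint == "OR":
        return np.unique(y[idx]).size < 2
    return event[idx].sum() < 1


# ---------------------------------------------------------------------------
# LASSO paths


def _logistic_lambda_grid(X, y, n_lambda, min_ratio):
    n = len(y)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_logistic_lasso(X, y, lam):
    n = len(y)
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", max_iter=500, tol=1e-6
    )
    clf.fit(X, y)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def _logistic_cv_lambda(X, y, grid, inner_folds, rng):
    """Pick lambda minimising mean validation deviance (log loss)."""
    n_splits = min(inner_folds, int(np.bincount(y.astype(int)).min()))
    if n_splits < 2:
        return grid[len(grid) // 2]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    dev = np.zeros(len(grid))
    for tr, va in skf.split(X, y):
        if np.unique(y[tr]).size < 2:
            continue
        for k, lam in enumerate(grid):
            coef, icpt = _fit_logistic_lasso(X[tr], y[tr], lam)
            eta = X[va] @ coef + icpt
            p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            dev[k] += -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
    return grid[int(np.argmin(dev))]


def _cox_neg_log_pl(X, time, event, beta) -> float:
    """Breslow negative log partial likelihood at fixed coefficients."""
    eta = X @ beta
    order = np.argsort(-time)  # descending: risk set = prefix
    eta, ev = eta[order], event[order]
    t = time[order]
    log_cum = np.logaddexp.accumulate(eta)
    # handle ties: risk set includes all with time >= t_i
    # for descending sort with ties, extend cumsum to the last tied index
    _, inv, counts = np.unique(-t, return_inverse=True, return_counts=True)
    last_idx = np.cumsum(counts) - 1
    log_risk = log_cum[last_idx[inv]]
    ll = np.sum(ev * (eta - log_risk))
    return float(-ll)


def _cox_lasso_path(X, time, event, alphas):
    """Coefficients along an L1 path for the Cox model (coxnet)."""
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(
        alphas=alphas, l1_ratio=1.0, fit_baseline_model=False, normalize=False,
        max_iter=100000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coefs = np.zeros((len(alphas), X.shape[1]))
    fitted = list(model.alphas_)
    for k, a in enumerate(alphas):
        if a in fitted:
            coefs[k] = model.coef_[:, fitted.index(a)]
        else:  # path truncated; nearest fitted alpha
            j = int(np.argmin(np.abs(np.log(np.asarray(fitted)) - np.log(a))))
            coefs[k] = model.coef_[:, j]
    return coefs


def _cox_lambda_grid(X, time, event, n_lambda, min_ratio):
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    probe = CoxnetSurvivalAnalysis(
        n_alphas=10, l1_ratio=1.0, alpha_min_ratio=0.5, fit_baseline_model=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probe.fit(X, y)
    lam_max = float(probe.alphas_[0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _cox_cv_lambda(X, time, event, grid, inner_folds, rng):
    n_splits = min(inner_folds, int(event.sum()))
    if n_splits < 2:
        return grid[len(grid) // 2]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    dev = np.zeros(len(grid))
    for tr, va in skf.split(X, event):
        if event[tr].sum() < 1 or event[va].sum() < 1:
            continue
        try:
            coefs = _cox_lasso_path(X[tr], time[tr], event[tr], grid)
        except Exception:
            continue
        for k in range(len(grid)):
            dev[k] += _cox_neg_log_pl(X[va], time[va], event[va], coefs[k])
    return grid[int(np.argmin(dev))]


# ---------------------------------------------------------------------------
# bootstrap LASSO feature ranking


def bootstrap_lasso_rank(
    X: pd.DataFrame,
    outcome,
    config: ModelingConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Rank features by LASSO selection frequency over N stratified
    bootstrap resamples.

    ``outcome`` is the binary vector for the OR endpoint or a
    ``(time, event)`` tuple for progression.  Inputs are standardized
    internally (columnwise z-score on the given data).  Ties in
    frequency break by mean absolute bootstrap coefficient, then name.
    Degenerate resamples (single class / no events) are redrawn up to a
    cap and skipped after that.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = list(X.columns)
    if len(names) < 2:
        raise ValueError("need >= 2 features to rank")
    Xv = X.to_numpy(dtype=float)
    n = len(Xv)
    if n < 20:
        raise ValueError("need n >= 20 for bootstrap ranking")
    mean, sd = _standardize_fit(Xv)
    Xs = (Xv - mean) / sd

    if config.endpoint == "OR":
        y = np.asarray(outcome, int)
        strata = y
        time = event = None
        grid = _logistic_lambda_grid(Xs, y, config.n_lambda, config.lambda_min_ratio)
    else:
        time, event = (np.asarray(a) for a in outcome)
        event = event.astype(int)
        if event.sum() < 5:
            raise ValueError("need >= 5 events for progression ranking")
        y = event
        strata = event
        grid = _cox_lambda_grid(Xs, time, event, config.n_lambda, config.lambda_min_ratio)

    sel_counts = np.zeros(len(names))
    abs_coefs = np.zeros(len(names))
    n_ok = 0
    for _ in range(config.n_bootstrap_rank):
        idx = None
        for _try in range(20):
            cand = _stratified_bootstrap(rng, strata)
            if not _is_degenerate(config.endpoint, y, time, event, cand):
                idx = cand
                break
        if idx is None:
            continue
        try:
            if config.endpoint == "OR":
                lam = _logistic_cv_lambda(Xs[idx], y[idx], grid, config.inner_folds, rng)
                coef, _ = _fit_logistic_lasso(Xs[idx], y[idx], lam)
            else:
                lam = _cox_cv_lambda(Xs[idx], time[idx], event[idx], grid,
                                     config.inner_folds, rng)
                coef = _cox_lasso_path(Xs[idx], time[idx], event[idx],
                                       np.array([lam]))[0]
        except Exception as exc:  # pragma: no cover - rare solver failures
            warnings.warn(f"bootstrap LASSO fit failed: {exc}", RuntimeWarning)
            continue
        nz = np.abs(coef) > 1e-10
        sel_counts += nz
        abs_coefs += np.abs(coef)
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("all bootstrap resamples failed")

    freq = sel_counts / n_ok
    mean_abs = abs_coefs / n_ok
    order = sorted(
        range(len(names)), key=lambda i: (-freq[i], -mean_abs[i], names[i])
    )
    out = pd.DataFrame(
        {
            "feature": [names[i] for i in order],
            "frequency": freq[order],
            "mean_abs_coef": mean_abs[order],
            "rank": np.arange(1, len(names) + 1),
        }
    ).set_index("feature")
    out.attrs["n_resamples_used"] = n_ok
    return out


# ---------------------------------------------------------------------------
# unpenalized fits and scoring


@dataclass
class FittedModel:
    """An unpenalised logistic or Cox fit on standardized features."""

    endpoint: str
    features: list[str]
    coef: np.ndarray                      # per-feature, standardized scale
    intercept: float                      # 0 for Cox
    mean: np.ndarray
    sd: np.ndarray
    baseline_cumhaz: pd.DataFrame | None = None   # Cox: Breslow H0(t)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.features].to_numpy(dtype=float) - self.mean) / self.sd
        return Z @ self.coef + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if self.endpoint != "OR":
            raise ValueError("predict_proba is for the OR endpoint")
        return expit(self.linear_predictor(X))

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Relative risk score (higher = earlier event for Cox)."""
        return self.linear_predictor(X)


def _fit_logistic(Xs, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(Xs, has_constant="add")).fit(
                disp=False, maxiter=200
            )
            params = np.asarray(res.params)
        except Exception:
            params = None
    if params is None or not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
        # separation fallback: light ridge keeps the fold usable
        clf = LogisticRegression(l1_ratio=0.0, C=100.0, max_iter=2000)
        clf.fit(Xs, y)
        params = np.concatenate(([clf.intercept_[0]], clf.coef_.ravel()))
    return float(params[0]), params[1:]


def _fit_cox(Xs, time, event):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.PHReg(time, Xs, status=event, ties="breslow").fit(disp=False)
            beta = np.asarray(res.params)
        except Exception:
            beta = None
    if beta is None or not np.all(np.isfinite(beta)) or np.abs(beta).max() > COEF_CAP:
        if beta is None:
            beta = np.zeros(Xs.shape[1])
        warnings.warn("Cox fit unstable: coefficients capped", RuntimeWarning)
        beta = np.clip(beta, -COEF_CAP, COEF_CAP)
    return beta


def _breslow_cumhaz(Xs, time, event, beta) -> pd.DataFrame:
    eta = Xs @ beta
    order = np.argsort(time)
    t, ev, ex = time[order], event[order], np.exp(eta[order])
    risk_rev = np.cumsum(ex[::-1])[::-1]  # sum over time >= t_i
    uniq = np.unique(t[ev == 1])
    h0 = []
    cum = 0.0
    for tu in uniq:
        d = int(ev[t == tu].sum())
        denom = risk_rev[np.searchsorted(t, tu, side="left")]
        cum += d / denom
        h0.append((tu, cum))
    return pd.DataFrame(h0, columns=["time", "cumhaz"])


def fit_model(endpoint: str, X: pd.DataFrame, outcome) -> FittedModel:
    """Fit an unpenalised model on the given features; standardization
    parameters are estimated from these rows only."""
    Xv = X.to_numpy(dtype=float)
    mean, sd = _standardize_fit(Xv)
    Xs = (Xv - mean) / sd
    if endpoint == "OR":
        y = np.asarray(outcome, int)
        icpt, coef = _fit_logistic(Xs, y)
        return FittedModel(endpoint, list(X.columns), np.asarray(coef, float),
                           icpt, mean, sd)
    time, event = (np.asarray(a, float) for a in outcome)
    event = event.astype(int)
    beta = _fit_cox(Xs, time, event)
    base = _breslow_cumhaz(Xs, time, event, beta)
    return FittedModel(endpoint, list(X.columns), np.asarray(beta, float),
                       0.0, mean, sd, baseline_cumhaz=base)


def _metric(endpoint: str, scores, outcome) -> float:
    if endpoint == "OR":
        return float(roc_auc_score(np.asarray(outcome, int), scores))
    time, event = outcome
    return float(concordance_index(time, -np.asarray(scores), event))


# ---------------------------------------------------------------------------
# model order selection


def one_se_choice(table: pd.DataFrame, one_se_rule: bool = True) -> int:
    """Model order from a (order -> mean, se) curve: the smallest order
    whose mean is within one standard error of the best order's mean
    (or simply the argmax when the rule is disabled)."""
    valid = table.dropna(subset=["mean"])
    best_order = int(valid["mean"].idxmax())
    if not one_se_rule:
        return best_order
    best_mean = float(valid.loc[best_order, "mean"])
    se_best = float(valid.loc[best_order, "se"])
    return int(valid.index[valid["mean"] >= best_mean - se_best].min())


@dataclass
class ModelOrderCurve:
    """Mean out-of-bag metric vs model order with the chosen order."""

    table: pd.DataFrame          # index=order; columns mean, se, n_boot
    chosen_order: int
    endpoint: str


def model_order_select(
    X: pd.DataFrame,
    outcome,
    ranking: pd.DataFrame,
    config: ModelingConfig,
    rng: np.random.Generator | None = None,
) -> ModelOrderCurve:
    """Choose how many top-ranked features the final model carries.

    For each order i, the top-i features are refit (unpenalised) on M
    stratified bootstrap resamples — the same M resamples for every
    order, so order comparisons are paired — and scored on the
    out-of-bag lesions.  The chosen order is the smallest whose mean
    metric is within one standard error of the best order's mean.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ranked = list(ranking.index)
    n_orders = len(ranked) if config.max_order is None else min(config.max_order, len(ranked))

    if config.endpoint == "OR":
        y = np.asarray(outcome, int)
        strata = y
        time = event = None
    else:
        time, event = (np.asarray(a, float) for a in outcome)
        event = event.astype(int)
        y = strata = event

    resamples = []
    for _ in range(config.n_bootstrap_order):
        for _try in range(20):
            idx = _stratified_bootstrap(rng, strata)
            oob = np.setdiff1d(np.arange(len(X)), idx)
            if oob.size < 2 or _is_degenerate(config.endpoint, y, time, event, idx):
                continue
            if config.endpoint == "OR" and np.unique(y[oob]).size < 2:
                continue
            if config.endpoint == "progression" and event[oob].sum() < 1:
                continue
            resamples.append((idx, oob))
            break

    rows = []
    metrics_by_order = {}
    for i in range(1, n_orders + 1):
        feats = ranked[:i]
        vals = []
        for idx, oob in resamples:
            Xi = X.iloc[idx][feats]
            Xo = X.iloc[oob]
            try:
                if config.endpoint == "OR":
                    m = fit_model("OR", Xi, y[idx])
                    score = m.predict_proba(Xo)
                    vals.append(_metric("OR", score, y[oob]))
                else:
                    m = fit_model("progression", Xi, (time[idx], event[idx]))
                    score = m.predict_risk(Xo)
                    vals.append(_metric("progression", score, (time[oob], event[oob])))
            except Exception:
                continue
        vals = np.asarray(vals)
        if vals.size == 0:
            rows.append({"order": i, "mean": np.nan, "se": np.nan, "n_boot": 0})
            continue
        rows.append(
            {
                "order": i,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
                "n_boot": int(vals.size),
            }
        )
        metrics_by_order[i] = vals
    table = pd.DataFrame(rows).set_index("order")
    chosen = one_se_choice(table, config.one_se_rule)
    return ModelOrderCurve(table, chosen, config.endpoint)


# ---------------------------------------------------------------------------
# ADASYN


def adasyn_balance(X, y, k: int = 5, rng: np.random.Generator | None = None,
                   extra: np.ndarray | None = None):
    """Adaptive synthetic oversampling of the minority class.

    Synthetic samples are interpolated between minority points and their
    k nearest minority neighbours, with per-point counts weighted toward
    points whose neighbourhoods are majority-dominated (the hard-to-learn
    boundary region).  Returns arrays with minority count raised to
    approximately the majority count (input returned unchanged when
    already balanced).  ``extra`` (e.g. survival times) is interpolated
    with the same weights and returned as a third output when given.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("adasyn_balance requires binary labels")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return (X, y) if extra is None else (X, y, extra)
    if n_min <= k:
        raise ValueError(f"minority count {n_min} <= k={k}; use a smaller k")

    Xmin = X[y == minority]
    extra_min = None if extra is None else np.asarray(extra, float)[y == minority]
    # density weights from the full-data neighbourhood composition
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx_all = nn_all.kneighbors(Xmin)
    r = np.array([
        np.mean(y[idx_row[1:]] != minority) for idx_row in idx_all
    ])
    if r.sum() == 0:
        r = np.ones_like(r)
    r = r / r.sum()
    g_total = n_maj - n_min
    g = np.floor(r * g_total).astype(int)
    # distribute the rounding remainder to the largest weights
    short = g_total - g.sum()
    if short > 0:
        g[np.argsort(-r)[:short]] += 1

    nn_min = NearestNeighbors(n_neighbors=min(k + 1, len(Xmin))).fit(Xmin)
    _, idx_min = nn_min.kneighbors(Xmin)
    synth, synth_extra = [], []
    for i, gi in enumerate(g):
        for _ in range(gi):
            j = idx_min[i][rng.integers(1, idx_min.shape[1])]
            lam = rng.random()
            synth.append(Xmin[i] + lam * (Xmin[j] - Xmin[i]))
            if extra_min is not None:
                synth_extra.append(extra_min[i] + lam * (extra_min[j] - extra_min[i]))
    if synth:
        X_out = np.vstack([X, np.array(synth)])
        y_out = np.concatenate([y, np.full(len(synth), minority)])
        if extra is not None:
            extra_out = np.concatenate([np.asarray(extra, float), np.array(synth_extra)])
            return X_out, y_out, extra_out
        return X_out, y_out
    return (X, y) if extra is None else (X, y, extra)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class CVPerformance:
    """Outer-fold metric distribution with bootstrap CI, per subgroup."""

    endpoint: str
    fold_metrics: pd.DataFrame       # columns: repeat, fold, subgroup, metric
    summary: pd.DataFrame            # index=subgroup; mean, ci_lo, ci_hi, n_folds
    fold_models: list = field(default_factory=list)
    predictions: pd.DataFrame | None = None   # out-of-fold scores: repeat, fold, row, score

    @property
    def mean(self) -> float:
        return float(self.summary.loc["all", "mean"])

    @property
    def ci(self) -> tuple[float, float]:
        row = self.summary.loc["all"]
        return float(row["ci_lo"]), float(row["ci_hi"])


def _percentile_ci(values, n_boot, rng, level=0.95):
    values = np.asarray(values, float)
    means = np.array([
        rng.choice(values, size=values.size, replace=True).mean() for _ in range(n_boot)
    ])
    a = (1 - level) / 2
    return float(np.quantile(means, a)), float(np.quantile(means, 1 - a))


def fit_fold(X_train: pd.DataFrame, outcome_train, config: ModelingConfig,
             fold_seed: int):
    """Train one fold end to end: rank, order-select and refit, using
    only the training rows.  Deterministic given (training data, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(fold_seed))
    Xf = X_train
    out = outcome_train
    if config.adasyn:
        if config.endpoint == "OR":
            Xb, yb = adasyn_balance(Xf.to_numpy(float), np.asarray(out, int),
                                    k=config.adasyn_k, rng=rng)
            Xf = pd.DataFrame(Xb, columns=Xf.columns)
            out = yb
        else:
            t, e = out
            Xb, eb, tb = adasyn_balance(Xf.to_numpy(float), np.asarray(e, int),
                                        k=config.adasyn_k, rng=rng,
                                        extra=np.asarray(t, float))
            Xf = pd.DataFrame(Xb, columns=Xf.columns)
            out = (tb, eb)
    if Xf.shape[1] == 1:
        # single-candidate model: nothing to rank or order-select
        name = Xf.columns[0]
        ranking = pd.DataFrame(
            {"feature": [name], "frequency": [1.0], "mean_abs_coef": [np.nan],
             "rank": [1]}
        ).set_index("feature")
        curve = ModelOrderCurve(
            pd.DataFrame({"order": [1], "mean": [np.nan], "se": [np.nan],
                          "n_boot": [0]}).set_index("order"),
            1, config.endpoint,
        )
        model = fit_model(config.endpoint, Xf, out)
        return model, ranking, curve
    ranking = bootstrap_lasso_rank(Xf, out, config, rng)
    curve = model_order_select(Xf, out, ranking, config, rng)
    feats = list(ranking.index[: curve.chosen_order])
    model = fit_model(config.endpoint, Xf[feats], out)
    return model, ranking, curve


def nested_cv_evaluate(
    X: pd.DataFrame,
    outcome,
    config: ModelingConfig,
    subgroups: pd.Series | None = None,
) -> CVPerformance:
    """Estimate generalisation performance with repeated stratified
    outer CV; all feature selection and tuning happens inside each
    training split.  Subgroup rows report the fold models applied to the
    subgroup members of each held-out fold."""
    if config.endpoint == "OR":
        y = np.asarray(outcome, int)
        strat = y
    else:
        time, event = (np.asarray(a, float) for a in outcome)
        event = event.astype(int)
        strat = event

    splitter = RepeatedStratifiedKFold(
        n_splits=config.outer_folds, n_repeats=config.outer_repeats,
        random_state=config.seed % (2**31 - 1),
    )
    records = []
    pred_records = []
    fold_models = []
    ss = np.random.SeedSequence(config.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in
                  ss.spawn(config.outer_folds * config.outer_repeats)]

    for f, (tr, te) in enumerate(splitter.split(X, strat)):
        rep, fold = divmod(f, config.outer_folds)
        if config.endpoint == "OR":
            out_tr, out_te = y[tr], y[te]
        else:
            out_tr = (time[tr], event[tr])
            out_te = (time[te], event[te])
        try:
            model, ranking, curve = fit_fold(X.iloc[tr], out_tr, config, fold_seeds[f])
        except Exception as exc:
            warnings.warn(f"fold {f} skipped: {exc}", RuntimeWarning)
            continue
        fold_models.append(
            {"repeat": rep, "fold": fold, "seed": fold_seeds[f],
             "train_idx": tr, "model": model, "ranking": ranking, "curve": curve}
        )

        try:
            scores_te = (model.predict_proba(X.iloc[te]) if config.endpoint == "OR"
                         else model.predict_risk(X.iloc[te]))
            for r, s in zip(te, scores_te):
                pred_records.append({"repeat": rep, "fold": fold, "row": int(r),
                                     "score": float(s)})
        except Exception:
            scores_te = None

        def _eval(rows, label):
            if rows.size < 2:
                return
            Xe = X.iloc[rows]
            try:
                if config.endpoint == "OR":
                    if np.unique(y[rows]).size < 2:
                        return
                    m = _metric("OR", model.predict_proba(Xe), y[rows])
                else:
                    if event[rows].sum() < 1:
                        return
                    m = _metric("progression", model.predict_risk(Xe),
                                (time[rows], event[rows]))
            except Exception:
                return
            records.append({"repeat": rep, "fold": fold, "subgroup": label, "metric": m})

        _eval(te, "all")
        if subgroups is not None:
            for g in pd.unique(subgroups):
                _eval(te[np.asarray(subgroups)[te] == g], str(g))

    fold_df = pd.DataFrame(records)
    if fold_df.empty or "all" not in set(fold_df["subgroup"]):
        raise RuntimeError("nested CV produced no evaluable folds")
    rng_ci = np.random.default_rng(np.random.SeedSequence([config.seed, 987654321]))
    rows = []
    for g, sub in fold_df.groupby("subgroup"):
        vals = sub["metric"].to_numpy()
        lo, hi = _percentile_ci(vals, config.n_ci_bootstrap, rng_ci)
        rows.append({"subgroup": g, "mean": float(vals.mean()),
                     "ci_lo": lo, "ci_hi": hi, "n_folds": len(vals)})
    summary = pd.DataFrame(rows).set_index("subgroup")
    return CVPerformance(config.endpoint, fold_df, summary, fold_models,
                         pd.DataFrame(pred_records))


def fit_final_model(X: pd.DataFrame, outcome, config: ModelingConfig):
    """Rank + order-select + refit on the full dataset — the reported
    model; generalisation estimates must come from ``nested_cv_evaluate``."""
    return fit_fold(X, outcome, config, config.seed)


# ---------------------------------------------------------------------------
# Kaplan-Meier stratification and calibration


def km_stratify(risk, time, event):
    """Median split of a risk score with Kaplan-Meier curves and the
    log-rank test between the high- and low-risk groups."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    med = np.median(risk)
    high = risk > med
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("median split produced a stratum with < 2 lesions")
    fitters = {}
    for label, sel in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter(label=label)
        kmf.fit(time[sel], event[sel])
        fitters[label] = kmf
    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    return {
        "groups": np.where(high, "high", "low"),
        "logrank_p": float(lr.p_value),
        "logrank_statistic": float(lr.test_statistic),
        "curves": fitters,
        "median_risk": float(med),
    }


def calibration_curve(pred_prob, labels) -> tuple[float, float]:
    """Logistic recalibration: regress observed labels on the logit of
    the predicted probabilities; ideal is slope 1, intercept 0."""
    p = np.asarray(pred_prob, float)
    ylab = np.asarray(labels, int)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie in (0, 1)")
    if np.unique(ylab).size < 2:
        raise ValueError("labels contain a single class")
    lp = logit(p)
    if np.ptp(lp) < 1e-12:
        raise ValueError("constant predictions cannot be calibrated")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(ylab, sm.add_constant(lp)).fit(disp=False, maxiter=200)
    icpt, slope = np.asarray(res.params)
    return float(slope), float(icpt)
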