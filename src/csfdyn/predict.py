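"""Outcome-prediction layer: logistic models, ROC, cut-offs, calibration.

The clinical endpoint is the desirable recovery level (dRL): modified Rankin
Scale 0-2 at follow-up, versus non-dRL (mRS 3-6). The candidate predictors
are the outflow resistance Rout and the drainage-derived RAP statistics. Five
model specifications are evaluated: each of Rout, dRAP1max%, dRAP2max% alone,
the two dRAP% terms combined, and the "total index" combining all three.
Single predictors are scored directly in their own units (monotone-equivalent
to the univariate logistic probability, so the AUC is identical and cut-offs
are reported on the predictor scale); multivariable models are scored by the
fitted logistic probability.

Discrimination is summarized by the Mann-Whitney AUC with a DeLong
variance-based 95% CI and a two-sided test against AUC = 0.5; the operating
point maximizes the Youden index; calibration uses the Hosmer-Lemeshow
chi-square over groups of predicted risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import SeparationWarning

MODEL_SPECS = (
    ("rout_only", ("rout",)),
    ("drap1", ("drap1max_pct",)),
    ("drap2", ("drap2max_pct",)),
    ("drap1_plus_drap2", ("drap1max_pct", "drap2max_pct")),
    ("total_index", ("rout", "drap1max_pct", "drap2max_pct")),
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Reporting-layer rounding: ties away from zero (89.47 -> 89.5, 56.25 -> 56.3)."""
    factor = 10.0**ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


def dichotomize_mrs(mrs) -> np.ndarray:
    """Map mRS 0-6 to the dRL indicator (1 for mRS <= 2, 0 for mRS 3-6)."""
    arr = np.asarray(mrs)
    if arr.ndim == 0:
        arr = arr[None]
        scalar = True
    else:
        scalar = False
    if not np.all(np.isin(arr, np.arange(7))):
        raise ValueError("mRS values must be integers in 0..6")
    out = (arr <= 2).astype(int)
    return int(out[0]) if scalar else out


# --------------------------------------------------------------------------
# Logistic regression by IRLS
# --------------------------------------------------------------------------

class LogisticOutcomeModel(BaseEstimator, ClassifierMixin):
    """Binary logistic regression fitted by iteratively reweighted least squares.

    Newton-Raphson (= IRLS for the canonical logit link) with deviance-based
    step-halving so the deviance is non-increasing across iterations;
    convergence when the largest coefficient step falls below ``tol`` (default
    1e-8) or after ``max_iter`` iterations. Wald standard errors come from the
    inverse observed information. (Quasi-)complete separation is reported via
    :class:`SeparationWarning` and ``separation_``; the coefficients of the
    final iteration are still exposed.

    Follows the scikit-learn estimator protocol (``fit``, ``predict``,
    ``predict_proba``, ``get_params``/``set_params``) and composes with
    sklearn pipelines and model selection.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100,
                 fit_intercept: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.fit_intercept = fit_intercept

    @staticmethod
    def _deviance(y, eta):
        # -2 log L written against the linear predictor for numerical safety
        return 2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("LogisticOutcomeModel requires exactly two classes")
        yy = (y == self.classes_[1]).astype(float)
        n, k = X.shape
        Xd = np.column_stack([np.ones(n), X]) if self.fit_intercept else X

        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise np.linalg.LinAlgError("singular design matrix")

        beta = np.zeros(Xd.shape[1])
        eta = Xd @ beta
        dev = self._deviance(yy, eta)
        self.deviances_ = [dev]
        converged = False
        for _ in range(self.max_iter):
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            w = np.maximum(w, 1e-10)
            XtWX = Xd.T @ (Xd * w[:, None])
            grad = Xd.T @ (yy - p)
            try:
                step = np.linalg.solve(XtWX, grad)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError("singular design matrix") from exc
            # step-halving keeps the deviance monotonically non-increasing
            scale = 1.0
            for _half in range(30):
                beta_new = beta + scale * step
                dev_new = self._deviance(yy, Xd @ beta_new)
                if dev_new <= dev + 1e-12:
                    break
                scale *= 0.5
            max_step = np.max(np.abs(beta_new - beta))
            beta, eta, dev = beta_new, Xd @ beta_new, dev_new
            self.deviances_.append(dev)
            if max_step < self.tol:
                converged = True
                break

        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]))
        bse = np.sqrt(np.diag(cov))

        self.converged_ = converged
        self.n_iter_ = len(self.deviances_) - 1
        self.separation_ = bool(
            np.all((p > 1 - 1e-6) == (yy == 1)) and np.all((p < 1e-6) == (yy == 0))
        ) and dev < 1e-4
        if self.separation_:
            warnings.warn(
                "perfect separation detected; coefficients diverge",
                SeparationWarning,
            )
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
            self.intercept_se_ = float(bse[0])
            self.coef_se_ = bse[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
            self.intercept_se_ = 0.0
            self.coef_se_ = bse.copy()
        self.cov_params_ = cov
        self.n_features_in_ = k
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(
            self.decision_function(X) >= 0, self.classes_[1], self.classes_[0]
        )

    def wald_pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values for the slope coefficients."""
        check_is_fitted(self, "coef_")
        z = self.coef_ / self.coef_se_
        return 2.0 * stats.norm.sf(np.abs(z))


def fit_logistic(cohort: pd.DataFrame, predictors, outcome: str = "drl"):
    """Fit a logistic model on cohort columns; returns the fitted estimator.

    Rows with missing predictor or outcome values are dropped (listwise
    deletion) with a warning naming the count.
    """
    cols = list(predictors) + [outcome]
    sub = cohort[cols]
    n0 = len(sub)
    sub = sub.dropna()
    if len(sub) < n0:
        warnings.warn(f"listwise deletion removed {n0 - len(sub)} incomplete rows")
    model = LogisticOutcomeModel()
    model.fit(sub[list(predictors)].to_numpy(float), sub[outcome].to_numpy(int))
    return model


def univariate_screen(cohort: pd.DataFrame, predictors, outcome: str = "drl",
                      alpha: float = 0.10) -> pd.DataFrame:
    """Single-covariate logistic screen; retain predictors with Wald p < alpha.

    Returns a DataFrame indexed by predictor with columns ``p_value``,
    ``retained`` and ``flag`` (zero-variance predictors are excluded with a
    flag rather than fitted).
    """
    y = cohort[outcome].to_numpy(int)
    n_event = int(y.sum())
    if min(n_event, y.size - n_event) < 10:
        warnings.warn("fewer than 10 events per arm; screen p-values are unstable")
    rows = []
    for name in predictors:
        x = cohort[name].to_numpy(float)
        if np.nanstd(x) == 0:
            rows.append((name, np.nan, False, "zero-variance"))
            continue
        model = fit_logistic(cohort, [name], outcome)
        p = float(model.wald_pvalues()[0])
        rows.append((name, p, p < alpha, ""))
    return pd.DataFrame(
        rows, columns=["predictor", "p_value", "retained", "flag"]
    ).set_index("predictor")


# --------------------------------------------------------------------------
# ROC machinery
# --------------------------------------------------------------------------

def roc_auc(scores, labels):
    """Mann-Whitney AUC (ties counted 1/2) and the empirical ROC curve.

    Returns ``(auc, curve)`` where curve is a DataFrame with columns
    ``threshold, fpr, tpr`` over all unique thresholds (prediction rule:
    score >= threshold is called positive).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (np.sum(ranks[y == 1]) - pos.size * (pos.size + 1) / 2.0) / (
        pos.size * neg.size
    )

    order = np.argsort(-s, kind="stable")
    ss, yy = s[order], y[order]
    thresholds, tps, fps = [], [], []
    tp = fp = 0
    i = 0
    while i < ss.size:
        j = i
        while j < ss.size and ss[j] == ss[i]:
            tp += yy[j]
            fp += 1 - yy[j]
            j += 1
        thresholds.append(ss[i])
        tps.append(tp)
        fps.append(fp)
        i = j
    curve = pd.DataFrame(
        {
            "threshold": thresholds,
            "fpr": np.asarray(fps) / neg.size,
            "tpr": np.asarray(tps) / pos.size,
        }
    )
    return float(auc), curve


def _delong_components(pos, neg):
    """DeLong structural components via midranks."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    r_all = stats.rankdata(allv)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def auc_ci(scores, labels, level: float = 0.95):
    """DeLong 95% CI for the AUC and two-sided p against AUC = 0.5.

    Returns ``(ci_low, ci_high, p_vs_half, se)``; the CI is truncated to
    [0, 1]. Warns when either class has fewer than 10 members.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if min(pos.size, neg.size) < 10:
        warnings.warn("fewer than 10 subjects in a class; CI will be wide")
    auc, _ = roc_auc(s, y)
    v10, v01 = _delong_components(pos, neg)
    var = np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    if se == 0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    return float(lo), float(hi), p, se


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
                     seed: int = 0):
    """Percentile-bootstrap AUC CI (stratified resampling); optional alternative."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    ipos, ineg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(ipos, ipos.size), rng.choice(ineg, ineg.size)]
        )
        aucs[b], _ = roc_auc(s[take], y[take])
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(aucs, alpha)),
        float(np.quantile(aucs, 1 - alpha)),
        float(np.var(aucs, ddof=1)),
    )


def youden_cutoff(curve: pd.DataFrame):
    """Maximize the Youden index J = sens + spec - 1 over observed thresholds.

    Ties are broken toward higher sensitivity, then toward the lower
    threshold. Returns ``(cutoff, sensitivity, specificity)`` with the rates
    as proportions.
    """
    sens = curve["tpr"].to_numpy(float)
    spec = 1.0 - curve["fpr"].to_numpy(float)
    j = sens + spec - 1.0
    best = np.flatnonzero(j == np.max(j))
    best = best[np.argsort(-sens[best], kind="stable")]
    top_sens = sens[best[0]]
    cand = best[sens[best] == top_sens]
    thr = curve["threshold"].to_numpy(float)[cand]
    pick = cand[np.argmin(thr)]
    return (
        float(curve["threshold"].iloc[pick]),
        float(sens[pick]),
        float(spec[pick]),
    )


def confusion_metrics(tp: int, fn: int, fp: int, tn: int):
    """Sensitivity, specificity, PPV, NPV in percent from a confusion matrix.

    Zero-denominator entries are returned as NaN. Raises on an all-zero
    matrix or negative counts.
    """
    counts = np.array([tp, fn, fp, tn], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return (
        ratio(tp, tp + fn),
        ratio(tn, tn + fp),
        ratio(tp, tp + fp),
        ratio(tn, tn + fn),
    )


def metrics_from_rates(sens: float, spec: float, prevalence: float):
    """PPV and NPV from sensitivity, specificity and prevalence (proportions).

    Bayes identities:
    ``ppv = sens*prev / (sens*prev + (1-spec)*(1-prev))`` and
    ``npv = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev)``.
    Degenerate denominators yield NaN.
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    d1 = sens * prevalence + (1 - spec) * (1 - prevalence)
    d2 = spec * (1 - prevalence) + (1 - sens) * prevalence
    ppv = sens * prevalence / d1 if d1 > 0 else float("nan")
    npv = spec * (1 - prevalence) / d2 if d2 > 0 else float("nan")
    return ppv, npv


def hosmer_lemeshow(predicted_probs, labels, g: int = 10):
    """Hosmer-Lemeshow goodness-of-fit chi-square over groups of predicted risk.

    Subjects are grouped by deciles of predicted probability with ties
    assigned to the lower group; empty groups (after tie collapse) are merged
    with the statistic's degrees of freedom reduced accordingly. Returns
    ``(stat, p)`` with p from chi-square on ``groups - 2`` df.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.size < 2 * g:
        raise ValueError("need at least 2*g observations")
    edges = np.quantile(p, np.linspace(0, 1, g + 1)[1:-1])
    grp = np.searchsorted(edges, p, side="left")
    stat = 0.0
    n_groups = 0
    for gi in np.unique(grp):
        m = grp == gi
        ng = int(m.sum())
        if ng == 0:
            continue
        obs = float(y[m].sum())
        exp = float(p[m].sum())
        denom = exp * (1.0 - exp / ng)
        if denom <= 0:
            # a fully degenerate risk group carries no information
            continue
        stat += (obs - exp) ** 2 / denom
        n_groups += 1
    df = max(n_groups - 2, 1)
    if n_groups < g:
        warnings.warn(f"tie collapse reduced risk groups to {n_groups}; df = {df}")
    return float(stat), float(stats.chi2.sf(stat, df))


def correlate(x, y):
    """Pearson or Spearman correlation, chosen by marginal normality.

    Shapiro-Wilk is applied to each variable; Pearson is used when both
    p >= 0.05, Spearman otherwise. Returns ``(coefficient, p_value, method)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 5:
        raise ValueError("need at least 5 paired complete observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    normal = stats.shapiro(x).pvalue >= 0.05 and stats.shapiro(y).pvalue >= 0.05
    if normal:
        r, p = stats.pearsonr(x, y)
        return float(r), float(p), "pearson"
    r, p = stats.spearmanr(x, y)
    return float(r), float(p), "spearman"


# --------------------------------------------------------------------------
# Model evaluation table
# --------------------------------------------------------------------------

@dataclass
class ModelEval:
    name: str
    predictors: tuple
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    p_value_auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    hl_stat: float
    hl_p: float
    coefficients: dict = field(default_factory=dict)
    error: str = ""

    def to_row(self) -> dict:
        return {
            "model": self.name,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "p_value_auc": self.p_value_auc,
            "cutoff": self.cutoff,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "hl_stat": self.hl_stat,
            "hl_p": self.hl_p,
            "error": self.error,
        }


def evaluate_models(cohort: pd.DataFrame, outcome: str = "drl",
                    specs=MODEL_SPECS, hl_groups: int = 10) -> list[ModelEval]:
    """Evaluate the five predictive model specifications on a cohort table.

    For single-predictor models the ROC score is the raw predictor (cut-offs
    reported in predictor units); for multivariable models it is the logistic
    predicted probability. The Hosmer-Lemeshow test always uses the logistic
    probabilities. Rows are emitted in the fixed specification order; a
    failed model carries its reason in ``error`` with NaN metrics.
    """
    if outcome not in cohort.columns and "mrs" in cohort.columns:
        cohort = cohort.assign(**{outcome: dichotomize_mrs(cohort["mrs"].to_numpy())})
    y = cohort[outcome].to_numpy(int)
    out = []
    for name, predictors in specs:
        try:
            model = fit_logistic(cohort, predictors, outcome)
            X = cohort[list(predictors)].to_numpy(float)
            probs = model.predict_proba(X)[:, 1]
            scores = cohort[predictors[0]].to_numpy(float) if len(predictors) == 1 else probs
            auc, curve = roc_auc(scores, y)
            lo, hi, p_auc, _ = auc_ci(scores, y)
            cutoff, sens, spec = youden_cutoff(curve)
            pred = scores >= cutoff
            tp = int(np.sum(pred & (y == 1)))
            fn = int(np.sum(~pred & (y == 1)))
            fp = int(np.sum(pred & (y == 0)))
            tn = int(np.sum(~pred & (y == 0)))
            sens_pct, spec_pct, ppv, npv = confusion_metrics(tp, fn, fp, tn)
            hl_stat, hl_p = hosmer_lemeshow(probs, y, g=hl_groups)
            coeffs = {
                "intercept": (model.intercept_, model.intercept_se_),
                **{
                    pname: (float(b), float(se))
                    for pname, b, se in zip(predictors, model.coef_, model.coef_se_)
                },
            }
            out.append(
                ModelEval(
                    name=name, predictors=tuple(predictors), auc=auc,
                    auc_ci_low=lo, auc_ci_high=hi, p_value_auc=p_auc,
                    cutoff=cutoff, sensitivity=sens_pct, specificity=spec_pct,
                    ppv=ppv, npv=npv, hl_stat=hl_stat, hl_p=hl_p,
                    coefficients=coeffs,
                )
            )
        except Exception as exc:  # noqa: BLE001 - failed rows carry their reason
            nan = float("nan")
            out.append(
                ModelEval(
                    name=name, predictors=tuple(predictors), auc=nan,
                    auc_ci_low=nan, auc_ci_high=nan, p_value_auc=nan,
                    cutoff=nan, sensitivity=nan, specificity=nan,
                    ppv=nan, npv=nan, hl_stat=nan, hl_p=nan,
                    error=str(exc),
                )
            )
    return out


def evaluation_table(evals: list[ModelEval]) -> pd.DataFrame:
    return pd.DataFrame([e.to_row() for e in evals]).set_index("model")
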