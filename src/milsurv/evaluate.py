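"""Risk-score metrics, stratification and outcome analysis.

Kaplan-Meier curves (Greenwood log-log confidence bands) and the log-rank
test are delegated to lifelines; the IPCW cumulative/dynamic AUC, Brier
scores and the Uno C-index to scikit-survival. The tau-truncated Harrell
C-index and the Cox proportional-hazards fit (Breslow ties, Newton-Raphson
to gradient norm < 1e-8) are implemented here because their exact
conventions are part of the package contract; the test suite cross-checks
both against independent library and brute-force routes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import (
    brier_score,
    concordance_index_ipcw,
    cumulative_dynamic_auc,
)
from sksurv.util import Surv


# --------------------------------------------------------------------- #
# concordance                                                           #
# --------------------------------------------------------------------- #
def concordance(scores, time, event, tau: float = 10.0,
                method: str = "harrell") -> float:
    """C-index of risk scores against right-censored outcomes.

    ``harrell``: follow-up truncated at ``tau`` (times clipped, events
    beyond tau treated as censored at tau); a pair is comparable iff the
    earlier time is an event and strictly precedes the other time; tied
    scores count 1/2. ``uno``: IPCW estimator (scikit-survival) with the
    same tau.
    """
    scores = np.asarray(scores, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    if method == "uno":
        surv = Surv.from_arrays(event=event.astype(bool), time=time)
        return float(concordance_index_ipcw(surv, surv, scores, tau=tau)[0])
    if method != "harrell":
        raise ValueError(f"unknown method {method!r}")

    t = np.minimum(time, tau)
    e = event * (time <= tau)
    # comparable pairs: i an event, t_i < t_j
    lt = t[:, None] < t[None, :]
    comparable = lt & (e[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    gt = scores[:, None] > scores[None, :]
    eq = scores[:, None] == scores[None, :]
    num = (comparable & gt).sum() + 0.5 * (comparable & eq).sum()
    return float(num / n_comp)


# --------------------------------------------------------------------- #
# time-dependent AUC and Brier                                          #
# --------------------------------------------------------------------- #
def cumulative_auc_and_brier(surv_curves, records, eval_times,
                             train_records=None):
    """IPCW cumulative/dynamic AUC at each time plus the integrated Brier
    score (trapezoid over ``eval_times``).

    ``surv_curves`` is (n, T): predicted survival probability per patient
    at each evaluation time.
    """
    s = np.atleast_2d(np.asarray(surv_curves, dtype=np.float64))
    eval_times = np.asarray(eval_times, dtype=np.float64)
    if train_records is None:
        train_records = records
    ev = np.asarray(records["event"]).astype(bool)
    if not ev.any():
        raise ValueError("all records censored; time-dependent metrics undefined")
    surv_test = Surv.from_arrays(event=ev, time=np.asarray(records["time_years"]))
    surv_train = Surv.from_arrays(
        event=np.asarray(train_records["event"]).astype(bool),
        time=np.asarray(train_records["time_years"]),
    )
    risk = 1.0 - s
    aucs, mean_auc = cumulative_dynamic_auc(surv_train, surv_test, risk, eval_times)
    _, briers = brier_score(surv_train, surv_test, s, eval_times)
    if len(eval_times) > 1:
        ibs = float(
            np.trapezoid(briers, eval_times) / (eval_times[-1] - eval_times[0])
        )
    else:
        ibs = float(briers[0])
    return {
        "times": eval_times,
        "auc": np.asarray(aucs, dtype=np.float64),
        "mean_auc": float(mean_auc),
        "brier": np.asarray(briers, dtype=np.float64),
        "integrated_brier": ibs,
    }


# --------------------------------------------------------------------- #
# Kaplan-Meier and log-rank                                             #
# --------------------------------------------------------------------- #
def km_estimate(time, event, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit survival curve with Greenwood log-log 95% CI."""
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(np.asarray(time), np.asarray(event))
    ci = kmf.confidence_interval_survival_function_
    return pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        }
    )


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-sided log-rank test across >= 2 groups; returns (chi2, p)."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if not np.asarray(event).astype(bool).any():
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(np.asarray(time), groups, np.asarray(event))
    return float(res.test_statistic), float(res.p_value)


# --------------------------------------------------------------------- #
# risk groups                                                           #
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class RiskGroups:
    """Training-set quantile cutoffs; the two lowest quartile groups are
    merged, so: low <= c50 < intermediate <= c75 < high."""

    c50: float
    c75: float

    def label(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=np.float64)
        out = np.where(s <= self.c50, "low",
                       np.where(s <= self.c75, "intermediate", "high"))
        return out.astype(object)


def assign_risk_groups(train_scores, new_scores=None):
    """Cutoffs from the training distribution only (linear-interpolation
    quantiles), applied unchanged to any new scores."""
    tr = np.asarray(train_scores, dtype=np.float64)
    if len(tr) < 4:
        raise ValueError("need at least 4 training scores")
    c50 = float(np.quantile(tr, 0.5, method="linear"))
    c75 = float(np.quantile(tr, 0.75, method="linear"))
    if not c50 < c75:
        raise ValueError("degenerate training scores: cutoffs coincide")
    groups = RiskGroups(c50=c50, c75=c75)
    target = tr if new_scores is None else np.asarray(new_scores, dtype=np.float64)
    return groups, groups.label(target)


# --------------------------------------------------------------------- #
# Cox proportional hazards                                              #
# --------------------------------------------------------------------- #
@dataclass
class CoxResult:
    names: list[str]
    coef: np.ndarray
    hr: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    loglik: float
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hr,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            },
            index=self.names,
        )


def _cox_loglik_grad_hess(beta, x, time, event):
    """Breslow partial log likelihood with gradient and Hessian."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    xs = x[order]
    ts = time[order]
    es = event[order]
    eta = xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)

    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * xs, axis=0)
    s2 = np.cumsum(w[:, None, None] * (xs[:, :, None] * xs[:, None, :]), axis=0)

    # risk set of an event at time t: all with time >= t -> with ties, every
    # tied subject must be included: use the last index of each tied block
    last_of_tie = np.searchsorted(-ts, -ts, side="right") - 1
    ev = np.flatnonzero(es == 1)
    ridx = last_of_tie[ev]

    s0e = s0[ridx]
    s1e = s1[ridx]
    s2e = s2[ridx]
    ll = float(np.sum(eta[ev] - np.log(s0e)))
    xbar = s1e / s0e[:, None]
    grad = xs[ev].sum(axis=0) - xbar.sum(axis=0)
    hess = -(s2e / s0e[:, None, None]
             - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return ll, grad, hess


def cox_fit(design: pd.DataFrame, time, event, max_iter: int = 100,
            tol: float = 1e-8) -> CoxResult:
    """Cox regression: Breslow ties, Newton-Raphson, Wald inference.

    Raises on constant or duplicated columns, absence of events,
    non-convergence, or separation (diverging coefficients).
    """
    x = np.asarray(design, dtype=np.float64)
    names = list(design.columns) if hasattr(design, "columns") else [
        f"x{i}" for i in range(x.shape[1])
    ]
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    if x.ndim != 2 or x.shape[0] != len(time):
        raise ValueError("design matrix must align with outcomes")
    if event.sum() < 1:
        raise ValueError("no events; Cox model undefined")
    if (x.std(axis=0) == 0).any():
        raise ValueError("design matrix contains a constant column")
    corr = np.corrcoef(x, rowvar=False) if x.shape[1] > 1 else np.ones((1, 1))
    if x.shape[1] > 1 and (np.abs(corr - np.eye(x.shape[1])) > 1.0 - 1e-12).any():
        raise ValueError("design matrix contains duplicated (collinear) columns")

    beta = np.zeros(x.shape[1])
    for it in range(1, max_iter + 1):
        ll, grad, hess = _cox_loglik_grad_hess(beta, x, time, event)
        # under separation the score vanishes as |beta| grows, so a
        # gradient-only stop would silently "converge" at the boundary
        if np.abs(beta).max() > 15:
            raise RuntimeError(
                "Cox fit diverged (possible separation in the design)"
            )
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in Cox fit") from exc
        beta = beta - step
        if not np.isfinite(beta).all() or np.abs(beta).max() > 1e3:
            raise RuntimeError(
                "Cox fit diverged (possible separation in the design)"
            )
    else:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")

    ll, grad, hess = _cox_loglik_grad_hess(beta, x, time, event)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    from scipy.stats import norm

    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return CoxResult(
        names=names,
        coef=beta,
        hr=np.exp(beta),
        se=se,
        ci_lower=np.exp(beta - 1.959963984540054 * se),
        ci_upper=np.exp(beta + 1.959963984540054 * se),
        p=p,
        loglik=ll,
        n_iter=it,
    )


def cox_loglik(beta, design, time, event) -> float:
    """Breslow partial log likelihood at ``beta`` (for optimality checks)."""
    x = np.asarray(design, dtype=np.float64)
    ll, _, _ = _cox_loglik_grad_hess(np.asarray(beta, dtype=np.float64),
                                     x, np.asarray(time, dtype=np.float64),
                                     np.asarray(event, dtype=np.int64))
    return ll


# --------------------------------------------------------------------- #
# treatment interaction                                                 #
# --------------------------------------------------------------------- #
def interaction_test(records: pd.DataFrame, risk,
                     categorical: bool = False) -> dict:
    """Wald p-value of the treatment x risk product term in a Cox model.

    Continuous mode: main effects (risk, treatment) plus their product.
    Categorical mode: ``risk`` holds low/intermediate/high labels; the
    tested product is treatment x high with the intermediate group
    adjusted for and low as the reference.
    """
    treat = np.asarray(records["treatment"], dtype=np.float64)
    if len(np.unique(treat)) < 2:
        raise ValueError("both treatment arms must be present")
    time = np.asarray(records["time_years"], dtype=np.float64)
    event = np.asarray(records["event"], dtype=np.int64)

    if categorical:
        labels = np.asarray(risk, dtype=object)
        high = (labels == "high").astype(np.float64)
        inter = (labels == "intermediate").astype(np.float64)
        design = pd.DataFrame(
            {
                "intermediate": inter,
                "high": high,
                "treatment": treat,
                "treatment_x_high": treat * high,
            }
        )
        term = "treatment_x_high"
    else:
        r = np.asarray(risk, dtype=np.float64)
        design = pd.DataFrame(
            {"risk": r, "treatment": treat, "treatment_x_risk": treat * r}
        )
        term = "treatment_x_risk"
    res = cox_fit(design, time, event)
    i = res.names.index(term)
    return {
        "term": term,
        "coef": float(res.coef[i]),
        "hr": float(res.hr[i]),
        "p": float(res.p[i]),
        "fit": res,
    }


# --------------------------------------------------------------------- #
# multi-slide aggregation                                               #
# --------------------------------------------------------------------- #
def aggregate_patient_risk(slide_scores: pd.DataFrame,
                           method: str = "mean") -> pd.Series:
    """Per-patient score from per-slide scores (columns patient_id, risk)."""
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    if slide_scores.empty:
        raise ValueError("no slide scores given")
    grouped = slide_scores.groupby("patient_id", sort=False)["risk"]
    return grouped.mean() if method == "mean" else grouped.median()
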