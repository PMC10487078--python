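"""Multi-marker logistic panels: backward elimination, ROC, LOOCV.

Single EV RNA markers are highly specific but insensitive (each is
expressed by only a fraction of tumors), so diagnostic power comes from
combining markers.  A logistic model on log1p-transformed within-biotype
normalized abundances is pruned by greedy backward elimination on AIC,
scored by training ROC and by leave-one-out cross-validation (marker set
fixed, coefficients re-fit per fold), and summarized with the AUC, its
DeLong 95% confidence interval, a Mann–Whitney p-value against AUC = 0.5,
and the Youden-optimal operating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import concordance_auc

logger = logging.getLogger(__name__)


class PanelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# logistic regression (IRLS with ridge fallback under separation)


@dataclass
class LogisticFit:
    coef: np.ndarray  # intercept first
    loglik: float
    aic: float
    converged: bool
    ridge_used: bool
    cov: np.ndarray | None = None


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
    separation_ridge: float = 1e-3,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS).

    ``X`` excludes the intercept (it is added internally).  Under complete
    or quasi-complete separation the unpenalized MLE diverges; the fit is
    then redone with an L2 penalty ``separation_ridge`` on the non-intercept
    coefficients and flagged via ``ridge_used``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        if len(classes) == 1:
            raise PanelError("labels contain a single class; cannot fit")
        raise PanelError("labels must be binary 0/1")
    if X.shape[1] > 0 and np.any(np.ptp(X, axis=0) == 0.0) and ridge == 0.0:
        raise PanelError("constant predictor column; drop it before fitting")
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    pen = np.zeros(k + 1)
    pen[1:] = ridge

    beta = np.zeros(k + 1)
    ll_old = -np.inf
    converged = False
    diverged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = np.clip(_sigmoid(eta), 1e-12, 1.0 - 1e-12)
        ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu))) - 0.5 * float(
            np.sum(pen * beta**2)
        )
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu) - pen * beta
        H = (Xd * w[:, None]).T @ Xd + np.diag(pen) + 1e-12 * np.eye(k + 1)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            diverged = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0 and ridge == 0.0:
            diverged = True
            break
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    if (diverged or not converged) and ridge == 0.0:
        logger.info("separation or non-convergence detected; refitting with ridge")
        fit = fit_logistic(X, y, ridge=separation_ridge, max_iter=max_iter, tol=tol)
        return LogisticFit(
            coef=fit.coef,
            loglik=fit.loglik,
            aic=fit.aic,
            converged=fit.converged,
            ridge_used=True,
            cov=fit.cov,
        )
    eta = Xd @ beta
    mu = np.clip(_sigmoid(eta), 1e-12, 1.0 - 1e-12)
    loglik = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
    aic = -2.0 * loglik + 2.0 * (k + 1)
    w = mu * (1.0 - mu)
    H = (Xd * w[:, None]).T @ Xd + np.diag(pen) + 1e-12 * np.eye(k + 1)
    cov = np.linalg.inv(H)
    return LogisticFit(
        coef=beta,
        loglik=loglik,
        aic=aic,
        converged=converged,
        ridge_used=ridge > 0.0,
        cov=cov,
    )


def predict_proba(fit: LogisticFit, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(len(X)), X])
    return _sigmoid(Xd @ fit.coef)


# ---------------------------------------------------------------------------
# backward elimination


def backward_eliminate(
    X: pd.DataFrame,
    y: np.ndarray,
    criterion: str = "aic",
    wald_alpha: float = 0.05,
    selection_ridge: float = 1.0,
) -> list[str]:
    """Greedy backward elimination over marker columns.

    ``criterion='aic'`` (default): repeatedly drop the marker whose removal
    most decreases the model AIC, stopping when no removal improves it.
    ``criterion='wald'``: repeatedly drop the marker with the largest Wald
    p-value above ``wald_alpha``.  Ties break to the lexicographically
    smallest marker id, so selection is deterministic.

    Every selection fit is L2-stabilized with the same ``selection_ridge``
    penalty, so all subsets are compared under one objective.  Comparing
    unpenalized fits is not an option here: candidate markers are near
    tumor-specific, so most subsets separate the training labels, the
    unpenalized MLE diverges, and subsets would be ranked by whichever
    fallback each happened to need rather than by fit.  The final reported
    model is re-fit with the light stabilizer only if needed.
    """
    if X.shape[1] == 0:
        raise PanelError("candidate set is empty")
    if criterion not in ("aic", "wald"):
        raise PanelError(f"unknown criterion {criterion!r}")
    # constant markers carry no information; drop them before the sweep
    current = sorted(c for c in X.columns if np.ptp(X[c].to_numpy()) > 0)
    if not current:
        raise PanelError("all candidate markers are constant")

    def _aic(cols: list[str]) -> float:
        return fit_logistic(X[cols].to_numpy(), y, ridge=selection_ridge).aic

    while len(current) > 1:
        if criterion == "aic":
            base = _aic(current)
            best_drop, best_aic = None, base
            for m in current:
                rest = [c for c in current if c != m]
                aic = _aic(rest)
                if aic < best_aic - 1e-12:
                    best_drop, best_aic = m, aic
            if best_drop is None:
                break
            current.remove(best_drop)
        else:
            fit = fit_logistic(X[current].to_numpy(), y)
            if fit.cov is None:
                break
            se = np.sqrt(np.diag(fit.cov))[1:]
            z = fit.coef[1:] / np.where(se > 0, se, np.inf)
            pvals = 2.0 * stats.norm.sf(np.abs(z))
            worst = int(np.argmax(pvals))
            if pvals[worst] <= wald_alpha:
                break
            current.remove(current[worst])
    return current


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    ci_low_untruncated: float
    ci_high_untruncated: float
    p: float
    sensitivity: float
    specificity: float
    threshold: float
    degenerate: bool = False


def roc_curve(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Empirical ROC over all score thresholds (descending)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    order = np.argsort(-scores, kind="mergesort")
    s, lab = scores[order], y[order]
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise PanelError("both classes must be present")
    tps = np.cumsum(lab)
    fps = np.cumsum(1 - lab)
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thr = np.r_[np.inf, s[distinct]]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[pd.DataFrame, float, dict]:
    """ROC curve, trapezoid AUC (= Mann–Whitney concordance) and the
    Youden-optimal operating point.

    Constant scores yield AUC 0.5 with the curve flagged degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    curve = roc_curve(scores, y)
    auc = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    degenerate = bool(np.ptp(scores) == 0.0)
    youden = curve["tpr"] - curve["fpr"]
    k = int(np.argmax(youden.to_numpy()))
    op = {
        "threshold": float(curve["threshold"].iloc[k]),
        "sensitivity": float(curve["tpr"].iloc[k]),
        "specificity": float(1.0 - curve["fpr"].iloc[k]),
        "degenerate": degenerate,
    }
    return curve, auc, op


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from the structural components."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise PanelError("DeLong CI needs >=2 samples per class")
    # pairwise concordance indicators with half weight for ties
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-case
    v01 = psi.mean(axis=0)  # per-control
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def delong_ci(
    scores: np.ndarray, y: np.ndarray, level: float = 0.95
) -> tuple[float, float, float, float]:
    """DeLong normal-approximation CI for the AUC.

    Returns ``(low, high, low_untruncated, high_untruncated)``; the first
    pair is clipped to [0, 1].  Zero variance (perfect separation) gives a
    point interval at the AUC, flagged by the caller.
    """
    auc, var = _delong_variance(scores, y)
    if var <= 0.0:
        return auc, auc, auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    lo_u, hi_u = auc - half, auc + half
    return max(0.0, lo_u), min(1.0, hi_u), lo_u, hi_u


def auc_pvalue(scores: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney test of AUC = 0.5.

    Exact enumeration when both classes have <= 10 tie-free observations;
    tie-corrected normal approximation otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise PanelError("both classes must be present")
    tie_free = len(np.unique(scores)) == len(scores)
    method = "exact" if (tie_free and max(len(pos), len(neg)) <= 10) else "asymptotic"
    return float(
        stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method).pvalue
    )


def summarize_roc(scores: np.ndarray, y: np.ndarray) -> RocSummary:
    _, auc, op = roc_auc(scores, y)
    lo, hi, lo_u, hi_u = delong_ci(scores, y)
    p = auc_pvalue(scores, y)
    return RocSummary(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        ci_low_untruncated=lo_u,
        ci_high_untruncated=hi_u,
        p=p,
        sensitivity=op["sensitivity"],
        specificity=op["specificity"],
        threshold=op["threshold"],
        degenerate=op["degenerate"],
    )


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


def loocv_scores(
    X: pd.DataFrame,
    y: np.ndarray,
    markers: list[str] | None = None,
    reselect: bool = False,
    criterion: str = "aic",
) -> np.ndarray:
    """Out-of-fold predicted probabilities, one per sample.

    By default the marker set is held fixed and only the coefficients are
    re-fit without the held-out sample.  ``reselect=True`` re-runs backward
    elimination inside every fold (the fully nested variant).  A fold whose
    fit fails falls back to the training prevalence.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise PanelError("LOOCV needs at least 10 samples")
    if markers is None:
        markers = sorted(X.columns)
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X.iloc[mask], y[mask]
        try:
            m_i = backward_eliminate(Xi, yi, criterion=criterion) if reselect else markers
            # a marker can be constant within a fold even if not overall
            m_i = [m for m in m_i if np.ptp(Xi[m].to_numpy()) > 0]
            if not m_i:
                raise PanelError("no non-constant marker in fold")
            fit = fit_logistic(Xi[m_i].to_numpy(), yi)
            scores[i] = predict_proba(fit, X.iloc[[i]][m_i].to_numpy())[0]
        except PanelError:
            logger.warning("LOOCV fold %d failed; scoring with the prior rate", i)
            scores[i] = float(yi.mean())
    return scores


# ---------------------------------------------------------------------------
# panel assembly


@dataclass
class PanelModel:
    marker_ids: list[str]
    coefficients: dict[str, float]  # "(intercept)" plus per-marker weights
    training: RocSummary
    loocv: RocSummary
    ridge_used: bool = False

    def to_dict(self) -> dict:
        return {
            "marker_ids": self.marker_ids,
            "coefficients": self.coefficients,
            "training": asdict(self.training),
            "loocv": asdict(self.loocv),
            "ridge_used": self.ridge_used,
        }


def marker_design(
    normalized: pd.DataFrame, marker_ids, sample_ids
) -> pd.DataFrame:
    """Predictor table: log1p of normalized abundance, samples x markers."""
    X = normalized.loc[list(marker_ids), list(sample_ids)].T
    return np.log1p(X.fillna(0.0))


def build_panel(
    X: pd.DataFrame,
    y: np.ndarray,
    criterion: str = "aic",
    loocv_reselect: bool = False,
) -> PanelModel:
    """Select markers, fit the final logistic model, and evaluate it.

    ``X`` is a samples x candidate-markers predictor table (already
    transformed); ``y`` binary labels (1 = case).
    """
    y = np.asarray(y, dtype=float)
    markers = backward_eliminate(X, y, criterion=criterion)
    fit = fit_logistic(X[markers].to_numpy(), y)
    train_scores = predict_proba(fit, X[markers].to_numpy())
    training = summarize_roc(train_scores, y)
    cv_scores = loocv_scores(X, y, markers=markers, reselect=loocv_reselect, criterion=criterion)
    loocv = summarize_roc(cv_scores, y)
    coeffs = {"(intercept)": float(fit.coef[0])}
    coeffs.update({m: float(c) for m, c in zip(markers, fit.coef[1:])})
    return PanelModel(
        marker_ids=markers,
        coefficients=coeffs,
        training=training,
        loocv=loocv,
        ridge_used=fit.ridge_used,
    )
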