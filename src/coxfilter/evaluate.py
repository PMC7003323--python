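"""Downstream evaluation of a prognostic gene signature.

A multivariate Cox model over the selected genes yields a per-sample risk
score (the linear predictor); samples are split at the median score into
high- and low-risk groups; Kaplan–Meier curves and a log-rank test
compare the groups.  Wilcoxon rank-sum tests compare expression between
groups (e.g. the two subtypes), and a cross-validated subtype classifier
quantifies how much subtype information the signature carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataError, ExpressionMatrix
from .screening import CoxData, EFRON, newton_cox


@dataclass
class RiskModel:
    """Multivariate Cox risk model: one log-hazard weight per gene.

    ``median_cutoff`` is the median risk score of the training samples,
    the threshold for the high/low split.
    """

    gene_ids: list
    coefficients: np.ndarray
    median_cutoff: float
    loglik: float = np.nan
    converged: bool = True
    message: str = ""


def _expr_submatrix(expr: ExpressionMatrix, gene_ids) -> np.ndarray:
    missing = [g for g in gene_ids if g not in expr.feature_ids]
    if missing:
        raise DataError(f"genes absent from expression matrix: {missing}")
    idx = [expr.feature_ids.index(g) for g in gene_ids]
    return expr.values[idx]


def fit_multivariate_cox(
    expr: ExpressionMatrix,
    gene_ids,
    time,
    event,
    ties_method: str = EFRON,
) -> RiskModel:
    """Fit a k-gene Cox model (no subtype terms) and set the median cutoff.

    Warns when the event count is below the number of covariates; raises
    on singular information (e.g. duplicated genes) with the condition
    number of the information matrix.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise DataError("at least one gene required")
    X = _expr_submatrix(expr, gene_ids).T  # n x k
    event = np.asarray(event, dtype=int)
    if event.sum() < len(gene_ids):
        warnings.warn(
            f"{event.sum()} events for {len(gene_ids)} covariates; "
            "estimates will be unstable",
            UserWarning, stacklevel=2,
        )
    res = newton_cox(X, time, event, ties_method)
    if res.message.startswith("singular"):
        from .screening import cox_loglik
        _, _, info = cox_loglik(
            np.zeros(X.shape[1]), X - X.mean(axis=0), CoxData(time, event),
            ties_method,
        )
        raise DataError(
            "singular information matrix "
            f"(condition number {np.linalg.cond(info):.3g}); "
            "check for collinear or duplicated genes"
        )
    model = RiskModel(gene_ids, res.beta, np.nan, res.loglik,
                      res.converged, res.message)
    model.median_cutoff = float(np.median(risk_score(model, expr)))
    return model


def risk_score(model: RiskModel, expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample linear predictor sum_g coef_g * X_g (no baseline term)."""
    X = _expr_submatrix(expr, model.gene_ids)
    return model.coefficients @ X


def dichotomize(scores, cutoff: Optional[float] = None) -> np.ndarray:
    """Label each sample ``high`` iff its score exceeds the cutoff.

    The cutoff defaults to the median of ``scores``; ties at the cutoff go
    to ``low``.  All-identical scores are a degenerate split and raise.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise DataError("need at least two samples to dichotomize")
    if np.ptp(scores) == 0:
        raise DataError("degenerate scores (all identical)")
    if cutoff is None:
        cutoff = np.median(scores)
    return np.where(scores > cutoff, "high", "low")


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    Steps occur at distinct event times only; ``survival[i]`` is S(t) just
    after ``times[i]``.  S(0) = 1 by convention.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.n_events}
        )


def km_curve(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    With no censoring this equals 1 minus the empirical CDF at the event
    times exactly; censored-only times contribute no step.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time < 0):
        raise DataError("negative survival time")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ev_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in ev_times])
    n_events = np.array([((t == u) & (e == 1)).sum() for u in ev_times])
    telescopes = (
        at_risk.size > 0
        and at_risk[0] == t.size
        and np.array_equal(at_risk[:-1] - n_events[:-1], at_risk[1:])
    )
    if telescopes:
        # no censoring interleaved with the events: the product collapses
        # to the empirical survival, computed as one exact division
        surv = (at_risk - n_events) / t.size
    else:
        surv = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(ev_times, surv, at_risk, n_events)


def logrank_test(time, event, group):
    """Log-rank test across two or more groups.

    At each distinct event time the observed per-group event counts are
    compared with their hypergeometric expectation given the risk sets;
    the statistic is chi-square with (#groups - 1) degrees of freedom.
    Returns ``(chi2, df, p)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = pd.unique(group)
    g = len(levels)
    if g < 2:
        raise DataError("log-rank test needs at least two groups")
    level_pos = {lev: i for i, lev in enumerate(np.sort(levels))}
    gidx = np.array([level_pos[v] for v in group])
    ev_times = np.unique(time[event == 1])
    omE = np.zeros(g)
    V = np.zeros((g, g))
    for u in ev_times:
        at_risk = time >= u
        n = at_risk.sum()
        d = ((time == u) & (event == 1)).sum()
        nk = np.bincount(gidx[at_risk], minlength=g).astype(float)
        dk = np.bincount(gidx[(time == u) & (event == 1)], minlength=g)
        e = d * nk / n
        omE += dk - e
        if n > 1:
            # hypergeometric covariance of per-group death counts
            V += (d * (n - d) / (n - 1)) * (
                np.diag(nk / n) - np.outer(nk / n, nk / n)
            )
    v = V[: g - 1, : g - 1]
    o = omE[: g - 1]
    if np.any(v):
        chi2 = float(o @ np.linalg.lstsq(v, o, rcond=None)[0])
    else:
        chi2 = 0.0
    df = g - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def wilcoxon_test(x, y):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when the combined sample size is at most 20 with no
    ties; otherwise the normal approximation with tie-corrected variance
    and continuity correction.  Returns ``(U statistic of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def subtype_auc(
    expr: ExpressionMatrix, gene_ids, subtype, n_splits: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated AUC of a logistic subtype classifier on a signature.

    Measures how much subtype information the signature genes carry: a
    purely prognostic, subtype-independent signature scores near 0.5.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    X = _expr_submatrix(expr, gene_ids).T
    y = (np.asarray(subtype) == np.sort(pd.unique(np.asarray(subtype)))[1])
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    prob = cross_val_predict(
        LogisticRegression(max_iter=1000), X, y.astype(int), cv=cv,
        method="predict_proba",
    )[:, 1]
    return float(roc_auc_score(y.astype(int), prob))


@dataclass
class SignatureEvaluation:
    model: RiskModel
    scores: np.ndarray
    groups: np.ndarray
    km: dict
    logrank_chi2: float
    logrank_p: float


def evaluate_signature(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    gene_ids,
    ties_method: str = EFRON,
    train_ids=None,
) -> SignatureEvaluation:
    """Risk-score pipeline: fit, score, median split, KM, log-rank.

    By default the model is trained and evaluated on the same cohort (the
    in-sample convention); pass ``train_ids`` to fit on a subset and
    evaluate on the remainder (holdout mode, which removes the in-sample
    optimism of the default).
    """
    time = clinical["os_time"].to_numpy(dtype=float)
    event = clinical["os_event"].to_numpy(dtype=int)
    if train_ids is not None:
        mask = np.asarray([s in set(train_ids) for s in expr.sample_ids])
        train_expr = expr.subset_samples(
            [s for s in expr.sample_ids if s in set(train_ids)])
        model = fit_multivariate_cox(
            train_expr, gene_ids, time[mask], event[mask], ties_method)
        eval_mask = ~mask
    else:
        model = fit_multivariate_cox(expr, gene_ids, time, event, ties_method)
        eval_mask = np.ones(len(time), dtype=bool)
    scores = risk_score(model, expr)[eval_mask]
    time, event = time[eval_mask], event[eval_mask]
    groups = dichotomize(scores, cutoff=model.median_cutoff
                         if train_ids is None else None)
    km = {lev: km_curve(time[groups == lev], event[groups == lev])
          for lev in ("high", "low") if np.any(groups == lev)}
    if len(km) == 2:
        chi2, _, p = logrank_test(time, event, groups)
    else:
        chi2, p = np.nan, np.nan
    return SignatureEvaluation(model, scores, groups, km, chi2, p)


def plot_km(km_by_group: dict, ax=None, title: str = ""):
    """Simple step-plot of one or more KM curves (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in km_by_group.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=str(label))
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
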