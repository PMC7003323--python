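"""Per-gene Cox proportional-hazards screen with a subtype interaction.

For each gene g the model is

    lambda_i(t) = lambda0(t) * exp(b1*I(i in c2) + b2*X_i + b3*I(i in c2)*X_i)

fitted by Newton–Raphson on the log partial likelihood (Efron or Breslow
ties).  Two Wald tests classify the gene: H0: b2 = 0 (prognostic value in
subtype c1) and H0: b2 + b3 = 0 (prognostic value in subtype c2).  The
two p-value families are Benjamini–Hochberg adjusted across genes —
separately by default, each being its own genome-wide screen — and genes
are labelled c1_specific / c2_specific / shared / none by which adjusted
p-values fall below alpha.  b1 is estimated but never tested.

The Newton engine (:func:`newton_cox`) is shared with the multivariate
risk model in :mod:`coxfilter.evaluate`; it maximises the partial
likelihood for any design matrix with step-halving, and flags monotone
likelihoods (separation) instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DataError, ExpressionMatrix, LOG2P1

EFRON = "efron"
BRESLOW = "breslow"

LABELS = ("c1_specific", "c2_specific", "shared", "none", "unfit")


# ---------------------------------------------------------------------------
# partial likelihood machinery

class CoxData:
    """Sorted survival data with precomputed risk-set/tie structure.

    Sorting and tie grouping are independent of the design matrix, so one
    instance is reused across all genes sharing an outcome.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.ndim != 1 or time.shape != event.shape:
            raise DataError("time and event must be equal-length 1-d arrays")
        if np.any(time < 0) or not np.all(np.isfinite(time)):
            raise DataError("times must be finite and non-negative")
        if not np.isin(event, (0, 1)).all():
            raise DataError("event indicators must be 0 or 1")
        if event.sum() == 0:
            raise DataError("no events")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order].astype(bool)
        # first sorted index sharing each row's time = start of its risk set
        u_times, starts = np.unique(self.time, return_index=True)
        self.risk_start = starts[np.searchsorted(u_times, self.time)]
        ev_idx = np.flatnonzero(self.event)
        # death groups: events sharing a time
        self.tied = np.unique(self.time[ev_idx]).size < ev_idx.size
        if self.tied:
            groups = {}
            for i in ev_idx:
                groups.setdefault(self.time[i], []).append(i)
            self.death_groups = [
                (self.risk_start[idx[0]], np.array(idx)) for idx in groups.values()
            ]
        else:
            self.ev_idx = ev_idx
        self.n_events = int(ev_idx.size)


def _revcumsum(a):
    return np.cumsum(a[::-1], axis=0)[::-1]


def cox_loglik(beta, Z, data: CoxData, ties_method: str = EFRON):
    """Log partial likelihood with analytic gradient and observed information.

    ``Z`` is the (n, k) design matrix in original sample order; ``beta`` a
    k-vector.  Returns ``(loglik, gradient, information)``.
    """
    if ties_method not in (EFRON, BRESLOW):
        raise ValueError(f"unknown ties method {ties_method!r}")
    beta = np.asarray(beta, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise DataError("design matrix contains non-finite values")
    Zs = Z[data.order]
    k = Zs.shape[1]
    eta = Zs @ beta
    # guard exp overflow during wild Newton trial steps
    w = np.exp(np.clip(eta, -700, 700))
    wz = w[:, None] * Zs
    wzz = wz[:, :, None] * Zs[:, None, :]
    R = _revcumsum(w)
    A = _revcumsum(wz)
    B = _revcumsum(wzz.reshape(data.n, -1)).reshape(data.n, k, k)

    if not data.tied:
        i = data.ev_idx
        fi = data.risk_start[i]
        r = R[fi]
        a = A[fi]
        b = B[fi]
        ll = eta[i].sum() - np.log(r).sum()
        grad = Zs[i].sum(axis=0) - (a / r[:, None]).sum(axis=0)
        info = (b / r[:, None, None]).sum(axis=0) - (
            a[:, :, None] * a[:, None, :] / (r ** 2)[:, None, None]
        ).sum(axis=0)
        return ll, grad, info

    ll = 0.0
    grad = np.zeros(k)
    info = np.zeros((k, k))
    for start, deaths in data.death_groups:
        d = deaths.size
        r, a, b = R[start], A[start], B[start]
        dw = w[deaths].sum()
        da = wz[deaths].sum(axis=0)
        db = wzz[deaths].sum(axis=0)
        ll += eta[deaths].sum()
        grad += Zs[deaths].sum(axis=0)
        for l in range(d):
            frac = l / d if ties_method == EFRON else 0.0
            phi = r - frac * dw
            av = a - frac * da
            bv = b - frac * db
            ll -= np.log(phi)
            grad -= av / phi
            info += bv / phi - np.outer(av, av) / phi ** 2
    return ll, grad, info


def partial_loglik(beta, design, time, event, ties_method: str = EFRON):
    """One-shot partial log-likelihood evaluation (see :func:`cox_loglik`)."""
    return cox_loglik(beta, design, CoxData(time, event), ties_method)


# ---------------------------------------------------------------------------
# Newton–Raphson fitting

@dataclass
class NewtonResult:
    beta: np.ndarray
    covariance: Optional[np.ndarray]
    loglik: float
    converged: bool
    iterations: int
    message: str


def newton_cox(
    Z,
    time,
    event,
    ties_method: str = EFRON,
    max_iter: int = 50,
    tol: float = 1e-8,
    max_halvings: int = 30,
    beta_bound: float = 10.0,
    data: Optional[CoxData] = None,
) -> NewtonResult:
    """Maximise the Cox partial likelihood from beta = 0 with step-halving.

    Convergence: relative log-likelihood change below ``tol``.  Any
    coefficient escaping ``beta_bound`` in absolute value flags a monotone
    likelihood (perfect separation of the event ranking); singular
    information flags a degenerate design.  Neither raises — the result
    carries ``converged=False`` and a message.
    """
    Z = np.asarray(Z, dtype=float)
    if data is None:
        data = CoxData(time, event)
    k = Z.shape[1]
    # center columns: partial likelihood is invariant to location shifts
    # but exp(eta) stays tame during line search
    Zc = Z - Z.mean(axis=0)
    beta = np.zeros(k)
    ll, grad, info = cox_loglik(beta, Zc, data, ties_method)
    message = "converged"
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return NewtonResult(beta, None, ll, False, it, "singular information")
        new_beta = beta + step
        new_ll, new_grad, new_info = cox_loglik(new_beta, Zc, data, ties_method)
        halvings = 0
        while new_ll < ll and halvings < max_halvings:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = cox_loglik(new_beta, Zc, data, ties_method)
            halvings += 1
        if new_ll < ll:
            # cannot improve along the Newton direction
            converged = True
            message = "converged (step search exhausted)"
            break
        delta = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.any(np.abs(beta) > beta_bound):
            return NewtonResult(
                beta, None, ll, False, it,
                "monotone likelihood (possible separation)",
            )
        if delta < tol * max(1.0, abs(ll)):
            converged = True
            break
    else:
        message = "maximum iterations reached"
    if not converged:
        return NewtonResult(beta, None, ll, False, it, message)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return NewtonResult(beta, None, ll, False, it,
                            "singular information at optimum")
    return NewtonResult(beta, cov, ll, True, it, message)


# ---------------------------------------------------------------------------
# per-gene model

@dataclass
class CoxGeneFit:
    """Per-gene interaction-model fit.

    ``beta`` holds (b1, b2, b3) for subtype indicator, expression and
    their product; ``covariance`` is the inverse observed information at
    the optimum (None when not converged).
    """

    gene_id: str
    beta: Optional[np.ndarray]
    covariance: Optional[np.ndarray]
    loglik: float
    n_events: int
    converged: bool
    iterations: int
    message: str


def _gene_design(gene_expr, i_c2):
    x = np.asarray(gene_expr, dtype=float)
    return np.column_stack([i_c2, x, i_c2 * x])


def fit_cox_gene(
    gene_expr,
    subtype_indicator,
    time,
    event,
    ties_method: str = EFRON,
    max_iter: int = 50,
    tol: float = 1e-8,
    gene_id: str = "",
    data: Optional[CoxData] = None,
) -> CoxGeneFit:
    """Fit the three-coefficient interaction model for one gene.

    ``subtype_indicator`` is I(sample in c2).  Degenerate covariates
    (expression constant overall, or constant within both subtype strata
    so the interaction is inestimable) and outcomes with no events return
    an unfit result rather than raising.
    """
    x = np.asarray(gene_expr, dtype=float)
    i_c2 = np.asarray(subtype_indicator, dtype=float)
    event = np.asarray(event, dtype=int)

    def unfit(msg):
        return CoxGeneFit(gene_id, None, None, np.nan, int(event.sum()),
                          False, 0, msg)

    if i_c2.min() == i_c2.max():
        return unfit("only one subtype present")
    if event.sum() == 0:
        return unfit("no events")
    if np.ptp(x) == 0:
        return unfit("degenerate covariate")
    if np.ptp(x[i_c2 == 0]) == 0 and np.ptp(x[i_c2 == 1]) == 0:
        return unfit("interaction inestimable (expression constant "
                     "within both subtype strata)")
    res = newton_cox(
        _gene_design(x, i_c2), time, event, ties_method,
        max_iter=max_iter, tol=tol, data=data,
    )
    return CoxGeneFit(
        gene_id, res.beta, res.covariance, res.loglik,
        int(event.sum()), res.converged, res.iterations, res.message,
    )


#: Wald weights for the two screening contrasts.
W_C1 = np.array([0.0, 1.0, 0.0])   # H0: b2 = 0
W_C2 = np.array([0.0, 1.0, 1.0])   # H0: b2 + b3 = 0


def wald_linear_test(fit: CoxGeneFit, weights):
    """Two-sided Wald test of H0: w'beta = 0.

    Returns ``(z, p)`` with z = w'beta / sqrt(w' Cov w) against a standard
    normal reference.
    """
    if not fit.converged:
        raise DataError("fit did not converge; Wald test unavailable")
    w = np.asarray(weights, dtype=float)
    var = float(w @ fit.covariance @ w)
    if var <= 0:
        raise DataError("non-positive variance")
    z = float(w @ fit.beta) / np.sqrt(var)
    return z, 2.0 * stats.norm.sf(abs(z))


def lrt_linear_test(
    gene_expr, subtype_indicator, time, event, weights,
    ties_method: str = EFRON, data: Optional[CoxData] = None,
):
    """Likelihood-ratio cross-check of H0: w'beta = 0.

    Refits the model constrained to the null space of w (beta = N @ gamma)
    and compares maximised log partial likelihoods on a chi-square(1)
    reference.  Returns ``(chi2, p)``.
    """
    Z = _gene_design(gene_expr, np.asarray(subtype_indicator, dtype=float))
    if data is None:
        data = CoxData(time, event)
    w = np.asarray(weights, dtype=float).reshape(1, -1)
    # orthonormal basis of the null space of w
    _, _, vt = np.linalg.svd(w)
    N = vt[1:].T
    full = newton_cox(Z, time, event, ties_method, data=data)
    constrained = newton_cox(Z @ N, time, event, ties_method, data=data)
    if not (full.converged and constrained.converged):
        raise DataError("LRT requires both fits to converge")
    chi2 = max(0.0, 2.0 * (full.loglik - constrained.loglik))
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# multiplicity and classification

def adjust_pvalues(pvals, method: str = "bh"):
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_gene(padj_c1: float, padj_c2: float, alpha: float) -> str:
    """Four-way subtype-specificity label from adjusted p-values."""
    in1 = padj_c1 < alpha
    in2 = padj_c2 < alpha
    if in1 and in2:
        return "shared"
    if in1:
        return "c1_specific"
    if in2:
        return "c2_specific"
    return "none"


@dataclass
class ScreenResult:
    """Genome-wide screen outcome.

    ``table`` has one row per gene (schema of the output TSV);
    ``set_c1`` / ``set_c2`` are the genes whose adjusted p-values fall
    below alpha for the c1 / c2 contrast, ``overlap`` their intersection.
    """

    table: pd.DataFrame
    set_c1: set = field(default_factory=set)
    set_c2: set = field(default_factory=set)
    overlap: set = field(default_factory=set)
    alpha: float = 0.05

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


_TABLE_COLS = [
    "gene_id", "beta1", "beta2", "beta3", "se_beta2", "se_b2p3",
    "p_c1", "p_c2", "padj_c1", "padj_c2", "label", "converged", "n_events",
]


def _finish_screen(rows, alpha, adjust_family):
    table = pd.DataFrame(rows, columns=_TABLE_COLS)
    fitted = table["converged"].to_numpy(dtype=bool)
    padj1 = np.full(len(table), np.nan)
    padj2 = np.full(len(table), np.nan)
    if fitted.any():
        p1 = table.loc[fitted, "p_c1"].to_numpy()
        p2 = table.loc[fitted, "p_c2"].to_numpy()
        if adjust_family == "separate":
            padj1[fitted] = adjust_pvalues(p1)
            padj2[fitted] = adjust_pvalues(p2)
        elif adjust_family == "pooled":
            both = adjust_pvalues(np.concatenate([p1, p2]))
            padj1[fitted] = both[: p1.size]
            padj2[fitted] = both[p1.size:]
        else:
            raise ValueError(f"unknown adjust_family {adjust_family!r}")
    table["padj_c1"] = padj1
    table["padj_c2"] = padj2
    labels = []
    for conv, a1, a2 in zip(fitted, padj1, padj2):
        labels.append(classify_gene(a1, a2, alpha) if conv else "unfit")
    table["label"] = labels
    ids = table["gene_id"]
    set_c1 = set(ids[fitted & (padj1 < alpha)])
    set_c2 = set(ids[fitted & (padj2 < alpha)])
    return ScreenResult(table, set_c1, set_c2, set_c1 & set_c2, alpha)


def _screen_rows(matrix, i_c2, outcome_iter, ties_method, max_iter, tol):
    rows = []
    for g, (gene_id, time, event, data) in enumerate(outcome_iter):
        fit = fit_cox_gene(
            matrix.values[g], i_c2, time, event, ties_method,
            max_iter=max_iter, tol=tol, gene_id=gene_id, data=data,
        )
        if fit.converged:
            se2 = np.sqrt(fit.covariance[1, 1])
            se23 = np.sqrt(W_C2 @ fit.covariance @ W_C2)
            _, p1 = wald_linear_test(fit, W_C1)
            _, p2 = wald_linear_test(fit, W_C2)
            rows.append([
                gene_id, fit.beta[0], fit.beta[1], fit.beta[2], se2, se23,
                p1, p2, np.nan, np.nan, "", True, fit.n_events,
            ])
        else:
            rows.append([
                gene_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                np.nan, np.nan, np.nan, np.nan, "unfit", False, fit.n_events,
            ])
    return rows


def subtype_indicator(subtype, levels=None):
    """Map a two-level subtype vector to I(c2); returns (indicator, levels)."""
    subtype = np.asarray(subtype, dtype=object)
    observed = pd.unique(subtype)
    if levels is None:
        levels = tuple(sorted(observed))
    if len(observed) != 2 or set(observed) != set(levels):
        raise DataError(
            f"subtype must have exactly the two levels {levels}, "
            f"observed {list(observed)}"
        )
    return (subtype == levels[1]).astype(float), tuple(levels)


def screen_genes(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    ties_method: str = EFRON,
    adjust_family: str = "separate",
    subtype_levels=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> ScreenResult:
    """Screen every gene against one shared survival outcome.

    Inputs must be aligned (matrix columns == clinical rows, same order,
    log2 scale).  The first subtype level (sorted, or ``subtype_levels``
    order) plays c1; the second c2.  Unfit genes are excluded from both
    adjustment families.
    """
    if matrix.scale_tag != LOG2P1:
        raise DataError("screen expects log2(FPKM+1) expression")
    if list(clinical["sample_id"]) != matrix.sample_ids:
        raise DataError("matrix and clinical table are not aligned")
    i_c2, _ = subtype_indicator(clinical["subtype"].to_numpy(), subtype_levels)
    time = clinical["os_time"].to_numpy(dtype=float)
    event = clinical["os_event"].to_numpy(dtype=int)
    data = CoxData(time, event)  # shared outcome: sort/ties computed once
    outcome_iter = (
        (gid, time, event, data) for gid in matrix.feature_ids
    )
    rows = _screen_rows(matrix, i_c2, outcome_iter, ties_method, max_iter, tol)
    result = _finish_screen(rows, alpha, adjust_family)
    if not result.table["converged"].any():
        raise DataError("all genes unfit")
    return result


def screen_genes_matched(
    matrix: ExpressionMatrix,
    subtype,
    times,
    events,
    alpha: float = 0.05,
    ties_method: str = EFRON,
    adjust_family: str = "separate",
    subtype_levels=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> ScreenResult:
    """Screen genes that each carry their own survival outcome.

    ``times`` and ``events`` are (n_genes, n_samples) panels as produced
    by :func:`coxfilter.simulate.generate_matched_cohort`; gene g is
    fitted against row g.  Used for calibration and recovery studies where
    every per-gene model must be exactly correctly specified.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != (matrix.n_features, matrix.n_samples):
        raise DataError("survival panel shape must be n_genes x n_samples")
    i_c2, _ = subtype_indicator(np.asarray(subtype), subtype_levels)
    outcome_iter = (
        (gid, times[g], events[g], None)
        for g, gid in enumerate(matrix.feature_ids)
    )
    rows = _screen_rows(matrix, i_c2, outcome_iter, ties_method, max_iter, tol)
    result = _finish_screen(rows, alpha, adjust_family)
    if not result.table["converged"].any():
        raise DataError("all genes unfit")
    return result
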