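"""Survival statistics core.

Kaplan-Meier product-limit estimation, the two-group log-rank test
(including a vectorized many-splits variant used by the cutoff scan),
Cox proportional-hazards regression with Efron tie handling, and the
minimal-p-value cutoff scan between expression quartiles with
Benjamini-Hochberg FDR over the derived cutoffs.

The cutoff scan emulates optimal-cutpoint survival analysis: every
distinct observed expression value between the lower and upper
quartiles is a candidate threshold, patients are split into low/high
at each candidate, the split minimizing the log-rank p-value is
selected, and the selection-induced optimism is accounted for by FDR
over all per-cutoff p-values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .cohort import ExpressionMatrix, SurvivalData
from .errors import (
    InsufficientGroupError,
    NoCutoffError,
    SingularDesignError,
    ValidationError,
)
from .roc import bh_fdr

DEFAULT_FDR_LEVEL = 0.10
MIN_SCAN_SAMPLES = 20


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival curve: steps only at event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(surv: SurvivalData) -> KmCurve:
    """Kaplan-Meier estimate; censoring decrements the risk set without a step."""
    mask = surv.complete_mask()
    t = surv.time[mask]
    e = surv.event[mask]
    if t.size == 0:
        raise ValidationError("empty survival data")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ev_times = np.unique(t[e == 1])
    s = 1.0
    probs, at_risk = [], []
    for et in ev_times:
        n_at = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_at
        probs.append(s)
        at_risk.append(n_at)
    return KmCurve(ev_times, np.array(probs), np.array(at_risk, dtype=int), int(t.size))


# ---------------------------------------------------------------------------
# log-rank (single split and vectorized many-splits)


def _logrank_many(time: np.ndarray, event: np.ndarray, groups: np.ndarray):
    """Log-rank chi-square (1 df) for many binary splits of one cohort.

    ``groups`` is (k, n) boolean, True marking membership in group 1.
    Returns (chi2, p, observed, expected) arrays of length k, using the
    standard hypergeometric variance at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    groups = np.atleast_2d(np.asarray(groups, dtype=float))
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    z = groups[:, order]
    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        raise ValidationError("log-rank requires at least one event")
    # at-risk indicator (n x T): sample i at risk at ev_times[j] iff t_i >= ev_times[j]
    at_risk = t[:, None] >= ev_times[None, :]
    death = (t[:, None] == ev_times[None, :]) & (e[:, None] == 1)
    n_t = at_risk.sum(axis=0).astype(float)  # (T,)
    d_t = death.sum(axis=0).astype(float)
    n1_t = z @ at_risk  # (k, T)
    d1_t = z @ death
    frac = n1_t / n_t
    observed = d1_t.sum(axis=1)
    expected = (d_t * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = np.where(
            n_t > 1, d_t * frac * (1.0 - frac) * (n_t - d_t) / (n_t - 1.0), 0.0
        )
    var = var_terms.sum(axis=1)
    chi2 = np.zeros(groups.shape[0])
    p = np.ones(groups.shape[0])
    ok = var > 0
    chi2[ok] = (observed[ok] - expected[ok]) ** 2 / var[ok]
    p[ok] = chi2_dist.sf(chi2[ok], 1)
    return chi2, p, observed, expected


def logrank_test(surv_a: SurvivalData, surv_b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square on 1 df, p-value)."""
    ma, mb = surv_a.complete_mask(), surv_b.complete_mask()
    ta, ea = surv_a.time[ma], surv_a.event[ma]
    tb, eb = surv_b.time[mb], surv_b.event[mb]
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    grp = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    if event.sum() == 0:
        raise ValidationError("log-rank requires at least one event")
    chi2, p, _, _ = _logrank_many(time, event, grp[None, :])
    return float(chi2[0]), float(p[0])


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit summary.

    Hazard ratios are exp(coefficients); 95% CI = exp(coef +- 1.96 SE);
    ``score_p`` is the global score test at beta = 0 (equals the
    log-rank test for a single binary covariate without ties).
    """

    covariates: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    wald_p: np.ndarray
    score_chi2: float
    score_p: float
    log_likelihood: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "wald_p": self.wald_p,
            }
        )


def _efron_quantities(beta, x, groups_idx):
    """Efron partial log-likelihood, gradient and information.

    ``groups_idx``: list of (risk_set_rows, death_rows) per distinct
    event time, with risk sets as index arrays into x.  The constant
    shift applied to eta cancels in the ratios and in the likelihood
    (one log term per death), so it only guards against overflow.
    """
    k = x.shape[1]
    eta = x @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wx = w[:, None] * x
    ll = 0.0
    grad = np.zeros(k)
    info = np.zeros((k, k))
    for risk, deaths in groups_idx:
        d = deaths.size
        s0 = w[risk].sum()
        s1 = wx[risk].sum(axis=0)
        s2 = (wx[risk].T @ x[risk])
        s0d = w[deaths].sum()
        s1d = wx[deaths].sum(axis=0)
        s2d = (wx[deaths].T @ x[deaths])
        ll += eta[deaths].sum()
        for l in range(d):
            phi = l / d
            s0l = s0 - phi * s0d
            s1l = s1 - phi * s1d
            s2l = s2 - phi * s2d
            ll -= math.log(s0l)
            mean_l = s1l / s0l
            grad -= mean_l
            info += s2l / s0l - np.outer(mean_l, mean_l)
        grad += x[deaths].sum(axis=0)
    return ll, grad, info


def _risk_sets(t: np.ndarray, e: np.ndarray):
    """Per distinct event time: (risk-set row indices, death row indices)."""
    out = []
    for et in np.unique(t[e == 1]):
        risk = np.flatnonzero(t >= et)
        deaths = np.flatnonzero((t == et) & (e == 1))
        out.append((risk, deaths))
    return out


def fit_cox(
    design,
    surv: SurvivalData,
    names: tuple[str, ...] | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Maximize the Efron partial likelihood by Newton-Raphson.

    ``design`` is (n, k) (a 1-D vector is treated as one covariate).
    Raises SingularDesignError on constant or collinear covariates;
    monotone likelihood (perfect separation) yields a flagged
    non-converged fit rather than silent output.
    """
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if names is None:
        names = tuple(f"x{i}" for i in range(x.shape[1]))
    mask = surv.complete_mask() & np.all(np.isfinite(x), axis=1)
    x = x[mask]
    t = surv.time[mask]
    e = surv.event[mask]
    n, k = x.shape
    n_events = int((e == 1).sum())
    if n_events < k + 1:
        raise ValidationError(f"need >= {k + 1} events for {k} covariates, have {n_events}")
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in range(k) if sd[i] == 0]
        raise SingularDesignError(f"constant covariates: {bad}")
    if np.linalg.matrix_rank(xc) < k:
        raise SingularDesignError("collinear covariate matrix")

    groups_idx = _risk_sets(t, e)
    # score test at beta = 0
    ll0, u0, i0 = _efron_quantities(np.zeros(k), xc, groups_idx)
    try:
        score_chi2 = float(u0 @ np.linalg.solve(i0, u0))
    except np.linalg.LinAlgError:
        raise SingularDesignError("singular information matrix at beta = 0") from None
    score_p = float(chi2_dist.sf(score_chi2, k))

    beta = np.zeros(k)
    ll, grad, info = ll0, u0, i0
    converged = False
    flags: tuple[str, ...] = ()
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags = ("singular_information",)
            break
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _efron_quantities(cand, xc, groups_idx)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 50:
            flags = ("monotone_likelihood",)
            break

    try:
        cov = np.linalg.inv(info)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    # a flat (monotone) likelihood can stall the gradient numerically and
    # masquerade as convergence; runaway coefficients or a broken
    # information matrix reveal it
    if converged and (not np.all(np.isfinite(se)) or np.max(np.abs(beta)) > 20):
        converged = False
        flags = flags + ("monotone_likelihood",)
    hr = np.exp(beta)
    ci_low = np.exp(beta - 1.96 * se)
    ci_high = np.exp(beta + 1.96 * se)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald_p = 2.0 * norm.sf(np.abs(beta / se))
    if not converged and not flags:
        flags = ("not_converged",)
    return CoxFit(
        covariates=tuple(names),
        coef=beta,
        se=se,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        wald_p=wald_p,
        score_chi2=score_chi2,
        score_p=score_p,
        log_likelihood=float(ll),
        n=n,
        n_events=n_events,
        n_iter=it,
        converged=converged,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# minimal-p cutoff scan


@dataclass
class CutoffScanResult:
    """Minimal-p-value cutoff scan of one expression vector.

    Candidates are the distinct observed values in [Q1, Q3) (type-7
    quartiles); the split rule is high = value > cutoff, so each arm
    keeps at least a quartile of the cohort.  ``fdr_q`` is BH over this
    scan's per-cutoff p-values; ``significant`` tests the q of the
    minimal-p cutoff against the FDR level.
    """

    name: str
    cutoffs: np.ndarray
    p_values: np.ndarray
    fdr_q: np.ndarray
    best_cutoff: float
    min_p: float
    best_q: float
    hr: float
    ci_low: float
    ci_high: float
    hr_wald_p: float
    n_low: int
    n_high: int
    significant: bool
    cox: CoxFit | None = None
    flags: tuple[str, ...] = ()

    @property
    def analyzable(self) -> bool:
        return np.isfinite(self.min_p)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.cutoffs, "p_value": self.p_values, "fdr_q": self.fdr_q}
        )


def candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Distinct observed values v with Q1 <= v < Q3 (type-7 quartiles)."""
    q1, q3 = np.quantile(values, [0.25, 0.75])
    distinct = np.unique(values)
    return distinct[(distinct >= q1) & (distinct < q3)]


def scan_cutoffs(
    values,
    surv: SurvivalData,
    name: str = "",
    fdr_level: float = DEFAULT_FDR_LEVEL,
    fit_hr: bool = True,
) -> CutoffScanResult:
    """Minimal-p-value survival cutoff for one expression vector.

    Every distinct observed value between the quartiles is tried as a
    threshold (high = value > threshold); per-cutoff p-values come from
    the log-rank test, the best cutoff is the argmin (ties toward the
    lower cutoff), and the hazard ratio with 95% CI at the best cutoff
    comes from a Cox fit on the binary indicator.
    """
    if isinstance(values, pd.Series):
        values = values.to_numpy(dtype=float)
    v = np.asarray(values, dtype=float)
    if surv.n != v.size:
        raise ValidationError("values and survival data length mismatch")
    mask = surv.complete_mask() & np.isfinite(v)
    v = v[mask]
    sub = surv.select(mask)
    if v.size < MIN_SCAN_SAMPLES:
        raise InsufficientGroupError(
            f"{name or 'scan'}: need >= {MIN_SCAN_SAMPLES} samples, have {v.size}"
        )
    if sub.n_events == 0:
        raise ValidationError("cutoff scan requires at least one event")
    cand = candidate_cutoffs(v)
    if cand.size == 0:
        raise NoCutoffError(
            f"{name or 'scan'}: no eligible cutoff between the quartiles (constant values?)"
        )
    groups = v[None, :] > cand[:, None]  # (k, n) high-expression arms
    _, p, _, _ = _logrank_many(sub.time, sub.event, groups)
    best = int(np.argmin(p))  # first (lowest) cutoff on ties
    q = bh_fdr(p)
    best_cutoff = float(cand[best])
    high = v > best_cutoff
    n_high = int(high.sum())
    n_low = int(v.size - n_high)
    hr = ci_low = ci_high = hr_p = math.nan
    cox = None
    flags: tuple[str, ...] = ()
    if fit_hr:
        try:
            cox = fit_cox(high.astype(float), sub, names=("high_expression",))
            hr = float(cox.hr[0])
            ci_low = float(cox.ci_low[0])
            ci_high = float(cox.ci_high[0])
            hr_p = float(cox.wald_p[0])
            if not cox.converged:
                flags = flags + cox.flags
        except (ValidationError, SingularDesignError):
            flags = flags + ("cox_failed",)
    return CutoffScanResult(
        name=name,
        cutoffs=cand,
        p_values=p,
        fdr_q=q,
        best_cutoff=best_cutoff,
        min_p=float(p[best]),
        best_q=float(q[best]),
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        hr_wald_p=hr_p,
        n_low=n_low,
        n_high=n_high,
        significant=bool(q[best] < fdr_level),
        cox=cox,
        flags=flags,
    )


def _failed_scan(name: str, reason: str) -> CutoffScanResult:
    nanarr = np.array([])
    return CutoffScanResult(
        name=name, cutoffs=nanarr, p_values=nanarr, fdr_q=nanarr,
        best_cutoff=math.nan, min_p=math.nan, best_q=math.nan,
        hr=math.nan, ci_low=math.nan, ci_high=math.nan, hr_wald_p=math.nan,
        n_low=0, n_high=0, significant=False, flags=(reason,),
    )


def outcome_screen(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    gene_list: list[str] | None = None,
    fdr_level: float = DEFAULT_FDR_LEVEL,
    fdr_scope: str = "within_gene",
    fit_hr: bool = True,
) -> list[CutoffScanResult]:
    """Minimal-p cutoff scan for every gene.

    ``fdr_scope`` selects whether BH runs within each gene's own scan
    (default) or pooled over every derived cutoff of every gene; the
    per-gene significance verdict always uses the q of the minimal-p
    cutoff.  Genes failing the scan are reported with a reason flag.
    """
    if fdr_scope not in ("within_gene", "pooled"):
        raise ValidationError("fdr_scope must be 'within_gene' or 'pooled'")
    genes = list(gene_list) if gene_list is not None else expr.genes
    results: list[CutoffScanResult] = []
    for g in genes:
        v = expr.gene_values(g)
        try:
            results.append(scan_cutoffs(v, surv, name=g, fdr_level=fdr_level,
                                        fit_hr=fit_hr))
        except NoCutoffError:
            results.append(_failed_scan(g, "no_cutoff"))
        except (InsufficientGroupError, ValidationError):
            results.append(_failed_scan(g, "insufficient_samples"))
    if fdr_scope == "pooled":
        ok = [r for r in results if r.analyzable]
        if ok:
            pooled = np.concatenate([r.p_values for r in ok])
            q_all = bh_fdr(pooled)
            pos = 0
            for r in ok:
                k = r.p_values.size
                r.fdr_q = q_all[pos:pos + k]
                best = int(np.argmin(r.p_values))
                r.best_q = float(r.fdr_q[best])
                r.significant = bool(r.best_q < fdr_level)
                pos += k
    return results


def outcome_table(results: list[CutoffScanResult]) -> pd.DataFrame:
    """Cross-gene summary of cutoff scans (one row per gene)."""
    return pd.DataFrame(
        {
            "gene": [r.name for r in results],
            "best_cutoff": [r.best_cutoff for r in results],
            "n_low": [r.n_low for r in results],
            "n_high": [r.n_high for r in results],
            "min_p": [r.min_p for r in results],
            "hr": [r.hr for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "fdr_q": [r.best_q for r in results],
            "significant": [int(bool(r.significant)) for r in results],
            "flags": [",".join(r.flags) for r in results],
        }
    )
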