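"""Responder ROC screening by Mann-Whitney.

Samples are dichotomized into responders (relapse-free for at least the
horizon, default 60 months) and non-responders (relapse before the
horizon); censored-before-horizon samples are excluded.  Each gene is
then compared between the two groups with a Mann-Whitney ROC analysis:
AUC from the U statistic, a two-sided p-value (exact enumeration for
small groups, tie-corrected normal approximation otherwise), and the
strongest cutoff by Youden's J with its FPR/TPR.  Benjamini-Hochberg
FDR over all screened genes gates significance at q < 0.10.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import ClinicalTable, ExpressionMatrix, SurvivalData
from .errors import InsufficientGroupError, ValidationError

DEFAULT_HORIZON = 60.0
DEFAULT_FDR_LEVEL = 0.10
#: groups at or below this size use exact permutation enumeration for p
EXACT_MAX_GROUP = 8
#: genes analyzed on fewer non-missing samples than this are flagged low-n
LOW_N = 20

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class ResponderLabels:
    """Per-sample responder dichotomy at a fixed horizon (months)."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    reasons: tuple[str, ...]  # empty string where included
    horizon: float = DEFAULT_HORIZON

    def __post_init__(self):
        if not (len(self.sample_ids) == len(self.labels) == len(self.reasons)):
            raise ValidationError("labels fields must have equal length")
        bad = set(self.labels) - {RESPONDER, NON_RESPONDER, EXCLUDED}
        if bad:
            raise ValidationError(f"unknown labels: {sorted(bad)}")

    @property
    def responder_mask(self) -> np.ndarray:
        return np.array([l == RESPONDER for l in self.labels])

    @property
    def nonresponder_mask(self) -> np.ndarray:
        return np.array([l == NON_RESPONDER for l in self.labels])

    @property
    def n_responder(self) -> int:
        return int(self.responder_mask.sum())

    @property
    def n_nonresponder(self) -> int:
        return int(self.nonresponder_mask.sum())

    @property
    def n_excluded(self) -> int:
        return len(self.labels) - self.n_responder - self.n_nonresponder

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "label": self.labels, "reason": self.reasons}
        )


@dataclass
class RocResult:
    """One gene's (or signature's) Mann-Whitney ROC summary.

    ``auc`` is P(responder value > non-responder value) + half the tie
    probability; direction is reported as-is (values < 0.5 allowed).
    ``cutoff`` maximizes Youden's J = TPR - FPR for the rule
    "predict responder when value > cutoff".
    """

    name: str
    auc: float
    p_value: float
    cutoff: float
    fpr: float
    tpr: float
    n_responder: int
    n_nonresponder: int
    fdr_q: float | None = None
    significant: bool | None = None
    flags: tuple[str, ...] = ()

    @property
    def analyzable(self) -> bool:
        return np.isfinite(self.p_value)


def derive_responder_labels(
    surv: SurvivalData, horizon: float = DEFAULT_HORIZON
) -> ResponderLabels:
    """Dichotomize survival at the horizon.

    Relapse before the horizon -> non-responder; relapse-free with
    follow-up >= horizon -> responder; censored before the horizon ->
    excluded (reason ``censored-before-horizon``); missing survival ->
    excluded (reason ``missing-survival``).
    """
    if surv.sample_ids is None:
        ids = tuple(f"sample{i}" for i in range(surv.n))
    else:
        ids = tuple(surv.sample_ids)
    labels, reasons = [], []
    for t, e in zip(surv.time, surv.event):
        if not (np.isfinite(t) and np.isfinite(e)):
            labels.append(EXCLUDED)
            reasons.append("missing-survival")
        elif e == 1 and t < horizon:
            labels.append(NON_RESPONDER)
            reasons.append("")
        elif t >= horizon:
            labels.append(RESPONDER)
            reasons.append("")
        else:
            labels.append(EXCLUDED)
            reasons.append("censored-before-horizon")
    out = ResponderLabels(ids, tuple(labels), tuple(reasons), horizon)
    if out.n_responder + out.n_nonresponder == 0:
        raise ValidationError("no sample classifiable as responder or non-responder")
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney core


def _youden_cutoff(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float, float]:
    """Strongest cutoff: maximize J = TPR - FPR over midpoints between
    consecutive distinct pooled values; ties broken toward the lower cutoff."""
    pooled = np.unique(np.concatenate([pos, neg]))
    if pooled.size < 2:
        return math.nan, math.nan, math.nan
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    # TPR(c) = P(pos > c), FPR(c) = P(neg > c)
    tpr = (pos[None, :] > mids[:, None]).mean(axis=1)
    fpr = (neg[None, :] > mids[:, None]).mean(axis=1)
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax returns first (lowest) maximizer
    return float(mids[best]), float(fpr[best]), float(tpr[best])


def _exact_two_sided_p(ranks: np.ndarray, n_pos: int, u_obs: float) -> float:
    """Exact permutation p: enumerate all assignments of n_pos labels,
    two-sided on |U - n1*n0/2|.  Valid with ties."""
    n = ranks.size
    n_neg = n - n_pos
    mu = n_pos * n_neg / 2.0
    offset = n_pos * (n_pos + 1) / 2.0
    d_obs = abs(u_obs - mu) - 1e-12
    hits = total = 0
    for combo in itertools.combinations(range(n), n_pos):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mu) >= d_obs:
            hits += 1
    return hits / total


def roc_compare(pos: np.ndarray, neg: np.ndarray, name: str = "") -> RocResult:
    """Mann-Whitney ROC comparison of two value vectors (pos = responders)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    n1, n0 = pos.size, neg.size
    if n1 < 3 or n0 < 3:
        raise InsufficientGroupError(
            f"{name or 'comparison'}: need >= 3 samples per group, got {n1} vs {n0}"
        )
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n0)
    flags: tuple[str, ...] = ()

    if np.unique(pooled).size == 1:
        cutoff, fpr, tpr = _youden_cutoff(pos, neg)
        return RocResult(name, 0.5, 1.0, cutoff, fpr, tpr, n1, n0,
                         flags=("degenerate",))

    if n1 <= EXACT_MAX_GROUP and n0 <= EXACT_MAX_GROUP:
        p = _exact_two_sided_p(ranks, n1, u1)
    else:
        n = n1 + n0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
        var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
            flags = ("degenerate",)
        else:
            z = (u1 - n1 * n0 / 2.0) / math.sqrt(var_u)
            p = float(2.0 * norm.sf(abs(z)))
    cutoff, fpr, tpr = _youden_cutoff(pos, neg)
    return RocResult(name, float(auc), float(min(p, 1.0)), cutoff, fpr, tpr,
                     n1, n0, flags=flags)


def mannwhitney_auc(values, labels: ResponderLabels, name: str = "") -> RocResult:
    """ROC-compare a value vector between responders and non-responders.

    ``values`` must align with ``labels.sample_ids`` (a pandas Series is
    reindexed by sample ID; an array is taken positionally).  Missing
    values and excluded samples are dropped.
    """
    if isinstance(values, pd.Series):
        v = values.reindex(list(labels.sample_ids)).to_numpy(dtype=float)
    else:
        v = np.asarray(values, dtype=float)
        if v.shape[0] != len(labels.sample_ids):
            raise ValidationError("values length does not match labels")
    return roc_compare(v[labels.responder_mask], v[labels.nonresponder_mask], name)


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j along sorted p; tied p-values
    receive identical q.  Inputs must lie in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# screening


def screen_genes(
    expr: ExpressionMatrix,
    labels: ResponderLabels,
    gene_list: list[str] | None = None,
    fdr_level: float = DEFAULT_FDR_LEVEL,
) -> list[RocResult]:
    """Per-gene Mann-Whitney ROC screen with BH FDR across genes.

    Returns one RocResult per requested gene, sorted by p ascending;
    genes that cannot be analyzed (insufficient group after missing-value
    removal) are kept at the end with an explanatory flag rather than
    dropped.  ``significant`` marks fdr_q < ``fdr_level``.
    """
    genes = list(gene_list) if gene_list is not None else expr.genes
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    id_index = {s: i for i, s in enumerate(expr.samples)}
    common = [s for s in labels.sample_ids if s in id_index]
    if not common:
        raise ValidationError("no overlap between labels and expression samples")
    lab_keep = [s in id_index for s in labels.sample_ids]
    resp = labels.responder_mask[lab_keep]
    nonresp = labels.nonresponder_mask[lab_keep]
    cols = [id_index[s] for s in np.asarray(labels.sample_ids, dtype=object)[lab_keep]]
    mat = expr.data.to_numpy(dtype=float)[:, cols]
    gene_rows = {g: i for i, g in enumerate(expr.genes)}

    results: list[RocResult] = []
    for g in genes:
        v = mat[gene_rows[g]]
        try:
            r = roc_compare(v[resp], v[nonresp], name=g)
        except InsufficientGroupError as exc:
            results.append(
                RocResult(g, math.nan, math.nan, math.nan, math.nan, math.nan,
                          int(np.isfinite(v[resp]).sum()),
                          int(np.isfinite(v[nonresp]).sum()),
                          flags=("insufficient_group",))
            )
            continue
        if r.n_responder + r.n_nonresponder < LOW_N:
            r = replace(r, flags=r.flags + ("low_n",))
        results.append(r)

    ok = [r for r in results if r.analyzable]
    if ok:
        q = bh_fdr([r.p_value for r in ok])
        for r, qi in zip(ok, q):
            r.fdr_q = float(qi)
            r.significant = bool(qi < fdr_level)
    results.sort(key=lambda r: (not r.analyzable, r.p_value if r.analyzable else 0.0))
    return results


def pcr_labels(clin: ClinicalTable) -> ResponderLabels:
    """Build responder labels from the pCR column (1 = responder)."""
    pcr = pd.to_numeric(clin.data["pcr"], errors="coerce")
    n_known = int(pcr.notna().sum())
    if n_known < 6:
        raise ValidationError(f"pCR known for only {n_known} samples; need >= 6")
    classes = set(pcr.dropna().unique())
    if classes != {0.0, 1.0}:
        raise ValidationError("pCR must contain both classes (0 and 1)")
    labels, reasons = [], []
    for v in pcr:
        if not np.isfinite(v):
            labels.append(EXCLUDED)
            reasons.append("missing-pcr")
        elif v == 1:
            labels.append(RESPONDER)
            reasons.append("")
        else:
            labels.append(NON_RESPONDER)
            reasons.append("")
    return ResponderLabels(tuple(clin.sample_ids), tuple(labels), tuple(reasons),
                           horizon=math.nan)


def analyze_pcr(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    gene_list: list[str] | None = None,
    fdr_level: float = DEFAULT_FDR_LEVEL,
) -> list[RocResult]:
    """Per-gene ROC screen against pathological complete response.

    Identical machinery to :func:`screen_genes`, with pCR = 1 as the
    responder class; pCR is a binary endpoint, not time-to-event.
    """
    return screen_genes(expr, pcr_labels(clin), gene_list, fdr_level)


def roc_table(results: list[RocResult]) -> pd.DataFrame:
    """Tabular view of a screen (one row per gene, stable TSV columns)."""
    return pd.DataFrame(
        {
            "gene": [r.name for r in results],
            "auc": [r.auc for r in results],
            "p_value": [r.p_value for r in results],
            "cutoff": [r.cutoff for r in results],
            "fpr": [r.fpr for r in results],
            "tpr": [r.tpr for r in results],
            "n_responder": [r.n_responder for r in results],
            "n_nonresponder": [r.n_nonresponder for r in results],
            "fdr_q": [r.fdr_q if r.fdr_q is not None else math.nan for r in results],
            "significant": [int(bool(r.significant)) for r in results],
            "flags": [",".join(r.flags) for r in results],
        }
    )
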