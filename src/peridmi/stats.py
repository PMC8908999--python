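"""Group-level statistical battery for the perilesional cohort.

* one-way ANCOVA of each normalized metric on diagnostic group,
  controlling for lesion volume, with Bonferroni correction across the
  three metrics;
* Pearson correlations (metric vs. T2 volume, age vs. metric);
* Mann-Whitney U comparisons of age and lesion volume (exact permutation
  null for small samples, tie-corrected normal approximation otherwise);
* ROC analysis with the equally-weighted sensitivity/specificity
  (Youden) optimal cutpoint and confusion metrics at that cutpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .forward_model import ValidationError

__all__ = [
    "AncovaResult",
    "RocResult",
    "ancova_group_effect",
    "pearson_correlation",
    "mann_whitney",
    "roc_analysis",
    "analyze_cohort",
]


@dataclass(frozen=True)
class AncovaResult:
    F: float
    df: tuple  # (numerator, denominator)
    p_raw: float
    p_bonferroni: float
    adjusted_means: dict  # group -> covariate-adjusted mean


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutpoint: float
    direction: str  # ">=" or "<=" predicts the positive class
    sens: float
    spec: float
    ppv: float
    npv: float


def ancova_group_effect(y, group, covariate, m_comparisons: int = 3) -> AncovaResult:
    """One-way ANCOVA: F-test of the group effect controlling for a covariate.

    Fits the linear model y = b0 + group dummies + b_cov * covariate by
    OLS and tests the group dummies jointly against the full-model
    residual (for two groups: df = (1, n - 3)).  The raw p-value is
    Bonferroni-corrected over ``m_comparisons`` tests.  ``adjusted_means``
    are the model predictions per group at the grand-mean covariate.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    cov = np.asarray(covariate, dtype=float)
    if not (len(y) == len(group) == len(cov)):
        raise ValidationError("y, group and covariate must have equal length")
    if not np.all(np.isfinite(cov)) or not np.all(np.isfinite(y)):
        raise ValidationError("y and covariate must be finite")
    levels = np.unique(group)
    k = len(levels)
    n = len(y)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    if n < k + 2:
        raise ValidationError(f"need n >= {k + 2} observations, got {n}")
    dummies = np.column_stack([(group == lv).astype(float) for lv in levels[1:]])
    X_full = sm.add_constant(np.column_stack([dummies, cov]), has_constant="add")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValidationError(
            "design is rank deficient (covariate collinear with the group "
            "coding); the group effect is inestimable"
        )
    full = sm.OLS(y, X_full).fit()
    X_red = sm.add_constant(cov, has_constant="add")
    reduced = sm.OLS(y, X_red).fit()
    F, p_raw, df_num = full.compare_f_test(reduced)
    F = max(float(F), 0.0)
    df = (int(df_num), int(full.df_resid))
    cbar = cov.mean()
    adjusted = {}
    for lv in levels:
        row = np.concatenate([[1.0], (levels[1:] == lv).astype(float), [cbar]])
        adjusted[lv] = float(row @ full.params)
    return AncovaResult(
        F=F,
        df=df,
        p_raw=float(p_raw),
        p_bonferroni=min(1.0, m_comparisons * float(p_raw)),
        adjusted_means=adjusted,
    )


def pearson_correlation(x, y):
    """Product-moment correlation with the two-sided t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _exact_mw_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact permutation p for the Mann-Whitney U with midranks.

    Enumerates all C(n, n1) assignments of the combined (mid)ranks to the
    first sample; p = P(|U - mu| >= |U_obs - mu|).
    """
    n = len(ranks)
    mu = n1 * (n - n1) / 2.0
    const = n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - const
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney(a, b):
    """Two-sided Mann-Whitney U test.

    Exact permutation null (midranks, so ties are handled) for combined
    n <= 12; tie-corrected normal approximation otherwise.  Returns
    (U, p) with U the statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be nonempty")
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= 12:
        p = _exact_mw_p(ranks, n1, u)
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(min(p, 1.0))


def _confusion(scores, positive, cut, direction):
    pred = scores >= cut if direction == ">=" else scores <= cut
    tp = int(np.sum(pred & positive))
    fp = int(np.sum(pred & ~positive))
    fn = int(np.sum(~pred & positive))
    tn = int(np.sum(~pred & ~positive))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return sens, spec, ppv, npv


def roc_analysis(scores, labels, positive_class) -> RocResult:
    """Empirical ROC with the equally-weighted optimal cutpoint.

    Candidate cutpoints are the midpoints between consecutive distinct
    sorted scores plus -inf/+inf sentinels.  The classification direction
    (">=" or "<=" predicts the positive class) is the one whose best
    sensitivity + specificity is higher.  The AUC is the trapezoidal area
    under the empirical curve for that direction; the optimal cutpoint
    maximizes sensitivity + specificity (Youden), the smallest candidate
    winning ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    positive = labels == positive_class
    if positive.all() or not positive.any():
        raise ValidationError("both classes must be present for ROC analysis")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cands = np.concatenate([[-np.inf], mids, [np.inf]])

    best = {}
    for direction in (">=", "<="):
        sens = np.empty(len(cands))
        spec = np.empty(len(cands))
        for i, c in enumerate(cands):
            sens[i], spec[i], _, _ = _confusion(scores, positive, c, direction)
        j_best = float(np.max(sens + spec))
        best[direction] = (j_best, sens, spec)
    direction = ">=" if best[">="][0] >= best["<="][0] else "<="
    _, sens, spec = best[direction]

    # empirical curve: ascending FPR, ties broken by TPR so vertical
    # segments are traversed upward (trapezoid then credits ties by 1/2)
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    youden = sens + spec
    winners = np.flatnonzero(youden >= youden.max() - 1e-12)
    cut = float(cands[winners].min())
    s, sp, ppv, npv = _confusion(scores, positive, cut, direction)
    return RocResult(
        thresholds=cands,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutpoint=cut,
        direction=direction,
        sens=s,
        spec=sp,
        ppv=ppv,
        npv=npv,
    )


def analyze_cohort(
    frame: pd.DataFrame, positive_class: str = "GBM", m_comparisons: int = 3
) -> pd.DataFrame:
    """Full statistical battery on a cohort table.

    One row per normalized metric: ANCOVA F / raw and Bonferroni p
    (controlling for lesion volume), ROC AUC, Youden cutpoint and
    confusion metrics for predicting ``positive_class``, and the Pearson
    correlation of the metric with T2 volume within each group.
    """
    rows = []
    for metric in ("v_intra_norm", "v_extra_norm", "v_csf_norm"):
        anc = ancova_group_effect(
            frame[metric], frame["group"], frame["t2_volume_ml"], m_comparisons
        )
        roc = roc_analysis(frame[metric].to_numpy(), frame["group"].to_numpy(),
                           positive_class)
        row = {
            "metric": metric,
            "F": anc.F,
            "df_num": anc.df[0],
            "df_den": anc.df[1],
            "p_raw": anc.p_raw,
            "p_bonferroni": anc.p_bonferroni,
            "auc": roc.auc,
            "cutpoint": roc.optimal_cutpoint,
            "direction": roc.direction,
            "sens": roc.sens,
            "spec": roc.spec,
            "ppv": roc.ppv,
            "npv": roc.npv,
        }
        for grp, sub in frame.groupby("group"):
            r, p = pearson_correlation(sub[metric], sub["t2_volume_ml"])
            row[f"r_volume_{grp}"] = r
            row[f"p_volume_{grp}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
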