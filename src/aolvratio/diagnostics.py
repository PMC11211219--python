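"""Cohort-level statistics for the Ao:LV ratio as a severity marker.

Implements the study's analysis battery: Pearson correlation of the ratio
against TTE severity parameters, ROC analysis with the "lower ratio =
positive" orientation (AUC via the Mann-Whitney identity, percentile-
bootstrap CI, Youden cut-off), sensitivity/specificity at fixed cut-offs,
one-way ANOVA with Tukey HSD over severity groups, stratified subgroup
comparisons (valve morphology, flow state, root dilation), and observer
agreement (ICC(2,1), Bland-Altman, paired Pearson).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "RocResult",
    "GroupComparison",
    "StratifiedComparison",
    "AgreementResult",
    "DiagnosticsError",
    "pearson_correlation",
    "roc_analysis",
    "sens_spec_at_cutoff",
    "group_comparison",
    "stratified_comparison",
    "agreement_stats",
]


class DiagnosticsError(ValueError):
    """Raised on degenerate statistical input."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its t-transform p-value."""

    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC for a 'lower score = positive' marker."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_cutoff: float
    orientation: str = "lower ratio = positive"


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA F/p plus Tukey-HSD adjusted pairwise p-values."""

    f_statistic: float
    p_value: float
    pairwise_p: Mapping[tuple[str, str], float]
    group_means: Mapping[str, float]
    group_sds: Mapping[str, float]
    group_ns: Mapping[str, int]


@dataclass(frozen=True)
class StratifiedComparison:
    """Per-severity two-stratum comparison with the cell-mean layout."""

    stratifier: str
    cell_means: pd.DataFrame  # strata x severity, NaN where the cell is empty
    cell_ns: pd.DataFrame
    p_values: Mapping[str, float]  # per severity; NaN where a cell is absent


@dataclass(frozen=True)
class AgreementResult:
    """Observer agreement: ICC(2,1), paired Pearson r, Bland-Altman limits."""

    icc: float
    icc_model: str
    pearson_inter: float
    pearson_intra: float
    bland_altman_bias: float
    loa_low: float
    loa_high: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise DiagnosticsError(f"{name} contains non-finite values")
    return arr


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise DiagnosticsError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise DiagnosticsError("need at least 3 pairs")
    for arr, name in ((xa, "x"), (ya, "y")):
        if np.ptp(arr) == 0:
            raise DiagnosticsError(f"variable {name} is constant")
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=xa.size)


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(score_pos < score_neg) + 0.5 P(tie), via midranks."""
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    # midranks of the positive scores within the pooled sample; lower score
    # = more diseased, so concordance counts positives BELOW negatives
    ranks = stats.rankdata(scores)
    r_pos = ranks[pos].sum()
    u = r_pos - n1 * (n1 + 1) / 2.0  # pairs where positive > negative (+ half ties)
    return 1.0 - u / (n1 * n0)


def sens_spec_at_cutoff(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> tuple[float, float]:
    """Sensitivity and specificity of the 'score < cutoff -> positive' rule."""
    s = _as_1d(scores, "scores")
    y = np.asarray(labels).astype(int).ravel()
    if s.size != y.size:
        raise DiagnosticsError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise DiagnosticsError("both classes must be present")
    call = s < cutoff
    tp = int(np.sum(call & (y == 1)))
    fn = int(np.sum(~call & (y == 1)))
    tn = int(np.sum(~call & (y == 0)))
    fp = int(np.sum(call & (y == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    ci_bootstrap_n: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC with the diseased class at LOWER ratios.

    The curve sweeps all distinct scores (plus sentinels) as '<' thresholds;
    AUC comes from the Mann-Whitney identity with ties counted half.  The
    95% CI is a percentile bootstrap over patients; pass ``ci_bootstrap_n=0``
    to skip it (CI then degenerates to the point estimate).  The Youden
    cut-off maximises sensitivity + specificity - 1, ties resolved toward
    higher specificity (the lower threshold).
    """
    s = _as_1d(scores, "scores")
    y = np.asarray(labels).astype(int).ravel()
    if s.size != y.size:
        raise DiagnosticsError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise DiagnosticsError("both classes must be present")

    uniq = np.unique(s)
    thresholds = np.concatenate(([uniq[0] - 1.0], uniq, [uniq[-1] + 1.0]))
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    for i, c in enumerate(thresholds):
        call = s < c
        sens[i] = np.sum(call & (y == 1)) / n1
        spec[i] = np.sum(~call & (y == 0)) / n0

    auc = _mann_whitney_auc(s, y)

    if ci_bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        idx_all = np.arange(s.size)
        boots = np.empty(ci_bootstrap_n)
        for b in range(ci_bootstrap_n):
            idx = rng.choice(idx_all, size=s.size, replace=True)
            yb = y[idx]
            if yb.min() == yb.max():  # single-class resample: redraw
                boots[b] = np.nan
                continue
            boots[b] = _mann_whitney_auc(s[idx], yb)
        boots = boots[np.isfinite(boots)]
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (auc, auc)

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    # among maximisers, the lowest threshold has the highest specificity
    youden = float(thresholds[best[0]])
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=float(auc), auc_ci=ci, youden_cutoff=youden,
    )


def group_comparison(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA over severity groups with Tukey-HSD pairwise p-values."""
    names = list(groups)
    arrays = [_as_1d(groups[k], k) for k in names]
    if len(arrays) < 2:
        raise DiagnosticsError("need at least 2 groups")
    for k, a in zip(names, arrays):
        if a.size < 2:
            raise DiagnosticsError(f"group {k!r} has fewer than 2 members")
    if all(np.ptp(a) == 0 for a in arrays):
        raise DiagnosticsError("all groups are constant; ANOVA undefined")

    f, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = float(tk.pvalue[i, j])
            pairwise[(names[j], names[i])] = float(tk.pvalue[i, j])
    return GroupComparison(
        f_statistic=float(f),
        p_value=float(p),
        pairwise_p=pairwise,
        group_means={k: float(a.mean()) for k, a in zip(names, arrays)},
        group_sds={k: float(a.std(ddof=1)) for k, a in zip(names, arrays)},
        group_ns={k: int(a.size) for k, a in zip(names, arrays)},
    )


_STRATIFIERS = {
    "morphology": ("bicuspid", ("tricuspid", "bicuspid")),
    "flow_state": ("low_flow", ("normal_flow", "low_flow")),
    "root_dilation": ("dilated_root", ("non_dilated", "dilated")),
}


def stratified_comparison(
    records: pd.DataFrame,
    stratifier: str,
    value_col: str = "ao_lv_ratio",
    severity_col: str = "severity",
) -> StratifiedComparison:
    """Within each severity class, compare the two strata of a binary factor.

    Reports the cell-mean table (strata rows, severity columns) and a
    pooled-variance two-sample t-test p-value per severity.  Cells with no
    members are flagged absent (NaN), not an error.
    """
    if stratifier not in _STRATIFIERS:
        raise DiagnosticsError(
            f"stratifier must be one of {sorted(_STRATIFIERS)}, got {stratifier!r}"
        )
    flag_col, (name0, name1) = _STRATIFIERS[stratifier]
    if flag_col not in records.columns:
        raise DiagnosticsError(f"records lack the {flag_col!r} column")

    severities = [s for s in ("control", "mild", "moderate", "severe")
                  if s in set(records[severity_col])]
    means = pd.DataFrame(index=[name0, name1], columns=severities, dtype=float)
    ns = pd.DataFrame(0, index=[name0, name1], columns=severities, dtype=int)
    pvals: dict[str, float] = {}
    for sev in severities:
        sub = records[records[severity_col] == sev]
        g0 = sub.loc[~sub[flag_col].astype(bool), value_col].to_numpy(float)
        g1 = sub.loc[sub[flag_col].astype(bool), value_col].to_numpy(float)
        means.loc[name0, sev] = g0.mean() if g0.size else np.nan
        means.loc[name1, sev] = g1.mean() if g1.size else np.nan
        ns.loc[name0, sev] = g0.size
        ns.loc[name1, sev] = g1.size
        if g0.size >= 2 and g1.size >= 2:
            pvals[sev] = float(stats.ttest_ind(g0, g1, equal_var=True).pvalue)
        else:
            pvals[sev] = float("nan")
    return StratifiedComparison(
        stratifier=stratifier, cell_means=means, cell_ns=ns, p_values=pvals
    )


def _icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is (subjects, raters).  Computed from the mean squares of the
    two-way layout: ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n).
    """
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((ratings - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        return 1.0  # no variance anywhere: readings agree exactly
    return float((msr - mse) / denom)


def agreement_stats(
    reader1: Sequence[float],
    reader2: Sequence[float],
    repeat1: Sequence[float] | None = None,
    repeat2: Sequence[float] | None = None,
) -> AgreementResult:
    """Inter-/intra-observer agreement for paired ratio measurements.

    ``reader1``/``reader2`` are the two readers' measurements of the same
    studies; ``repeat1``/``repeat2`` are one reader's two reads (defaulting
    to the inter-reader pair when not supplied).  ICC is ICC(2,1); limits of
    agreement are bias +/- 1.96 SD of the inter-reader differences.
    """
    r1 = _as_1d(reader1, "reader1")
    r2 = _as_1d(reader2, "reader2")
    if r1.size != r2.size:
        raise DiagnosticsError(f"length mismatch: {r1.size} vs {r2.size}")
    if r1.size < 5:
        raise DiagnosticsError("need at least 5 paired measurements")
    if repeat1 is None or repeat2 is None:
        rep1, rep2 = r1, r2
    else:
        rep1, rep2 = _as_1d(repeat1, "repeat1"), _as_1d(repeat2, "repeat2")
        if rep1.size != rep2.size:
            raise DiagnosticsError("repeat series differ in length")

    icc = _icc_2_1(np.column_stack([r1, r2]))

    def _safe_pearson(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 1.0 if np.allclose(a, b) else float("nan")
        return float(stats.pearsonr(a, b).statistic)

    diffs = r1 - r2
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        icc=float(icc),
        icc_model="ICC(2,1) two-way random, absolute agreement, single measure",
        pearson_inter=_safe_pearson(r1, r2),
        pearson_intra=_safe_pearson(rep1, rep2),
        bland_altman_bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )
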