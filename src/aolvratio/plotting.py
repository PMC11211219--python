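"""Plots for the Ao:LV analysis: severity dot plots, ROC curves, Bland-Altman."""

from __future__ import annotations

import numpy as np

from .diagnostics import AgreementResult, RocResult

SEVERITY_ORDER = ["control", "mild", "moderate", "severe"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def dotplot_by_severity(cohort, value_col: str = "ao_lv_ratio", ax=None):
    """Jittered dot plot of the ratio per severity group with group means."""
    ax = _get_ax(ax)
    rng = np.random.default_rng(0)
    for i, sev in enumerate(SEVERITY_ORDER):
        vals = cohort.loc[cohort["severity"] == sev, value_col].to_numpy(float)
        if vals.size == 0:
            continue
        x = i + rng.uniform(-0.18, 0.18, vals.size)
        ax.plot(x, vals, "o", ms=3, alpha=0.5)
        ax.hlines(vals.mean(), i - 0.3, i + 0.3, color="k", lw=2)
    ax.set_xticks(range(len(SEVERITY_ORDER)), SEVERITY_ORDER)
    ax.set_ylabel("Ao:LV ratio")
    return ax


def roc_plot(roc: RocResult, ax=None):
    ax = _get_ax(ax)
    fpr = 1.0 - roc.specificity
    order = np.argsort(fpr, kind="stable")
    ax.plot(fpr[order], roc.sensitivity[order], "-", lw=1.5)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(f"AUC = {roc.auc:.2f} (95% CI {roc.auc_ci[0]:.2f}-{roc.auc_ci[1]:.2f})")
    return ax


def bland_altman_plot(reader1, reader2, result: AgreementResult | None = None, ax=None):
    """Paired-difference plot with bias and 95% limits of agreement."""
    ax = _get_ax(ax)
    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    mean = (r1 + r2) / 2.0
    diff = r1 - r2
    if result is None:
        bias = diff.mean()
        sd = diff.std(ddof=1)
        lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    else:
        bias, lo, hi = result.bland_altman_bias, result.loa_low, result.loa_high
    ax.plot(mean, diff, "o", ms=4, alpha=0.6)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("Mean of readers")
    ax.set_ylabel("Reader difference")
    return ax
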