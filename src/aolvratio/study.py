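"""Study-level model: fit the full Ao:LV analysis battery to a cohort.

:class:`AoLVStudy` is built from a cohort DataFrame (one row per patient
with the ratio, severity label, TTE covariates and subgroup flags);
``fit()`` returns an :class:`AoLVStudyResults` carrying group summaries,
correlations, ROC blocks, fixed-cutoff operating points, stratified
subgroup tables and a ``summary()`` text report.  :func:`run_study`
replicates the whole pipeline over seeded synthetic cohorts and reports
Monte-Carlo means and standard errors of every statistic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cohort import CohortConfig, SeverityClass, generate_cohort
from .diagnostics import (
    AgreementResult,
    CorrelationResult,
    GroupComparison,
    RocResult,
    StratifiedComparison,
    agreement_stats,
    group_comparison,
    pearson_correlation,
    roc_analysis,
    sens_spec_at_cutoff,
    stratified_comparison,
)
from .measurement import CutoffScheme, measure_series
from .phantom import PhantomSpec, render_phantom

__all__ = [
    "AoLVStudy",
    "AoLVStudyResults",
    "ObserverModel",
    "RunConfig",
    "StudyReport",
    "run_study",
    "simulate_readers",
]

REPORT_SCHEMA_VERSION = "1"

#: Table-2-style correlates of the ratio available in a cohort table.
CORRELATE_COLUMNS = {
    "peak_velocity_ms": "TTE peak velocity (m/s)",
    "dimensionless_index": "Dimensionless index",
    "mean_gradient_mmhg": "Mean pressure gradient (mmHg)",
    "peak_gradient_mmhg": "Peak pressure gradient (mmHg)",
    "ava_cm2": "Aortic valve area (cm^2)",
}

SEVERITY_ORDER = ["control", "mild", "moderate", "severe"]


class AoLVStudy:
    """The Ao:LV severity analysis, bound to one cohort table.

    Parameters
    ----------
    cohort
        DataFrame with at least ``ao_lv_ratio`` and ``severity`` columns
        (severity labels control/mild/moderate/severe); TTE covariate and
        flag columns enable the correlation and subgroup blocks.
    cutoffs
        Ratio cut-offs for the fixed operating points.
    """

    def __init__(self, cohort: pd.DataFrame, cutoffs: CutoffScheme | None = None):
        if "ao_lv_ratio" not in cohort.columns or "severity" not in cohort.columns:
            raise ValueError("cohort needs 'ao_lv_ratio' and 'severity' columns")
        self.cohort = cohort.reset_index(drop=True)
        self.cutoffs = cutoffs if cutoffs is not None else CutoffScheme()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cutoffs: CutoffScheme | None = None):
        return cls(df, cutoffs)

    @classmethod
    def from_csv(cls, path, cutoffs: CutoffScheme | None = None):
        from .cohort import read_cohort_csv

        return cls(read_cohort_csv(path), cutoffs)

    # -----------------------------------------------------------------
    def fit(self, ci_bootstrap_n: int = 2000, seed: int = 0) -> "AoLVStudyResults":
        """Run the full battery; ``ci_bootstrap_n=0`` skips bootstrap CIs."""
        df = self.cohort
        ratio = df["ao_lv_ratio"].to_numpy(float)
        sev = df["severity"].astype(str)

        groups = {
            s: ratio[(sev == s).to_numpy()]
            for s in SEVERITY_ORDER
            if int((sev == s).sum()) > 0
        }
        comparison = group_comparison(groups) if len(groups) >= 2 else None

        correlations = {}
        for col in CORRELATE_COLUMNS:
            if col in df.columns and df[col].notna().all():
                correlations[col] = pearson_correlation(ratio, df[col].to_numpy(float))

        any_as = (sev != "control").astype(int).to_numpy()
        severe = (sev == "severe").astype(int).to_numpy()
        roc_any = roc_severe = None
        op_points = {}
        if 0 < any_as.sum() < len(any_as):
            roc_any = roc_analysis(ratio, any_as, ci_bootstrap_n=ci_bootstrap_n, seed=seed)
            op_points["any_as"] = sens_spec_at_cutoff(ratio, any_as, self.cutoffs.any_as_cutoff)
        if 0 < severe.sum() < len(severe):
            roc_severe = roc_analysis(
                ratio, severe, ci_bootstrap_n=ci_bootstrap_n, seed=seed + 1
            )
            op_points["severe_as"] = sens_spec_at_cutoff(
                ratio, severe, self.cutoffs.severe_cutoff
            )

        stratified = {}
        for strat, flag in (
            ("morphology", "bicuspid"),
            ("flow_state", "low_flow"),
            ("root_dilation", "dilated_root"),
        ):
            if flag in df.columns:
                stratified[strat] = stratified_comparison(df, strat)

        return AoLVStudyResults(
            model=self,
            n=len(df),
            group_comparison=comparison,
            correlations=correlations,
            roc_any=roc_any,
            roc_severe=roc_severe,
            operating_points=op_points,
            stratified=stratified,
        )


@dataclass
class AoLVStudyResults:
    """Fitted study results; ``summary()`` renders the report table."""

    model: AoLVStudy
    n: int
    group_comparison: GroupComparison | None
    correlations: dict[str, CorrelationResult]
    roc_any: RocResult | None
    roc_severe: RocResult | None
    operating_points: dict[str, tuple[float, float]]
    stratified: dict[str, StratifiedComparison]
    agreement: AgreementResult | None = None

    # --- presentation -------------------------------------------------
    def summary(self) -> str:
        cut = self.model.cutoffs
        lines = [
            "Ao:LV ratio severity analysis",
            "=" * 64,
            f"Patients: {self.n}",
            "",
            "Group ratio summary (mean +/- SD [n]):",
        ]
        if self.group_comparison is not None:
            gc = self.group_comparison
            for s in SEVERITY_ORDER:
                if s in gc.group_means:
                    lines.append(
                        f"  {s:<9} {gc.group_means[s]:.2f} +/- {gc.group_sds[s]:.2f}"
                        f"  [{gc.group_ns[s]}]"
                    )
            lines.append(
                f"  ANOVA: F = {gc.f_statistic:.2f}, p = {gc.p_value:.3g}"
            )
        if self.correlations:
            lines += ["", "Pearson correlations with Ao:LV ratio:"]
            for col, res in self.correlations.items():
                lines.append(
                    f"  {CORRELATE_COLUMNS.get(col, col):<34} r = {res.r:+.3f}"
                    f"  (p = {res.p_value:.3g}, n = {res.n})"
                )
        if self.roc_any is not None:
            s, sp = self.operating_points["any_as"]
            lines += [
                "",
                f"Any AS vs control: AUC = {self.roc_any.auc:.2f}"
                f" (95% CI {self.roc_any.auc_ci[0]:.2f}-{self.roc_any.auc_ci[1]:.2f})",
                f"  cutoff < {cut.any_as_cutoff}: sensitivity {100 * s:.0f}%,"
                f" specificity {100 * sp:.0f}%",
                f"  Youden-optimal cutoff: {self.roc_any.youden_cutoff:.2f}",
            ]
        if self.roc_severe is not None:
            s, sp = self.operating_points["severe_as"]
            lines += [
                f"Severe AS vs rest: AUC = {self.roc_severe.auc:.2f}"
                f" (95% CI {self.roc_severe.auc_ci[0]:.2f}-{self.roc_severe.auc_ci[1]:.2f})",
                f"  cutoff < {cut.severe_cutoff}: sensitivity {100 * s:.0f}%,"
                f" specificity {100 * sp:.0f}%",
            ]
        for strat, res in self.stratified.items():
            lines += ["", f"Stratified by {strat} (cell means):"]
            lines.append("  " + res.cell_means.round(2).to_string().replace("\n", "\n  "))
        if self.agreement is not None:
            a = self.agreement
            lines += [
                "",
                f"Observer agreement: ICC = {a.icc:.3f}, inter-reader r = "
                f"{a.pearson_inter:.3f}, intra-reader r = {a.pearson_intra:.3f}",
                f"  Bland-Altman bias {a.bland_altman_bias:+.3f} "
                f"(LoA {a.loa_low:+.3f} to {a.loa_high:+.3f})",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d: dict = {"n": self.n}
        if self.group_comparison is not None:
            gc = self.group_comparison
            d["groups"] = {
                s: {"mean": gc.group_means[s], "sd": gc.group_sds[s], "n": gc.group_ns[s]}
                for s in gc.group_means
            }
            d["anova"] = {
                "f": gc.f_statistic,
                "p": gc.p_value,
                "tukey_p": {f"{a}|{b}": p for (a, b), p in gc.pairwise_p.items() if a < b},
            }
        d["correlations"] = {
            c: {"r": r.r, "p": r.p_value, "n": r.n} for c, r in self.correlations.items()
        }
        for name, roc in (("roc_any_as", self.roc_any), ("roc_severe_as", self.roc_severe)):
            if roc is not None:
                d[name] = {
                    "auc": roc.auc,
                    "auc_ci": list(roc.auc_ci),
                    "youden_cutoff": roc.youden_cutoff,
                }
        d["operating_points"] = {
            k: {"sensitivity": v[0], "specificity": v[1]}
            for k, v in self.operating_points.items()
        }
        d["stratified"] = {
            k: {
                "cell_means": json.loads(v.cell_means.to_json(orient="split")),
                "p_values": v.p_values,
            }
            for k, v in self.stratified.items()
        }
        if self.agreement is not None:
            a = self.agreement
            d["agreement"] = {
                "icc": a.icc,
                "pearson_inter": a.pearson_inter,
                "pearson_intra": a.pearson_intra,
                "bias": a.bland_altman_bias,
                "loa": [a.loa_low, a.loa_high],
            }
        return d

    # --- plotting -----------------------------------------------------
    def plot_dotplot(self, ax=None):
        from .plotting import dotplot_by_severity

        return dotplot_by_severity(self.model.cohort, ax=ax)

    def plot_roc(self, which: str = "any", ax=None):
        from .plotting import roc_plot

        roc = self.roc_any if which == "any" else self.roc_severe
        if roc is None:
            raise ValueError(f"no ROC block for {which!r}")
        return roc_plot(roc, ax=ax)


# ---------------------------------------------------------------------
# Observer simulation

@dataclass(frozen=True)
class ObserverModel:
    """Measurement-noise model for dual-reader agreement simulation.

    Readers observe the true ratio plus independent zero-mean Gaussian
    error; ``inter_sd`` applies between readers, ``intra_sd`` between one
    reader's repeated reads.  Defaults are calibrated so that, with the
    default cohort's between-subject spread, paired Pearson correlations
    land near the observed inter-/intra-reader values.
    """

    inter_sd: float = 0.08
    intra_sd: float = 0.058
    subset_fraction: float = 0.15


def simulate_readers(
    cohort: pd.DataFrame,
    model: ObserverModel | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (reader1, reader2, repeat1, repeat2) on a cohort subset."""
    m = model if model is not None else ObserverModel()
    rng = np.random.default_rng(seed)
    truth = cohort["ao_lv_ratio"].to_numpy(float)
    k = max(int(round(m.subset_fraction * truth.size)), 5)
    idx = rng.choice(truth.size, size=min(k, truth.size), replace=False)
    t = truth[idx]
    reader1 = t + rng.normal(0.0, m.inter_sd, t.size)
    reader2 = t + rng.normal(0.0, m.inter_sd, t.size)
    # two reads by the same reader: shared truth, independent intra errors
    repeat1 = t + rng.normal(0.0, m.intra_sd, t.size)
    repeat2 = t + rng.normal(0.0, m.intra_sd, t.size)
    return reader1, reader2, repeat1, repeat2


# ---------------------------------------------------------------------
# Replicated study runs

@dataclass(frozen=True)
class RunConfig:
    """Configuration of a replicated desk-scale study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig.default)
    cutoffs: CutoffScheme = field(default_factory=CutoffScheme)
    replicates: int = 200
    seed: int = 0
    phantom_template: PhantomSpec | None = None
    phantom_count: int = 0
    phantom_ratio_range: tuple[float, float] = (0.3, 1.2)
    observer: ObserverModel = field(default_factory=ObserverModel)

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.phantom_count < 0:
            raise ValueError("phantom_count must be >= 0")
        self.cohort.validate()

    def digest(self) -> str:
        blob = json.dumps(
            {
                "cohort": self.cohort.to_dict(),
                "cutoffs": [self.cutoffs.any_as_cutoff, self.cutoffs.severe_cutoff],
                "replicates": self.replicates,
                "seed": self.seed,
                "phantom_count": self.phantom_count,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Aggregated report of a replicated run; JSON-serialisable."""

    schema_version: str
    provenance: dict
    group_summary: dict
    roc: dict
    operating_points: dict
    correlations: dict
    stratified: dict
    agreement: dict | None
    phantoms: list[dict]

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "provenance": self.provenance,
            "group_summary": self.group_summary,
            "roc": self.roc,
            "operating_points": self.operating_points,
            "correlations": self.correlations,
            "stratified": self.stratified,
            "agreement": self.agreement,
            "phantoms": self.phantoms,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _mc(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "mc_se": se, "replicates": int(arr.size)}


def run_study(config: RunConfig | None = None) -> StudyReport:
    """Replicate cohort generation + analysis; aggregate every statistic.

    Each replicate draws a fresh cohort from a child seed of ``config.seed``
    and refits the study (bootstrap CIs skipped inside the loop; the first
    replicate also gets a full bootstrap CI).  Aggregates are Monte-Carlo
    means with standard errors.  Deterministic for a fixed seed.
    """
    cfg = config if config is not None else RunConfig()
    cfg.validate()
    child_seeds = [int(s) for s in
                   np.random.SeedSequence(cfg.seed).generate_state(cfg.replicates + 2)
                   % (2**31)]

    auc_any, auc_severe = [], []
    sens_any, spec_any, sens_sev, spec_sev = [], [], [], []
    youden_any = []
    group_means: dict[str, list[float]] = {}
    corr_r: dict[str, list[float]] = {}
    strat_p: dict[str, dict[str, list[float]]] = {}
    first_fit: AoLVStudyResults | None = None

    for rep in range(cfg.replicates):
        cohort_cfg = replace(cfg.cohort, seed=child_seeds[rep])
        cohort = generate_cohort(cohort_cfg)
        study = AoLVStudy(cohort, cutoffs=cfg.cutoffs)
        boot = 2000 if rep == 0 else 0
        res = study.fit(ci_bootstrap_n=boot, seed=child_seeds[rep])
        if rep == 0:
            first_fit = res
        if res.roc_any is not None:
            auc_any.append(res.roc_any.auc)
            youden_any.append(res.roc_any.youden_cutoff)
            s, sp = res.operating_points["any_as"]
            sens_any.append(s)
            spec_any.append(sp)
        if res.roc_severe is not None:
            auc_severe.append(res.roc_severe.auc)
            s, sp = res.operating_points["severe_as"]
            sens_sev.append(s)
            spec_sev.append(sp)
        if res.group_comparison is not None:
            for g, m in res.group_comparison.group_means.items():
                group_means.setdefault(g, []).append(m)
        for c, r in res.correlations.items():
            corr_r.setdefault(c, []).append(r.r)
        for strat, sres in res.stratified.items():
            for sev_label, p in sres.p_values.items():
                if np.isfinite(p):
                    strat_p.setdefault(strat, {}).setdefault(sev_label, []).append(p)

    assert first_fit is not None
    agreement_block = None
    if first_fit.model.cohort.shape[0] >= 5:
        r1, r2, q1, q2 = simulate_readers(
            first_fit.model.cohort, cfg.observer, seed=child_seeds[cfg.replicates]
        )
        agr = agreement_stats(r1, r2, q1, q2)
        agreement_block = {
            "icc": agr.icc,
            "icc_model": agr.icc_model,
            "pearson_inter": agr.pearson_inter,
            "pearson_intra": agr.pearson_intra,
            "bias": agr.bland_altman_bias,
            "loa": [agr.loa_low, agr.loa_high],
            "subset_n": int(len(r1)),
        }

    phantom_blocks = []
    if cfg.phantom_count > 0:
        template = cfg.phantom_template or PhantomSpec()
        ratios = np.linspace(*cfg.phantom_ratio_range, cfg.phantom_count)
        for i, tr in enumerate(ratios):
            spec = replace(
                template, true_ratio=float(tr),
                seed=child_seeds[cfg.replicates + 1] + i,
            )
            series, landmarks, truth = render_phantom(spec)
            meas, call = measure_series(series, landmarks, cfg.cutoffs)
            phantom_blocks.append(
                {
                    "true_ratio": truth,
                    "measured_ratio": meas.ratio,
                    "frame_index": meas.frame_index,
                    "severity_call": call.value,
                }
            )

    roc_block = {
        "any_as": {
            **_mc(auc_any),
            "first_replicate_ci": list(first_fit.roc_any.auc_ci)
            if first_fit.roc_any else None,
            "youden_cutoff": _mc(youden_any) if youden_any else None,
        },
        "severe_as": {
            **_mc(auc_severe),
            "first_replicate_ci": list(first_fit.roc_severe.auc_ci)
            if first_fit.roc_severe else None,
        },
    }
    report = StudyReport(
        schema_version=REPORT_SCHEMA_VERSION,
        provenance={
            "seed": cfg.seed,
            "config_digest": cfg.digest(),
            "package_version": _pkg_version,
            "replicates": cfg.replicates,
        },
        group_summary={g: _mc(v) for g, v in group_means.items()},
        roc=roc_block,
        operating_points={
            "any_as_cutoff": cfg.cutoffs.any_as_cutoff,
            "severe_cutoff": cfg.cutoffs.severe_cutoff,
            "sensitivity_any": _mc(sens_any),
            "specificity_any": _mc(spec_any),
            "sensitivity_severe": _mc(sens_sev),
            "specificity_severe": _mc(spec_sev),
        },
        correlations={c: _mc(v) for c, v in corr_r.items()},
        stratified={
            strat: {sev_label: _mc(v) for sev_label, v in d.items()}
            for strat, d in strat_p.items()
        },
        agreement=agreement_block,
        phantoms=phantom_blocks,
    )
    return report
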