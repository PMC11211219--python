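"""Synthetic patient cohorts for the Ao:LV ratio study design.

Generates cohorts whose severity-conditional distributions of the Ao:LV
blood-signal ratio and the standard echocardiographic (TTE) severity
parameters match configured group means/SDs, so that every downstream
statistic (ROC, ANOVA, correlations, subgroup comparisons) is testable
without patient data.

Within each severity group the ratio and peak jet velocity are drawn from
truncated-normal marginals coupled through a Gaussian copula; transvalvular
gradients are derived from velocity via the simplified Bernoulli relation
(peak gradient = 4 v^2) plus residual noise so the TTE fields are mutually
consistent.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeverityClass",
    "GroupParams",
    "CohortConfig",
    "PatientRecord",
    "CohortConfigError",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "LOW_FLOW_SVI_THRESHOLD",
    "DILATED_ROOT_THRESHOLD_MM",
]

#: Stroke volume index (ml/m^2) at or below which a patient is in a low-flow state.
LOW_FLOW_SVI_THRESHOLD = 35.0
#: Aortic root diameter (mm) above which the root is called dilated.
DILATED_ROOT_THRESHOLD_MM = 40.0

COHORT_CSV_COLUMNS = [
    "id",
    "severity",
    "ao_lv_ratio",
    "peak_velocity_ms",
    "mean_gradient_mmhg",
    "peak_gradient_mmhg",
    "dimensionless_index",
    "ava_cm2",
    "svi_ml_m2",
    "bicuspid",
    "dilated_root",
    "low_flow",
    "field_strength",
]


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


class SeverityClass(enum.IntEnum):
    """Aortic-stenosis severity grade, ordered control < mild < moderate < severe.

    Grading follows TTE peak jet velocity: mild < 3.0 m/s, moderate
    3.0-4.0 m/s, severe > 4.0 m/s; controls have no stenosis.
    """

    CONTROL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "SeverityClass":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise CohortConfigError(f"unknown severity label: {label!r}") from None


@dataclass(frozen=True)
class GroupParams:
    """Distributional parameters of one severity group.

    Means and SDs parameterise (truncated) normal marginals; fractions are
    Bernoulli probabilities for the morphology / root-dilation flags.
    """

    n: int
    ratio_mean: float
    ratio_sd: float
    peak_velocity_mean: float  # m/s
    peak_velocity_sd: float
    mean_gradient_mean: float  # mmHg
    mean_gradient_sd: float
    peak_gradient_mean: float  # mmHg
    peak_gradient_sd: float
    dimensionless_index_mean: float
    dimensionless_index_sd: float
    ava_mean: float  # cm^2
    ava_sd: float
    svi_mean: float  # ml/m^2
    svi_sd: float
    bicuspid_fraction: float
    dilated_root_fraction: float

    def validate(self, name: str = "group") -> None:
        if self.n < 0:
            raise CohortConfigError(f"{name}: n must be >= 0, got {self.n}")
        for f_name in (
            "ratio_sd", "peak_velocity_sd", "mean_gradient_sd", "peak_gradient_sd",
            "dimensionless_index_sd", "ava_sd", "svi_sd",
        ):
            v = getattr(self, f_name)
            if v < 0:
                raise CohortConfigError(f"{name}.{f_name} must be >= 0, got {v}")
        for f_name in ("bicuspid_fraction", "dilated_root_fraction"):
            v = getattr(self, f_name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{name}.{f_name} must lie in [0, 1], got {v}")


# Group-conditional parameters of the 1.5 T study population: Ao:LV ratio
# distributions per severity, TTE parameters, and morphology / root-dilation
# prevalences (fractions are printed counts over group size).
DEFAULT_GROUP_PARAMS: dict[SeverityClass, GroupParams] = {
    SeverityClass.CONTROL: GroupParams(
        n=86, ratio_mean=1.01, ratio_sd=0.19,
        peak_velocity_mean=1.59, peak_velocity_sd=0.61,
        mean_gradient_mean=8.0, mean_gradient_sd=7.0,
        peak_gradient_mean=11.0, peak_gradient_sd=9.0,
        dimensionless_index_mean=0.65, dimensionless_index_sd=0.14,
        ava_mean=2.65, ava_sd=0.93,
        svi_mean=49.0, svi_sd=17.0,
        bicuspid_fraction=7 / 86, dilated_root_fraction=32 / 86,
    ),
    SeverityClass.MILD: GroupParams(
        n=66, ratio_mean=0.83, ratio_sd=0.14,
        peak_velocity_mean=2.34, peak_velocity_sd=0.63,
        mean_gradient_mean=13.0, mean_gradient_sd=7.0,
        peak_gradient_mean=24.0, peak_gradient_sd=13.0,
        dimensionless_index_mean=0.47, dimensionless_index_sd=0.12,
        ava_mean=1.66, ava_sd=0.42,
        svi_mean=46.0, svi_sd=10.0,
        bicuspid_fraction=22 / 66, dilated_root_fraction=16 / 66,
    ),
    SeverityClass.MODERATE: GroupParams(
        n=78, ratio_mean=0.67, ratio_sd=0.13,
        peak_velocity_mean=3.14, peak_velocity_sd=0.68,
        mean_gradient_mean=23.0, mean_gradient_sd=11.0,
        peak_gradient_mean=42.0, peak_gradient_sd=17.0,
        dimensionless_index_mean=0.33, dimensionless_index_sd=0.08,
        ava_mean=1.18, ava_sd=0.32,
        svi_mean=47.0, svi_sd=14.0,
        bicuspid_fraction=19 / 78, dilated_root_fraction=13 / 78,
    ),
    SeverityClass.SEVERE: GroupParams(
        n=84, ratio_mean=0.45, ratio_sd=0.12,
        peak_velocity_mean=4.08, peak_velocity_sd=0.89,
        mean_gradient_mean=42.0, mean_gradient_sd=19.0,
        peak_gradient_mean=72.0, peak_gradient_sd=30.0,
        dimensionless_index_mean=0.26, dimensionless_index_sd=0.18,
        ava_mean=0.82, ava_sd=0.23,
        svi_mean=47.0, svi_sd=10.0,
        bicuspid_fraction=14 / 84, dilated_root_fraction=14 / 84,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Free parameters of the cohort generator.

    Parameters
    ----------
    groups
        Per-severity :class:`GroupParams`.
    within_group_coupling
        Gaussian-copula correlation between Ao:LV ratio and peak velocity
        inside each severity group.  The study prints only an overall
        correlation, so this is a calibration choice (default -0.5).
    truncation_floor
        Lowest admissible ratio / velocity; marginals are normals truncated
        below at this value to forbid non-physical draws.
    morphology_ratio_means
        Optional per-severity ``(tricuspid_mean, bicuspid_mean)`` overrides
        of the ratio mean, for emulating morphology-dependent means.
    separation_shrink
        Factor by which group-mean separations from the control mean are
        shrunk under the 3 T preset (which shows weaker severity separation).
    """

    groups: Mapping[SeverityClass, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    within_group_coupling: float = -0.5
    truncation_floor: float = 0.05
    seed: int = 0
    field_strength: str = "1.5T"
    morphology_ratio_means: Mapping[SeverityClass, tuple[float, float]] | None = None
    separation_shrink: float = 0.5

    def validate(self) -> None:
        if not -1.0 <= self.within_group_coupling <= 1.0:
            raise CohortConfigError(
                f"within_group_coupling must lie in [-1, 1], got {self.within_group_coupling}"
            )
        if self.truncation_floor <= 0:
            raise CohortConfigError(
                f"truncation_floor must be > 0, got {self.truncation_floor}"
            )
        if self.field_strength not in ("1.5T", "3T"):
            raise CohortConfigError(
                f"field_strength must be '1.5T' or '3T', got {self.field_strength!r}"
            )
        for sev, gp in self.groups.items():
            gp.validate(name=SeverityClass(sev).label)

    @classmethod
    def default(cls, field_strength: str = "1.5T", seed: int = 0, **kwargs) -> "CohortConfig":
        """The study-population preset.

        The 1.5 T preset uses the printed group distributions directly.  The
        3 T preset is a stand-in with group ratio means pulled toward the
        control mean by ``separation_shrink`` (no 3 T group parameters are
        printed; only that severity separation is weaker).
        """
        cfg = cls(field_strength=field_strength, seed=seed, **kwargs)
        if field_strength == "3T":
            mu_c = cfg.groups[SeverityClass.CONTROL].ratio_mean
            shrunk = {
                sev: replace(gp, ratio_mean=mu_c - cfg.separation_shrink * (mu_c - gp.ratio_mean))
                for sev, gp in cfg.groups.items()
            }
            cfg = replace(cfg, groups=shrunk)
        return cfg

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "groups": {SeverityClass(s).label: asdict(g) for s, g in self.groups.items()},
            "within_group_coupling": self.within_group_coupling,
            "truncation_floor": self.truncation_floor,
            "seed": self.seed,
            "field_strength": self.field_strength,
            "separation_shrink": self.separation_shrink,
        }
        if self.morphology_ratio_means is not None:
            d["morphology_ratio_means"] = {
                SeverityClass(s).label: list(v) for s, v in self.morphology_ratio_means.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        groups = {
            SeverityClass.from_label(lbl): GroupParams(**gp)
            for lbl, gp in d.pop("groups", {}).items()
        } or dict(DEFAULT_GROUP_PARAMS)
        morph = d.pop("morphology_ratio_means", None)
        if morph is not None:
            morph = {
                SeverityClass.from_label(lbl): (float(v[0]), float(v[1]))
                for lbl, v in morph.items()
            }
        return cls(groups=groups, morphology_ratio_means=morph, **d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load a config from a JSON or YAML document."""
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic subject: severity label, Ao:LV ratio, TTE covariates, flags."""

    id: str
    severity: SeverityClass
    ao_lv_ratio: float
    peak_velocity: float
    mean_gradient: float
    peak_gradient: float
    dimensionless_index: float
    ava: float
    svi: float
    bicuspid: bool
    dilated_root: bool
    low_flow: bool
    field_strength: str


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, floor: float) -> np.ndarray:
    """Inverse CDF of a normal truncated below at ``floor`` (degenerate if sd=0)."""
    if sd == 0.0:
        return np.full_like(np.asarray(u, dtype=float), max(mean, floor))
    a = (floor - mean) / sd
    return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def _group_frame(
    sev: SeverityClass,
    gp: GroupParams,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = gp.n
    floor = cfg.truncation_floor
    rho = cfg.within_group_coupling

    bicuspid = rng.random(n) < gp.bicuspid_fraction
    dilated = rng.random(n) < gp.dilated_root_fraction

    # Gaussian copula: correlated standard normals -> uniforms -> truncated-
    # normal marginals for (ratio, velocity).
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    u1 = stats.norm.cdf(z1)
    u2 = stats.norm.cdf(z2)

    ratio_mean = np.full(n, gp.ratio_mean)
    if cfg.morphology_ratio_means and sev in cfg.morphology_ratio_means:
        tav_mean, bav_mean = cfg.morphology_ratio_means[sev]
        ratio_mean = np.where(bicuspid, bav_mean, tav_mean)
    if gp.ratio_sd == 0.0:
        ratio = np.maximum(ratio_mean, floor)
    else:
        a = (floor - ratio_mean) / gp.ratio_sd
        ratio = stats.truncnorm.ppf(u1, a, np.inf, loc=ratio_mean, scale=gp.ratio_sd)

    velocity = _truncnorm_ppf(u2, gp.peak_velocity_mean, gp.peak_velocity_sd, floor)

    # Bernoulli-consistent gradients: peak = 4 v^2 + residual, mean = c * peak
    # + residual, with residual SDs solved so marginal SDs match the group
    # params (delta-method variance of 4 v^2 is (8 mu_v sd_v)^2; clipped at 0).
    implied_pg_sd = 8.0 * gp.peak_velocity_mean * gp.peak_velocity_sd
    resid_pg = np.sqrt(max(gp.peak_gradient_sd**2 - implied_pg_sd**2, 0.0))
    peak_gradient = np.maximum(4.0 * velocity**2 + rng.normal(0.0, resid_pg, n), 0.0)

    c = gp.mean_gradient_mean / gp.peak_gradient_mean if gp.peak_gradient_mean > 0 else 0.0
    implied_mg_sd = abs(c) * gp.peak_gradient_sd
    resid_mg = np.sqrt(max(gp.mean_gradient_sd**2 - implied_mg_sd**2, 0.0))
    mean_gradient = np.maximum(c * peak_gradient + rng.normal(0.0, resid_mg, n), 0.0)

    di = _truncnorm_ppf(rng.random(n), gp.dimensionless_index_mean,
                        gp.dimensionless_index_sd, 0.01)
    ava = _truncnorm_ppf(rng.random(n), gp.ava_mean, gp.ava_sd, 0.05)
    svi = _truncnorm_ppf(rng.random(n), gp.svi_mean, gp.svi_sd, 1.0)

    return pd.DataFrame(
        {
            "id": [f"{sev.label}_{i + 1:03d}" for i in range(n)],
            "severity": sev.label,
            "ao_lv_ratio": ratio,
            "peak_velocity_ms": velocity,
            "mean_gradient_mmhg": mean_gradient,
            "peak_gradient_mmhg": peak_gradient,
            "dimensionless_index": di,
            "ava_cm2": ava,
            "svi_ml_m2": svi,
            "bicuspid": bicuspid,
            "dilated_root": dilated,
            "low_flow": svi <= LOW_FLOW_SVI_THRESHOLD,
            "field_strength": cfg.field_strength,
        }
    )


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort as a DataFrame, one row per patient.

    Group order and record order are fixed, and all draws come from one
    seeded generator, so a fixed seed reproduces the cohort bit for bit.
    """
    cfg = config if config is not None else CohortConfig.default()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    frames = [
        _group_frame(sev, cfg.groups[sev], cfg, rng)
        for sev in sorted(cfg.groups, key=int)
        if cfg.groups[sev].n > 0
    ]
    if not frames:
        return pd.DataFrame(columns=COHORT_CSV_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def as_records(cohort: pd.DataFrame) -> list[PatientRecord]:
    """View a cohort DataFrame as a list of :class:`PatientRecord`."""
    return [
        PatientRecord(
            id=row.id,
            severity=SeverityClass.from_label(row.severity),
            ao_lv_ratio=float(row.ao_lv_ratio),
            peak_velocity=float(row.peak_velocity_ms),
            mean_gradient=float(row.mean_gradient_mmhg),
            peak_gradient=float(row.peak_gradient_mmhg),
            dimensionless_index=float(row.dimensionless_index),
            ava=float(row.ava_cm2),
            svi=float(row.svi_ml_m2),
            bicuspid=bool(row.bicuspid),
            dilated_root=bool(row.dilated_root),
            low_flow=bool(row.low_flow),
            field_strength=row.field_strength,
        )
        for row in cohort.itertuples(index=False)
    ]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.loc[:, COHORT_CSV_COLUMNS].copy()
    for col in ("bicuspid", "dilated_root", "low_flow"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise CohortConfigError(f"cohort CSV missing columns: {sorted(missing)}")
    for col in ("bicuspid", "dilated_root", "low_flow"):
        df[col] = df[col].astype(bool)
    return df
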