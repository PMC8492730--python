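"""Per-eye pipeline orchestration, exclusion rules and cohort statistics.

The per-eye pipeline runs, in order: projection-artifact removal ->
surface segmentation -> retina substack extraction -> axial rescaling by
the pitch ratio -> global intermeans threshold -> binarization -> 3D
vascular volume -> 3D perfusion density, plus the 2D SCP/DVC en-face
densities computed on the artifact-removed volume.  The order matters and
is part of the contract (thresholding before rescaling gives different
voxel counts).

Cohort reporting mirrors the clinical analysis: scans with signal strength
index below 7 are excluded, group comparisons use the independent-samples
(pooled-variance) Student's t-test, normality is screened with
Shapiro-Wilk, and metric-covariate associations in the diabetic group use
Pearson correlation.  p-values are reported raw (no multiple-testing
correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import quantify2d, quantify3d
from .errors import PipelineStageError, ReportError
from .projection import remove_projection_artifacts
from .quantify3d import EyeMetrics
from .segmentation import (
    extract_retina_substack,
    neuroretinal_volume,
    segment_surfaces,
)
from .synthetic import EyeRecord, SimulatedEye
from .volume import OCTAVolume

__all__ = [
    "PipelineConfig",
    "CohortTable",
    "run_pipeline",
    "run_cohort",
    "filter_by_ssi",
    "shapiro_wilk",
    "two_sample_ttest",
    "pearson_corr",
    "build_table1",
    "build_table2",
]

METRIC_FIELDS = (
    "vascular_volume_mm3",
    "perfusion_density_3d_pct",
    "scp_density_2d_pct",
    "dvc_density_2d_pct",
    "mean_thickness_um",
    "macular_volume_mm3",
)
METRIC_LABELS = {
    "vascular_volume_mm3": "Vascular volume (mm3)",
    "perfusion_density_3d_pct": "3D perfusion density (%)",
    "scp_density_2d_pct": "SCP perfusion density (%)",
    "dvc_density_2d_pct": "DVC perfusion density (%)",
    "mean_thickness_um": "Average macular thickness (um)",
    "macular_volume_mm3": "Average macular volume (mm3)",
}
# decimals for mean/SD per metric; p-values get 3
DEFAULT_ROUNDING = {
    "vascular_volume_mm3": 2,
    "perfusion_density_3d_pct": 1,
    "scp_density_2d_pct": 1,
    "dvc_density_2d_pct": 1,
    "mean_thickness_um": 1,
    "macular_volume_mm3": 2,
    "p": 3,
}
OCTA_METRICS = METRIC_FIELDS[:4]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the per-eye pipeline (defaults are the study recipe)."""

    projection_mode: str = "axial_peak"
    projection_alpha: float = 0.3
    noise_floor: str | int = "auto"
    min_run: int = 3
    smoothness_cap_px: int = 20
    margin_px: int = 5
    interpolation: str = "linear"
    histogram_excludes_masked: bool = True
    enface_method: str = "otsu"
    enface_operator: str = "max"
    scp_depth_um: float = quantify2d.DEFAULT_SCP_DEPTH_UM
    dvc_depth_um: float = quantify2d.DEFAULT_DVC_DEPTH_UM


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage tag."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(
    structural: OCTAVolume,
    octa: OCTAVolume,
    config: Optional[PipelineConfig] = None,
) -> EyeMetrics:
    """Run the full 3D + 2D quantification on one eye.

    Deterministic: the same inputs always produce the same metrics.
    Stage failures propagate as :class:`PipelineStageError` with the stage
    name in the message.
    """
    cfg = config or PipelineConfig()

    with _stage("inputs"):
        if structural is None or octa is None:
            raise ValueError("both structural and OCTA volumes are required")
        if structural.shape != octa.shape:
            raise ValueError(
                f"volumes do not share geometry: {structural.shape} vs {octa.shape}"
            )

    with _stage("projection_removal"):
        cleaned = remove_projection_artifacts(
            octa,
            mode=cfg.projection_mode,
            alpha=cfg.projection_alpha,
            noise_floor=cfg.noise_floor,
            min_run=cfg.min_run,
        )

    with _stage("segment_surfaces"):
        surfaces = segment_surfaces(
            structural, smoothness_cap_px=cfg.smoothness_cap_px
        )
        mean_thickness_um, macular_volume_mm3 = neuroretinal_volume(surfaces)

    with _stage("extract_retina_substack"):
        substack = extract_retina_substack(cleaned, surfaces, cfg.margin_px)

    with _stage("rescale_z"):
        factor = quantify3d.z_scale_factor(octa.geometry)
        rescaled = quantify3d.rescale_z(substack, factor, cfg.interpolation)

    with _stage("threshold"):
        threshold = quantify3d.default_global_threshold(
            rescaled, exclude_masked=cfg.histogram_excludes_masked
        )
        mask = quantify3d.binarize(rescaled, threshold)

    with _stage("quantify3d"):
        vascular_mm3 = quantify3d.vascular_volume_3d(mask)
        density_3d = quantify3d.perfusion_density_3d(
            vascular_mm3, macular_volume_mm3
        )

    with _stage("quantify2d"):
        densities = {}
        for plexus in ("scp", "dvc"):
            bounds = quantify2d.slab_bounds(
                surfaces,
                plexus,
                scp_depth_um=cfg.scp_depth_um,
                dvc_depth_um=cfg.dvc_depth_um,
            )
            enface = quantify2d.enface_project(
                cleaned, bounds, operator=cfg.enface_operator
            )
            binary = quantify2d.binarize_enface(enface, method=cfg.enface_method)
            densities[plexus] = quantify2d.perfusion_density_2d(binary)

    return EyeMetrics(
        vascular_volume_mm3=vascular_mm3,
        perfusion_density_3d_pct=density_3d,
        scp_density_2d_pct=densities["scp"],
        dvc_density_2d_pct=densities["dvc"],
        mean_thickness_um=mean_thickness_um,
        macular_volume_mm3=macular_volume_mm3,
    )


# --------------------------------------------------------------------------
# exclusion and elementary statistics

def filter_by_ssi(
    records: Iterable[EyeRecord], min_ssi: float = 7.0
) -> list[EyeRecord]:
    """Apply the scan-quality exclusion: keep records with SSI >= min_ssi."""
    return [r for r in records if r.ssi >= min_ssi]


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic and p-value)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant data")
    res = scipy.stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], equal_variance: bool = True
) -> tuple[float, float, float]:
    """Independent two-sample t-test: returns (t, df, two-sided p).

    Pooled-variance Student's t by default (df = n_a + n_b - 2); Welch's
    correction with ``equal_variance=False``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        raise ValueError("zero pooled variance: t-test undefined")
    res = scipy.stats.ttest_ind(a, b, equal_var=equal_variance)
    df = float(a.size + b.size - 2) if equal_variance else float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def pearson_corr(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# cohort table and reports

@dataclass
class CohortTable:
    """Eye records with completed metrics, ready for reporting.

    Invariants: one record per subject, no record with SSI < 7, and every
    record carries metrics.
    """

    records: list[EyeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ReportError("duplicate subject ids in cohort")
        for r in self.records:
            if r.ssi < 7.0:
                raise ReportError(
                    f"record {r.subject_id} has SSI {r.ssi} < 7; apply "
                    "filter_by_ssi before building a cohort table"
                )
            if r.metrics is None:
                raise ReportError(f"record {r.subject_id} has no metrics")

    def group(self, name: str) -> list[EyeRecord]:
        return [r for r in self.records if r.group == name]

    def metric_values(self, metric: str, group: Optional[str] = None) -> np.ndarray:
        recs = self.records if group is None else self.group(group)
        return np.array([getattr(r.metrics, metric) for r in recs], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "hba1c": r.hba1c,
                "duration": r.diabetes_duration,
                "ssi": r.ssi,
                "laterality": r.laterality,
            }
            row.update({m: getattr(r.metrics, m) for m in METRIC_FIELDS})
            rows.append(row)
        return pd.DataFrame(rows)


def run_cohort(
    eyes: Iterable[SimulatedEye],
    pipeline_config: Optional[PipelineConfig] = None,
    min_ssi: float = 7.0,
) -> CohortTable:
    """Quantify every eye, apply the SSI exclusion and assemble the cohort."""
    records = []
    for eye in eyes:
        eye.record.metrics = run_pipeline(
            eye.structural, eye.octa, pipeline_config
        )
        records.append(eye.record)
    return CohortTable(filter_by_ssi(records, min_ssi))


def build_table1(
    cohort: CohortTable,
    rounding: Optional[dict] = None,
    formatted: bool = False,
) -> pd.DataFrame:
    """Group comparison table: mean +/- SD per group and Student's t p-value.

    Six rows (3D vascular volume, 3D perfusion density, SCP and DVC 2D
    densities, macular thickness, macular volume).  ``formatted=True``
    returns printed-precision strings; otherwise numeric columns.
    """
    rounding = {**DEFAULT_ROUNDING, **(rounding or {})}
    diabetic = cohort.group("diabetic")
    control = cohort.group("control")
    if not diabetic or not control:
        raise ReportError("both diabetic and control groups must be non-empty")

    def _shapiro_p(values):
        # screening only; never gates the t-test
        try:
            return shapiro_wilk(values)[1]
        except ValueError:
            return float("nan")

    rows = []
    for metric in METRIC_FIELDS:
        a = cohort.metric_values(metric, "diabetic")
        b = cohort.metric_values(metric, "control")
        t, df, p = two_sample_ttest(a, b)
        rows.append(
            {
                "metric": METRIC_LABELS[metric],
                "diabetic_mean": a.mean(),
                "diabetic_sd": a.std(ddof=1),
                "control_mean": b.mean(),
                "control_sd": b.std(ddof=1),
                "t": t,
                "df": df,
                "p": p,
                "shapiro_p_diabetic": _shapiro_p(a),
                "shapiro_p_control": _shapiro_p(b),
            }
        )
    table = pd.DataFrame(rows).set_index("metric")
    if not formatted:
        return table

    def fmt(mean, sd, nd):
        return f"{mean:.{nd}f} ± {sd:.{nd}f}"

    decimals = [rounding[m] for m in METRIC_FIELDS]
    out = pd.DataFrame(
        {
            "diabetic": [
                fmt(r["diabetic_mean"], r["diabetic_sd"], nd)
                for (_, r), nd in zip(table.iterrows(), decimals)
            ],
            "control": [
                fmt(r["control_mean"], r["control_sd"], nd)
                for (_, r), nd in zip(table.iterrows(), decimals)
            ],
            "p": [f"{p:.{rounding['p']}f}" for p in table["p"]],
        },
        index=table.index,
    )
    out.attrs["footer"] = (
        "Data are mean ± SD; independent-samples Student's t-test; "
        "p-values unadjusted."
    )
    return out


def build_table2(
    cohort: CohortTable,
    covariates: Sequence[str] = ("hba1c", "duration"),
) -> pd.DataFrame:
    """Pearson correlations of OCTA metrics with clinical covariates.

    Diabetic records only; one row per (covariate, metric) pair with the
    correlation coefficient and its two-sided p-value (4 metrics x the
    covariates requested = 8 cells by default).
    """
    diabetic = cohort.group("diabetic")
    if not diabetic:
        raise ReportError("table 2 requires a non-empty diabetic group")
    attr = {"hba1c": "hba1c", "duration": "diabetes_duration"}
    rows = []
    for cov in covariates:
        if cov not in attr:
            raise ReportError(f"unknown covariate '{cov}'")
        values = [getattr(r, attr[cov]) for r in diabetic]
        if any(v is None for v in values):
            raise ReportError(f"covariate '{cov}' missing for some records")
        values = np.asarray(values, dtype=float)
        for metric in OCTA_METRICS:
            r_, p_ = pearson_corr(
                cohort.metric_values(metric, "diabetic"), values
            )
            rows.append(
                {
                    "covariate": cov,
                    "metric": METRIC_LABELS[metric],
                    "r": r_,
                    "p": p_,
                }
            )
    return pd.DataFrame(rows).set_index(["covariate", "metric"])
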