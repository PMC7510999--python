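"""Cohort-level feature tables, Spearman redundancy and robustness reports.

Three feature sets are extracted per lesion — static (90), parametric (90,
same definitions on the metabolic-rate image) and dynamic (38, temporal) —
and compared with Spearman's rank correlation:

* a *parametric* feature is redundant when its same-name static counterpart
  correlates with signed rho > 0.7 (only corresponding pairs are compared:
  the mathematical definitions coincide);
* a *dynamic* feature is redundant when it correlates with |rho| > 0.7 with
  *any* static feature — redundant features carry no information beyond the
  spatial set;
* a dynamic feature is *robust* to frame duration when its 150 s- and
  300 s-frame versions correlate with rho > 0.7 across the cohort.

Strength labels: |rho| < 0.3 negligible, 0.3-0.5 low, 0.5-0.7 moderate,
> 0.7 high.  Undefined rho (a constant feature column) is excluded from
max-|rho| reductions with a warning rather than treated as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import discretise, patlak, phantom, static_radiomics, temporal_radiomics
from .grid_io import extract_voi_values

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_rho",
    "strength_label",
    "cross_correlation_matrix",
    "CorrelationReport",
    "classify_dynamic_redundancy",
    "classify_parametric_redundancy",
    "frame_duration_robustness",
    "CohortResult",
    "run_cohort",
]

REDUNDANCY_THRESHOLD = 0.7


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, average-rank ties).

    Returns NaN, with a log entry, when either vector has zero rank
    variance (a constant column has no defined rank correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("undefined Spearman rho: zero rank variance")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def strength_label(abs_rho: float) -> str:
    if np.isnan(abs_rho):
        return "undefined"
    if abs_rho < 0.3:
        return "negligible"
    if abs_rho < 0.5:
        return "low"
    if abs_rho <= 0.7:
        return "moderate"
    return "high"


@dataclass
class CorrelationReport:
    """Spearman correlations of one feature table against another.

    ``matrix`` has the first table's features as rows; ``max_abs_rho`` is the
    per-row maximum |rho| over defined entries.
    """

    matrix: pd.DataFrame
    max_abs_rho: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            self.max_abs_rho = self.matrix.abs().max(axis=1, skipna=True)


def _flat_columns(table: pd.DataFrame) -> pd.DataFrame:
    if isinstance(table.columns, pd.MultiIndex):
        out = table.copy()
        out.columns = [f"{fam}/{name}" for fam, name in table.columns]
        return out
    return table


def cross_correlation_matrix(a: pd.DataFrame, b: pd.DataFrame) -> CorrelationReport:
    """All-pairs Spearman rho between the columns of two lesion tables."""
    if not a.index.equals(b.index):
        raise ValueError("feature tables must list the same lesions in the same order")
    af, bf = _flat_columns(a), _flat_columns(b)
    mat = pd.DataFrame(index=af.columns, columns=bf.columns, dtype=float)
    for ca in af.columns:
        for cb in bf.columns:
            try:
                mat.loc[ca, cb] = spearman_rho(af[ca].to_numpy(), bf[cb].to_numpy())
            except ValueError:
                mat.loc[ca, cb] = np.nan
    return CorrelationReport(mat)


def classify_dynamic_redundancy(report: CorrelationReport,
                                threshold: float = REDUNDANCY_THRESHOLD) -> pd.DataFrame:
    """Label each dynamic feature redundant iff max |rho| vs any static
    feature exceeds the threshold."""
    max_rho = report.max_abs_rho
    return pd.DataFrame({
        "max_abs_rho": max_rho,
        "redundant": max_rho > threshold,
        "strength": [strength_label(r) for r in max_rho],
    })


def classify_parametric_redundancy(static: pd.DataFrame, parametric: pd.DataFrame,
                                   threshold: float = REDUNDANCY_THRESHOLD) -> pd.DataFrame:
    """Corresponding-pair (same feature name) redundancy, signed rho rule."""
    sf, pf = _flat_columns(static), _flat_columns(parametric)
    if set(sf.columns) != set(pf.columns):
        raise ValueError("static and parametric tables must share one feature name set")
    rows = {}
    for col in sf.columns:
        try:
            rho = spearman_rho(sf[col].to_numpy(), pf[col].to_numpy())
        except ValueError:
            rho = np.nan
        rows[col] = {"rho": rho, "redundant": bool(rho > threshold) if not np.isnan(rho) else False,
                     "strength": strength_label(abs(rho))}
    return pd.DataFrame.from_dict(rows, orient="index")


def frame_duration_robustness(f150: pd.DataFrame, f300: pd.DataFrame,
                              threshold: float = REDUNDANCY_THRESHOLD) -> pd.DataFrame:
    """Per-feature rho between frame durations; robust iff rho > threshold."""
    a, b = _flat_columns(f150), _flat_columns(f300)
    if list(a.columns) != list(b.columns):
        raise ValueError("both tables must list the same dynamic features")
    if not a.index.equals(b.index):
        raise ValueError("both tables must list the same lesions")
    rows = {}
    for col in a.columns:
        try:
            rho = spearman_rho(a[col].to_numpy(), b[col].to_numpy())
        except ValueError:
            rho = np.nan
        rows[col] = {"rho": rho,
                     "robust": bool(rho > threshold) if not np.isnan(rho) else False}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# end-to-end cohort pipeline
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Feature tables, bin widths and reports of one cohort run."""

    static_table: pd.DataFrame
    parametric_table: pd.DataFrame
    dyn150_table: pd.DataFrame
    dyn300_table: pd.DataFrame
    widths: discretise.WidthConfig
    robustness: pd.DataFrame
    dynamic_redundancy: pd.DataFrame
    parametric_redundancy: pd.DataFrame

    @property
    def combined_feature_count(self) -> int:
        return (self.static_table.shape[1] + self.parametric_table.shape[1]
                + self.dyn150_table.shape[1])


def run_cohort(n_lesions: int = 20, seed: int = 0, noise_sd: float = 0.02,
               lesions: list[phantom.PhantomLesion] | None = None) -> CohortResult:
    """Full analysis of a (synthetic) lesion cohort.

    Generates the cohort (unless one is supplied), derives population-based
    bin widths, extracts all four feature tables and produces the three
    correlation reports.  Deterministic for a fixed ``(n_lesions, seed,
    noise_sd)``.
    """
    if lesions is None:
        lesions = phantom.generate_cohort(n_lesions, seed, noise_sd=noise_sd)

    # parametric images first (their VOI values feed the population width)
    mrglc_images = []
    for les in lesions:
        settings = patlak.ParametricSettings(
            plasma_glucose=les.phantom.truth.plasma_glucose,
            lumped_constant=les.phantom.truth.lumped_constant,
        )
        mrglc, _ = patlak.compute_parametric_image(
            les.phantom.series, les.phantom.plasma, settings)
        mrglc_images.append(mrglc)

    def voi_values(image, les):
        return extract_voi_values(image, les.mask)[0]

    static_vals = [voi_values(les.static_image, les) for les in lesions]
    param_vals = [np.clip(voi_values(img, les), 0.0, None)
                  for img, les in zip(mrglc_images, lesions)]

    widths = discretise.WidthConfig(
        static=discretise.population_width(static_vals),
        parametric=discretise.population_width(param_vals),
        frames=[],
    )
    n150 = lesions[0].phantom.series.n_frames
    widths150 = [
        discretise.population_width(
            [les.phantom.series.data[..., t][les.mask.mask] for les in lesions])
        for t in range(n150)
    ]
    n300 = lesions[0].series_300.n_frames
    widths300 = [
        discretise.population_width(
            [les.series_300.data[..., t][les.mask.mask] for les in lesions])
        for t in range(n300)
    ]
    widths.frames = widths150

    static_rows, param_rows, d150_rows, d300_rows = {}, {}, {}, {}
    for les, mrglc in zip(lesions, mrglc_images):
        sid = les.lesion_id
        static_rows[sid] = static_radiomics.extract_static_feature_set(
            les.static_image, les.mask,
            discretise.DiscretisationScheme(widths.static))
        param_rows[sid] = static_radiomics.extract_static_feature_set(
            mrglc, les.mask, discretise.DiscretisationScheme(widths.parametric))
        d150_rows[sid] = temporal_radiomics.extract_dynamic_feature_set(
            les.phantom.series, les.mask, widths150)
        d300_rows[sid] = temporal_radiomics.extract_dynamic_feature_set(
            les.series_300, les.mask, widths300)

    static_table = pd.DataFrame.from_dict(static_rows, orient="index")
    param_table = pd.DataFrame.from_dict(param_rows, orient="index")
    d150_table = pd.DataFrame.from_dict(d150_rows, orient="index")
    d300_table = pd.DataFrame.from_dict(d300_rows, orient="index")

    robustness = frame_duration_robustness(d150_table, d300_table)
    dyn_report = cross_correlation_matrix(d150_table, static_table)
    dynamic_redundancy = classify_dynamic_redundancy(dyn_report)
    parametric_redundancy = classify_parametric_redundancy(static_table, param_table)

    return CohortResult(static_table, param_table, d150_table, d300_table,
                        widths, robustness, dynamic_redundancy,
                        parametric_redundancy)
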