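"""Longitudinal analyses: reference stability, per-endoscope trends, and
before/after-repair comparisons.

Drift and trend tests are ordinary-least-squares slopes against time in
days since the first record, with a two-sided t-test on the slope at level
0.05. The 5% change rule is delegated to :func:`endoqc.qa.significant_change`
so there is a single source of truth for significance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError
from .qa import QAConfig, decide_rejection, significant_change
from .registry import Context, MeasurementRecord, Metric

__all__ = [
    "StabilityReport",
    "TrendReport",
    "RepairClassification",
    "RepairEffect",
    "stability_report",
    "trend",
    "repair_effect",
]

MIN_RECORDS = 3
DEFAULT_BANDS = (2.0, 3.0)
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class StabilityReport:
    metric: Metric
    mean: float
    #: band percent -> fraction of points with |x - mean| / mean <= band/100
    fraction_within: dict[float, float]
    drift_slope: float  # units per day
    drift_slope_se: float
    drift_pvalue: float
    drift_significant: bool
    n: int

    def to_json_dict(self) -> dict:
        return {
            "metric": self.metric.value,
            "mean": self.mean,
            "fraction_within": {str(k): v for k, v in self.fraction_within.items()},
            "drift_slope": self.drift_slope,
            "drift_slope_se": self.drift_slope_se,
            "drift_pvalue": self.drift_pvalue,
            "drift_significant": self.drift_significant,
            "n": self.n,
        }


@dataclass(frozen=True)
class TrendReport:
    serial: str
    metric: Metric
    slope: float  # units per day
    slope_se: float
    pvalue: float
    slope_significant: bool
    endpoint_change_percent: float
    endpoint_change_significant: bool
    crossed_rejection: bool
    crossed_date: str | None  # ISO timestamp of the first rejected record
    n: int

    def to_json_dict(self) -> dict:
        return {
            "serial": self.serial,
            "metric": self.metric.value,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "pvalue": self.pvalue,
            "slope_significant": self.slope_significant,
            "endpoint_change_percent": self.endpoint_change_percent,
            "endpoint_change_significant": self.endpoint_change_significant,
            "crossed_rejection": self.crossed_rejection,
            "crossed_date": self.crossed_date,
            "n": self.n,
        }


class RepairClassification(str, enum.Enum):
    IMPROVED = "IMPROVED"
    UNCHANGED = "UNCHANGED"
    WORSENED = "WORSENED"


@dataclass(frozen=True)
class RepairEffect:
    serial: str
    metric: Metric
    before: float
    after: float
    change_percent: float
    classification: RepairClassification

    def to_json_dict(self) -> dict:
        return {
            "serial": self.serial,
            "metric": self.metric.value,
            "before": self.before,
            "after": self.after,
            "change_percent": self.change_percent,
            "classification": self.classification.value,
        }


def _series(
    records: list[MeasurementRecord], metric: Metric
) -> tuple[np.ndarray, np.ndarray, list[MeasurementRecord]]:
    if len(records) < MIN_RECORDS:
        raise InsufficientDataError(
            f"need at least {MIN_RECORDS} records, got {len(records)}"
        )
    ordered = sorted(records, key=lambda r: r.timestamp)
    t0 = ordered[0].timestamp
    days = np.array([(r.timestamp - t0).total_seconds() / 86400.0 for r in ordered])
    values = np.array([r.value(metric) for r in ordered])
    return days, values, ordered


def _ols_slope(days: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """(slope, slope standard error, two-sided p-value)."""
    if np.ptp(values) == 0:  # degenerate: linregress p-value undefined
        return 0.0, 0.0, 1.0
    fit = stats.linregress(days, values)
    return float(fit.slope), float(fit.stderr), float(fit.pvalue)


def stability_report(
    reference_records: list[MeasurementRecord],
    metric: Metric,
    bands: tuple[float, ...] = DEFAULT_BANDS,
    alpha: float = DEFAULT_ALPHA,
) -> StabilityReport:
    """Summarize a reference-endoscope series: mean, fraction of points
    within each relative band of the mean, and an OLS drift test."""
    days, values, _ = _series(reference_records, metric)
    mean = float(values.mean())
    fraction_within: dict[float, float] = {}
    for band in sorted(bands):
        within = np.abs(values - mean) / mean <= band / 100.0
        fraction_within[float(band)] = float(within.mean())
    slope, se, pvalue = _ols_slope(days, values)
    return StabilityReport(
        metric=metric,
        mean=mean,
        fraction_within=fraction_within,
        drift_slope=slope,
        drift_slope_se=se,
        drift_pvalue=pvalue,
        drift_significant=bool(pvalue < alpha),
        n=len(values),
    )


def trend(
    records: list[MeasurementRecord],
    metric: Metric,
    bests: dict[Metric, float],
    config: QAConfig = QAConfig(),
    alpha: float = DEFAULT_ALPHA,
) -> TrendReport:
    """Per-endoscope trend: OLS slope, endpoint change significance, and
    whether (and when) the series first crossed the rejection level.

    Crossing is evaluated by applying the clinical rejection rule pointwise
    against *bests*; records are coerced to CLINICAL context for that check.
    """
    days, values, ordered = _series(records, metric)
    serials = {r.serial for r in ordered}
    if len(serials) != 1:
        raise InvalidArgumentError(f"records span multiple serials: {sorted(serials)}")
    slope, se, pvalue = _ols_slope(days, values)
    endpoint_significant, endpoint_change = significant_change(
        float(values[0]), float(values[-1]), config
    )
    crossed = False
    crossed_date: str | None = None
    rule = f"{metric.value.lower()}-below-rejection"
    for rec in ordered:
        decision = decide_rejection(
            replace(rec, context=Context.CLINICAL), bests, config
        )
        if rule in decision.triggered_rules:
            crossed = True
            crossed_date = rec.timestamp.isoformat()
            break
    return TrendReport(
        serial=ordered[0].serial,
        metric=metric,
        slope=slope,
        slope_se=se,
        pvalue=pvalue,
        slope_significant=bool(pvalue < alpha),
        endpoint_change_percent=endpoint_change,
        endpoint_change_significant=endpoint_significant,
        crossed_rejection=crossed,
        crossed_date=crossed_date,
        n=len(values),
    )


def repair_effect(
    before: MeasurementRecord,
    after: MeasurementRecord,
    config: QAConfig = QAConfig(),
) -> dict[Metric, RepairEffect]:
    """Classify the effect of one repair per metric with the >5% rule."""
    if before.serial != after.serial:
        raise InvalidArgumentError(
            f"serial mismatch: {before.serial!r} vs {after.serial!r}"
        )
    if before.context is not Context.BEFORE_REPAIR:
        raise InvalidArgumentError(
            f"before record must have BEFORE_REPAIR context, got {before.context}"
        )
    if after.context is not Context.AFTER_REPAIR:
        raise InvalidArgumentError(
            f"after record must have AFTER_REPAIR context, got {after.context}"
        )
    effects: dict[Metric, RepairEffect] = {}
    for metric in Metric:
        b, a = before.value(metric), after.value(metric)
        significant, change = significant_change(b, a, config)
        if significant and change > 0:
            cls = RepairClassification.IMPROVED
        elif significant:
            cls = RepairClassification.WORSENED
        else:
            cls = RepairClassification.UNCHANGED
        effects[metric] = RepairEffect(
            serial=before.serial,
            metric=metric,
            before=b,
            after=a,
            change_percent=change,
            classification=cls,
        )
    return effects
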