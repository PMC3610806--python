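"""Database-relative accept/reject decision logic.

New and repaired endoscopes are accepted when each metric reaches at least
40% of the best stored value for the same type (boundary inclusive).
Clinically used endoscopes are rejected when either metric falls strictly
below 20% of best-of-type. Changes larger than 5% relative to the previous
value are considered significant; 5% exactly is not.

Comparisons are made on value/best fractions (not pre-scaled percentages)
so the configured boundaries are exact in floating point. Both metrics must
pass independently: acceptance is an AND over metrics, rejection an OR.
Moisture is reported on the decision but never forces a rejection on its
own.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .errors import InvalidArgumentError, NoBaselineError
from .registry import Context, MeasurementRecord, Metric

__all__ = [
    "QAConfig",
    "Verdict",
    "Decision",
    "relative_performance",
    "decide_acceptance",
    "decide_rejection",
    "significant_change",
]

ACCEPTANCE_CONTEXTS = frozenset({Context.NEW, Context.AFTER_REPAIR})


@dataclass(frozen=True)
class QAConfig:
    """Decision thresholds, as fractions of best-of-type / previous value."""

    acceptance_fraction: float = 0.40
    rejection_fraction: float = 0.20
    significance_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.rejection_fraction < self.acceptance_fraction <= 1:
            raise InvalidArgumentError(
                "require 0 < rejection_fraction < acceptance_fraction <= 1, got "
                f"{self.rejection_fraction}, {self.acceptance_fraction}"
            )
        if self.significance_fraction <= 0:
            raise InvalidArgumentError("significance_fraction must be > 0")


class Verdict(str, enum.Enum):
    ACCEPT = "ACCEPT"
    REJECT = "REJECT"
    PASS = "PASS"


@dataclass(frozen=True)
class Decision:
    verdict: Verdict
    per_metric_relative: dict[Metric, float]
    triggered_rules: tuple[str, ...] = ()
    moisture_flagged: bool = False

    def to_json_dict(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "per_metric_relative": {
                m.value: v for m, v in sorted(self.per_metric_relative.items())
            },
            "triggered_rules": list(self.triggered_rules),
            "moisture_flagged": self.moisture_flagged,
        }


def relative_performance(value: float, best: float) -> float:
    """Percent of the best same-type value; 100% means equal to the best."""
    if best <= 0:
        raise NoBaselineError(f"best-of-type must be > 0, got {best}")
    return 100.0 * value / best


def _relatives(
    record: MeasurementRecord, bests: Mapping[Metric, float]
) -> dict[Metric, float]:
    missing = [m for m in Metric if m not in bests]
    if missing:
        raise NoBaselineError(f"missing best-of-type for {missing}")
    return {m: relative_performance(record.value(m), bests[m]) for m in Metric}


def decide_acceptance(
    record: MeasurementRecord,
    bests: Mapping[Metric, float],
    config: QAConfig = QAConfig(),
) -> Decision:
    """Accept a NEW or AFTER_REPAIR endoscope iff every metric is at least
    the acceptance fraction of best-of-type (inclusive boundary)."""
    if record.context not in ACCEPTANCE_CONTEXTS:
        raise InvalidArgumentError(
            f"acceptance applies to NEW/AFTER_REPAIR records, got {record.context}"
        )
    rel = _relatives(record, bests)
    failing = [
        m
        for m in Metric
        if record.value(m) / bests[m] < config.acceptance_fraction
    ]
    rules = tuple(f"{m.value.lower()}-below-acceptance" for m in failing)
    verdict = Verdict.REJECT if failing else Verdict.ACCEPT
    return Decision(
        verdict=verdict,
        per_metric_relative=rel,
        triggered_rules=rules,
        moisture_flagged=record.moisture,
    )


def decide_rejection(
    record: MeasurementRecord,
    bests: Mapping[Metric, float],
    config: QAConfig = QAConfig(),
) -> Decision:
    """Reject a CLINICAL endoscope iff any metric falls strictly below the
    rejection fraction of best-of-type; moisture is flagged, not rejecting."""
    if record.context is not Context.CLINICAL:
        raise InvalidArgumentError(
            f"rejection applies to CLINICAL records, got {record.context}"
        )
    rel = _relatives(record, bests)
    failing = [
        m
        for m in Metric
        if record.value(m) / bests[m] < config.rejection_fraction
    ]
    rules = tuple(f"{m.value.lower()}-below-rejection" for m in failing)
    verdict = Verdict.REJECT if failing else Verdict.PASS
    return Decision(
        verdict=verdict,
        per_metric_relative=rel,
        triggered_rules=rules,
        moisture_flagged=record.moisture,
    )


def significant_change(
    previous: float,
    current: float,
    config: QAConfig = QAConfig(),
) -> tuple[bool, float]:
    """(is-significant, signed relative change in percent of *previous*).

    Significant iff the absolute relative change strictly exceeds the
    significance fraction.
    """
    if previous <= 0:
        raise InvalidArgumentError(f"previous value must be > 0, got {previous}")
    change = (current - previous) / previous
    return abs(change) > config.significance_fraction, 100.0 * change
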