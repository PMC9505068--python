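"""Bioanalytical method-validation statistics and acceptance rules.

Covers the regulatory validation workflow for a chromatographic assay:
weighted least-squares calibration (weights 1, 1/x or 1/x^2 on the
concentration), back-calculation of concentrations from responses,
quality-control accuracy / precision summaries, and the standard
acceptance rules:

* accuracy / precision: accuracy within 80–120% and RSD < 20% at the
  LLOQ; within 85–115% and RSD < 15% at the other levels (RSD bound
  strict, accuracy bounds inclusive);
* matrix effect: spike ratio within 85–115%;
* stability: accuracy within 85–115% and RSD <= 15% (inclusive).

Accuracy is 100 * mean(measured) / nominal; RSD is 100 * SD / mean with
the sample (n - 1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CalibrationCurve",
    "QCBatch",
    "ValidationMetrics",
    "fit_calibration",
    "back_calculate",
    "qc_summary",
    "fda_acceptance",
    "signal_ratio_metric",
    "WEIGHTINGS",
]

WEIGHTINGS = ("none", "1/x", "1/x2")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response model: response = slope * concentration + intercept."""

    matrix_label: str
    slope: float
    intercept: float
    r2: float
    weighting: str
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be below range_high")

    def respond(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class QCBatch:
    """Replicate measurements of one nominal QC concentration across days."""

    matrix_label: str
    nominal: float
    replicates: tuple[tuple[int, float], ...]  # (day index, measured)

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(self.replicates))
        if self.nominal <= 0:
            raise ValueError("nominal concentration must be positive")
        if len(self.replicates) < 2:
            raise ValueError("at least 2 replicates are required")

    def days(self) -> list[int]:
        return sorted({d for d, _ in self.replicates})


@dataclass(frozen=True)
class ValidationMetrics:
    accuracy_pct: float
    rsd_pct: float
    n: int
    scope: str  # "intra_day" | "inter_day"
    verdict: str | None = None  # filled by fda_acceptance


def _weights(levels: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(levels)
    if weighting == "1/x":
        return 1.0 / levels
    if weighting == "1/x2":
        return 1.0 / levels**2
    raise ValueError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    weighting: str = "1/x2",
    matrix_label: str = "",
) -> CalibrationCurve:
    """Weighted least-squares line of instrument response on nominal
    concentration; r^2 is the weighted coefficient of determination."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and responses must be 1-D and equal length")
    if np.unique(x).size < 2:
        raise ValueError("calibration needs at least 2 distinct levels")
    if np.any(x <= 0) and weighting != "none":
        raise ValueError("concentration weighting requires positive levels")
    res = sm.WLS(y, sm.add_constant(x), weights=_weights(x, weighting)).fit()
    intercept, slope = res.params
    return CalibrationCurve(
        matrix_label=matrix_label,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(res.rsquared),
        weighting=weighting,
        range_low=float(x.min()),
        range_high=float(x.max()),
    )


def back_calculate(
    curve: CalibrationCurve, response: float
) -> tuple[float, bool]:
    """Invert the calibration line.

    Returns ``(concentration, in_range)`` where ``in_range`` is False when
    the back-calculated value falls outside the validated range (including
    negative values from responses below the intercept).
    """
    conc = (response - curve.intercept) / curve.slope
    in_range = curve.range_low <= conc <= curve.range_high
    return conc, in_range


def _metrics(measured: np.ndarray, nominal: float, scope: str) -> ValidationMetrics:
    mean = float(measured.mean())
    sd = float(measured.std(ddof=1))
    return ValidationMetrics(
        accuracy_pct=100.0 * mean / nominal,
        rsd_pct=100.0 * sd / mean,
        n=int(measured.size),
        scope=scope,
    )


def qc_summary(
    batch: QCBatch, intra_day: int | None = None
) -> dict[str, ValidationMetrics]:
    """Intra-day (one day's replicates; the earliest day by default) and
    inter-day (all replicates pooled) accuracy and precision."""
    if intra_day is None:
        intra_day = batch.days()[0]
    intra = np.array([m for d, m in batch.replicates if d == intra_day], dtype=float)
    if intra.size < 2:
        raise ValueError(f"day {intra_day} has fewer than 2 replicates")
    pooled = np.array([m for _, m in batch.replicates], dtype=float)
    return {
        "intra_day": _metrics(intra, batch.nominal, "intra_day"),
        "inter_day": _metrics(pooled, batch.nominal, "inter_day"),
    }


def fda_acceptance(
    metrics: ValidationMetrics,
    level_kind: str = "other",
    rule: str = "accuracy_precision",
) -> ValidationMetrics:
    """Classify a metrics row against the applicable acceptance rule.

    ``level_kind`` is ``"LLOQ"`` or ``"other"`` (only relevant to the
    accuracy/precision rule). Returns a copy with ``verdict`` set to
    ``"pass"`` or ``"fail"``.
    """
    if level_kind not in ("LLOQ", "other"):
        raise ValueError("level_kind must be 'LLOQ' or 'other'")
    acc, rsd = metrics.accuracy_pct, metrics.rsd_pct
    if rule == "accuracy_precision":
        if level_kind == "LLOQ":
            ok = 80.0 <= acc <= 120.0 and rsd < 20.0
        else:
            ok = 85.0 <= acc <= 115.0 and rsd < 15.0
    elif rule == "matrix_effect":
        ok = 85.0 <= acc <= 115.0
    elif rule == "stability":
        ok = 85.0 <= acc <= 115.0 and rsd <= 15.0
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return replace(metrics, verdict="pass" if ok else "fail")


def signal_ratio_metric(
    test_areas: Iterable[float], reference_areas: Iterable[float]
) -> float:
    """Percent ratio of mean test signal to mean reference signal.

    Used both for extraction recovery (extracted vs post-extraction spike)
    and for the matrix effect (post-extraction spike vs neat solution).
    """
    test = np.asarray(list(test_areas), dtype=float)
    ref = np.asarray(list(reference_areas), dtype=float)
    if test.size == 0 or ref.size == 0:
        raise ValueError("both signal groups must be non-empty")
    if ref.mean() == 0:
        raise ValueError("reference mean signal is zero")
    return float(100.0 * test.mean() / ref.mean())
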