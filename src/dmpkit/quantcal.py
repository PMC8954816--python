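"""Calibration-curve fitting, back-calculation and qualification statistics.

Quantification follows the standard LC-MS bioanalytical workflow: the
response (analyte / internal-standard peak-area ratio) of duplicate
standards at eight concentration levels is fitted with a quadratic model
``ratio = a*x^2 + b*x + c`` under 1/x^2 weighting (x = nominal
concentration), unknowns are back-calculated by inverting the fit, and QC
statistics (mean accuracy %, CV %) are judged against a fit-for-purpose
+/-25% acceptance band.  Dilution-integrity and stability assessments reuse
the same accuracy/precision arithmetic grouped by design factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chem import ComputationError, ValidationError

__all__ = [
    "DEFAULT_CALIBRATION_RANGE",
    "DEFAULT_QC_LEVELS",
    "CalibrationStandard",
    "CalibrationFit",
    "BackCalcResult",
    "QCEvaluation",
    "fit_calibration",
    "back_calculate",
    "accuracy_precision",
    "evaluate_run",
    "dilution_integrity",
    "stability_evaluate",
    "round_sig",
]

#: Qualified assay range (ng/mL), LLOQ..ULOQ.
DEFAULT_CALIBRATION_RANGE = (1.02, 2220.0)
#: QC nominal levels (ng/mL): low, medium, high.
DEFAULT_QC_LEVELS = (15.0, 165.0, 1820.0)


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if value == 0 or not math.isfinite(value):
        return value
    magnitude = math.floor(math.log10(abs(value)))
    factor = 10.0 ** (sig - 1 - magnitude)
    return math.floor(abs(value) * factor + 0.5) / factor * math.copysign(1, value)


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration (or QC) injection: nominal conc and response ratio."""

    level_id: str
    nominal_conc: float
    area_ratio: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.nominal_conc <= 0:
            raise ValidationError(
                f"nominal concentration must be > 0, got {self.nominal_conc}"
            )
        if self.area_ratio < 0:
            raise ValidationError(
                f"area ratio must be >= 0, got {self.area_ratio}"
            )


@dataclass
class CalibrationFit:
    """A 1/x^2-weighted quadratic response model over [lloq, uloq]."""

    a: float
    b: float
    c: float
    corr_coeff: float
    lloq: float
    uloq: float
    weighting: str = "1/x^2"
    n_levels: int = 0

    def predict(self, conc) -> np.ndarray | float:
        return np.polyval([self.a, self.b, self.c], conc)


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated concentration; ``conc`` includes the dilution factor."""

    conc: float
    assay_conc: float
    flag: str  # ok | BLQ | ALQ


@dataclass(frozen=True)
class QCEvaluation:
    """Accuracy/precision statistics for one QC group with a pass flag."""

    scope: str  # intra | inter | dilution | stability
    nominal: float
    n: int
    mean_measured: float
    mean_accuracy_pct: float
    cv_pct: float
    passed: bool
    run_id: str | None = None
    level_id: str | None = None
    condition: str | None = None


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    min_levels: int = 6,
) -> CalibrationFit:
    """Weighted least squares of the quadratic response model.

    Weights are 1/nominal^2 (nominal, not fitted, concentration).  The
    reported correlation coefficient is the Pearson correlation between
    observed and fitted area ratios, which equals 1 in the noiseless case.
    """
    if not standards:
        raise ValidationError("no calibration standards supplied")
    x = np.array([s.nominal_conc for s in standards], dtype=float)
    y = np.array([s.area_ratio for s in standards], dtype=float)
    levels = np.unique(x)
    if levels.size < max(3, min_levels):
        raise ValidationError(
            f"need at least {max(3, min_levels)} distinct concentration "
            f"levels, got {levels.size}"
        )
    design = np.column_stack([x**2, x, np.ones_like(x)])
    result = sm.WLS(y, design, weights=1.0 / x**2).fit()
    a, b, c = result.params
    fitted = np.asarray(result.fittedvalues, dtype=float)
    corr = float(np.corrcoef(y, fitted)[0, 1])
    return CalibrationFit(
        a=float(a),
        b=float(b),
        c=float(c),
        corr_coeff=corr,
        lloq=float(levels.min()),
        uloq=float(levels.max()),
        n_levels=int(levels.size),
    )


def back_calculate(
    area_ratio: float,
    fit: CalibrationFit,
    dilution_factor: float = 1.0,
) -> BackCalcResult:
    """Invert the response model for one observed area ratio.

    Solves ``a*x^2 + b*x + (c - ratio) = 0`` and selects the real root in
    [0, 2*ULOQ] (preferring the one inside [LLOQ, ULOQ] when two qualify);
    genuinely ambiguous cases raise rather than guess.  The returned
    concentration is multiplied by the dilution factor; the flag reports
    whether the in-assay concentration fell below/above the qualified range
    (BLQ/ALQ), without clamping.
    """
    if dilution_factor < 1:
        raise ValidationError(
            f"dilution factor must be >= 1, got {dilution_factor}"
        )
    if fit.a == 0.0:
        if fit.b == 0.0:
            raise ComputationError("degenerate calibration: a = b = 0")
        roots = [(area_ratio - fit.c) / fit.b]
    else:
        disc = fit.b**2 - 4.0 * fit.a * (fit.c - area_ratio)
        if disc < 0:
            raise ComputationError(
                f"no admissible real root for area ratio {area_ratio}"
            )
        sq = math.sqrt(disc)
        roots = [(-fit.b + sq) / (2 * fit.a), (-fit.b - sq) / (2 * fit.a)]
        if abs(roots[0] - roots[1]) < 1e-12 * max(1.0, abs(roots[0])):
            roots = roots[:1]
    admissible = [r for r in roots if 0.0 <= r <= 2.0 * fit.uloq]
    if not admissible:
        raise ComputationError(
            f"no admissible real root for area ratio {area_ratio} "
            f"(candidates {roots})"
        )
    if len(admissible) > 1:
        in_range = [r for r in admissible if fit.lloq <= r <= fit.uloq]
        if len(in_range) == 1:
            admissible = in_range
        else:
            raise ComputationError(
                f"ambiguous roots {admissible} for area ratio {area_ratio}"
            )
    assay_conc = admissible[0]
    if assay_conc < fit.lloq:
        flag = "BLQ"
    elif assay_conc > fit.uloq:
        flag = "ALQ"
    else:
        flag = "ok"
    return BackCalcResult(
        conc=assay_conc * dilution_factor, assay_conc=assay_conc, flag=flag
    )


def accuracy_precision(
    measured: Sequence[float], nominal: float
) -> tuple[float, float]:
    """Mean accuracy (%) and CV (%) of measured concentrations vs nominal.

    Accuracy = mean(measured)/nominal x 100.  CV uses the sample (n-1)
    standard deviation over the mean; with a single replicate the CV is NaN.
    """
    values = np.asarray(list(measured), dtype=float)
    if values.size == 0:
        raise ValidationError("no measured values supplied")
    if nominal <= 0:
        raise ValidationError(f"nominal must be > 0, got {nominal}")
    mean = float(values.mean())
    accuracy = mean / nominal * 100.0
    if values.size >= 2 and mean != 0:
        cv = float(values.std(ddof=1) / mean * 100.0)
    else:
        cv = float("nan")
    return accuracy, cv


def _evaluate(
    measured: Sequence[float],
    nominal: float,
    criteria_pct: float,
    scope: str,
    **labels,
) -> QCEvaluation:
    accuracy, cv = accuracy_precision(measured, nominal)
    values = np.asarray(list(measured), dtype=float)
    passed = (100.0 - criteria_pct) <= accuracy <= (100.0 + criteria_pct)
    return QCEvaluation(
        scope=scope,
        nominal=float(nominal),
        n=int(values.size),
        mean_measured=float(values.mean()),
        mean_accuracy_pct=accuracy,
        cv_pct=cv,
        passed=passed,
        **labels,
    )


def evaluate_run(
    qc: pd.DataFrame,
    criteria_pct: float = 25.0,
    levels: Mapping[str, float] | None = None,
) -> list[QCEvaluation]:
    """Intra-run (per run, per level) and pooled inter-run QC statistics.

    ``qc`` needs columns ``run_id``, ``level_id``, ``measured`` and either a
    ``nominal`` column or a ``levels`` mapping from level label to nominal
    concentration.  Inter-run statistics pool all replicates of all runs.
    """
    frame = qc.copy()
    required = {"run_id", "level_id", "measured"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"QC table missing columns: {sorted(missing)}")
    if levels is not None:
        unknown = set(frame["level_id"]) - set(levels)
        if unknown:
            raise ValidationError(f"unknown QC level labels: {sorted(unknown)}")
        frame["nominal"] = frame["level_id"].map(levels)
    elif "nominal" not in frame.columns:
        raise ValidationError("QC table needs a 'nominal' column or a levels map")
    evaluations: list[QCEvaluation] = []
    level_order = (
        frame[["level_id", "nominal"]]
        .drop_duplicates()
        .sort_values("nominal")["level_id"]
        .tolist()
    )
    for run_id in sorted(frame["run_id"].unique()):
        run = frame[frame["run_id"] == run_id]
        for level in level_order:
            group = run[run["level_id"] == level]
            if group.empty:
                continue
            evaluations.append(
                _evaluate(
                    group["measured"],
                    float(group["nominal"].iloc[0]),
                    criteria_pct,
                    "intra",
                    run_id=str(run_id),
                    level_id=str(level),
                )
            )
    for level in level_order:
        group = frame[frame["level_id"] == level]
        evaluations.append(
            _evaluate(
                group["measured"],
                float(group["nominal"].iloc[0]),
                criteria_pct,
                "inter",
                level_id=str(level),
            )
        )
    return evaluations


def dilution_integrity(
    measured: Sequence[float],
    dilution_factor: float,
    theoretical: float,
    criteria_pct: float = 25.0,
) -> QCEvaluation:
    """Accuracy/precision of dilution QCs (measured values already include
    the dilution factor) against the theoretical concentration."""
    if dilution_factor < 1:
        raise ValidationError(
            f"dilution factor must be >= 1, got {dilution_factor}"
        )
    return _evaluate(
        measured,
        theoretical,
        criteria_pct,
        "dilution",
        level_id=f"{dilution_factor:g}-fold",
    )


def stability_evaluate(
    stability: pd.DataFrame,
    criteria_pct: float = 25.0,
) -> list[QCEvaluation]:
    """Accuracy/precision per (storage condition, QC level).

    ``stability`` needs columns ``condition``, ``level_id``, ``nominal``,
    ``measured``; condition labels (short_term, long_term, freeze_thaw, ...)
    are free text.
    """
    required = {"condition", "level_id", "nominal", "measured"}
    missing = required - set(stability.columns)
    if missing:
        raise ValidationError(
            f"stability table missing columns: {sorted(missing)}"
        )
    evaluations: list[QCEvaluation] = []
    for condition in pd.unique(stability["condition"]):
        block = stability[stability["condition"] == condition]
        level_order = (
            block[["level_id", "nominal"]]
            .drop_duplicates()
            .sort_values("nominal")["level_id"]
            .tolist()
        )
        for level in level_order:
            group = block[block["level_id"] == level]
            evaluations.append(
                _evaluate(
                    group["measured"],
                    float(group["nominal"].iloc[0]),
                    criteria_pct,
                    "stability",
                    level_id=str(level),
                    condition=str(condition),
                )
            )
    return evaluations
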