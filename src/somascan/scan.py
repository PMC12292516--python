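"""3D-scan somatotype pathway.

Optical full-body scanners cannot image the head apex reliably (hair) and
cannot pinch skinfolds, so two substitutions make automated somatotyping
possible:

* **stature** is predicted from the floor-to-C7-vertebra landmark height via
  a linear regression calibrated against manually measured stature;
* **relative fatness** comes from the US Navy circumference equations
  (waist/neck, plus hips for women), converted to endomorphy at 5% body
  fat per unit.

Mesomorphy uses the same linear form as the manual pathway but without
skinfold corrections to the girths (the scanner has no skinfolds), and
ectomorphy shares the piecewise HWR rule.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .classify import classify_13, somatochart_coordinates
from .errors import ArgumentError, DomainError, SingularFitError
from .manual import ectomorphy_from_hwr
from .records import (
    Pathway,
    ScanAnthropometry,
    Sex,
    SomatotypeResult,
    body_mass_index,
    floor_component,
    height_weight_ratio,
)

logger = logging.getLogger(__name__)

#: Plausible C7 landmark range (mm); predictions outside only warn.
C7_PLAUSIBLE_MM = (1000.0, 2100.0)

#: Body-fat clamp bounds (%): outside values are clamped with a log entry.
BF_CLAMP = (0.0, 75.0)


@dataclass(frozen=True)
class HeightModel:
    """Linear stature predictor: height_cm = slope_a * c7_mm + intercept_b.

    Carries its fit diagnostics so downstream reports can state how good the
    calibration was: coefficient of determination, residual standard error
    (n-2 denominator, the "Sy.x" of regression output), and a 95% t-based
    confidence interval for the slope.
    """

    slope_a: float  # cm of stature per mm of C7 height
    intercept_b: float  # cm
    r_squared: float
    residual_se: float  # cm
    slope_ci_low: float
    slope_ci_high: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ArgumentError(f"height model needs n >= 3, got {self.n}")
        if self.residual_se < 0:
            raise ArgumentError("residual_se must be non-negative")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ArgumentError(f"r_squared out of [0, 1]: {self.r_squared}")
        if not (self.slope_ci_low <= self.slope_a <= self.slope_ci_high):
            raise ArgumentError("slope must lie inside its confidence interval")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HeightModel":
        return cls(**json.loads(Path(path).read_text()))


#: Default calibration shipped with the package (117-subject study cohort,
#: TC2 NX-16 scanner).  Refit with :func:`fit_height_model` for any other
#: scanner or population.
DEFAULT_HEIGHT_MODEL = HeightModel(
    slope_a=0.1039,
    intercept_b=19.39,
    r_squared=0.9218,
    residual_se=2.535,
    slope_ci_low=0.09840,
    slope_ci_high=0.1094,
    n=117,
)


def predict_height(c7_height: float, model: HeightModel = DEFAULT_HEIGHT_MODEL) -> float:
    """Predicted stature (cm) from the C7 landmark height (mm)."""
    if c7_height <= 0:
        raise DomainError(f"c7_height must be positive, got {c7_height}")
    if not (C7_PLAUSIBLE_MM[0] <= c7_height <= C7_PLAUSIBLE_MM[1]):
        logger.warning(
            "c7_height %.1f mm outside plausible range %s; extrapolating",
            c7_height,
            C7_PLAUSIBLE_MM,
        )
    return model.slope_a * c7_height + model.intercept_b


def fit_height_model(pairs: Sequence[tuple[float, float]]) -> HeightModel:
    """Ordinary least squares of stature (cm) on C7 landmark height (mm).

    Returns the fitted :class:`HeightModel` with R², residual standard
    error (n-2 denominator) and a 95% t-based slope confidence interval.
    """
    if len(pairs) < 3:
        raise ArgumentError(f"need at least 3 pairs, got {len(pairs)}")
    c7 = np.asarray([p[0] for p in pairs], dtype=float)
    height = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(c7) == 0:
        raise SingularFitError("all C7 heights identical; slope undefined")
    fit = stats.linregress(c7, height)
    n = len(pairs)
    resid = height - (fit.slope * c7 + fit.intercept)
    residual_se = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    tcrit = stats.t.ppf(0.975, n - 2)
    half = tcrit * fit.stderr
    return HeightModel(
        slope_a=float(fit.slope),
        intercept_b=float(fit.intercept),
        r_squared=min(float(fit.rvalue**2), 1.0),
        residual_se=residual_se,
        slope_ci_low=float(fit.slope - half),
        slope_ci_high=float(fit.slope + half),
        n=n,
    )


def navy_body_fat(
    sex: Sex,
    circ_waist: float,
    circ_neck: float,
    height: float,
    circ_hips: Optional[float] = None,
    *,
    subject_id: str | None = None,
) -> float:
    """US Navy circumference body-fat estimate (%), metric, base-10 logs.

    Men:   495 / (1.0324 - 0.19077*log10(waist - neck)
                        + 0.15456*log10(height)) - 450
    Women: 495 / (1.29679 - 0.35004*log10(waist + hips - neck)
                         + 0.22100*log10(height)) - 450

    All circumferences and height in cm.  The result is clamped to
    [0, 75]% with a logged clamp event — the formula can stray outside any
    physiological range for extreme inputs, and a clamped cohort run with
    an audit trail beats an aborted one.
    """
    if height <= 0:
        raise DomainError(f"height must be positive, got {height}")
    if sex is Sex.male:
        margin = circ_waist - circ_neck
        if margin <= 0:
            raise DomainError(
                f"male body-fat formula requires circ_waist > circ_neck "
                f"(waist={circ_waist}, neck={circ_neck})"
            )
        denom = 1.0324 - 0.19077 * math.log10(margin) + 0.15456 * math.log10(height)
    else:
        if circ_hips is None:
            raise ArgumentError("female body-fat formula requires circ_hips")
        margin = circ_waist + circ_hips - circ_neck
        if margin <= 0:
            raise DomainError(
                f"female body-fat formula requires circ_waist + circ_hips > "
                f"circ_neck (waist={circ_waist}, hips={circ_hips}, neck={circ_neck})"
            )
        denom = 1.29679 - 0.35004 * math.log10(margin) + 0.22100 * math.log10(height)
    bf = 495.0 / denom - 450.0
    if not (BF_CLAMP[0] <= bf <= BF_CLAMP[1]):
        clamped = min(max(bf, BF_CLAMP[0]), BF_CLAMP[1])
        logger.warning(
            "body fat %.2f%% clamped to %.2f%%%s",
            bf,
            clamped,
            f" (subject {subject_id})" if subject_id else "",
        )
        bf = clamped
    return bf


def endomorphy_from_bf(bf_percent: float) -> float:
    """Endomorphy from body-fat percent: 5% body fat = 1 unit, floored at 0.1."""
    if bf_percent < 0:
        raise DomainError(f"bf_percent must be non-negative, got {bf_percent}")
    return floor_component(bf_percent / 5.0, name="endomorphy")


def mesomorphy_scan(
    breadth_humerus: float,
    breadth_femur: float,
    girth_biceps: float,
    girth_calf: float,
    height: float,
    *,
    subject_id: str | None = None,
) -> float:
    """Mesomorphy from scanner dimensions — no skinfold girth corrections.

        0.858*humerus + 0.601*femur + 0.188*biceps + 0.161*calf
        - 0.131*height + 4.5
    """
    for name, v in (
        ("breadth_humerus", breadth_humerus),
        ("breadth_femur", breadth_femur),
        ("girth_biceps", girth_biceps),
        ("girth_calf", girth_calf),
        ("height", height),
    ):
        if v <= 0:
            raise DomainError(f"{name} must be positive, got {v}")
    meso = (
        0.858 * breadth_humerus
        + 0.601 * breadth_femur
        + 0.188 * girth_biceps
        + 0.161 * girth_calf
        - 0.131 * height
        + 4.5
    )
    return floor_component(meso, name="mesomorphy", subject_id=subject_id)


def somatotype_scan(
    record: ScanAnthropometry,
    model: HeightModel = DEFAULT_HEIGHT_MODEL,
    breadth_source: str = "scan",
    manual_breadths: Optional[tuple[float, float]] = None,
) -> SomatotypeResult:
    """Full scan-pathway somatotype for one subject.

    ``breadth_source`` selects where the bone breadths entering mesomorphy
    come from: ``"scan"`` uses the record's scanner breadths; ``"manual"``
    uses the caliper pair supplied in ``manual_breadths`` (humerus, femur) —
    the hybrid mode that isolates the scanner's landmark-detection error in
    breadths from the rest of the pipeline.
    """
    if breadth_source not in ("scan", "manual"):
        raise ArgumentError(f"breadth_source must be 'scan' or 'manual', got {breadth_source!r}")
    if breadth_source == "manual":
        if manual_breadths is None:
            raise ArgumentError("manual_breadths required when breadth_source='manual'")
        humerus, femur = manual_breadths
        pathway = Pathway.scan_manual_breadths
    else:
        humerus, femur = record.breadth_humerus, record.breadth_femur
        pathway = Pathway.scan

    try:
        height = predict_height(record.c7_height, model)
        bf = navy_body_fat(
            record.sex,
            record.circ_waist,
            record.circ_neck,
            height,
            record.circ_hips if record.sex is Sex.female else None,
            subject_id=record.subject_id,
        )
        endo = endomorphy_from_bf(bf)
        meso = mesomorphy_scan(
            humerus,
            femur,
            record.girth_biceps,
            record.girth_calf,
            height,
            subject_id=record.subject_id,
        )
        hwr = height_weight_ratio(height, record.weight)
        ecto = ectomorphy_from_hwr(hwr)
    except DomainError as err:
        raise DomainError(f"subject {record.subject_id}: {err}") from err
    x, y = somatochart_coordinates(endo, meso, ecto)
    return SomatotypeResult(
        subject_id=record.subject_id,
        pathway=pathway,
        endomorphy=endo,
        mesomorphy=meso,
        ectomorphy=ecto,
        hwr=hwr,
        bmi=body_mass_index(height, record.weight),
        bf_percent=bf,
        chart_x=x,
        chart_y=y,
        category=classify_13(endo, meso, ecto).label,
    )
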