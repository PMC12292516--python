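"""Manual (reference) Heath-Carter pathway.

Classical anthropometric somatotyping from caliper, tape and bone-caliper
measurements:

* endomorphy — cubic in the height-corrected sum of the triceps,
  subscapular and supraspinale skinfolds,
* mesomorphy — linear combination of bone breadths, skinfold-corrected limb
  girths and stature,
* ectomorphy — piecewise linear in the height-to-weight ratio (shared with
  the scan pathway).

All component outputs are floored at 0.1 by convention.
"""

from __future__ import annotations

from .classify import classify_13, somatochart_coordinates
from .errors import DomainError
from .records import (
    ManualAnthropometry,
    Pathway,
    SomatotypeResult,
    body_mass_index,
    floor_component,
    height_weight_ratio,
)

#: Reference stature (cm) of the skinfold-sum height correction.
_REFERENCE_STATURE = 170.18


def endomorphy_manual(
    skinfold_triceps: float,
    skinfold_subscapular: float,
    skinfold_supraspinale: float,
    height: float,
    *,
    subject_id: str | None = None,
) -> float:
    """Endomorphy from three skinfolds (mm) and stature (cm).

    The skinfold sum is scaled by 170.18/height so that the same cubic
    applies across statures, then evaluated as

        -0.7182 + 0.1451*X - 0.00068*X**2 + 0.0000014*X**3

    and floored at 0.1 (the cubic is negative for very small X).
    """
    for name, v in (
        ("skinfold_triceps", skinfold_triceps),
        ("skinfold_subscapular", skinfold_subscapular),
        ("skinfold_supraspinale", skinfold_supraspinale),
        ("height", height),
    ):
        if v <= 0:
            raise DomainError(f"{name} must be positive, got {v}")
    x = (skinfold_triceps + skinfold_subscapular + skinfold_supraspinale) * (
        _REFERENCE_STATURE / height
    )
    endo = -0.7182 + 0.1451 * x - 0.00068 * x**2 + 0.0000014 * x**3
    return floor_component(endo, name="endomorphy", subject_id=subject_id)


def mesomorphy_manual(
    breadth_humerus: float,
    breadth_femur: float,
    girth_biceps: float,
    skinfold_triceps: float,
    girth_calf: float,
    skinfold_medial_calf: float,
    height: float,
    *,
    subject_id: str | None = None,
) -> float:
    """Mesomorphy from breadths, skinfold-corrected girths and stature.

    Girths (cm) are corrected by subtracting the overlying skinfold
    converted from mm to cm (divide by 10):

        0.858*humerus + 0.601*femur + 0.188*(biceps - triceps_sf/10)
        + 0.161*(calf - calf_sf/10) - 0.131*height + 4.5
    """
    for name, v in (
        ("breadth_humerus", breadth_humerus),
        ("breadth_femur", breadth_femur),
        ("girth_biceps", girth_biceps),
        ("skinfold_triceps", skinfold_triceps),
        ("girth_calf", girth_calf),
        ("skinfold_medial_calf", skinfold_medial_calf),
        ("height", height),
    ):
        if v <= 0:
            raise DomainError(f"{name} must be positive, got {v}")
    corrected_biceps = girth_biceps - skinfold_triceps / 10.0
    corrected_calf = girth_calf - skinfold_medial_calf / 10.0
    if corrected_biceps <= 0:
        raise DomainError(
            f"skinfold-corrected biceps girth non-positive ({corrected_biceps:.3f} cm)"
        )
    if corrected_calf <= 0:
        raise DomainError(
            f"skinfold-corrected calf girth non-positive ({corrected_calf:.3f} cm)"
        )
    meso = (
        0.858 * breadth_humerus
        + 0.601 * breadth_femur
        + 0.188 * corrected_biceps
        + 0.161 * corrected_calf
        - 0.131 * height
        + 4.5
    )
    return floor_component(meso, name="mesomorphy", subject_id=subject_id)


def ectomorphy_from_hwr(hwr: float) -> float:
    """Piecewise-linear ectomorphy from the height-to-weight ratio.

    Three branches with inclusive lower bounds:

    * HWR >= 40.75        ->  0.732*HWR - 28.58
    * 38.25 <= HWR < 40.75 -> 0.463*HWR - 17.63
    * HWR < 38.25         ->  0.1

    The middle branch evaluates slightly below 0.1 for HWR just above
    38.25 (it crosses 0.1 near 38.293), so the conventional component
    floor applies to its output as well.
    """
    if hwr <= 0:
        raise DomainError(f"hwr must be positive, got {hwr}")
    if hwr >= 40.75:
        value = 0.732 * hwr - 28.58
    elif hwr >= 38.25:
        value = 0.463 * hwr - 17.63
    else:
        value = 0.1
    return floor_component(value, name="ectomorphy")


def somatotype_manual(record: ManualAnthropometry) -> SomatotypeResult:
    """Full manual-pathway somatotype for one subject."""
    try:
        endo = endomorphy_manual(
            record.skinfold_triceps,
            record.skinfold_subscapular,
            record.skinfold_supraspinale,
            record.height,
            subject_id=record.subject_id,
        )
        meso = mesomorphy_manual(
            record.breadth_humerus,
            record.breadth_femur,
            record.girth_biceps,
            record.skinfold_triceps,
            record.girth_calf,
            record.skinfold_medial_calf,
            record.height,
            subject_id=record.subject_id,
        )
        hwr = height_weight_ratio(record.height, record.weight)
        ecto = ectomorphy_from_hwr(hwr)
    except DomainError as err:
        raise DomainError(f"subject {record.subject_id}: {err}") from err
    x, y = somatochart_coordinates(endo, meso, ecto)
    return SomatotypeResult(
        subject_id=record.subject_id,
        pathway=Pathway.manual,
        endomorphy=endo,
        mesomorphy=meso,
        ectomorphy=ecto,
        hwr=hwr,
        bmi=body_mass_index(record.height, record.weight),
        bf_percent=None,
        chart_x=x,
        chart_y=y,
        category=classify_13(endo, meso, ecto).label,
    )
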