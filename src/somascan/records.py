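"""Domain record types and the basic derived indices (HWR, BMI).

Two record types carry a subject through the two measurement pathways:

* :class:`ManualAnthropometry` — the caliper/tape/bone-caliper measurements
  of classical Heath-Carter somatotyping (four skinfolds, two girths, two
  bone breadths, stature, mass).
* :class:`ScanAnthropometry` — the dimensions a full-body optical scanner
  exports (C7-landmark height as a stature proxy, trunk circumferences for
  circumference-based body fat, limb girths and bone breadths), plus the
  manually entered body mass.

Units are fixed package-wide: centimetres everywhere except skinfolds (mm)
and the C7 landmark height (mm).  Converters in :mod:`somascan.io` normalise
on ingest; nothing downstream converts.

Validation is performed at construction and violations are hard errors, so
the component equations never see a log-domain failure silently.
"""

from __future__ import annotations

import enum
import logging
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DomainError

logger = logging.getLogger(__name__)

#: Conventional lower bound for each somatotype component.
COMPONENT_FLOOR = 0.1


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Pathway(str, enum.Enum):
    """Which measurement pathway produced a somatotype result."""

    manual = "manual"
    scan = "scan"
    #: Scan pathway but with bone breadths taken from manual calipers
    #: (the hybrid mode used to isolate the scanner's breadth error).
    scan_manual_breadths = "scan_manual_breadths"


class ManualAnthropometry(BaseModel):
    """One subject's manually measured anthropometry.

    Skinfolds are in mm; every other length in cm; weight in kg.
    """

    model_config = ConfigDict(frozen=True)

    subject_id: str
    sex: Sex
    age: float = Field(gt=0)
    height: float = Field(ge=100, le=230, description="stature, cm")
    weight: float = Field(ge=25, le=250, description="body mass, kg")
    skinfold_triceps: float = Field(ge=1, le=80, description="mm")
    skinfold_subscapular: float = Field(ge=1, le=80, description="mm")
    skinfold_supraspinale: float = Field(ge=1, le=80, description="mm")
    skinfold_medial_calf: float = Field(ge=1, le=80, description="mm")
    girth_biceps: float = Field(gt=0, description="flexed upper-arm girth, cm")
    girth_calf: float = Field(gt=0, description="cm")
    breadth_humerus: float = Field(gt=0, description="biepicondylar, cm")
    breadth_femur: float = Field(gt=0, description="biepicondylar, cm")

    @model_validator(mode="after")
    def _breadths_below_girths(self) -> "ManualAnthropometry":
        # a bone breadth larger than the limb girth around it is anatomically
        # impossible and almost always a column-mapping mistake
        if self.breadth_humerus >= self.girth_biceps:
            raise ValueError(
                f"breadth_humerus ({self.breadth_humerus}) must be smaller than "
                f"girth_biceps ({self.girth_biceps})"
            )
        if self.breadth_femur >= self.girth_calf:
            raise ValueError(
                f"breadth_femur ({self.breadth_femur}) must be smaller than "
                f"girth_calf ({self.girth_calf})"
            )
        return self


class ScanAnthropometry(BaseModel):
    """One subject's 3D-scan-derived dimensions plus manually entered weight.

    The C7 landmark height is in mm (scanner convention); circumferences,
    girths and breadths in cm; weight in kg.
    """

    model_config = ConfigDict(frozen=True)

    subject_id: str
    sex: Sex
    age: float = Field(gt=0)
    weight: float = Field(ge=25, le=250, description="manually entered, kg")
    c7_height: float = Field(ge=1000, le=2100, description="floor to C7 landmark, mm")
    circ_waist: float = Field(gt=0, description="cm")
    circ_hips: float = Field(gt=0, description="cm")
    circ_neck: float = Field(gt=0, description="cm")
    girth_biceps: float = Field(gt=0, description="cm")
    girth_calf: float = Field(gt=0, description="cm")
    breadth_humerus: float = Field(gt=0, description="cm")
    breadth_femur: float = Field(gt=0, description="cm")

    @model_validator(mode="after")
    def _navy_log_domain(self) -> "ScanAnthropometry":
        # the circumference body-fat formula takes log10 of these margins;
        # enforce positivity here so the formula never sees log(<=0)
        if self.sex is Sex.male and self.circ_waist <= self.circ_neck:
            raise ValueError(
                f"male record requires circ_waist > circ_neck "
                f"(got waist={self.circ_waist}, neck={self.circ_neck})"
            )
        if self.sex is Sex.female and self.circ_waist + self.circ_hips <= self.circ_neck:
            raise ValueError(
                f"female record requires circ_waist + circ_hips > circ_neck "
                f"(got waist={self.circ_waist}, hips={self.circ_hips}, "
                f"neck={self.circ_neck})"
            )
        return self


class SomatotypeResult(BaseModel):
    """The three somatotype components plus derived indices for one subject.

    Component values are stored at full floating precision; the conventional
    rounding to whole numbers happens only when rendering reports.
    """

    model_config = ConfigDict(frozen=True)

    subject_id: str
    pathway: Pathway
    endomorphy: float = Field(ge=COMPONENT_FLOOR)
    mesomorphy: float = Field(ge=COMPONENT_FLOOR)
    ectomorphy: float = Field(ge=COMPONENT_FLOOR)
    hwr: float = Field(gt=0)
    bmi: float = Field(gt=0)
    #: circumference-estimated body fat; only the scan pathway produces it
    bf_percent: Optional[float] = None
    chart_x: float
    chart_y: float
    category: str

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.endomorphy, self.mesomorphy, self.ectomorphy)


def height_weight_ratio(height: float, weight: float) -> float:
    """Height-to-weight ratio (ponderal index): height / weight**(1/3).

    Parameters are stature in cm and mass in kg; the result is the
    dimensionless index the ectomorphy rule branches on.  Full floating
    precision is kept — rounding is a presentation concern.
    """
    if height <= 0:
        raise DomainError(f"height must be positive, got {height}")
    if weight <= 0:
        raise DomainError(f"weight must be positive, got {weight}")
    return height / weight ** (1.0 / 3.0)


def body_mass_index(height: float, weight: float) -> float:
    """BMI in kg/m**2 from height in cm and weight in kg."""
    if height <= 0:
        raise DomainError(f"height must be positive, got {height}")
    if weight <= 0:
        raise DomainError(f"weight must be positive, got {weight}")
    return weight / (height / 100.0) ** 2


def bmi_category(bmi: float) -> str:
    """WHO adult BMI class, half-open bins with inclusive lower bounds."""
    if bmi <= 0:
        raise DomainError(f"bmi must be positive, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def floor_component(value: float, *, name: str, subject_id: str | None = None) -> float:
    """Apply the 0.1 component floor, logging every floor event."""
    if value < COMPONENT_FLOOR:
        logger.info(
            "component floor engaged: %s=%.4f -> %.1f%s",
            name,
            value,
            COMPONENT_FLOOR,
            f" (subject {subject_id})" if subject_id else "",
        )
        return COMPONENT_FLOOR
    return value
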