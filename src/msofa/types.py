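"""Domain types: bedside physiology snapshots, organ-score panels, cohort records.

A *snapshot* is one patient's raw physiology at one assessment time; it is the
common input to both scoring instruments.  SOFA needs the laboratory variables
(PaO2, platelets, bilirubin, creatinine); MSOFA works from bedside observation
alone (pulse oximetry, bleeding signs, jaundice grade, urine output), so the
laboratory fields are optional and their absence blocks SOFA scoring only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Optional

from .errors import ValidationError


class Timepoint(str, enum.Enum):
    """Assessment times: ICU admission, +24 h, +48 h."""

    T0 = "T0"
    T24 = "T24"
    T48 = "T48"


class Instrument(str, enum.Enum):
    SOFA = "sofa"
    MSOFA = "msofa"


class OrganSystem(str, enum.Enum):
    RESPIRATORY = "respiratory"
    COAGULATION = "coagulation"
    CARDIOVASCULAR = "cardiovascular"
    LIVER = "liver"
    CNS = "cns"
    RENAL = "renal"


ORGAN_ORDER = (
    OrganSystem.RESPIRATORY,
    OrganSystem.COAGULATION,
    OrganSystem.CARDIOVASCULAR,
    OrganSystem.LIVER,
    OrganSystem.CNS,
    OrganSystem.RENAL,
)


class BleedingSign(str, enum.Enum):
    NONE = "none"
    PETECHIAE = "petechiae_purpura_ecchymosis"
    SPONTANEOUS = "spontaneous_bleeding"


class JaundiceGrade(str, enum.Enum):
    NONE = "none"
    SCLERAL = "scleral"
    SKIN = "skin"


class Outcome(str, enum.Enum):
    DECEASED = "deceased"
    SURVIVED = "survived"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Cause(str, enum.Enum):
    TRAUMATIC = "traumatic"
    NONTRAUMATIC = "nontraumatic"


@dataclass
class PhysiologySnapshot:
    """Raw bedside variables for one patient at one timepoint.

    FiO2 is the inspired-oxygen *fraction*: 55% oxygen is written 0.55, never
    55.  Vasoactive doses are in ug/kg/min.  Laboratory values may be absent
    (``None``) on bedside-only records.
    """

    patient_id: str
    timepoint: Timepoint
    spo2: float  # percent, 0-100
    fio2: float  # fraction, 0.21-1.0
    on_respiratory_support: bool
    bleeding_sign: BleedingSign
    map: float  # mmHg
    dopamine: float  # ug/kg/min
    dobutamine: float
    epinephrine: float
    norepinephrine: float
    jaundice: JaundiceGrade
    gcs: int  # 3-15
    urine_output_per_kg: float  # mL/kg/h
    pao2: Optional[float] = None  # mmHg
    platelets: Optional[float] = None  # 10^3/uL
    bilirubin: Optional[float] = None  # mg/dL
    creatinine: Optional[float] = None  # mg/dL
    urine_output_daily: Optional[float] = None  # mL/day

    def __post_init__(self):
        self.timepoint = Timepoint(self.timepoint)
        self.bleeding_sign = BleedingSign(self.bleeding_sign)
        self.jaundice = JaundiceGrade(self.jaundice)
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValidationError(
                f"fio2={self.fio2!r} out of range [0.21, 1.0]; FiO2 is an "
                "inspired-oxygen fraction (55% is written 0.55)"
            )
        if not 0.0 <= self.spo2 <= 100.0:
            raise ValidationError(f"spo2={self.spo2!r} out of range [0, 100]")
        if not (isinstance(self.gcs, (int,)) and 3 <= self.gcs <= 15):
            raise ValidationError(f"gcs={self.gcs!r} must be an integer in [3, 15]")
        for name in ("dopamine", "dobutamine", "epinephrine", "norepinephrine"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} dose must be >= 0")
        if self.urine_output_per_kg < 0:
            raise ValidationError("urine_output_per_kg must be >= 0")
        for name in ("pao2", "platelets", "bilirubin", "creatinine", "urine_output_daily"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0 when present")


@dataclass(frozen=True)
class ScorePanel:
    """Six organ subscores (0-4 each) and their total (0-24) for one instrument."""

    instrument: Instrument
    timepoint: Timepoint
    respiratory: int
    coagulation: int
    cardiovascular: int
    liver: int
    cns: int
    renal: int

    def __post_init__(self):
        object.__setattr__(self, "instrument", Instrument(self.instrument))
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))
        for organ in ORGAN_ORDER:
            v = getattr(self, organ.value)
            if not (isinstance(v, int) and 0 <= v <= 4):
                raise ValidationError(f"{organ.value} subscore {v!r} not an integer in [0, 4]")
        if self.instrument is Instrument.MSOFA:
            for organ in (OrganSystem.COAGULATION, OrganSystem.LIVER):
                if getattr(self, organ.value) % 2:
                    raise ValidationError(
                        f"MSOFA {organ.value} subscore must be 0, 2 or 4 "
                        "(clinical grading has no odd grades)"
                    )

    @property
    def total(self) -> int:
        return sum(getattr(self, organ.value) for organ in ORGAN_ORDER)

    def subscores(self) -> dict:
        return {organ.value: getattr(self, organ.value) for organ in ORGAN_ORDER}


@dataclass
class CohortRecord:
    """One patient: demographics, ICU outcome, and up to three snapshots."""

    patient_id: str
    age: float
    sex: Sex
    cause: Cause
    outcome: Outcome
    snapshots: dict = field(default_factory=dict)  # Timepoint -> PhysiologySnapshot
    ventilation_days: Optional[float] = None
    icu_days: Optional[float] = None
    hospital_days: Optional[float] = None

    def __post_init__(self):
        self.sex = Sex(self.sex)
        self.cause = Cause(self.cause)
        self.outcome = Outcome(self.outcome)
        self.snapshots = {Timepoint(k): v for k, v in self.snapshots.items()}


SNAPSHOT_FIELDS = tuple(f.name for f in fields(PhysiologySnapshot))
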