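"""Synthetic ICU cohorts for exercising the scoring and evaluation pipeline.

No patient-level data accompany the study this package models, so cohorts are
simulated at two levels:

* **score level** — per patient and timepoint, a bivariate-normal (SOFA, MSOFA)
  total is drawn with group-specific means/SDs for deceased and survived
  patients and a cross-instrument correlation rho.  This is the calibration
  target for the evaluation pipeline.
* **physiology level** — a target MSOFA panel is drawn per patient-timepoint
  (total allocated over the six organs), then raw bedside physiology is
  sampled *inside* the band that maps back to each target subscore, so the
  scoring engine reproduces the target panel exactly.  Laboratory variables
  (PaO2, platelets, bilirubin, creatinine) are sampled in the band matching
  the same clinical grade, so SOFA totals track MSOFA totals.

The default calibration reproduces the published two-group summary statistics:
250 patients (78 deceased / 172 survived), group means/SDs per instrument and
timepoint, rho = 0.95, and exact demographic counts (101 traumatic admissions,
154 male).  One seeded generator drives all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import (
    ORGAN_ORDER,
    BleedingSign,
    Cause,
    CohortRecord,
    Instrument,
    JaundiceGrade,
    Outcome,
    OrganSystem,
    PhysiologySnapshot,
    ScorePanel,
    Sex,
    Timepoint,
)

__all__ = [
    "GroupScoreParams",
    "GeneratorConfig",
    "default_calibration",
    "generate_score_cohort",
    "generate_physiology_cohort",
]

TIMEPOINTS = (Timepoint.T0, Timepoint.T24, Timepoint.T48)


@dataclass(frozen=True)
class GroupScoreParams:
    """Normal parameters of one instrument's total at one timepoint."""

    mean_deceased: float
    sd_deceased: float
    mean_survived: float
    sd_survived: float

    def __post_init__(self):
        if self.sd_deceased <= 0 or self.sd_survived <= 0:
            raise ValidationError("score SDs must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the cohort generators need, in one validated object."""

    n_deceased: int
    n_survived: int
    score_params: Dict[Tuple[Instrument, Timepoint], GroupScoreParams]
    rho: float = 0.95
    age_deceased: Tuple[float, float] = (51.29, 17.72)  # mean, SD (years)
    age_survived: Tuple[float, float] = (43.55, 19.78)
    n_male_deceased: int = 41
    n_male_survived: int = 113
    n_traumatic: int = 101
    seed: int = 0

    def __post_init__(self):
        if self.n_deceased <= 0 or self.n_survived <= 0:
            raise ValidationError("group sizes must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho={self.rho!r} outside [-1, 1]")
        if self.age_deceased[1] <= 0 or self.age_survived[1] <= 0:
            raise ValidationError("age SDs must be > 0")
        if not 0 <= self.n_male_deceased <= self.n_deceased:
            raise ValidationError("n_male_deceased exceeds group size")
        if not 0 <= self.n_male_survived <= self.n_survived:
            raise ValidationError("n_male_survived exceeds group size")
        if not 0 <= self.n_traumatic <= self.n_deceased + self.n_survived:
            raise ValidationError("n_traumatic exceeds cohort size")
        for key in (
            (inst, tp) for inst in (Instrument.SOFA, Instrument.MSOFA) for tp in TIMEPOINTS
        ):
            if key not in self.score_params:
                raise ValidationError(f"score_params missing {key}")

    @property
    def n_total(self) -> int:
        return self.n_deceased + self.n_survived

    @property
    def prevalence(self) -> float:
        return self.n_deceased / self.n_total

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def default_calibration(seed: int = 0) -> GeneratorConfig:
    """The published-cohort calibration: 78 deceased / 172 survived with the
    reported group means and SDs of both instruments at admission, 24 h and
    48 h, and cross-instrument correlation 0.95 (reported range 0.942-0.972)."""
    p = {
        (Instrument.MSOFA, Timepoint.T0): GroupScoreParams(9.93, 3.17, 5.98, 2.62),
        (Instrument.MSOFA, Timepoint.T24): GroupScoreParams(14.67, 3.88, 5.19, 2.49),
        (Instrument.MSOFA, Timepoint.T48): GroupScoreParams(14.26, 3.88, 5.54, 2.55),
        (Instrument.SOFA, Timepoint.T0): GroupScoreParams(10.92, 3.06, 6.31, 2.94),
        (Instrument.SOFA, Timepoint.T24): GroupScoreParams(15.71, 3.60, 5.51, 2.83),
        (Instrument.SOFA, Timepoint.T48): GroupScoreParams(15.27, 3.30, 5.98, 2.85),
    }
    return GeneratorConfig(n_deceased=78, n_survived=172, score_params=p, seed=seed)


# ---------------------------------------------------------------------------
# score-level generator
# ---------------------------------------------------------------------------


def generate_score_cohort(config: GeneratorConfig, round_scores: bool = False) -> pd.DataFrame:
    """Draw per-patient (SOFA, MSOFA) totals at the three timepoints.

    Returns a long-format frame with columns ``patient_id, outcome, timepoint,
    sofa, msofa``.  Scores are bivariate normal with the group parameters and
    correlation ``config.rho``; with ``round_scores`` they are rounded to
    integers and clipped to [0, 24] (evaluation defaults to unrounded).
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    groups = (
        (Outcome.DECEASED, config.n_deceased, 0),
        (Outcome.SURVIVED, config.n_survived, config.n_deceased),
    )
    for outcome, n, offset in groups:
        for tp in TIMEPOINTS:
            ps = config.score_params[(Instrument.SOFA, tp)]
            pm = config.score_params[(Instrument.MSOFA, tp)]
            if outcome is Outcome.DECEASED:
                mu = [ps.mean_deceased, pm.mean_deceased]
                sd = [ps.sd_deceased, pm.sd_deceased]
            else:
                mu = [ps.mean_survived, pm.mean_survived]
                sd = [ps.sd_survived, pm.sd_survived]
            cov = [
                [sd[0] ** 2, config.rho * sd[0] * sd[1]],
                [config.rho * sd[0] * sd[1], sd[1] ** 2],
            ]
            draws = rng.multivariate_normal(mu, cov, size=n)
            if round_scores:
                draws = np.clip(np.rint(draws), 0, 24)
            for i in range(n):
                rows.append(
                    {
                        "patient_id": f"P{offset + i + 1:04d}",
                        "outcome": outcome.value,
                        "timepoint": tp.value,
                        "sofa": draws[i, 0],
                        "msofa": draws[i, 1],
                    }
                )
    df = pd.DataFrame(rows)
    return df.sort_values(["patient_id", "timepoint"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# physiology-level generator
# ---------------------------------------------------------------------------


def _allocate_subscores(total: int, rng: np.random.Generator) -> List[int]:
    """Apportion a target MSOFA total over the six organs.

    Largest-remainder apportionment over Dirichlet-jittered weights, then the
    coagulation and liver grades are remapped to the nearest even value (the
    bedside grades have no odd levels) with the unit difference compensated on
    another organ so the total is preserved exactly.
    """
    if not 0 <= total <= 24:
        raise ValidationError(f"target total {total} outside [0, 24]")
    if total == 0:
        return [0] * 6
    weights = rng.dirichlet(np.full(6, 2.0))
    quota = np.minimum(total * weights, 4.0)
    scores = np.floor(quota).astype(int)
    frac_order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    # distribute the remainder one unit at a time, largest fraction first
    while scores.sum() < total:
        progressed = False
        for idx in frac_order:
            if scores.sum() == total:
                break
            if scores[idx] < 4:
                scores[idx] += 1
                progressed = True
        if not progressed:  # pragma: no cover - total <= 24 guarantees room
            raise ValidationError("allocation failed")

    even_idx = [ORGAN_ORDER.index(OrganSystem.COAGULATION), ORGAN_ORDER.index(OrganSystem.LIVER)]
    unit_idx = [i for i in range(6) if i not in even_idx]
    for idx in even_idx:
        if scores[idx] % 2 == 0:
            continue
        # nearest even grades are +-1 away; pick a direction a unit organ can absorb
        up_ok = scores[idx] < 4 and any(scores[i] > 0 for i in unit_idx)
        down_ok = any(scores[i] < 4 for i in unit_idx)
        go_up = up_ok and (not down_ok or rng.random() < 0.5)
        if go_up:
            scores[idx] += 1
            donor = rng.choice([i for i in unit_idx if scores[i] > 0])
            scores[donor] -= 1
        else:
            scores[idx] -= 1
            taker = rng.choice([i for i in unit_idx if scores[i] < 4])
            scores[taker] += 1
    assert scores.sum() == total and all(0 <= s <= 4 for s in scores)
    return [int(s) for s in scores]


# Sampling ranges per target MSOFA grade.  Each range lies strictly inside the
# band that maps back to the grade, with a margin so floating-point round trips
# through ratio arithmetic cannot cross a band edge.
_SF_RATIO = {0: (402.0, 474.0), 1: (316.0, 399.0), 2: (236.0, 313.0), 3: (151.0, 233.0), 4: (80.0, 148.0)}
_PF_RATIO = {0: (405.0, 495.0), 1: (305.0, 395.0), 2: (205.0, 295.0), 3: (105.0, 195.0), 4: (45.0, 95.0)}
_PLATELETS = {0: (160.0, 380.0), 2: (55.0, 95.0), 4: (6.0, 18.0)}
_BILIRUBIN = {0: (0.3, 1.1), 2: (2.2, 5.7), 4: (12.5, 24.0)}
_GCS = {0: (15, 15), 1: (13, 14), 2: (10, 12), 3: (6, 9), 4: (3, 5)}
_URINE_PKG = {0: (0.55, 1.8), 1: (0.31, 0.48), 2: (0.21, 0.29), 3: (0.11, 0.19), 4: (0.0, 0.09)}
_CREATININE = {0: (0.5, 1.1), 1: (1.25, 1.9), 2: (2.05, 3.35), 3: (3.55, 4.85), 4: (5.1, 8.5)}
_BLEEDING = {0: BleedingSign.NONE, 2: BleedingSign.PETECHIAE, 4: BleedingSign.SPONTANEOUS}
_JAUNDICE = {0: JaundiceGrade.NONE, 2: JaundiceGrade.SCLERAL, 4: JaundiceGrade.SKIN}


def _snapshot_for_panel(
    patient_id: str,
    tp: Timepoint,
    sub: Dict[OrganSystem, int],
    weight_kg: float,
    rng: np.random.Generator,
) -> PhysiologySnapshot:
    g_resp = sub[OrganSystem.RESPIRATORY]
    ratio = rng.uniform(*_SF_RATIO[g_resp])
    fio2_low = float(np.clip(60.0 / ratio, 0.21, 0.95))
    fio2_high = min(1.0, 100.0 / ratio - 1e-4)
    fio2 = rng.uniform(fio2_low, max(fio2_low + 1e-4, fio2_high))
    spo2 = ratio * fio2
    pao2 = rng.uniform(*_PF_RATIO[g_resp]) * fio2

    g_cv = sub[OrganSystem.CARDIOVASCULAR]
    dop = dob = epi = nor = 0.0
    if g_cv == 0:
        map_ = rng.uniform(72.0, 105.0)
    else:
        map_ = rng.uniform(45.0, 68.0)
        if g_cv == 2:
            dop = rng.uniform(1.0, 4.9)
        elif g_cv == 3:
            if rng.random() < 0.5:
                dop = rng.uniform(5.2, 14.5)
            else:
                nor = rng.uniform(0.02, 0.095)
        elif g_cv == 4:
            nor = rng.uniform(0.12, 0.8)

    g_renal = sub[OrganSystem.RENAL]
    upk = rng.uniform(*_URINE_PKG[g_renal])
    g_cns = sub[OrganSystem.CNS]

    return PhysiologySnapshot(
        patient_id=patient_id,
        timepoint=tp,
        spo2=float(spo2),
        fio2=float(fio2),
        on_respiratory_support=g_resp >= 3,
        bleeding_sign=_BLEEDING[sub[OrganSystem.COAGULATION]],
        map=float(map_),
        dopamine=float(dop),
        dobutamine=float(dob),
        epinephrine=float(epi),
        norepinephrine=float(nor),
        jaundice=_JAUNDICE[sub[OrganSystem.LIVER]],
        gcs=int(rng.integers(_GCS[g_cns][0], _GCS[g_cns][1] + 1)),
        urine_output_per_kg=float(upk),
        pao2=float(pao2),
        platelets=float(rng.uniform(*_PLATELETS[sub[OrganSystem.COAGULATION]])),
        bilirubin=float(rng.uniform(*_BILIRUBIN[sub[OrganSystem.LIVER]])),
        creatinine=float(rng.uniform(*_CREATININE[g_renal])),
        urine_output_daily=float(upk * weight_kg * 24.0),
    )


def _exact_count_labels(n: int, k: int, positive, negative, rng) -> list:
    """k positive labels among n, in seeded random order (exact counts)."""
    labels = np.array([1] * k + [0] * (n - k))
    rng.shuffle(labels)
    return [positive if v else negative for v in labels]


def generate_physiology_cohort(config: GeneratorConfig, return_targets: bool = False):
    """Generate full patient records whose bedside physiology scores back to a
    drawn MSOFA target panel exactly.

    Per patient-timepoint, the target MSOFA total is a rounded, clipped draw
    from the group normal; the total is apportioned over organs; physiology is
    sampled inside the matching bands.  Demographics use exact published
    counts (sex within outcome group, traumatic cause cohort-wide) in seeded
    random order.

    With ``return_targets`` the drawn target panels are returned alongside the
    records, keyed by (patient_id, timepoint), so the round trip through the
    scoring engine can be audited.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_total

    outcomes = [Outcome.DECEASED] * config.n_deceased + [Outcome.SURVIVED] * config.n_survived
    sex_d = _exact_count_labels(config.n_deceased, config.n_male_deceased, Sex.MALE, Sex.FEMALE, rng)
    sex_s = _exact_count_labels(config.n_survived, config.n_male_survived, Sex.MALE, Sex.FEMALE, rng)
    sexes = sex_d + sex_s
    causes = _exact_count_labels(n, config.n_traumatic, Cause.TRAUMATIC, Cause.NONTRAUMATIC, rng)

    records: List[CohortRecord] = []
    targets: Dict[tuple, ScorePanel] = {}
    for i in range(n):
        outcome = outcomes[i]
        age_mu, age_sd = config.age_deceased if outcome is Outcome.DECEASED else config.age_survived
        age = float(np.clip(rng.normal(age_mu, age_sd), 18.0, 95.0))
        weight = float(rng.uniform(55.0, 95.0))
        pid = f"P{i + 1:04d}"
        snapshots = {}
        for tp in TIMEPOINTS:
            pm = config.score_params[(Instrument.MSOFA, tp)]
            mu, sd = (
                (pm.mean_deceased, pm.sd_deceased)
                if outcome is Outcome.DECEASED
                else (pm.mean_survived, pm.sd_survived)
            )
            total = int(np.clip(np.rint(rng.normal(mu, sd)), 0, 24))
            sub = dict(zip(ORGAN_ORDER, _allocate_subscores(total, rng)))
            snapshots[tp] = _snapshot_for_panel(pid, tp, sub, weight, rng)
            targets[(pid, tp)] = ScorePanel(
                instrument=Instrument.MSOFA,
                timepoint=tp,
                **{organ.value: grade for organ, grade in sub.items()},
            )
        records.append(
            CohortRecord(
                patient_id=pid,
                age=age,
                sex=sexes[i],
                cause=causes[i],
                outcome=outcome,
                snapshots=snapshots,
            )
        )
    if return_targets:
        return records, targets
    return records
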