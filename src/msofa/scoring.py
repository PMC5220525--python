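"""Organ-failure scoring: original SOFA and the bedside modified score (MSOFA).

Both instruments grade six organ systems 0-4 and sum to a 0-24 total.  SOFA
reads laboratory values (PaO2/FiO2, platelets, bilirubin, creatinine); MSOFA
replaces each laboratory component with a bedside observation (SpO2/FiO2 from
pulse oximetry, bleeding signs, jaundice grade, hourly urine output per kg).
Scoring is deterministic band-table lookup; missing required variables raise
:class:`~msofa.errors.MissingDataError` rather than scoring 0.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from . import bands
from .errors import MissingDataError, ValidationError
from .types import (
    ORGAN_ORDER,
    BleedingSign,
    Instrument,
    JaundiceGrade,
    OrganSystem,
    PhysiologySnapshot,
    ScorePanel,
)

__all__ = ["score_component", "score_panel", "worst_panel"]


def _require(snapshot: PhysiologySnapshot, name: str) -> float:
    value = getattr(snapshot, name)
    if value is None:
        raise MissingDataError(name)
    return value


def _respiratory_from_ratio(ratio: float, band_table, on_support: bool) -> int:
    if ratio > band_table[0][0]:
        return 0
    for edge, score in band_table[1:-1]:
        if ratio >= edge:
            return min(score, bands.RESPIRATORY_SUPPORT_CAP) if not on_support else score
    score = band_table[-1][1]
    return score if on_support else bands.RESPIRATORY_SUPPORT_CAP


def _score_respiratory(s: PhysiologySnapshot, instrument: Instrument) -> int:
    if instrument is Instrument.MSOFA:
        ratio = s.spo2 / s.fio2
        return _respiratory_from_ratio(ratio, bands.SPO2_FIO2_BANDS, s.on_respiratory_support)
    pao2 = _require(s, "pao2")
    ratio = pao2 / s.fio2
    # SOFA convention: ratio exactly 400 still scores 0.
    if ratio >= bands.PAO2_FIO2_BANDS[0][0]:
        return 0
    return _respiratory_from_ratio(ratio, bands.PAO2_FIO2_BANDS, s.on_respiratory_support)


def _score_coagulation(s: PhysiologySnapshot, instrument: Instrument) -> int:
    if instrument is Instrument.MSOFA:
        return bands.BLEEDING_SCORES[BleedingSign(s.bleeding_sign).value]
    platelets = _require(s, "platelets")
    for edge, score in bands.PLATELET_BANDS[:-1]:
        if platelets >= edge:
            return score
    return bands.PLATELET_BANDS[-1][1]


def _score_cardiovascular(s: PhysiologySnapshot, instrument: Instrument) -> int:
    # Shared between instruments: MAP plus vasoactive dose bands (ug/kg/min).
    if (
        s.dopamine > bands.DOPAMINE_HIGH
        or s.epinephrine > bands.EPI_NOREPI_HIGH
        or s.norepinephrine > bands.EPI_NOREPI_HIGH
    ):
        return 4
    if s.dopamine > bands.DOPAMINE_MID or s.epinephrine > 0 or s.norepinephrine > 0:
        return 3
    if s.dopamine > 0 or s.dobutamine > 0:
        return 2
    if s.map < bands.MAP_HYPOTENSION:
        return 1
    return 0


def _score_liver(s: PhysiologySnapshot, instrument: Instrument) -> int:
    if instrument is Instrument.MSOFA:
        return bands.JAUNDICE_SCORES[JaundiceGrade(s.jaundice).value]
    bilirubin = _require(s, "bilirubin")
    for edge, score in bands.BILIRUBIN_BANDS[:-1]:
        if bilirubin < edge:
            return score
    return bands.BILIRUBIN_BANDS[-1][1]


def _score_cns(s: PhysiologySnapshot, instrument: Instrument) -> int:
    gcs = s.gcs
    for edge, score in bands.GCS_BANDS[:-1]:
        if gcs >= edge:
            return score
    return bands.GCS_BANDS[-1][1]


def _score_renal(s: PhysiologySnapshot, instrument: Instrument) -> int:
    if instrument is Instrument.MSOFA:
        urine = s.urine_output_per_kg
        for edge, score in bands.URINE_PER_KG_BANDS[:-1]:
            if urine >= edge:
                return score
        return bands.URINE_PER_KG_BANDS[-1][1]
    creatinine = _require(s, "creatinine")
    score = bands.CREATININE_BANDS[-1][1]
    for edge, band_score in bands.CREATININE_BANDS[:-1]:
        if creatinine < edge:
            score = band_score
            break
    if s.urine_output_daily is not None:
        if s.urine_output_daily < bands.URINE_DAILY_SCORE_4:
            score = max(score, 4)
        elif s.urine_output_daily < bands.URINE_DAILY_SCORE_3:
            score = max(score, 3)
    return score


_SCORERS = {
    OrganSystem.RESPIRATORY: _score_respiratory,
    OrganSystem.COAGULATION: _score_coagulation,
    OrganSystem.CARDIOVASCULAR: _score_cardiovascular,
    OrganSystem.LIVER: _score_liver,
    OrganSystem.CNS: _score_cns,
    OrganSystem.RENAL: _score_renal,
}


def score_component(
    snapshot: PhysiologySnapshot, system: OrganSystem, instrument: Instrument
) -> int:
    """Score one organ system (0-4) for the given instrument.

    Raises :class:`MissingDataError` naming the absent variable when a
    laboratory value required by SOFA is not on the snapshot.
    """
    system = OrganSystem(system)
    instrument = Instrument(instrument)
    return _SCORERS[system](snapshot, instrument)


def score_panel(snapshot: PhysiologySnapshot, instrument: Instrument) -> ScorePanel:
    """Score all six organ systems and assemble the panel.

    Collects missing-variable problems across *all* systems before raising, so
    the error names every unscorable system at once.
    """
    instrument = Instrument(instrument)
    scores = {}
    missing = []
    for system in ORGAN_ORDER:
        try:
            scores[system.value] = score_component(snapshot, system, instrument)
        except MissingDataError as exc:
            missing.extend(f"{system.value}: {v}" for v in exc.variables)
    if missing:
        raise MissingDataError(missing, context=f"snapshot {snapshot.patient_id}/{snapshot.timepoint.value}")
    return ScorePanel(instrument=instrument, timepoint=snapshot.timepoint, **scores)


def worst_panel(panels: Sequence[ScorePanel]) -> ScorePanel:
    """Worst-of-day aggregation: element-wise maximum of each organ subscore.

    All panels must share one instrument and timepoint (repeat measurements of
    the same patient-day); the total is recomputed from the maxima.
    Commutative, associative and idempotent.
    """
    panels = list(panels)
    if not panels:
        raise ValidationError("worst_panel requires at least one panel")
    instruments = {p.instrument for p in panels}
    if len(instruments) > 1:
        raise ValidationError("worst_panel: panels mix instruments")
    timepoints = {p.timepoint for p in panels}
    if len(timepoints) > 1:
        raise ValidationError("worst_panel: panels mix timepoints")
    maxima = {
        organ.value: max(getattr(p, organ.value) for p in panels) for organ in ORGAN_ORDER
    }
    return ScorePanel(instrument=panels[0].instrument, timepoint=panels[0].timepoint, **maxima)
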