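"""Band tables for both scoring instruments, collected in one place.

Every threshold that either instrument uses lives here so that the boundary
convention can be audited (and swept by tests) in a single file.  Convention:
each band is left-closed on its *worse* side — a value exactly on an edge takes
the worse score, except where a table below states otherwise explicitly.

The SOFA tables are the canonical published definition.  The MSOFA bedside
tables (SpO2/FiO2 ratio, urine output in mL/kg/h) span the full 0-4 range; the
coagulation and liver bedside grades are three-level clinical assessments and
can only produce 0, 2 or 4.
"""

from __future__ import annotations

# --- Respiratory ----------------------------------------------------------
# SpO2/FiO2 ratio (MSOFA).  Scores 3 and 4 additionally require respiratory
# support (ventilator or airway oxygen); without support the score caps at 2.
SPO2_FIO2_BANDS = (
    (400.0, 0),  # ratio >  400 -> 0
    (315.0, 1),  # 315 <= ratio <= 400 -> 1
    (235.0, 2),  # 235 <= ratio <  315 -> 2
    (150.0, 3),  # 150 <= ratio <  235 -> 3 (with support)
    (None, 4),   # ratio <  150 -> 4 (with support)
)

# PaO2/FiO2 ratio (SOFA), same support rule for scores 3-4.
PAO2_FIO2_BANDS = (
    (400.0, 0),  # ratio >= 400 -> 0
    (300.0, 1),  # 300 <= ratio < 400 -> 1
    (200.0, 2),  # 200 <= ratio < 300 -> 2
    (100.0, 3),  # 100 <= ratio < 200 -> 3 (with support)
    (None, 4),   # ratio <  100 -> 4 (with support)
)

RESPIRATORY_SUPPORT_CAP = 2  # max score without respiratory support

# --- Coagulation ----------------------------------------------------------
# SOFA: platelet count, 10^3/uL; value >= edge -> that score's band ends.
PLATELET_BANDS = (
    (150.0, 0),  # >= 150 -> 0
    (100.0, 1),  # >= 100 -> 1
    (50.0, 2),   # >= 50 -> 2
    (20.0, 3),   # >= 20 -> 3
    (None, 4),   # <  20 -> 4
)

# MSOFA: bedside bleeding assessment.
BLEEDING_SCORES = {
    "none": 0,
    "petechiae_purpura_ecchymosis": 2,
    "spontaneous_bleeding": 4,
}

# --- Cardiovascular (shared) ----------------------------------------------
MAP_HYPOTENSION = 70.0  # mmHg
DOPAMINE_MID = 5.0      # ug/kg/min: dose <= 5 scores 2, > 5 scores 3
DOPAMINE_HIGH = 15.0    # dose > 15 scores 4
EPI_NOREPI_HIGH = 0.1   # epinephrine/norepinephrine dose > 0.1 scores 4

# --- Liver -----------------------------------------------------------------
# SOFA: total bilirubin, mg/dL.
BILIRUBIN_BANDS = (
    (1.2, 0),   # <  1.2 -> 0
    (2.0, 1),   # 1.2 - 1.9 -> 1
    (6.0, 2),   # 2.0 - 5.9 -> 2
    (12.0, 3),  # 6.0 - 11.9 -> 3
    (None, 4),  # >= 12 -> 4
)

# MSOFA: bedside jaundice grade.
JAUNDICE_SCORES = {"none": 0, "scleral": 2, "skin": 4}

# --- Central nervous system (shared) ---------------------------------------
# Glasgow Coma Scale: lower = worse.
GCS_BANDS = (
    (15, 0),   # 15 -> 0
    (13, 1),   # 13-14 -> 1
    (10, 2),   # 10-12 -> 2
    (6, 3),    # 6-9 -> 3
    (None, 4), # 3-5 -> 4
)

# --- Renal -----------------------------------------------------------------
# SOFA: serum creatinine, mg/dL; the daily-urine criterion below is combined
# with the creatinine band by taking the worse of the two.
CREATININE_BANDS = (
    (1.2, 0),   # <  1.2 -> 0
    (2.0, 1),   # 1.2 - 1.9 -> 1
    (3.5, 2),   # 2.0 - 3.4 -> 2
    (5.0, 3),   # 3.5 - 4.9 -> 3
    (None, 4),  # >= 5.0 -> 4
)
URINE_DAILY_SCORE_3 = 500.0  # mL/day: below -> at least 3
URINE_DAILY_SCORE_4 = 200.0  # mL/day: below -> 4

# MSOFA: hourly urine output normalised to body weight, mL/kg/h.
URINE_PER_KG_BANDS = (
    (0.5, 0),   # >= 0.5 -> 0
    (0.3, 1),   # 0.3 - 0.49 -> 1
    (0.2, 2),   # 0.2 - 0.29 -> 2
    (0.1, 3),   # 0.1 - 0.19 -> 3
    (None, 4),  # <  0.1 -> 4
)
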