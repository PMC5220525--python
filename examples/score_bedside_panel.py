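"""Score one patient-day with both instruments.

Builds a single bedside snapshot for a hypotensive, drowsy patient on
norepinephrine, scores it with the bedside MSOFA and the laboratory SOFA, and
prints the organ subscores.  Higher subscores mean worse organ function;
totals run 0 (all normal) to 24 (every organ failing).
"""

from msofa import Instrument, PhysiologySnapshot, score_panel, worst_panel

snapshot = PhysiologySnapshot(
    patient_id="demo-001",
    timepoint="T0",
    spo2=91.0,
    fio2=0.40,                    # 40% oxygen -> SpO2/FiO2 = 227.5
    on_respiratory_support=True,
    bleeding_sign="petechiae_purpura_ecchymosis",
    map=62.0,
    dopamine=0.0,
    dobutamine=0.0,
    epinephrine=0.0,
    norepinephrine=0.08,          # ug/kg/min, low-dose pressor
    jaundice="scleral",
    gcs=12,
    urine_output_per_kg=0.4,      # mild oliguria
    pao2=70.0,                    # PaO2/FiO2 = 175
    platelets=85.0,
    bilirubin=2.8,
    creatinine=1.6,
    urine_output_daily=700.0,
)

for instrument in (Instrument.MSOFA, Instrument.SOFA):
    panel = score_panel(snapshot, instrument)
    print(f"{instrument.value.upper():6s}", panel.subscores(), "total =", panel.total)

# Worst-of-day aggregation: if the same patient is re-assessed and any organ
# deteriorates, the recorded panel is the element-wise maximum.
evening = score_panel(snapshot, Instrument.MSOFA)
morning = PhysiologySnapshot(**{**snapshot.__dict__, "gcs": 9, "map": 75.0, "norepinephrine": 0.0})
worst = worst_panel([evening, score_panel(morning, Instrument.MSOFA)])
print("worst-of-day MSOFA total =", worst.total)
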