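"""Band-table scoring: worked examples, totality/monotonicity sweeps,
worst-of-day aggregation algebra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msofa import (
    Instrument,
    MissingDataError,
    OrganSystem,
    ScorePanel,
    ValidationError,
    score_component,
    score_panel,
    worst_panel,
)
from msofa.types import ORGAN_ORDER

from conftest import make_snapshot

MSOFA = Instrument.MSOFA
SOFA = Instrument.SOFA


class TestComponentExamples:
    @pytest.mark.parametrize(
        "overrides,system,instrument,expected",
        [
            # bedside coagulation: three-level clinical grade
            ({"bleeding_sign": "spontaneous_bleeding"}, OrganSystem.COAGULATION, MSOFA, 4),
            ({"bleeding_sign": "petechiae_purpura_ecchymosis"}, OrganSystem.COAGULATION, MSOFA, 2),
            # bedside liver: jaundice grade
            ({"jaundice": "scleral"}, OrganSystem.LIVER, MSOFA, 2),
            ({"jaundice": "skin"}, OrganSystem.LIVER, MSOFA, 4),
            # neurological (shared)
            ({"gcs": 15}, OrganSystem.CNS, MSOFA, 0),
            ({"gcs": 15}, OrganSystem.CNS, SOFA, 0),
            ({"gcs": 13}, OrganSystem.CNS, SOFA, 1),
            ({"gcs": 10}, OrganSystem.CNS, SOFA, 2),
            ({"gcs": 6}, OrganSystem.CNS, SOFA, 3),
            ({"gcs": 5}, OrganSystem.CNS, SOFA, 4),
            # cardiovascular: hypotension without vasoactives scores 1
            ({"map": 65.0}, OrganSystem.CARDIOVASCULAR, MSOFA, 1),
            ({"map": 65.0}, OrganSystem.CARDIOVASCULAR, SOFA, 1),
            ({"map": 65.0, "dopamine": 3.0}, OrganSystem.CARDIOVASCULAR, SOFA, 2),
            ({"map": 65.0, "dobutamine": 4.0}, OrganSystem.CARDIOVASCULAR, SOFA, 2),
            ({"map": 65.0, "dopamine": 8.0}, OrganSystem.CARDIOVASCULAR, SOFA, 3),
            ({"map": 65.0, "norepinephrine": 0.05}, OrganSystem.CARDIOVASCULAR, SOFA, 3),
            ({"map": 65.0, "norepinephrine": 0.2}, OrganSystem.CARDIOVASCULAR, SOFA, 4),
            ({"map": 65.0, "dopamine": 20.0}, OrganSystem.CARDIOVASCULAR, SOFA, 4),
            # respiratory: SpO2 99 on room air -> ratio 471 -> 0
            ({"spo2": 99.0, "fio2": 0.21}, OrganSystem.RESPIRATORY, MSOFA, 0),
            # ratio 200 without support caps at 2, with support scores 3
            ({"spo2": 90.0, "fio2": 0.45}, OrganSystem.RESPIRATORY, MSOFA, 2),
            ({"spo2": 90.0, "fio2": 0.45, "on_respiratory_support": True}, OrganSystem.RESPIRATORY, MSOFA, 3),
            ({"spo2": 70.0, "fio2": 0.9, "on_respiratory_support": True}, OrganSystem.RESPIRATORY, MSOFA, 4),
            # SOFA respiratory from PaO2/FiO2
            ({"pao2": 95.0, "fio2": 0.21}, OrganSystem.RESPIRATORY, SOFA, 0),  # ratio 452
            ({"pao2": 75.0, "fio2": 0.21}, OrganSystem.RESPIRATORY, SOFA, 1),  # ratio 357
            ({"pao2": 90.0, "fio2": 0.36}, OrganSystem.RESPIRATORY, SOFA, 2),  # ratio 250
            ({"pao2": 75.0, "fio2": 0.5, "on_respiratory_support": True}, OrganSystem.RESPIRATORY, SOFA, 3),
            ({"pao2": 50.0, "fio2": 0.8, "on_respiratory_support": True}, OrganSystem.RESPIRATORY, SOFA, 4),
            # coagulation SOFA from platelets
            ({"platelets": 150.0}, OrganSystem.COAGULATION, SOFA, 0),
            ({"platelets": 120.0}, OrganSystem.COAGULATION, SOFA, 1),
            ({"platelets": 60.0}, OrganSystem.COAGULATION, SOFA, 2),
            ({"platelets": 30.0}, OrganSystem.COAGULATION, SOFA, 3),
            ({"platelets": 10.0}, OrganSystem.COAGULATION, SOFA, 4),
            # liver SOFA from bilirubin
            ({"bilirubin": 1.0}, OrganSystem.LIVER, SOFA, 0),
            ({"bilirubin": 1.2}, OrganSystem.LIVER, SOFA, 1),
            ({"bilirubin": 3.0}, OrganSystem.LIVER, SOFA, 2),
            ({"bilirubin": 8.0}, OrganSystem.LIVER, SOFA, 3),
            ({"bilirubin": 12.0}, OrganSystem.LIVER, SOFA, 4),
            # renal: MSOFA hourly urine vs SOFA creatinine/daily urine
            ({"urine_output_per_kg": 0.5}, OrganSystem.RENAL, MSOFA, 0),
            ({"urine_output_per_kg": 0.35}, OrganSystem.RENAL, MSOFA, 1),
            ({"urine_output_per_kg": 0.25}, OrganSystem.RENAL, MSOFA, 2),
            ({"urine_output_per_kg": 0.15}, OrganSystem.RENAL, MSOFA, 3),
            ({"urine_output_per_kg": 0.05}, OrganSystem.RENAL, MSOFA, 4),
            ({"creatinine": 1.5}, OrganSystem.RENAL, SOFA, 1),
            ({"creatinine": 2.5}, OrganSystem.RENAL, SOFA, 2),
            ({"creatinine": 4.0}, OrganSystem.RENAL, SOFA, 3),
            ({"creatinine": 5.5}, OrganSystem.RENAL, SOFA, 4),
            # daily-urine criterion dominates a benign creatinine
            ({"creatinine": 0.8, "urine_output_daily": 400.0}, OrganSystem.RENAL, SOFA, 3),
            ({"creatinine": 0.8, "urine_output_daily": 150.0}, OrganSystem.RENAL, SOFA, 4),
        ],
    )
    def test_band_lookup(self, overrides, system, instrument, expected):
        assert score_component(make_snapshot(**overrides), system, instrument) == expected

    def test_missing_lab_blocks_sofa_only(self):
        snap = make_snapshot(pao2=None, platelets=None, bilirubin=None, creatinine=None)
        assert score_panel(snap, MSOFA).total == 0
        with pytest.raises(MissingDataError) as exc:
            score_panel(snap, SOFA)
        msg = str(exc.value)
        for var in ("pao2", "platelets", "bilirubin", "creatinine"):
            assert var in msg

    def test_missing_single_variable_named(self):
        snap = make_snapshot(creatinine=None)
        with pytest.raises(MissingDataError, match="creatinine"):
            score_component(snap, OrganSystem.RENAL, SOFA)

    def test_percent_fio2_rejected(self):
        # FiO2 is a fraction: 55% must be written 0.55
        with pytest.raises(ValidationError, match="fio2"):
            make_snapshot(fio2=55.0)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValidationError):
            make_snapshot(gcs=2)
        with pytest.raises(ValidationError):
            make_snapshot(spo2=105.0)
        with pytest.raises(ValidationError):
            make_snapshot(norepinephrine=-0.1)


class TestPanel:
    def test_normal_snapshot_scores_zero(self, normal_snapshot):
        for inst in (SOFA, MSOFA):
            panel = score_panel(normal_snapshot, inst)
            assert panel.total == 0

    def test_worst_snapshot_scores_24(self, worst_snapshot):
        for inst in (SOFA, MSOFA):
            assert score_panel(worst_snapshot, inst).total == 24

    def test_total_is_sum_of_components(self, rng):
        # totals always equal independently recomputed component sums
        for _ in range(50):
            snap = _random_snapshot(rng)
            for inst in (SOFA, MSOFA):
                panel = score_panel(snap, inst)
                parts = [score_component(snap, organ, inst) for organ in ORGAN_ORDER]
                assert panel.total == sum(parts)
                assert 0 <= panel.total <= 24

    def test_msofa_coag_liver_always_even(self, rng):
        for _ in range(100):
            panel = score_panel(_random_snapshot(rng), MSOFA)
            assert panel.coagulation in (0, 2, 4)
            assert panel.liver in (0, 2, 4)

    def test_odd_msofa_grade_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            ScorePanel(
                instrument=MSOFA, timepoint="T0", respiratory=0, coagulation=1,
                cardiovascular=0, liver=0, cns=0, renal=0,
            )


def _random_snapshot(rng):
    return make_snapshot(
        spo2=float(rng.uniform(60, 100)),
        fio2=float(rng.uniform(0.21, 1.0)),
        on_respiratory_support=bool(rng.random() < 0.5),
        bleeding_sign=str(rng.choice(["none", "petechiae_purpura_ecchymosis", "spontaneous_bleeding"])),
        map=float(rng.uniform(40, 110)),
        dopamine=float(rng.choice([0, 0, 3, 8, 20])),
        norepinephrine=float(rng.choice([0, 0, 0.05, 0.3])),
        jaundice=str(rng.choice(["none", "scleral", "skin"])),
        gcs=int(rng.integers(3, 16)),
        urine_output_per_kg=float(rng.uniform(0, 2)),
        pao2=float(rng.uniform(40, 120)),
        platelets=float(rng.uniform(5, 400)),
        bilirubin=float(rng.uniform(0.2, 20)),
        creatinine=float(rng.uniform(0.4, 8)),
        urine_output_daily=float(rng.uniform(50, 3000)),
    )


class TestBandSweeps:
    """Each band table partitions its domain: every input yields exactly one
    score, and worsening the input never improves the score."""

    @staticmethod
    def _assert_monotone(values, scores):
        scores = np.asarray(scores)
        assert set(np.unique(scores)) <= {0, 1, 2, 3, 4}
        assert np.all(np.diff(scores) >= 0)

    def test_gcs_sweep(self):
        scores = [score_component(make_snapshot(gcs=g), OrganSystem.CNS, SOFA) for g in range(15, 2, -1)]
        self._assert_monotone(range(len(scores)), scores)
        assert scores[0] == 0 and scores[-1] == 4

    def test_spo2_fio2_sweep(self):
        # worsen by lowering the ratio at fixed FiO2, on support
        ratios = np.linspace(470, 60, 600)
        scores = [
            score_component(
                make_snapshot(spo2=min(100.0, r * 0.21), fio2=0.21, on_respiratory_support=True),
                OrganSystem.RESPIRATORY, MSOFA,
            )
            for r in ratios
        ]
        self._assert_monotone(ratios, scores)
        assert scores[0] == 0 and scores[-1] == 4

    def test_pao2_fio2_sweep(self):
        ratios = np.linspace(450, 50, 600)
        scores = [
            score_component(
                make_snapshot(pao2=r * 0.4, fio2=0.4, on_respiratory_support=True),
                OrganSystem.RESPIRATORY, SOFA,
            )
            for r in ratios
        ]
        self._assert_monotone(ratios, scores)
        assert scores[0] == 0 and scores[-1] == 4

    def test_respiratory_support_cap(self):
        # without support neither instrument can exceed 2
        for ratio in np.linspace(40, 230, 50):
            s = make_snapshot(spo2=min(100.0, ratio * 0.3), fio2=0.3, pao2=ratio * 0.3)
            assert score_component(s, OrganSystem.RESPIRATORY, MSOFA) == 2
            assert score_component(s, OrganSystem.RESPIRATORY, SOFA) == 2

    @pytest.mark.parametrize(
        "field,lo,hi,system,instrument,reverse",
        [
            ("platelets", 1.0, 400.0, OrganSystem.COAGULATION, SOFA, True),
            ("bilirubin", 0.1, 20.0, OrganSystem.LIVER, SOFA, False),
            ("creatinine", 0.3, 8.0, OrganSystem.RENAL, SOFA, False),
            ("urine_output_per_kg", 0.0, 2.0, OrganSystem.RENAL, MSOFA, True),
        ],
    )
    def test_lab_sweeps(self, field, lo, hi, system, instrument, reverse):
        grid = np.linspace(lo, hi, 500)
        if reverse:  # lower value is worse
            grid = grid[::-1]
        scores = [score_component(make_snapshot(**{field: float(v)}), system, instrument) for v in grid]
        self._assert_monotone(grid, scores)
        assert scores[0] == 0 and scores[-1] == 4

    def test_map_sweep_no_drugs(self):
        scores = [
            score_component(make_snapshot(map=float(m)), OrganSystem.CARDIOVASCULAR, SOFA)
            for m in np.linspace(110, 40, 200)
        ]
        self._assert_monotone(range(len(scores)), scores)
        assert scores[0] == 0 and scores[-1] == 1

    def test_bleeding_and_jaundice_grades_monotone(self):
        bl = [score_component(make_snapshot(bleeding_sign=b), OrganSystem.COAGULATION, MSOFA)
              for b in ("none", "petechiae_purpura_ecchymosis", "spontaneous_bleeding")]
        ja = [score_component(make_snapshot(jaundice=j), OrganSystem.LIVER, MSOFA)
              for j in ("none", "scleral", "skin")]
        assert bl == [0, 2, 4] and ja == [0, 2, 4]


subscore = st.integers(min_value=0, max_value=4)
even_subscore = st.sampled_from([0, 2, 4])


@st.composite
def panels(draw, instrument=SOFA):
    coag = draw(even_subscore if instrument is MSOFA else subscore)
    liver = draw(even_subscore if instrument is MSOFA else subscore)
    return ScorePanel(
        instrument=instrument,
        timepoint="T0",
        respiratory=draw(subscore),
        coagulation=coag,
        cardiovascular=draw(subscore),
        liver=liver,
        cns=draw(subscore),
        renal=draw(subscore),
    )


class TestWorstPanel:
    def test_single_panel_identity(self):
        p = ScorePanel(instrument=SOFA, timepoint="T0", respiratory=2, coagulation=0,
                       cardiovascular=0, liver=0, cns=0, renal=0)
        assert worst_panel([p]) == p

    def test_elementwise_max_example(self):
        a = ScorePanel(instrument=SOFA, timepoint="T0", respiratory=2, coagulation=0,
                       cardiovascular=0, liver=0, cns=0, renal=0)
        b = ScorePanel(instrument=SOFA, timepoint="T0", respiratory=0, coagulation=0,
                       cardiovascular=0, liver=0, cns=3, renal=0)
        w = worst_panel([a, b])
        assert (w.respiratory, w.cns, w.total) == (2, 3, 5)

    def test_empty_and_mixed_inputs_rejected(self):
        p = ScorePanel(instrument=SOFA, timepoint="T0", respiratory=0, coagulation=0,
                       cardiovascular=0, liver=0, cns=0, renal=0)
        q = ScorePanel(instrument=MSOFA, timepoint="T0", respiratory=0, coagulation=0,
                       cardiovascular=0, liver=0, cns=0, renal=0)
        r = ScorePanel(instrument=SOFA, timepoint="T24", respiratory=0, coagulation=0,
                       cardiovascular=0, liver=0, cns=0, renal=0)
        with pytest.raises(ValidationError):
            worst_panel([])
        with pytest.raises(ValidationError):
            worst_panel([p, q])
        with pytest.raises(ValidationError):
            worst_panel([p, r])

    @given(panels(), panels(), panels())
    def test_commutative_associative_idempotent(self, a, b, c):
        assert worst_panel([a, b]) == worst_panel([b, a])
        assert worst_panel([worst_panel([a, b]), c]) == worst_panel([a, worst_panel([b, c])])
        assert worst_panel([a, a]) == a
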