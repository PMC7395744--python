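"""Gold-standard labelers: suspected infection, SOFA, Sepsis-3, KDIGO, ALI."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from earlywarn.gold_standards import (
    detect_suspected_infection,
    label_admission,
    label_aki,
    label_ali,
    label_sepsis,
    sofa_score,
)
from tests.conftest import T0, make_timeline
from tests.oracles import oracle_aki, oracle_ali, oracle_sepsis

H = pd.Timedelta(hours=1)
DIS = T0 + pd.Timedelta(hours=200)


class TestSuspectedInfection:
    def test_culture_then_antibiotic_within_72h(self):
        tl = make_timeline(
            [(10, "culture_sample", 1), (81, "antibiotic_administration", 1)], discharge=DIS
        )
        si = detect_suspected_infection(tl)
        assert si is not None and si.si_time == T0 + 10 * H

    def test_antibiotic_then_culture_outside_24h_is_none(self):
        tl = make_timeline(
            [(10, "antibiotic_administration", 1), (35.5, "culture_sample", 1)], discharge=DIS
        )
        assert detect_suspected_infection(tl) is None

    def test_antibiotic_then_culture_within_24h_anchors_at_antibiotic(self):
        tl = make_timeline(
            [(10, "antibiotic_administration", 1), (30, "culture_sample", 1)], discharge=DIS
        )
        si = detect_suspected_infection(tl)
        assert si is not None and si.si_time == T0 + 10 * H

    def test_earliest_qualifying_pair_wins(self):
        tl = make_timeline(
            [
                (10, "culture_sample", 1),
                (20, "antibiotic_administration", 1),
                (90, "antibiotic_administration", 1),
            ],
            discharge=DIS,
        )
        si = detect_suspected_infection(tl)
        assert si.si_time == T0 + 10 * H

    def test_no_events_is_none(self):
        assert detect_suspected_infection(make_timeline([(1, "Pulse rate", 80)])) is None


class TestSofaScore:
    def test_normal_snapshot_scores_zero(self):
        snap = {
            "B-Platelets": 250,
            "P-Bilirubin": 10,
            "Systolic blood pressure": 120,
            "Diastolic blood pressure": 80,
            "P-Creatinine": 80,
            "SpO2": 98,
        }
        assert sofa_score(snap) == 0

    @pytest.mark.parametrize(
        "snap, expected",
        [
            ({"B-Platelets": 90}, 2),  # coagulation band 50-99
            ({"P-Bilirubin": 40, "B-Platelets": 90}, 4),  # liver 2 + coagulation 2
            ({"P-Creatinine": 350}, 3),
            ({"Systolic blood pressure": 80, "Diastolic blood pressure": 50}, 1),
            ({"SpO2": 88}, 2),
        ],
    )
    def test_subsystem_bands_are_additive(self, snap, expected):
        assert sofa_score(snap) == expected

    def test_all_missing_warns_and_scores_zero(self):
        with pytest.warns(UserWarning, match="no available"):
            assert sofa_score({}) == 0


def _sepsis_timeline(sofa_rise: int, with_si: bool = True):
    """SI at hour 60; platelets drop to produce the requested coagulation rise."""
    platelets_low = {0: 250, 1: 120, 2: 90, 3: 40}[sofa_rise]
    events = [(5, "B-Platelets", 250), (40, "B-Platelets", 250), (62, "B-Platelets", platelets_low)]
    if with_si:
        events += [(60, "culture_sample", 1), (70, "antibiotic_administration", 1)]
    return make_timeline(events, discharge=DIS)


class TestLabelSepsis:
    def test_constant_sofa_is_negative(self):
        assert not label_sepsis(_sepsis_timeline(0)).positive

    def test_sofa_rise_of_two_with_si_is_positive_anchored_at_si(self):
        label = label_sepsis(_sepsis_timeline(2))
        assert label.positive and label.onset_time == T0 + 60 * H

    def test_rise_of_one_is_negative(self):
        assert not label_sepsis(_sepsis_timeline(1)).positive

    def test_sofa_rise_without_si_is_negative(self):
        assert not label_sepsis(_sepsis_timeline(3, with_si=False)).positive


class TestLabelAki:
    def test_absolute_rise_at_threshold_fires(self):
        tl = make_timeline([(10, "P-Creatinine", 60), (50, "P-Creatinine", 87)], discharge=DIS)
        label = label_aki(tl)
        assert label.positive and label.onset_time == T0 + 50 * H

    def test_rise_just_below_threshold_negative(self):
        tl = make_timeline([(10, "P-Creatinine", 60), (50, "P-Creatinine", 86)], discharge=DIS)
        assert not label_aki(tl).positive

    def test_rise_outside_48h_window_negative(self):
        tl = make_timeline([(10, "P-Creatinine", 60), (60, "P-Creatinine", 87)], discharge=DIS)
        assert not label_aki(tl).positive

    def test_habitual_ratio_at_threshold_fires(self):
        history = [(-24.0 * 7 * (k + 2), "P-Creatinine", 80.0) for k in range(4)]
        tl = make_timeline(history + [(10, "P-Creatinine", 120.0)], discharge=DIS)
        label = label_aki(tl)
        assert label.positive and label.onset_time == T0 + 10 * H

    def test_habitual_ratio_just_below_negative(self):
        history = [(-24.0 * 7 * (k + 2), "P-Creatinine", 80.0) for k in range(4)]
        tl = make_timeline(history + [(10, "P-Creatinine", 119.0)], discharge=DIS)
        assert not label_aki(tl).positive

    def test_no_creatinine_events_negative(self):
        assert not label_aki(make_timeline([(1, "Pulse rate", 80)])).positive

    def test_no_history_means_definition_two_cannot_fire(self):
        tl = make_timeline([(10, "P-Creatinine", 120.0)], discharge=DIS)
        assert not label_aki(tl).positive


class TestLabelAli:
    def test_first_of_cpap_and_niv_is_onset(self):
        tl = make_timeline([(30, "cpap", 1), (40, "niv", 1)], discharge=DIS)
        label = label_ali(tl)
        assert label.positive and label.onset_time == T0 + 30 * H

    def test_no_ventilation_negative(self):
        assert not label_ali(make_timeline([(1, "Pulse rate", 80)])).positive

    def test_event_at_admit_time_counts(self):
        tl = make_timeline([(0, "niv", 1)], discharge=DIS)
        label = label_ali(tl)
        assert label.positive and label.onset_time == T0


class TestLabelerProperties:
    def test_time_translation_invariance(self):
        """Shifting all timestamps shifts every onset by the same constant."""
        shift = pd.Timedelta(hours=777)
        base = _sepsis_timeline(2)
        shifted = make_timeline([], admit=T0 + shift, discharge=DIS + shift)
        shifted.events = base.events.assign(timestamp=base.events["timestamp"] + shift)
        l1, l2 = label_sepsis(base), label_sepsis(shifted)
        assert l1.positive and l2.positive
        assert l2.onset_time - l1.onset_time == shift

    def test_sepsis_monotone_in_qualifying_pairs(self):
        """Adding a qualifying culture/antibiotic pair never flips positive->negative."""
        base = _sepsis_timeline(2)
        label_before = label_sepsis(base)
        extra = pd.DataFrame(
            {
                "timestamp": [T0 + 100 * H, T0 + 101 * H],
                "parameter": ["culture_sample", "antibiotic_administration"],
                "value": [1.0, 1.0],
            }
        )
        richer = make_timeline([], discharge=DIS)
        richer.events = pd.concat([base.events, extra], ignore_index=True)
        assert label_before.positive
        assert label_sepsis(richer).positive

    def test_agreement_with_bruteforce_oracles_on_structured_timelines(self, rng):
        """Handcrafted random timelines: package labelers match exhaustive oracles."""
        for _ in range(60):
            events = []
            for __ in range(rng.integers(0, 4)):
                events.append((float(rng.uniform(0, 150)), "culture_sample", 1))
            for __ in range(rng.integers(0, 4)):
                events.append((float(rng.uniform(0, 150)), "antibiotic_administration", 1))
            for __ in range(rng.integers(0, 8)):
                events.append((float(rng.uniform(0, 150)), "B-Platelets", float(rng.uniform(10, 400))))
            for __ in range(rng.integers(0, 8)):
                events.append((float(rng.uniform(0, 150)), "P-Creatinine", float(rng.uniform(40, 400))))
            for __ in range(rng.integers(0, 2)):
                events.append((float(rng.uniform(0, 150)), "cpap", 1))
            tl = make_timeline(events, discharge=DIS)
            labels = label_admission(tl)
            for name, oracle in (("sepsis", oracle_sepsis), ("aki", oracle_aki), ("ali", oracle_ali)):
                want_pos, want_onset = oracle(tl)
                assert labels[name].positive == want_pos, (name, tl.events)
                if want_pos:
                    assert labels[name].onset_time == want_onset
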