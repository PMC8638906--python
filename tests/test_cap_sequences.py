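import math

import numpy as np
import pytest

import capdetect as cd
from capdetect.cap_sequences import (build_sequences, cap_parameters,
                                     sleep_quality)
from capdetect.io import NREM_STAGES
from _oracles import oracle_sequences, random_event_list


def _events(*iv):
    return cd.EventList(events=list(iv), source="scorer")


# --------------------------------------------------------------------------
# sequence assembly
# --------------------------------------------------------------------------

def test_worked_two_cycle_sequence(all_s2_hypnogram):
    """Two A phases 15 s apart followed by a distant A: one sequence of two
    cycles whose closing B is truncated at 60 s."""
    hyp = all_s2_hypnogram(40)  # 1200 s of S2
    seqs = build_sequences(_events((100, 105), (120, 126), (300, 304)), hyp)
    assert len(seqs) == 1
    (seq,) = seqs
    assert seq.n_cycles == 2
    assert seq.cycles[0].a_interval == (100, 105)
    assert seq.cycles[0].b_interval == (105, 120)
    assert seq.cycles[1].a_interval == (120, 126)
    assert seq.cycles[1].b_interval == (126, 186)  # 60-s truncation
    assert seq.span == (100, 186)

def test_gap_above_sixty_seconds_breaks_pairing(all_s2_hypnogram):
    seqs = build_sequences(_events((100, 105), (170, 175)), all_s2_hypnogram(20))
    assert seqs == []

def test_single_a_phase_is_no_sequence(all_s2_hypnogram):
    assert build_sequences(_events((100, 105)), all_s2_hypnogram(20)) == []

def test_overlong_event_breaks_a_run(all_s2_hypnogram):
    """A 70-s event violates the 2-60 s phase rule and severs the run."""
    hyp = all_s2_hypnogram(40)
    seqs = build_sequences(
        _events((100, 105), (110, 180), (185, 190)), hyp)
    assert seqs == []

def test_stage_transition_breaks_a_run():
    # A phases in two different NREM segments never chain
    hyp = cd.Hypnogram(stages=["S2", "S2", "R", "S2", "S2"])
    seqs = build_sequences(_events((20, 25), (95, 100)), hyp)
    assert seqs == []

def test_sequence_seconds_lie_in_nrem(all_s2_hypnogram):
    hyp = cd.Hypnogram(stages=["S2"] * 10 + ["R"] * 10)
    seqs = build_sequences(_events((250, 255), (270, 275)), hyp)
    nrem = hyp.class_mask(NREM_STAGES)
    for s in seqs:
        assert nrem[s.span[0]:s.span[1]].all()

@pytest.mark.parametrize("seed", range(3))
def test_sequences_match_direct_scan_oracle(seed, all_s2_hypnogram):
    hyp = all_s2_hypnogram(40)
    nrem = hyp.class_mask(NREM_STAGES)
    rng = np.random.default_rng(seed)
    for _ in range(170):
        evs = random_event_list(rng, 1200, max_events=10, max_dur=70)
        if not evs:
            continue
        ours = build_sequences(cd.EventList(events=evs), hyp)
        ref = oracle_sequences(evs, nrem, 1200)
        assert len(ours) == len(ref)
        for s, r in zip(ours, ref):
            assert [(c.a_interval, c.b_interval) for c in s.cycles] == r

def test_removing_an_a_event_never_increases_cap_time(all_s2_hypnogram):
    hyp = all_s2_hypnogram(40)
    rng = np.random.default_rng(9)
    for _ in range(40):
        evs = random_event_list(rng, 1200, max_events=8, max_dur=30)
        if len(evs) < 2:
            continue
        full = cap_parameters(build_sequences(cd.EventList(events=evs), hyp),
                              cd.EventList(events=evs), hyp)
        drop = evs[:1] + evs[2:]
        less = cap_parameters(build_sequences(cd.EventList(events=drop), hyp),
                              cd.EventList(events=drop), hyp)
        assert less.cap_time_min["NREM"] <= full.cap_time_min["NREM"] + 1e-12


# --------------------------------------------------------------------------
# CAP parameters
# --------------------------------------------------------------------------

def test_cap_time_and_rate_for_worked_sequence(all_s2_hypnogram):
    hyp = all_s2_hypnogram(40)  # S2 sleep time 1200 s
    ev = _events((100, 105), (120, 126), (300, 304))
    params = cap_parameters(build_sequences(ev, hyp), ev, hyp)
    assert params.cap_time_min["LS"] == pytest.approx(86 / 60)
    assert params.cap_rate_pct["LS"] == pytest.approx(86 / 1200 * 100)
    assert params.n_a_events == 3
    assert params.mean_a_duration_s == pytest.approx((5 + 6 + 4) / 3)

def test_no_sequences_yield_zero_cap_time(all_s2_hypnogram):
    hyp = all_s2_hypnogram(10)
    params = cap_parameters([], _events(), hyp)
    assert params.cap_time_min == {"NREM": 0.0, "LS": 0.0, "SWS": 0.0}
    assert params.cap_rate_pct["NREM"] == 0.0
    assert math.isnan(params.mean_a_duration_s)

def test_cap_time_additivity_across_stage_classes():
    # sequence spanning an S2->S3 transition splits exactly into LS + SWS
    hyp = cd.Hypnogram(stages=["S2"] * 4 + ["S3"] * 4)
    ev = _events((100, 110), (125, 135))
    seqs = build_sequences(ev, hyp)
    params = cap_parameters(seqs, ev, hyp)
    assert params.cap_time_min["NREM"] == pytest.approx(
        params.cap_time_min["LS"] + params.cap_time_min["SWS"])
    assert params.cap_time_min["SWS"] > 0

def test_rate_undefined_without_sleep_in_class():
    hyp = cd.Hypnogram(stages=["S2"] * 8)  # no SWS at all
    params = cap_parameters([], _events(), hyp)
    assert params.cap_rate_pct["SWS"] is None


# --------------------------------------------------------------------------
# sleep quality
# --------------------------------------------------------------------------

def test_sleep_quality_worked_example():
    hyp = cd.Hypnogram(stages=["W", "W", "S1", "S2", "W", "S2", "R", "W"])
    sq = sleep_quality(hyp)
    assert sq.tst_min == pytest.approx(2.0)
    assert sq.waso_min == pytest.approx(0.5)
    assert sq.pct_sleep == pytest.approx(80.0)

def test_all_wake_night_is_missing():
    sq = sleep_quality(cd.Hypnogram(stages=["W"] * 6))
    assert sq.tst_min is None and sq.waso_min is None and sq.pct_sleep is None

def test_uninterrupted_sleep_has_zero_waso():
    sq = sleep_quality(cd.Hypnogram(stages=["W", "S2", "S2", "R"]))
    assert sq.waso_min == 0.0
    assert sq.pct_sleep == pytest.approx(100.0)
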