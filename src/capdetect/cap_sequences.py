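"""CAP sequence assembly and summary parameters (standard CAP scoring rules).

A CAP cycle is an A phase followed by its B phase (the background until the
next activation); both must last 2-60 s.  At least two consecutive cycles
make a CAP sequence, which therefore begins with an A and ends with a B.
CAP time is the sleep time spanned by CAP sequences and CAP rate its ratio to
the sleep time of the same stage class (NREM, light sleep S1-S2, slow-wave
sleep S3-S4).  Sleep-quality measures (TST, WASO, %-Sleep) are computed from
the hypnogram alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import (EventList, Hypnogram, LS_STAGES, NREM_STAGES, SLEEP_STAGES,
                 SWS_STAGES)

STAGE_CLASSES = {"NREM": NREM_STAGES, "LS": LS_STAGES, "SWS": SWS_STAGES}

PHASE_MIN_S = 2
PHASE_MAX_S = 60


@dataclass
class CapCycle:
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]

    @property
    def span(self) -> tuple[int, int]:
        return (self.a_interval[0], self.b_interval[1])


@dataclass
class CapSequence:
    cycles: list[CapCycle]

    @property
    def span(self) -> tuple[int, int]:
        return (self.cycles[0].a_interval[0], self.cycles[-1].b_interval[1])

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass
class CapParameters:
    cap_time_min: dict[str, float]          # per stage class, minutes
    cap_rate_pct: dict[str, float | None]   # None where the class has no sleep
    n_a_events: int
    mean_a_duration_s: float                # nan when there are no events


@dataclass
class SleepQuality:
    tst_min: float | None
    waso_min: float | None
    pct_sleep: float | None


def build_sequences(a_events: EventList, hyp: Hypnogram) -> list[CapSequence]:
    """Group A phases into CAP sequences.

    A run of consecutive A phases forms a sequence when every A lasts 2-60 s,
    lies entirely in NREM, and each inter-A background gap (the B phase) is
    2-60 s of uninterrupted NREM.  Runs of length one (isolated A phases) and
    events with out-of-range durations (which additionally break any run they
    interrupt) yield no sequence.  The closing B of a run extends from the
    last A to the earliest of: the next event's onset, the end of the NREM
    segment, or 60 s — and is kept even when a stage transition cuts it short
    of 2 s.
    """
    n_seconds = max(hyp.duration_s,
                    a_events.events[-1][1] if a_events.events else 0)
    nrem = hyp.class_mask(NREM_STAGES, n_seconds)

    def in_nrem(a: int, b: int) -> bool:
        return bool(nrem[a:b].all()) if b > a else True

    def valid(ev: tuple[int, int]) -> bool:
        a, b = ev
        return PHASE_MIN_S <= b - a <= PHASE_MAX_S and in_nrem(a, b)

    events = a_events.events
    sequences: list[CapSequence] = []
    i = 0
    while i < len(events):
        if not valid(events[i]):
            i += 1
            continue
        run = [events[i]]
        j = i + 1
        while j < len(events) and valid(events[j]):
            gap = events[j][0] - run[-1][1]
            if not (PHASE_MIN_S <= gap <= PHASE_MAX_S and
                    in_nrem(run[-1][1], events[j][0])):
                break
            run.append(events[j])
            j += 1
        if len(run) >= 2:
            cycles = [
                CapCycle(a_interval=run[k], b_interval=(run[k][1], run[k + 1][0]))
                for k in range(len(run) - 1)
            ]
            last_a = run[-1]
            seg_end = _segment_end(nrem, last_a[1])
            next_onset = events[j][0] if j < len(events) else n_seconds
            b_end = min(next_onset, seg_end, last_a[1] + PHASE_MAX_S)
            if b_end > last_a[1]:
                cycles.append(CapCycle(a_interval=last_a,
                                       b_interval=(last_a[1], b_end)))
            if len(cycles) >= 2:
                sequences.append(CapSequence(cycles=cycles))
        i = max(j, i + 1)
    return sequences


def _segment_end(nrem: np.ndarray, start: int) -> int:
    """End of the NREM run containing (or starting at) second ``start``."""
    end = start
    while end < len(nrem) and nrem[end]:
        end += 1
    return end


def cap_parameters(seqs: list[CapSequence], a_events: EventList,
                   hyp: Hypnogram) -> CapParameters:
    """CAP time/rate per stage class plus A-event count and mean duration.

    CAP time of a class is the seconds of CAP-sequence spans falling in that
    class; CAP rate divides it by the class's total sleep time.  The event
    count and mean duration cover all detected A events, whether or not they
    ended up inside a sequence.
    """
    n_seconds = max(hyp.duration_s,
                    max((s.span[1] for s in seqs), default=0))
    cap_mask = np.zeros(n_seconds, dtype=bool)
    for s in seqs:
        cap_mask[s.span[0]:s.span[1]] = True

    cap_time: dict[str, float] = {}
    cap_rate: dict[str, float | None] = {}
    for name, stages in STAGE_CLASSES.items():
        cls = hyp.class_mask(stages, n_seconds)
        secs = int((cap_mask & cls).sum())
        cap_time[name] = secs / 60.0
        total = int(cls.sum())
        cap_rate[name] = (secs / total * 100.0) if total > 0 else None

    durs = a_events.durations()
    return CapParameters(
        cap_time_min=cap_time,
        cap_rate_pct=cap_rate,
        n_a_events=len(a_events),
        mean_a_duration_s=float(durs.mean()) if durs.size else math.nan,
    )


def sleep_quality(hyp: Hypnogram) -> SleepQuality:
    """TST, WASO and %-Sleep from the hypnogram.

    Sleep onset is the first epoch of any sleep stage; the analysis span runs
    from onset to the end of the last sleep epoch ("the last awakening").
    TST counts all sleep epochs, WASO the wake epochs inside the span, and
    %-Sleep is TST as a percentage of the span.
    """
    epoch_min = hyp.epoch_len_s / 60.0
    sleep = [st in SLEEP_STAGES for st in hyp.stages]
    if not any(sleep):
        return SleepQuality(tst_min=None, waso_min=None, pct_sleep=None)
    onset = sleep.index(True)
    last = len(sleep) - 1 - sleep[::-1].index(True)
    tst = sum(sleep) * epoch_min
    waso = sum(1 for e in range(onset, last + 1) if hyp.stages[e] == "W") * epoch_min
    span = (last - onset + 1) * epoch_min
    return SleepQuality(tst_min=tst, waso_min=waso,
                        pct_sleep=tst / span * 100.0)
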