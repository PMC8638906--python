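"""Independent brute-force reference implementations used as test oracles.

Everything here is written as a direct, per-second or pairwise transcription
of the detection/scoring rules, deliberately sharing no code with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np


def oracle_clean(mask, merge_gap=1, min_dur=2):
    """Mask -> events: merge gaps <= merge_gap, then drop events < min_dur."""
    secs = sorted(np.flatnonzero(np.asarray(mask, bool)).tolist())
    events = []
    for t in secs:
        if events and t - events[-1][1] <= merge_gap:
            events[-1][1] = t + 1
        else:
            events.append([t, t + 1])
    return [(a, b) for a, b in events if b - a >= min_dur]


def oracle_global(per_deriv_events, n_seconds, merge_gap=1, min_dur=2):
    """Union of all derivations' seconds, then the same cleanup."""
    covered = set()
    for evs in per_deriv_events.values():
        for a, b in evs:
            covered.update(range(a, b))
    mask = np.zeros(n_seconds, bool)
    for t in covered:
        if t < n_seconds:
            mask[t] = True
    return oracle_clean(mask, merge_gap, min_dur)


def oracle_common(per_deriv_events, n_seconds, merge_gap=1, min_dur=2,
                  min_support=2, min_overlap=1):
    """Global events that contain >= min_overlap seconds where >= min_support
    derivations' raw events coincide."""
    glob = oracle_global(per_deriv_events, n_seconds, merge_gap, min_dur)
    out = []
    for a, b in glob:
        supported = 0
        for t in range(a, b):
            n = sum(
                any(x <= t < y for x, y in evs)
                for evs in per_deriv_events.values()
            )
            if n >= min_support:
                supported += 1
        if supported >= min_overlap:
            out.append((a, b))
    return out


def oracle_match(detected, reference, min_overlap=1):
    """Pairwise O(n*m) overlap counting: (tp, fn, fp)."""
    def ov(p, q):
        return max(0, min(p[1], q[1]) - max(p[0], q[0]))

    tp = sum(1 for r in reference if any(ov(d, r) >= min_overlap for d in detected))
    fn = len(reference) - tp
    fp = sum(1 for d in detected if not any(ov(d, r) >= min_overlap for r in reference))
    return tp, fn, fp


def oracle_sequences(a_events, nrem_mask, n_seconds,
                     phase_min=2, phase_max=60):
    """Direct scan over A-event runs; returns a list of sequences, each a list
    of (a_interval, b_interval) cycles."""
    nrem = np.asarray(nrem_mask, bool)

    def all_nrem(a, b):
        return all(nrem[t] for t in range(a, b))

    def valid(ev):
        a, b = ev
        return phase_min <= b - a <= phase_max and all_nrem(a, b)

    sequences = []
    i = 0
    while i < len(a_events):
        if not valid(a_events[i]):
            i += 1
            continue
        run = [a_events[i]]
        j = i + 1
        while j < len(a_events) and valid(a_events[j]):
            gap = a_events[j][0] - run[-1][1]
            if not (phase_min <= gap <= phase_max and
                    all_nrem(run[-1][1], a_events[j][0])):
                break
            run.append(a_events[j])
            j += 1
        if len(run) >= 2:
            cycles = []
            for k in range(len(run) - 1):
                cycles.append((run[k], (run[k][1], run[k + 1][0])))
            last = run[-1]
            seg_end = last[1]
            while seg_end < n_seconds and nrem[seg_end]:
                seg_end += 1
            nxt = a_events[j][0] if j < len(a_events) else n_seconds
            b_end = min(nxt, seg_end, last[1] + phase_max)
            if b_end > last[1]:
                cycles.append((last, (last[1], b_end)))
            if len(cycles) >= 2:
                sequences.append(cycles)
        i = max(j, i + 1)
    return sequences


def oracle_detect_band(x, fs, segs, epoch=90, step=30,
                       rms_factor=1.5, var_factor=1.6):
    """Literal per-second transcription of the detection conditions."""
    from scipy.signal import hilbert

    spr = int(round(fs))
    n_seconds = len(x) // spr
    marked = np.zeros(n_seconds, bool)
    for seg_a, seg_b in segs:
        seg = np.asarray(x[seg_a * spr:seg_b * spr], float)
        L = seg_b - seg_a
        env = np.abs(hilbert(seg))

        def sd(t):           # sample SD of second t (segment-local)
            return float(np.std(seg[t * spr:(t + 1) * spr]))

        def env_max(t):
            return float(np.max(env[t * spr:(t + 1) * spr]))

        if L < epoch:
            windows = [(0, (0, L))]
        else:
            last = L - epoch
            starts = list(range(0, last, step)) + [last]
            windows = []
            for k in starts:
                lo = 0 if k == 0 else k + step
                hi = L if k == last else k + 2 * step
                windows.append((k, (lo, hi)))
        for k, (lo, hi) in windows:
            w_hi = min(k + epoch, L)
            win = seg[k * spr:w_hi * spr]
            rms = float(np.sqrt(np.mean(win ** 2)))
            var_ctx = float(np.mean([sd(t) for t in range(k, w_hi)]))
            for t in range(lo, hi):
                if sd(t) > var_factor * var_ctx and env_max(t) > rms_factor * rms:
                    marked[seg_a + t] = True
    return marked


def random_event_list(rng, n_seconds, max_events=8, max_dur=70, min_dur=1):
    """Sorted disjoint integer-second events for oracle comparisons."""
    events = []
    t = int(rng.integers(0, 30))
    for _ in range(int(rng.integers(0, max_events + 1))):
        dur = int(rng.integers(min_dur, max_dur))
        if t + dur >= n_seconds:
            break
        events.append((t, t + dur))
        t = t + dur + int(rng.integers(1, 80))
    return events
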