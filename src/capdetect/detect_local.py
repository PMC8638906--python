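"""Single-derivation CAP A-phase detection (adapted band-descriptor algorithm).

The detector marks, second by second within NREM sleep, activations whose
amplitude stands out from the surrounding background.  The signal is analysed
in 90-s context epochs advanced by 30 s; a second in the central 30 s of an
epoch is marked when

* its variability (sample SD of the band-filtered signal within the second)
  exceeds ``var_factor`` (default 1.6) times the epoch's variability, and
* the envelope of the band-filtered signal (analytic-signal magnitude)
  exceeds ``rms_factor`` (default 1.5) times the epoch RMS at at least one
  sample of the second.

``rms_mode`` selects where the RMS reference is taken: ``per_epoch`` uses the
90-s context epoch (the adapted variant, which tracks the local background as
the CAP rules demand), while ``whole_nrem`` uses the RMS of the entire NREM
signal (the original variant, kept for comparison).  Both thresholds are
relative, so detection is invariant to a global amplitude rescaling.

Marked seconds are turned into events by merging runs separated by at most
1 s and discarding isolated 1-s events; slow- and fast-band events are then
merged into the derivation's final event list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .io import Derivation, EventList, Hypnogram, NREM_STAGES
from .preprocess import FilterBankConfig, filter_band_segments


@dataclass
class DetectorConfig:
    epoch_len_s: int = 90          # context epoch
    step_s: int = 30               # epoch advance = decided central third
    rms_factor: float = 1.5        # envelope threshold, x epoch RMS
    var_factor: float = 1.6        # variability threshold, x epoch variability
    merge_gap_s: int = 1           # combine events separated by <= this gap
    min_event_s: int = 2           # drop events shorter than this after merging
    max_event_s: int = 60          # CAP rule upper bound; longer events are flagged
    rms_mode: str = "per_epoch"    # "per_epoch" (adapted) | "whole_nrem" (original)

    def __post_init__(self) -> None:
        if self.epoch_len_s != 3 * self.step_s:
            raise ValueError("epoch_len_s must be 3 x step_s (central-third scheme)")
        if self.rms_factor <= 1 or self.var_factor <= 1:
            raise ValueError("threshold factors must exceed 1")
        if self.merge_gap_s < 0:
            raise ValueError("merge_gap_s must be >= 0")
        if self.rms_mode not in ("per_epoch", "whole_nrem"):
            raise ValueError(f"unknown rms_mode {self.rms_mode!r}")


@dataclass
class DetectionVector:
    """Per-second detection marks for one frequency band.

    Seconds outside NREM are always False.
    """

    seconds: np.ndarray   # bool, one entry per second of the analysed span
    band: str             # "slow" | "fast"


def nrem_segments(hyp: Hypnogram) -> list[tuple[int, int]]:
    """Maximal runs of consecutive NREM epochs as half-open second intervals."""
    segs: list[tuple[int, int]] = []
    start: int | None = None
    for e, st in enumerate(hyp.stages):
        if st in NREM_STAGES:
            if start is None:
                start = e
        elif start is not None:
            segs.append((start * hyp.epoch_len_s, e * hyp.epoch_len_s))
            start = None
    if start is not None:
        segs.append((start * hyp.epoch_len_s, hyp.n_epochs * hyp.epoch_len_s))
    return segs


def second_variability(x: np.ndarray, fs: float) -> np.ndarray:
    """Sample standard deviation of the signal within each whole second."""
    spr = int(round(fs))
    n_sec = len(x) // spr
    if n_sec == 0:
        return np.zeros(0)
    return np.asarray(x[: n_sec * spr], dtype=float).reshape(n_sec, spr).std(axis=1)


def _second_env_max(x: np.ndarray, fs: float) -> np.ndarray:
    """Per-second maximum of the analytic-signal magnitude."""
    env = np.abs(hilbert(np.asarray(x, dtype=float)))
    spr = int(round(fs))
    n_sec = len(x) // spr
    return env[: n_sec * spr].reshape(n_sec, spr).max(axis=1)


def _window_decisions(seg_len_s: int, epoch_len_s: int, step_s: int):
    """Yield (epoch_start, decision_range) pairs for one segment.

    Each 90-s epoch decides its central 30 s; the leading and trailing thirds
    of the segment are decided by the first and last epoch respectively.
    Segments shorter than one epoch are their own context and decide
    everything at once.
    """
    if seg_len_s < epoch_len_s:
        yield 0, (0, seg_len_s)
        return
    last = seg_len_s - epoch_len_s
    starts = list(range(0, last, step_s)) + [last]  # final window is flush right
    for k in starts:
        lo = 0 if k == 0 else k + step_s
        hi = seg_len_s if k == last else k + 2 * step_s
        yield k, (lo, hi)


def detect_band(x: np.ndarray, fs: float, segs: list[tuple[int, int]],
                cfg: DetectorConfig | None = None, band: str = "slow") -> DetectionVector:
    """Run the per-second threshold detector on one band-filtered signal."""
    cfg = cfg or DetectorConfig()
    n_seconds = len(x) // int(round(fs))
    marks = np.zeros(n_seconds, dtype=bool)
    spr = int(round(fs))

    whole_rms = None
    if cfg.rms_mode == "whole_nrem":
        chunks = [np.asarray(x[a * spr:b * spr], dtype=float) for a, b in segs]
        if chunks:
            cat = np.concatenate(chunks)
            whole_rms = float(np.sqrt(np.mean(cat ** 2))) if cat.size else 0.0

    for a, b in segs:
        seg = np.asarray(x[a * spr:b * spr], dtype=float)
        L = b - a
        if L <= 0:
            continue
        sec_sd = second_variability(seg, fs)
        env_max = _second_env_max(seg, fs)
        for k, (lo, hi) in _window_decisions(L, cfg.epoch_len_s, cfg.step_s):
            w_hi = min(k + cfg.epoch_len_s, L)
            win = seg[k * spr:w_hi * spr]
            rms = whole_rms if whole_rms is not None else float(np.sqrt(np.mean(win ** 2)))
            var_ctx = float(sec_sd[k:w_hi].mean())
            sel = (sec_sd[lo:hi] > cfg.var_factor * var_ctx) & \
                  (env_max[lo:hi] > cfg.rms_factor * rms)
            marks[a + lo:a + hi] |= sel
    return DetectionVector(seconds=marks, band=band)


def clean_events(v: DetectionVector | np.ndarray, cfg: DetectorConfig | None = None,
                 source: str = "", band: str | None = None) -> EventList:
    """Detection vector -> event list: merge 1-s gaps, then drop 1-s events."""
    cfg = cfg or DetectorConfig()
    if isinstance(v, DetectionVector):
        mask, band = v.seconds, band or v.band
    else:
        mask, band = np.asarray(v, dtype=bool), band or "n/a"
    raw = EventList.from_mask(mask).events
    merged: list[tuple[int, int]] = []
    for ev in raw:
        if merged and ev[0] - merged[-1][1] <= cfg.merge_gap_s:
            merged[-1] = (merged[-1][0], ev[1])
        else:
            merged.append(ev)
    kept = [(s, e) for s, e in merged if e - s >= cfg.min_event_s]
    return EventList(events=kept, source=source, band=band)


def detect_derivation(d: Derivation, hyp: Hypnogram,
                      cfg: DetectorConfig | None = None,
                      fb: FilterBankConfig | None = None) -> EventList:
    """Full single-derivation pipeline: both bands, merged and cleaned."""
    cfg = cfg or DetectorConfig()
    fb = fb or FilterBankConfig()
    segs = nrem_segments(hyp)
    n_seconds = int(len(d.signal) // round(d.fs))
    union = np.zeros(n_seconds, dtype=bool)
    for band in ("slow", "fast"):
        filt = filter_band_segments(d.signal, d.fs, band, segs, fb)
        vec = detect_band(filt, d.fs, segs, cfg, band=band)
        union |= clean_events(vec, cfg, source=d.label).to_mask(n_seconds)
    return clean_events(union, cfg, source=d.label, band="merged")


def flag_overlong(ev: EventList, cfg: DetectorConfig | None = None) -> list[bool]:
    """Mark events exceeding the 60-s CAP bound (sequence breakers downstream)."""
    cfg = cfg or DetectorConfig()
    return [e - s > cfg.max_event_s for s, e in ev.events]
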