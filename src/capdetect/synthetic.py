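"""Synthetic multi-derivation polysomnography with known CAP ground truth.

The generator emulates the statistical structure the detector assumes: a
pink-noise EEG background (correlated across derivations, as scalp channels
are), CAP A phases injected into *all* derivations simultaneously as
amplitude-scaled slow-band and/or fast-band bursts, organised into CAP
sequences obeying the 2-60 s phase rules, and single-derivation artifacts.
Every fixture comes with the exact event log used to build it, so detection
performance can be scored without any external data.

Amplitudes are controlled in-band: a burst with ``burst_amplitude_ratio`` r
raises the RMS of the band-filtered signal during the burst to r times the
background's in-band RMS (A phases run about one third above background, the
default r = 4/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cap_sequences import PHASE_MAX_S, PHASE_MIN_S
from .detect_local import nrem_segments
from .io import (EventList, Hypnogram, Recording, write_edf, write_events,
                 write_hypnogram)
from .preprocess import FilterBankConfig, filter_fast, filter_slow

#: the six right-hemisphere derivations used throughout
DEFAULT_DERIVATIONS = ("Fp2-F4", "F4-C4", "C4-P4", "P4-O2", "C4-A1", "F4-A1")


@dataclass
class SimConfig:
    n_derivations: int = 6
    fs: float = 128.0
    duration_min: float = 60.0
    stage_plan: list[str] | None = None      # default: default_stage_plan()
    burst_amplitude_ratio: float = 4.0 / 3.0
    a_duration_range_s: tuple[int, int] = (4, 15)    # within the 2-60 s rule
    b_duration_range_s: tuple[int, int] = (5, 40)
    target_cap_rate_pct: float = 30.0
    artifact_rate_per_min: float = 0.2       # per NREM minute
    artifact_amplitude_ratio: float = 3.0
    artifact_duration_range_s: tuple[int, int] = (3, 8)
    cycles_per_sequence: tuple[int, int] = (2, 6)
    interseq_gap_range_s: tuple[int, int] = (65, 180)  # > 60 s breaks sequences
    subtype_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # slow/fast/both
    background_rms_uv: float = 25.0
    shared_fraction: float = 0.5             # cross-derivation variance share
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_amplitude_ratio <= 1:
            raise ValueError("burst_amplitude_ratio must exceed 1")
        for lo, hi in (self.a_duration_range_s, self.b_duration_range_s):
            if not (PHASE_MIN_S <= lo <= hi <= PHASE_MAX_S):
                raise ValueError("phase duration ranges must lie within [2, 60] s")
        if self.interseq_gap_range_s[0] <= PHASE_MAX_S:
            raise ValueError("inter-sequence gaps must exceed 60 s")
        if abs(sum(self.subtype_probs) - 1) > 1e-9:
            raise ValueError("subtype_probs must sum to 1")

    @property
    def labels(self) -> list[str]:
        if self.n_derivations <= len(DEFAULT_DERIVATIONS):
            return list(DEFAULT_DERIVATIONS[: self.n_derivations])
        extra = [f"D{i}" for i in range(len(DEFAULT_DERIVATIONS), self.n_derivations)]
        return list(DEFAULT_DERIVATIONS) + extra


@dataclass
class GroundTruth:
    a_events: EventList
    a_bands: list[str]                       # "slow" | "fast" | "both" per event
    artifact_events: dict[str, EventList]    # per derivation
    hypnogram: Hypnogram


def default_stage_plan(duration_min: float) -> list[str]:
    """A plausible abbreviated night: wake, a long NREM block with a
    slow-wave core, a REM interlude, a second NREM block, final wake."""
    n = int(round(duration_min * 2))  # 30-s epochs
    plan: list[str] = []
    plan += ["W"] * 2 + ["S1"] * 2
    core = ["S2"] * 40 + ["S3"] * 20 + ["S2"] * 28 + ["R"] * 10 + ["S2"] * 16
    while len(plan) < n - 2:
        take = core[: n - 2 - len(plan)]
        plan += take
    plan += ["W"] * 2
    return plan[:n]


# --------------------------------------------------------------------------
# event placement
# --------------------------------------------------------------------------

def _place_cap_events(cfg: SimConfig, hyp: Hypnogram,
                      rng: np.random.Generator) -> tuple[list[tuple[int, int]], list[str]]:
    """Lay CAP sequences into the NREM segments until the target CAP rate
    (sequence-span seconds / NREM seconds) is reached."""
    segs = nrem_segments(hyp)
    nrem_total = sum(e - s for s, e in segs)
    if nrem_total == 0:
        raise ValueError("stage plan contains no NREM sleep")
    target_s = cfg.target_cap_rate_pct / 100.0 * nrem_total

    events: list[tuple[int, int]] = []
    bands: list[str] = []
    placed = 0.0
    a_lo, a_hi = cfg.a_duration_range_s
    b_lo, b_hi = cfg.b_duration_range_s

    for seg_start, seg_end in segs:
        t = seg_start + int(rng.integers(5, 21))
        while placed < target_s:
            n_cyc = int(rng.integers(cfg.cycles_per_sequence[0],
                                     cfg.cycles_per_sequence[1] + 1))
            seq: list[tuple[int, int]] = []
            pos = t
            for c in range(n_cyc):
                a_dur = int(rng.integers(a_lo, a_hi + 1))
                if pos + a_dur + PHASE_MIN_S > seg_end:
                    break
                seq.append((pos, pos + a_dur))
                pos += a_dur
                span_so_far = pos - t
                if c < n_cyc - 1:
                    if placed + span_so_far >= target_s:
                        break  # sequence already fills the budget
                    pos += int(rng.integers(b_lo, b_hi + 1))
            if len(seq) < 2:
                break  # no room left in this segment
            events.extend(seq)
            bands.extend(_draw_bands(cfg, rng, len(seq)))
            gap = int(rng.integers(*cfg.interseq_gap_range_s))
            closing_b = min(PHASE_MAX_S, seg_end - seq[-1][1], gap)
            placed += (seq[-1][1] + closing_b) - seq[0][0]
            t = seq[-1][1] + gap
            if t >= seg_end - (a_lo + b_lo) * 2:
                break
        if placed >= target_s:
            break

    achieved = placed / nrem_total * 100.0
    if achieved < cfg.target_cap_rate_pct - 5.0:
        raise ValueError(
            f"target CAP rate {cfg.target_cap_rate_pct}% infeasible for this "
            f"stage plan (reached {achieved:.1f}%)"
        )
    return events, bands


def _draw_bands(cfg: SimConfig, rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(["slow", "fast", "both"], size=n, p=cfg.subtype_probs))


def _place_artifacts(cfg: SimConfig, hyp: Hypnogram,
                     a_events: list[tuple[int, int]],
                     rng: np.random.Generator) -> dict[str, EventList]:
    """Single-derivation artifact events in NREM, clear of the A phases."""
    segs = nrem_segments(hyp)
    nrem_total = sum(e - s for s, e in segs)
    labels = cfg.labels
    out: dict[str, list[tuple[int, int]]] = {lab: [] for lab in labels}
    n_art = int(rng.poisson(cfg.artifact_rate_per_min * nrem_total / 60.0))

    blocked = np.zeros(hyp.duration_s + 1, dtype=bool)
    for a, b in a_events:  # keep artifacts >= 5 s away from genuine A phases
        blocked[max(0, a - 5):min(len(blocked), b + 5)] = True

    lo, hi = cfg.artifact_duration_range_s
    placed = 0
    for _ in range(n_art * 50):
        if placed >= n_art:
            break
        seg = segs[int(rng.integers(len(segs)))]
        dur = int(rng.integers(lo, hi + 1))
        if seg[1] - seg[0] < dur + 4:
            continue
        start = int(rng.integers(seg[0] + 2, seg[1] - dur - 2))
        if blocked[start:start + dur].any():
            continue
        lab = labels[int(rng.integers(len(labels)))]
        out[lab].append((start, start + dur))
        blocked[max(0, start - 3):start + dur + 3] = True
        placed += 1
    return {
        lab: EventList(events=sorted(evs), source=lab, band="n/a")
        for lab, evs in out.items()
    }


# --------------------------------------------------------------------------
# signal synthesis
# --------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, rng: np.random.Generator,
                f_hi: float = 30.0, f_knee: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f-shaped noise, low-passed at ``f_hi``.

    The spectrum is flat below ``f_knee`` (EEG power spectra level off at low
    frequencies; an unbounded 1/f rise would make the background variance
    grow with record length) and falls as 1/f above it.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, f_knee))
    shape[freqs > f_hi] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _band_noise(n: int, fs: float, band: str, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise confined to the slow or fast analysis band."""
    white = rng.standard_normal(n + 2 * int(fs))  # head/tail guard for the filter
    fn = filter_slow if band == "slow" else filter_fast
    x = fn(white, fs)[int(fs):int(fs) + n]
    return x / x.std()


def _taper(n: int, fs: float) -> np.ndarray:
    ramp = min(int(0.5 * fs), max(1, n // 4))
    w = np.ones(n)
    r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    w[:ramp] = r
    w[-ramp:] = r[::-1]
    return w


def simulate(cfg: SimConfig | None = None) -> tuple[Recording, GroundTruth]:
    """Generate a recording plus its exact ground truth (deterministic per seed)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    stages = list(cfg.stage_plan) if cfg.stage_plan else default_stage_plan(cfg.duration_min)
    hyp = Hypnogram(stages=stages)
    n_seconds = hyp.duration_s
    spr = int(round(cfg.fs))
    n_samples = n_seconds * spr
    labels = cfg.labels

    a_events, a_bands = _place_cap_events(cfg, hyp, rng)
    artifacts = _place_artifacts(cfg, hyp, a_events, rng)

    shared = _pink_noise(n_samples, cfg.fs, rng)
    sig = np.empty((cfg.n_derivations, n_samples))
    for d in range(cfg.n_derivations):
        private = _pink_noise(n_samples, cfg.fs, rng)
        bg = (np.sqrt(cfg.shared_fraction) * shared +
              np.sqrt(1 - cfg.shared_fraction) * private)
        sig[d] = cfg.background_rms_uv * bg / bg.std()

    # in-band background RMS per derivation, measured before injection
    bg_rms = {
        "slow": np.array([filter_slow(sig[d], cfg.fs).std()
                          for d in range(cfg.n_derivations)]),
        "fast": np.array([filter_fast(sig[d], cfg.fs).std()
                          for d in range(cfg.n_derivations)]),
    }
    extra = np.sqrt(cfg.burst_amplitude_ratio ** 2 - 1)
    extra_art = np.sqrt(cfg.artifact_amplitude_ratio ** 2 - 1)

    for (a, b), band in zip(a_events, a_bands):
        i, j = a * spr, b * spr
        parts = ("slow", "fast") if band == "both" else (band,)
        for part in parts:
            w = _band_noise(j - i, cfg.fs, part, rng) * _taper(j - i, cfg.fs)
            w /= w.std()
            # same activation waveform on every derivation, scaled to its bg
            sig[:, i:j] += extra * bg_rms[part][:, None] * w[None, :]

    for d, lab in enumerate(labels):
        for a, b in artifacts[lab].events:
            i, j = a * spr, b * spr
            part = "slow" if rng.random() < 0.5 else "fast"
            w = _band_noise(j - i, cfg.fs, part, rng) * _taper(j - i, cfg.fs)
            w /= w.std()
            sig[d, i:j] += extra_art * bg_rms[part][d] * w

    rec = Recording(signals=sig, fs=cfg.fs, channel_labels=labels)
    gt = GroundTruth(
        a_events=EventList(events=a_events, source="ground_truth", band="merged"),
        a_bands=a_bands,
        artifact_events=artifacts,
        hypnogram=hyp,
    )
    return rec, gt


def write_fixture(rec: Recording, gt: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a fixture as EDF + hypnogram + annotation files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": write_edf(rec, out_dir / "recording.edf"),
        "hypnogram": write_hypnogram(gt.hypnogram, out_dir / "hypnogram.txt"),
        "a_events": write_events(gt.a_events, out_dir / "a_events.tsv", label="A"),
    }
    art = [(lab, a, b) for lab, ev in gt.artifact_events.items() for a, b in ev.events]
    lines = ["onset_s\tduration_s\tlabel"]
    for lab, a, b in sorted(art, key=lambda t: t[1]):
        lines.append(f"{a}\t{b - a}\tartifact:{lab}")
    p = out_dir / "artifacts.tsv"
    p.write_text("\n".join(lines) + "\n")
    paths["artifacts"] = p
    return paths
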