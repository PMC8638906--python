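"""Band filtering for CAP A-phase detection.

Two views of each derivation are produced: a slow band (0.3-4.5 Hz) carrying
the high-voltage synchronised component of A phases, and a fast band
(7-25 Hz) with the sigma range (11-15 Hz, sleep spindles) removed by a
band-stop so spindle activity does not masquerade as an activation.  All
filters are applied forward-backward (zero phase) so the per-second grid of
the detector stays aligned with the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass
class FilterBankConfig:
    """Band edges and filter orders for the slow/fast filter bank.

    Defaults follow standard CAP band-descriptor practice: Butterworth
    band-passes, and a band-stop across 11-15 Hz centred on 13 Hz to exclude
    the sigma (spindle) band from the fast trace.
    """

    slow_band: tuple[float, float] = (0.3, 4.5)
    fast_band: tuple[float, float] = (7.0, 25.0)
    notch_center: float = 13.0
    notch_bw: float = 4.0
    order: int = 4
    notch_order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.slow_band, self.fast_band):
            if not 0 < lo < hi:
                raise ValueError("band edges must satisfy 0 < low < high")
        lo = self.notch_center - self.notch_bw / 2
        hi = self.notch_center + self.notch_bw / 2
        if not (self.fast_band[0] < lo < hi < self.fast_band[1]):
            raise ValueError("notch interval must lie inside the fast band")

    @property
    def notch_band(self) -> tuple[float, float]:
        return (self.notch_center - self.notch_bw / 2,
                self.notch_center + self.notch_bw / 2)


def _check_fs(fs: float, band_high: float) -> None:
    if fs <= 2 * band_high:
        raise ValueError(
            f"fs={fs} too low for a band extending to {band_high} Hz"
        )


def design_slow(fs: float, cfg: FilterBankConfig | None = None) -> np.ndarray:
    cfg = cfg or FilterBankConfig()
    _check_fs(fs, cfg.slow_band[1])
    return signal.butter(cfg.order, cfg.slow_band, btype="bandpass", fs=fs,
                         output="sos")


def design_fast(fs: float, cfg: FilterBankConfig | None = None) -> np.ndarray:
    """Fast-band chain: band-pass 7-25 Hz stacked with the sigma band-stop."""
    cfg = cfg or FilterBankConfig()
    _check_fs(fs, cfg.fast_band[1])
    sos_bp = signal.butter(cfg.order, cfg.fast_band, btype="bandpass", fs=fs,
                           output="sos")
    sos_bs = signal.butter(cfg.notch_order, cfg.notch_band, btype="bandstop",
                           fs=fs, output="sos")
    return np.vstack([sos_bp, sos_bs])


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    if zero_phase:
        # reflect padding of one impulse-response length at the boundaries
        padlen = min(x.size - 1, 3 * (2 * sos.shape[0] + 1) * 10)
        return signal.sosfiltfilt(sos, x, padlen=padlen)
    return signal.sosfilt(sos, x)


def filter_slow(x: np.ndarray, fs: float,
                cfg: FilterBankConfig | None = None) -> np.ndarray:
    """0.3-4.5 Hz zero-phase band-pass; same length as the input."""
    cfg = cfg or FilterBankConfig()
    return _apply(design_slow(fs, cfg), x, cfg.zero_phase)


def filter_fast(x: np.ndarray, fs: float,
                cfg: FilterBankConfig | None = None) -> np.ndarray:
    """7-25 Hz zero-phase band-pass with the 11-15 Hz sigma band removed."""
    cfg = cfg or FilterBankConfig()
    return _apply(design_fast(fs, cfg), x, cfg.zero_phase)


def filter_band_segments(x: np.ndarray, fs: float, band: str,
                         segments_s: list[tuple[int, int]],
                         cfg: FilterBankConfig | None = None) -> np.ndarray:
    """Filter each contiguous segment independently.

    Filtering per NREM segment (rather than across a concatenated signal)
    avoids ringing at the joins between non-adjacent pieces of the night.
    Samples outside the segments are zero in the output.
    """
    cfg = cfg or FilterBankConfig()
    fn = filter_slow if band == "slow" else filter_fast
    out = np.zeros_like(np.asarray(x, dtype=float))
    for a, b in segments_s:
        i, j = int(round(a * fs)), int(round(b * fs))
        out[i:j] = fn(x[i:j], fs, cfg)
    return out
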