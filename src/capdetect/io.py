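"""Reading and writing polysomnography artifacts.

EDF/EDF+ recordings are read through MNE; a minimal EDF writer is provided so
synthetic fixtures can be materialised on disk.  Hypnograms and CAP A-phase
event lists use a plain tab-delimited text format.  The module also builds the
analysis derivations (bipolar and referential montages) from the channels
present in a recording, including telescoped combinations such as
F4-A1 = (F4-C4) + (C4-A1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: stage codes understood by the hypnogram parser
STAGE_CODES = ("W", "S1", "S2", "S3", "S4", "R", "MT", "UNK")
NREM_STAGES = frozenset({"S1", "S2", "S3", "S4"})
LS_STAGES = frozenset({"S1", "S2"})
SWS_STAGES = frozenset({"S3", "S4"})
SLEEP_STAGES = frozenset({"S1", "S2", "S3", "S4", "R"})

#: common synonyms found in scoring files, mapped onto the canonical codes
_STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "0": "W",
    "S1": "S1", "N1": "S1", "1": "S1",
    "S2": "S2", "N2": "S2", "2": "S2",
    "S3": "S3", "N3": "S3", "3": "S3",
    "S4": "S4", "4": "S4",
    "R": "R", "REM": "R", "5": "R",
    "MT": "MT",
    "UNK": "UNK", "?": "UNK",
}


class MissingChannelError(KeyError):
    """A requested channel is not present in the recording."""


class DerivationError(ValueError):
    """A derivation spec cannot be resolved from the available channels."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Recording:
    """Multi-channel EEG recording on a single common sampling grid.

    Amplitudes are in microvolts.  All channels share ``fs`` and length; the
    reader resamples on load when the source EDF mixes sampling rates.
    """

    signals: np.ndarray          # (n_channels, n_samples), microvolts
    fs: float                    # samples per second
    channel_labels: list[str]
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs < 64:
            raise ValueError(
                f"fs={self.fs} too low: the fast band extends to 25 Hz, need fs >= 64"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise MissingChannelError(label) from None
        return self.signals[idx]


@dataclass
class Derivation:
    """One analysis trace: a channel or an arithmetic combination of channels."""

    label: str
    signal: np.ndarray
    fs: float


@dataclass
class Hypnogram:
    """Ordered 30-s epoch sleep stages for a night."""

    stages: list[str]
    epoch_len_s: int = 30

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGE_CODES]
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(set(bad))}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> int:
        return self.n_epochs * self.epoch_len_s

    def stage_of_second(self, n_seconds: int | None = None) -> np.ndarray:
        """Stage label for each second of the covered span (object array)."""
        n = self.duration_s if n_seconds is None else n_seconds
        out = np.full(n, "UNK", dtype=object)
        for e, st in enumerate(self.stages):
            lo = e * self.epoch_len_s
            if lo >= n:
                break
            out[lo:min(n, lo + self.epoch_len_s)] = st
        return out

    def class_mask(self, stages: Iterable[str], n_seconds: int | None = None) -> np.ndarray:
        """Boolean per-second mask for a stage class (e.g. NREM_STAGES)."""
        sec = self.stage_of_second(n_seconds)
        stages = set(stages)
        return np.array([s in stages for s in sec], dtype=bool)


@dataclass
class EventList:
    """Sorted, disjoint half-open intervals [start_s, end_s) on the 1-s grid."""

    events: list[tuple[int, int]] = field(default_factory=list)
    source: str = ""
    band: str = "n/a"

    def __post_init__(self) -> None:
        evs = [(int(a), int(b)) for a, b in self.events]
        for a, b in evs:
            if b <= a:
                raise ValueError(f"empty or inverted interval [{a},{b})")
        for (a0, b0), (a1, b1) in zip(evs, evs[1:]):
            if a1 < b0:
                raise ValueError("events must be sorted and pairwise disjoint")
        self.events = evs

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.events], dtype=int)

    def total_seconds(self) -> int:
        return int(self.durations().sum()) if self.events else 0

    def to_mask(self, n_seconds: int) -> np.ndarray:
        m = np.zeros(n_seconds, dtype=bool)
        for a, b in self.events:
            m[max(a, 0):min(b, n_seconds)] = True
        return m

    @classmethod
    def from_mask(cls, mask: np.ndarray, source: str = "", band: str = "n/a") -> "EventList":
        mask = np.asarray(mask, dtype=bool)
        events: list[tuple[int, int]] = []
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for a, b in zip(edges[::2], edges[1::2]):
            events.append((int(a), int(b)))
        return cls(events=events, source=source, band=band)


# --------------------------------------------------------------------------
# EDF reading / writing
# --------------------------------------------------------------------------

def read_edf(path: str | Path, wanted_channels: Sequence[str]) -> Recording:
    """Read the requested channels from an EDF/EDF+ file.

    Channels with different sampling rates are brought to the maximum rate on
    load (MNE resamples mixed-rate EDF channels when reading).  Missing
    channels raise :class:`MissingChannelError` listing what was absent.
    """
    import mne

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    present = list(raw.ch_names)
    missing = [ch for ch in wanted_channels if ch not in present]
    if missing:
        raise MissingChannelError(
            f"channels {missing} not found in {path.name}; available: {present}"
        )
    raw.pick([str(ch) for ch in wanted_channels])
    data = raw.get_data() * 1e6  # MNE volts -> microvolts
    return Recording(
        signals=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(wanted_channels),
    )


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` as a plain EDF file (16-bit, 1-s records).

    Minimal writer sufficient for fixtures: one data record per second,
    physical unit microvolts, per-channel physical scaling.
    """
    path = Path(path)
    n_ch = len(rec.channel_labels)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        raise ValueError("signal length must be a whole number of seconds")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    phys_min, phys_max, scaled = [], [], []
    for sig in rec.signals:
        lo = float(np.min(sig)) if sig.size else -1.0
        hi = float(np.max(sig)) if sig.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        # small head-room so rounding never clips
        span = hi - lo
        lo -= 0.01 * span
        hi += 0.01 * span
        dig = np.round((sig - lo) / (hi - lo) * (32767 - (-32768)) + (-32768))
        scaled.append(dig.astype("<i2"))
        phys_min.append(lo)
        phys_max.append(hi)

    header = b""
    header += pad("0", 8)                       # version
    header += pad("X X X X", 80)                # patient id
    header += pad("Startdate X X X X", 80)      # recording id
    header += pad("01.01.00", 8)                # start date
    header += pad("00.00.00", 8)                # start time
    header += pad(str(256 + 256 * n_ch), 8)     # header bytes
    header += pad("", 44)                       # reserved
    header += pad(str(n_rec), 8)                # number of records
    header += pad("1", 8)                       # record duration, s
    header += pad(str(n_ch), 4)

    def cat(vals: list[str], n: int) -> bytes:
        return b"".join(pad(v, n) for v in vals)

    header += cat(rec.channel_labels, 16)
    header += cat(["EEG"] * n_ch, 80)           # transducer
    header += cat(["uV"] * n_ch, 8)
    header += cat([f"{v:.8g}"[:8] for v in phys_min], 8)
    header += cat([f"{v:.8g}"[:8] for v in phys_max], 8)
    header += cat(["-32768"] * n_ch, 8)
    header += cat(["32767"] * n_ch, 8)
    header += cat([""] * n_ch, 80)              # prefiltering
    header += cat([str(spr)] * n_ch, 8)
    header += cat([""] * n_ch, 32)              # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(scaled[ch][r * spr:(r + 1) * spr].tobytes())
    return path


# --------------------------------------------------------------------------
# derivations
# --------------------------------------------------------------------------

def build_derivations(rec: Recording, specs: Sequence[str]) -> list[Derivation]:
    """Resolve derivation labels against the channels of a recording.

    A spec that names a present channel is passed through unchanged.  A spec
    of the form ``"X-Y"`` absent from the recording is resolved by telescoping
    present bipolar/referential channels: a chain X-Z1, Z1-Z2, ..., Zk-Y sums
    to X-Y because the intermediate electrodes cancel (for example
    F4-A1 = (F4-C4) + (C4-A1)).  Channels may also be used reversed with a
    sign flip.
    """
    out: list[Derivation] = []
    # electrode graph: edge u->v with weight +1 for a channel named "u-v"
    edges: dict[str, list[tuple[str, str, int]]] = {}
    for lab in rec.channel_labels:
        if "-" in lab:
            u, v = lab.split("-", 1)
            edges.setdefault(u, []).append((v, lab, +1))
            edges.setdefault(v, []).append((u, lab, -1))

    for spec in specs:
        if spec in rec.channel_labels:
            out.append(Derivation(spec, rec.channel(spec).copy(), rec.fs))
            continue
        if "-" not in spec:
            raise DerivationError(f"cannot resolve derivation {spec!r}")
        src, dst = spec.split("-", 1)
        path = _electrode_path(edges, src, dst)
        if path is None:
            raise DerivationError(
                f"cannot resolve derivation {spec!r} from channels {rec.channel_labels}"
            )
        sig = np.zeros(rec.n_samples)
        for lab, sign in path:
            sig += sign * rec.channel(lab)
        out.append(Derivation(spec, sig, rec.fs))
    return out


def _electrode_path(edges, src: str, dst: str) -> list[tuple[str, int]] | None:
    """BFS over the electrode graph; returns [(channel_label, sign), ...]."""
    if src not in edges:
        return None
    seen = {src}
    queue: list[tuple[str, list[tuple[str, int]]]] = [(src, [])]
    while queue:
        node, path = queue.pop(0)
        if node == dst:
            return path
        for nxt, lab, sign in edges.get(node, []):
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, path + [(lab, sign)]))
    return None


# --------------------------------------------------------------------------
# hypnogram / event text formats
# --------------------------------------------------------------------------

def read_hypnogram(path: str | Path, epoch_len_s: int = 30) -> Hypnogram:
    """Read a hypnogram: one stage code per line, or ``onset_s<TAB>stage`` pairs."""
    path = Path(path)
    stages: list[str] = []
    pairs: list[tuple[float, str]] = []
    paired = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) >= 2 and _is_number(parts[0]):
            paired = True
            pairs.append((float(parts[0]), parts[1]))
        else:
            stages.append(parts[0])
    if paired:
        stages = []
        for onset, code in pairs:
            epoch = int(round(onset / epoch_len_s))
            while len(stages) < epoch:
                stages.append("UNK")
            stages.append(code)
    canon = []
    for code in stages:
        mapped = _STAGE_ALIASES.get(code.upper())
        if mapped is None:
            logger.warning("unknown stage code %r mapped to UNK", code)
            mapped = "UNK"
        canon.append(mapped)
    return Hypnogram(stages=canon, epoch_len_s=epoch_len_s)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(hyp.stages) + "\n")
    return path


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


EVENT_HEADER = "onset_s\tduration_s\tlabel"


def read_events(path: str | Path, source: str = "scorer", band: str = "n/a") -> EventList:
    """Read a delimited A-phase annotation file (onset_s, duration_s, label).

    Overlapping or touching intervals are normalised by merging, with a
    warning, so the result satisfies the EventList disjointness invariant.
    """
    path = Path(path)
    raw: list[tuple[int, int]] = []
    lines = path.read_text().splitlines()
    for i, line in enumerate(lines):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if i == 0 and line.lower().startswith("onset"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        onset, dur = float(parts[0]), float(parts[1])
        a, b = int(round(onset)), int(round(onset + dur))
        if b > a:
            raw.append((a, b))
    raw.sort()
    merged: list[tuple[int, int]] = []
    overlapped = False
    for a, b in raw:
        if merged and a <= merged[-1][1]:
            if a < merged[-1][1]:
                overlapped = True
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    if overlapped:
        logger.warning("overlapping events in %s merged on read", path.name)
    return EventList(events=merged, source=source, band=band)


def write_events(ev: EventList, path: str | Path, label: str | None = None) -> Path:
    path = Path(path)
    label = label or (ev.source or "A")
    lines = [EVENT_HEADER]
    for a, b in ev.events:
        lines.append(f"{a}\t{b - a}\t{label}")
    path.write_text("\n".join(lines) + "\n")
    return path
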