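"""Multi-trace fusion of per-derivation CAP A-phase detections.

CAP is a global EEG phenomenon: an A phase should be visible concurrently on
several derivations, while artifacts typically contaminate a single trace.
Two fusion rules are provided:

* **Global Analysis** — the per-second union of the events found on every
  derivation, re-cleaned with the same merge-gap / minimum-duration rules as
  the local detector.  Maximises sensitivity at the cost of collecting every
  single-trace false positive.
* **Global Analysis — Common Events** — the Global Analysis output filtered
  to events supported by at least two derivations simultaneously; events seen
  on exactly one derivation (the typical artifact signature) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect_local import DetectorConfig, clean_events
from .io import EventList


@dataclass
class MultiTraceConfig:
    merge_gap_s: int = 1     # as in the local cleanup
    min_event_s: int = 2
    min_support: int = 2     # derivations that must co-detect a common event
    min_overlap_s: int = 1   # seconds of >=min_support coverage required

    def _detector_cfg(self) -> DetectorConfig:
        return DetectorConfig(merge_gap_s=self.merge_gap_s,
                              min_event_s=self.min_event_s)


def _support_counts(per_derivation: dict[str, EventList], n_seconds: int) -> np.ndarray:
    counts = np.zeros(n_seconds, dtype=int)
    for ev in per_derivation.values():
        counts += ev.to_mask(n_seconds)
    return counts


def global_analysis(per_derivation: dict[str, EventList], n_seconds: int,
                    cfg: MultiTraceConfig | None = None) -> EventList:
    """Per-second union of all derivations' events, merged and cleaned."""
    cfg = cfg or MultiTraceConfig()
    if not per_derivation:
        raise ValueError("global analysis needs at least one derivation")
    union = _support_counts(per_derivation, n_seconds) >= 1
    return clean_events(union, cfg._detector_cfg(), source="global", band="merged")


def common_events(per_derivation: dict[str, EventList], n_seconds: int,
                  cfg: MultiTraceConfig | None = None) -> EventList:
    """Global events supported by >= ``min_support`` derivations at once.

    Support is evaluated on the raw per-derivation event lists inside each
    merged global event: the event is retained iff at least
    ``min_overlap_s`` of its seconds are covered by ``min_support`` or more
    derivations simultaneously.
    """
    cfg = cfg or MultiTraceConfig()
    if len(per_derivation) < cfg.min_support:
        raise ValueError(
            f"common-events fusion needs >= {cfg.min_support} derivations, "
            f"got {len(per_derivation)}"
        )
    glob = global_analysis(per_derivation, n_seconds, cfg)
    counts = _support_counts(per_derivation, n_seconds)
    kept = [
        (a, b) for a, b in glob.events
        if int((counts[a:b] >= cfg.min_support).sum()) >= cfg.min_overlap_s
    ]
    return EventList(events=kept, source="common", band="merged")
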