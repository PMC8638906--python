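#!/usr/bin/env python
"""Optional harness for locally downloaded CAP Sleep Database recordings.

Given one recording of PhysioNet's CAP Sleep Database (an EDF file plus its
expert scoring text file, downloaded separately), this script runs the
single-derivation detector on each available analysis derivation and both
multi-trace fusions, and prints the per-method performance metrics against
the expert's CAP A annotation in a layout comparable with a per-subject
clinical report.

The PhysioNet scoring files come in slightly varying dialects; this reader
is best-effort (it looks for event onset/duration columns and "A1"/"A2"/
"A3"/"A" phase labels, and for the stage column to rebuild the hypnogram).
Nothing here is part of the tested contract.

Usage:
    python scripts/physionet_harness.py --edf n1.edf --scoring n1.txt
"""

from __future__ import annotations

import argparse
import json
import re
import sys
from pathlib import Path

import capdetect as cd
from capdetect.evaluate import match_events, metrics

DERIVATIONS = ["Fp2-F4", "F2-F4", "F4-C4", "C4-P4", "P4-O2", "C4-A1", "F4-A1"]
STAGE_MAP = {"W": "W", "S1": "S1", "S2": "S2", "S3": "S3", "S4": "S4",
             "R": "R", "REM": "R", "MT": "MT"}


def parse_scoring(path: Path, epoch_len_s: int = 30):
    """Best-effort parse of a CAP Sleep Database scoring file."""
    a_events, stage_rows = [], []
    for line in path.read_text(errors="replace").splitlines():
        parts = re.split(r"[\t;]", line.strip())
        if len(parts) < 3:
            continue
        # look for: position/onset (s), duration (s), event label, stage
        nums = [p for p in parts if re.fullmatch(r"\d+", p)]
        label = next((p for p in parts if re.fullmatch(r"A[123]?", p)), None)
        stage = next((STAGE_MAP[p] for p in parts if p in STAGE_MAP), None)
        if label and len(nums) >= 2:
            onset, dur = int(nums[0]), int(nums[1])
            if dur > 0:
                a_events.append((onset, onset + dur))
        if stage is not None and nums:
            stage_rows.append((int(nums[0]), stage))
    stages = []
    for onset, stage in sorted(stage_rows):
        idx = onset // epoch_len_s
        while len(stages) < idx:
            stages.append("UNK")
        stages.append(stage)
    merged = []
    for a, b in sorted(a_events):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return (cd.EventList(events=merged, source="scorer"),
            cd.Hypnogram(stages=stages) if stages else None)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--edf", type=Path, required=True)
    ap.add_argument("--scoring", type=Path, required=True)
    ap.add_argument("--hypnogram", type=Path, default=None,
                    help="Separate hypnogram file if the scoring file has no stages.")
    args = ap.parse_args()

    reference, hyp = parse_scoring(args.scoring)
    if hyp is None:
        if args.hypnogram is None:
            print("no stages found in scoring file; pass --hypnogram", file=sys.stderr)
            return 1
        hyp = cd.read_hypnogram(args.hypnogram)

    import mne
    raw = mne.io.read_raw_edf(str(args.edf), preload=False, verbose="error")
    rec = cd.read_edf(args.edf, [ch for ch in raw.ch_names if "-" in ch])
    wanted = [lab for lab in DERIVATIONS
              if lab in rec.channel_labels or "-" in lab]
    derivs = []
    for lab in wanted:
        try:
            derivs.extend(cd.build_derivations(rec, [lab]))
        except cd.io.DerivationError:
            pass
    if not derivs:
        print("none of the analysis derivations could be built", file=sys.stderr)
        return 1

    n_seconds = int(rec.duration_s)
    per = {d.label: cd.detect_derivation(d, hyp) for d in derivs}
    rows = dict(per)
    if len(per) >= 2:
        rows["Global Analysis"] = cd.global_analysis(per, n_seconds)
        rows["Global Analysis - Common Events"] = cd.common_events(per, n_seconds)

    table = {}
    for name, ev in rows.items():
        m = metrics(match_events(ev, reference))
        table[name] = {k: (round(v, 2) if v is not None else None)
                       for k, v in vars(m).items()}
    print(json.dumps(table, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
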