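import numpy as np
import pytest

import capdetect as cd


@pytest.fixture(scope="session")
def study_fixture():
    """The 60-min, 6-derivation synthetic recording used for end-to-end
    parameter-recovery checks: bursts at twice the in-band background RMS,
    default CAP rate and stage plan, generator default seed."""
    cfg = cd.SimConfig(duration_min=60.0, seed=0, burst_amplitude_ratio=2.0)
    rec, gt = cd.simulate(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def study_detections(study_fixture):
    """Per-derivation, global and common-events detections on the study fixture."""
    _, rec, gt = study_fixture
    hyp = gt.hypnogram
    n_seconds = int(rec.duration_s)
    derivs = cd.build_derivations(rec, rec.channel_labels)
    per = {d.label: cd.detect_derivation(d, hyp) for d in derivs}
    glob = cd.global_analysis(per, n_seconds)
    common = cd.common_events(per, n_seconds)
    return {"per_derivation": per, "global": glob, "common": common,
            "n_seconds": n_seconds}


@pytest.fixture()
def all_s2_hypnogram():
    def make(n_epochs: int) -> cd.Hypnogram:
        return cd.Hypnogram(stages=["S2"] * n_epochs)
    return make
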