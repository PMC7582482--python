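import numpy as np
import pytest
from hypothesis import settings

from mousebeat import arrhythmia as arr
from mousebeat import ecg, simulate as sim

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: printed per-subject, per-type 24 h event counts for the two genotypes
#: (order: single, doublet, run>=3 extrasystoles, sinus arrest, blocked P,
#: AV block); used as tabulation inputs
PUBLISHED_EVENT_COUNTS = {
    "WT_A": [2, 0, 0, 14, 12, 3],
    "WT_B": [33, 0, 0, 27, 3, 0],
    "WT_C": [6, 0, 0, 29, 2, 0],
    "WT_D": [14, 1, 0, 3, 1, 0],
    "MFS_A": [50, 4, 0, 3, 7, 0],
    "MFS_B": [894, 275, 2, 9, 1, 0],
    "MFS_C": [204, 27, 1, 10, 7, 0],
    "MFS_D": [41, 16, 0, 17, 3, 1],
}


def published_counts_as_dicts() -> dict[str, dict[str, int]]:
    return {
        subj: dict(zip(sim.EVENT_TYPES, counts))
        for subj, counts in PUBLISHED_EVENT_COUNTS.items()
    }


@pytest.fixture(scope="session")
def synthetic_recording():
    """A 10-min mouse trace with 5 injected events of each type + truth."""
    spec = sim.RRSpec(mean_rr_ms=100.0, sd_rr_ms=2.0, duration_s=600.0, seed=1)
    rr = sim.generate_rr_series(spec)
    specs = [
        sim.EventSpec(t, 5, pause_multiple=2.3) if t == "sinus_arrest"
        else sim.EventSpec(t, 5)
        for t in sim.EVENT_TYPES
    ]
    rr_out, truth = sim.inject_events(rr, specs, seed=3)
    trace = sim.synthesize_ecg(truth, noise_sd=0.05, seed=5)
    return trace, rr_out, truth


@pytest.fixture(scope="session")
def detected(synthetic_recording):
    """Detection + classification results on the shared recording."""
    trace, _, truth = synthetic_recording
    r = ecg.detect_r_peaks(trace)
    pw = ecg.detect_p_waves(trace, r)
    series = ecg.rr_intervals(r)
    events = arr.classify_events(series, arr.flag_deviant_rr(series.rr), pw)
    return r, pw, series, events
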