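import numpy as np
import pytest

from hrvstim import synth
from hrvstim.core import RrSeries
from hrvstim.evaluate import ClassHierarchy


@pytest.fixture
def hierarchy_2x2() -> ClassHierarchy:
    return ClassHierarchy(
        {"consonant": ["unison", "fifth"], "dissonant": ["tritone", "minor_second"]}
    )


@pytest.fixture
def constant_rr() -> RrSeries:
    return RrSeries(np.full(100, 800.0))


@pytest.fixture
def alternating_rr() -> RrSeries:
    """101 intervals alternating 800/860 ms: the 100 successive differences
    are exactly +/-60 ms with zero mean, so closed forms are exact."""
    return RrSeries(np.concatenate([np.tile([800.0, 860.0], 50), [800.0]]))


@pytest.fixture
def clean_ecg_60bpm():
    """60 s of clean ECG at exactly 60 bpm with known R apexes."""
    rr = synth.generate_rr_series(
        synth.RrGenConfig(
            duration_s=60, mean_rr_ms=1000, lf_mod=(0.1, 0.0), hf_mod=(0.25, 0.0),
            jitter_sd_ms=0.0, seed=0,
        )
    )
    return synth.generate_ecg(rr, synth.EcgGenConfig(sample_rate_hz=360))


def match_beats(detected_s, truth_s, tol_s=0.02):
    """Sensitivity and positive predictivity of detected beat times."""
    detected_s = np.asarray(detected_s)
    truth_s = np.asarray(truth_s)
    if len(detected_s) == 0:
        return 0.0, 0.0
    tp = sum(np.min(np.abs(detected_s - t)) <= tol_s for t in truth_s)
    pred_ok = sum(np.min(np.abs(truth_s - d)) <= tol_s for d in detected_s)
    return tp / len(truth_s), pred_ok / len(detected_s)
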