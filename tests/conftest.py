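import numpy as np
import pytest

from ecgtfmap.preprocess import bandpass_filter, detect_r_peaks_combined
from ecgtfmap.synthetic import SynthesisConfig, synthesize_record


@pytest.fixture(scope="session")
def clean_nsr():
    """Noise-free 60 bpm NSR record with ground truth (10 s, 500 Hz)."""
    cfg = SynthesisConfig(class_label="NSR", heart_rate_bpm=60, duration_s=10,
                          noise_sd_mv=0.0, baseline_wander_amp_mv=0.0, seed=1)
    return synthesize_record(cfg)


@pytest.fixture(scope="session")
def filtered_nsr(clean_nsr):
    record, truth = clean_nsr
    return bandpass_filter(record), truth


@pytest.fixture(scope="session")
def nsr_sequences(filtered_nsr):
    from ecgtfmap.clustering import build_sequences
    record, _ = filtered_nsr
    peaks = detect_r_peaks_combined(record.signal[0], record.fs)
    return build_sequences(record, peaks)
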