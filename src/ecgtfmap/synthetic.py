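"""Synthetic 12-lead ECG generator with per-beat ground truth.

Each heartbeat is a sum of five Gaussian bumps (P, Q, R, S, T) on a common
time axis; a fixed 12 x 5 gain table projects the bumps onto the 12 leads so
lead-specific morphology (e.g. the dominant S in V1, inverted aVR) is
plausible without any torso model. Rhythm classes are expressed as explicit
modifications of the template:

* ``NSR``   — unmodified template.
* ``AF``    — P amplitude zero, RR irregularity (coefficient of variation
  >= 0.25) and a band-limited 5.3–10 Hz fibrillatory oscillation.
* ``I-AVB`` — the P wave moved so the P-onset-to-QRS-onset interval exceeds
  200 ms on every beat.
* ``LBBB``  — QRS widened beyond 120 ms with an M-shaped notch, strongest in
  the lateral leads (I, aVL, V5, V6).
* ``RBBB``  — QRS widened with a secondary R' deflection in V1/V2 and a
  slurred S in the lateral leads.
* ``PAC``   — a minority run of premature beats (preceding RR shortened by
  40 %) with normal morphology.
* ``PVC``   — a minority run of premature beats that are P-less, wide
  (QRS 120–210 ms), tall and with discordant T.
* ``STD`` / ``STE`` — the ST segment offset by -/+ 0.1 mV or more.

Premature beats are emitted as one contiguous episode: the representative-
signal clustering operates on 3-beat sliding windows, where every abnormal
beat contaminates up to three windows, so a contiguous run is what keeps
abnormal windows a minority of the record the way an episodic arrhythmia
does.

Amplitudes are in mV, times in seconds, and the generator is bit-exact
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import CLASSES, LEAD_NAMES, EcgRecord

# Gaussian wave parameters of the template beat, relative to the R peak.
# columns: P, Q, R, S, T
_WAVE_CENTER_S = np.array([-0.21, -0.035, 0.0, 0.035, 0.32])
_WAVE_SIGMA_S = np.array([0.025, 0.012, 0.013, 0.014, 0.070])
_WAVE_AMP_MV = np.array([0.12, -0.08, 1.10, -0.25, 0.35])

# Per-lead gains for (P, Q, R, S, T); lead II is the reference. Right-
# precordial leads carry an rS pattern, aVR is inverted. Only relative
# differences between leads matter for exercising lead-specific morphology.
_LEAD_GAIN = np.array([
    [0.60, 0.50, 0.70, 0.50, 0.60],   # I
    [1.00, 1.00, 1.00, 1.00, 1.00],   # II
    [0.50, 0.60, 0.45, 0.60, 0.50],   # III
    [-0.80, -0.70, -0.90, -0.70, -0.80],  # aVR
    [0.30, 0.30, 0.35, 0.30, 0.30],   # aVL
    [0.75, 0.80, 0.70, 0.80, 0.75],   # aVF
    [0.25, 0.30, -0.45, 1.20, -0.40],  # V1
    [0.30, 0.40, -0.25, 1.50, 0.80],  # V2
    [0.35, 0.50, 0.35, 1.10, 0.90],   # V3
    [0.40, 0.60, 1.30, 0.80, 0.80],   # V4
    [0.45, 0.60, 1.15, 0.50, 0.70],   # V5
    [0.50, 0.50, 0.90, 0.30, 0.60],   # V6
])

_LATERAL = [LEAD_NAMES.index(n) for n in ("I", "aVL", "V5", "V6")]
_RIGHT_PRECORDIAL = [LEAD_NAMES.index(n) for n in ("V1", "V2")]


@dataclass
class SynthesisConfig:
    """Knobs of the generator; defaults emulate a 500 Hz short clinical strip."""

    fs: float = 500.0
    duration_s: float = 10.0
    heart_rate_bpm: float = 70.0
    rr_jitter_frac: float = 0.03
    class_label: str = "NSR"
    noise_sd_mv: float = 0.01
    baseline_wander_amp_mv: float = 0.05
    baseline_wander_hz: float = 0.25
    premature_fraction: float = 0.2   # PAC/PVC: fraction of beats in the episode
    st_fraction: float = 1.0          # STD/STE: fraction of beats with the shift
    st_offset_mv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30 <= self.heart_rate_bpm <= 220:
            raise ValueError(f"heart_rate_bpm {self.heart_rate_bpm} outside [30, 220]")
        if not 0 <= self.rr_jitter_frac <= 0.5:
            raise ValueError(f"rr_jitter_frac {self.rr_jitter_frac} outside [0, 0.5]")
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")


@dataclass
class BeatGroundTruth:
    """True R-peak locations and per-beat morphology tags."""

    r_sample_indices: list[int] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)  # normal|premature|ST-shifted|blocked

    def abnormal_indices(self) -> list[int]:
        return [r for r, t in zip(self.r_sample_indices, self.tags) if t != "normal"]


def _rr_series(cfg: SynthesisConfig, rng: np.random.Generator):
    """Beat-to-beat intervals and tags before morphology synthesis."""
    mean_rr = 60.0 / cfg.heart_rate_bpm
    jitter = cfg.rr_jitter_frac
    if cfg.class_label == "AF":
        jitter = max(jitter, 0.25)
    n_max = int(np.ceil(cfg.duration_s / (0.5 * mean_rr))) + 6
    rr = mean_rr * (1.0 + jitter * np.clip(rng.standard_normal(n_max), -2.5, 2.5))
    rr = np.maximum(rr, 0.3)
    # beats that will actually fit the record (placement must stay inside)
    n_fit = max(3, int(cfg.duration_s / mean_rr) - 1)

    tags = ["normal"] * (n_max + 1)
    if cfg.class_label in ("PAC", "PVC"):
        n_run = max(1, round(cfg.premature_fraction * n_fit))
        # contiguous premature episode away from the record edges
        start = int(rng.integers(1, max(2, n_fit - n_run)))
        for k in range(start, min(start + n_run, n_max)):
            rr[k - 1] *= 0.60          # beat arrives >= 25 % early
            tags[k] = "premature"
        stop = min(start + n_run, n_max - 1)
        rr[stop - 1] *= 1.25           # compensatory pause after the episode
    elif cfg.class_label in ("LBBB", "RBBB"):
        tags = ["blocked"] * (n_max + 1)
    elif cfg.class_label in ("STD", "STE"):
        n_shift = max(1, round(cfg.st_fraction * n_fit))
        if cfg.st_fraction >= 1.0:
            shifted = set(range(n_max + 1))
        else:
            start = int(rng.integers(1, max(2, n_fit - n_shift)))
            shifted = set(range(start, start + n_shift))
        tags = ["ST-shifted" if k in shifted else "normal"
                for k in range(n_max + 1)]
    return rr, tags


def _gauss(t, center, sigma):
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _beat_waveform(t: np.ndarray, r_time: float, lead: int, cfg: SynthesisConfig,
                   tag: str) -> np.ndarray:
    """One beat's contribution to one lead over the time axis ``t``."""
    centers = _WAVE_CENTER_S.copy()
    sigmas = _WAVE_SIGMA_S.copy()
    amps = _WAVE_AMP_MV * _LEAD_GAIN[lead]
    label = cfg.class_label
    extra = 0.0

    if label == "AF":
        amps[0] = 0.0
    elif label == "I-AVB":
        centers[0] = -0.30  # P onset ~350 ms before QRS onset (~60 ms pre-R)
    elif label == "LBBB":
        widen = 3.2 if lead in _LATERAL else 2.2
        sigmas[1:4] *= widen
        if lead in _LATERAL:  # M-shaped notch
            extra = extra + 0.55 * amps[2] * _gauss(t, r_time + 0.045, sigmas[2] * 0.6)
    elif label == "RBBB":
        sigmas[3] *= 3.0  # slurred, wide S
        if lead in _RIGHT_PRECORDIAL:
            rp = 0.6 if lead == _RIGHT_PRECORDIAL[0] else 0.3
            extra = extra + rp * _gauss(t, r_time + 0.055, 0.018)
    elif label == "PVC" and tag == "premature":
        amps[0] = 0.0
        sigmas[1:4] *= 4.0           # QRS width in the 120-210 ms range
        amps[2] *= 1.3
        amps[4] *= -1.0              # discordant T
        centers[4] = 0.40
    y = np.zeros_like(t)
    for c, s, a in zip(centers, sigmas, amps):
        if a != 0.0:
            y += a * _gauss(t, r_time + c, s)
    y = y + extra

    if label in ("STD", "STE") and tag == "ST-shifted":
        sign = -1.0 if label == "STD" else 1.0
        # plateau between the end of S and the T peak, tapered by gaussians
        st = sign * cfg.st_offset_mv * (
            0.5 * (np.tanh((t - (r_time + 0.06)) / 0.015)
                   - np.tanh((t - (r_time + 0.28)) / 0.03))
        )
        # strongest in the leads used clinically for ST assessment
        st *= max(0.4, abs(_LEAD_GAIN[lead, 4]))
        y = y + st
    return y


def synthesize_record(config: SynthesisConfig) -> tuple[EcgRecord, BeatGroundTruth]:
    """Generate one labeled 12-lead record plus exact beat-level ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    rr, tags_all = _rr_series(cfg, rng)
    first = 0.4 * 60.0 / cfg.heart_rate_bpm
    r_times = first + np.concatenate([[0.0], np.cumsum(rr)])
    keep = r_times < cfg.duration_s - 0.05
    r_times = r_times[keep]
    tags = [tags_all[k] for k in range(len(r_times))]
    if len(r_times) < 2:
        raise ValueError(
            f"duration {cfg.duration_s} s too short for two beats at "
            f"{cfg.heart_rate_bpm} bpm"
        )

    signal = np.zeros((12, n))
    for lead in range(12):
        y = np.zeros(n)
        for r_time, tag in zip(r_times, tags):
            y += _beat_waveform(t, r_time, lead, cfg, tag)
        signal[lead] = y

    if cfg.class_label == "AF":
        # band-limited fibrillatory oscillation, scaled like the P wave
        white = rng.standard_normal(n + 400)
        sos = sps.butter(2, [5.3, 10.0], btype="bandpass", fs=cfg.fs, output="sos")
        fib = sps.sosfiltfilt(sos, white)[200:200 + n]
        fib = 0.06 * fib / max(np.std(fib), 1e-12)
        signal += np.abs(_LEAD_GAIN[:, 0])[:, None] * fib[None, :]

    if cfg.baseline_wander_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi, size=12)
        signal += cfg.baseline_wander_amp_mv * np.sin(
            2 * np.pi * cfg.baseline_wander_hz * t[None, :] + phase[:, None]
        )
    if cfg.noise_sd_mv > 0:
        signal += cfg.noise_sd_mv * rng.standard_normal(signal.shape)

    record = EcgRecord(
        signal=signal, fs=cfg.fs,
        labels=[cfg.class_label],
        record_id=f"syn-{cfg.class_label}-{cfg.seed}",
    )
    truth = BeatGroundTruth(
        r_sample_indices=[int(round(rt * cfg.fs)) for rt in r_times],
        tags=tags,
    )
    return record, truth


def add_white_noise(record: EcgRecord, snr_db: float, seed: int = 0) -> EcgRecord:
    """Return a copy of ``record`` with white noise at the given SNR (per lead)."""
    rng = np.random.default_rng(seed)
    power = np.mean(record.signal ** 2, axis=1, keepdims=True)
    noise_sd = np.sqrt(power / 10 ** (snr_db / 10.0))
    noisy = record.signal + noise_sd * rng.standard_normal(record.signal.shape)
    return EcgRecord(signal=noisy, fs=record.fs, lead_names=list(record.lead_names),
                     labels=list(record.labels), record_id=record.record_id + "-noisy")


def make_dataset(class_labels, n_per_class: int, seed: int,
                 **config_kwargs) -> list[tuple[EcgRecord, BeatGroundTruth]]:
    """Convenience: n records per class with independent derived seeds."""
    base = SynthesisConfig(seed=0, **config_kwargs)
    out = []
    for ci, label in enumerate(class_labels):
        for k in range(n_per_class):
            cfg = replace(base, class_label=label,
                          seed=(seed * 10007 + ci * 389 + k) % (2 ** 31))
            out.append(synthesize_record(cfg))
    return out
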