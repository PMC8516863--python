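"""Noise removal and R-peak detection.

Filtering is a zero-phase Butterworth band-pass (default 0.5–50 Hz), which
removes baseline wander and motion artifact while keeping the QRS band.

R-peaks are detected on filtered lead I only and reused for all 12 leads.
Two detectors are provided and combined:

* Pan–Tompkins: 5–15 Hz band-pass, derivative, squaring, 150 ms moving-
  window integration, adaptive dual thresholds with search-back. The
  squaring stage suppresses QRS complexes that are unusually narrow or wide.
* Shannon-energy envelope: ``-v^2 log v^2`` of the normalised derivative,
  smoothed with a 120 ms rectangular window. The logarithm compresses the
  dynamic range, so wide or low-slope QRS complexes (e.g. ventricular
  ectopy) survive where squaring buries them.

The combined detector takes the union of both candidate sets and merges
candidates closer than the refractory period, keeping the one with the
larger absolute filtered amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import EcgRecord

#: Physiological minimum RR interval used to merge/duplicate-suppress peaks.
REFRACTORY_S = 0.2

#: Candidates are relocated to the signal extremum within this radius.
RELOCATE_RADIUS_S = 0.05


@dataclass
class FilterSpec:
    """Band-pass specification; defaults follow the 0.5–50 Hz analysis band."""

    low_cut_hz: float = 0.5
    high_cut_hz: float = 50.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ValueError(
                f"need 0 < low ({self.low_cut_hz}) < high ({self.high_cut_hz})"
            )
        if self.high_cut_hz >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high_cut_hz} Hz >= Nyquist ({fs / 2} Hz)"
            )


@dataclass
class RPeakSeries:
    """Strictly increasing R-peak sample indices detected on lead I."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.indices) / self.fs


def bandpass_filter(record: EcgRecord, spec: FilterSpec | None = None) -> EcgRecord:
    """Apply the same band-pass to every lead; zero-phase by default."""
    spec = spec or FilterSpec()
    spec.validate(record.fs)
    sos = sps.butter(spec.order, [spec.low_cut_hz, spec.high_cut_hz],
                     btype="bandpass", fs=record.fs, output="sos")
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, record.signal, axis=1)
    else:
        filtered = sps.sosfilt(sos, record.signal, axis=1)
    return EcgRecord(signal=filtered, fs=record.fs,
                     lead_names=list(record.lead_names),
                     labels=list(record.labels), record_id=record.record_id)


def _relocate(candidates: np.ndarray, x: np.ndarray, fs: float) -> np.ndarray:
    """Snap each candidate to the largest |x| within +/- RELOCATE_RADIUS_S."""
    r = max(1, int(round(RELOCATE_RADIUS_S * fs)))
    out = []
    for c in candidates:
        lo, hi = max(0, c - r), min(len(x), c + r + 1)
        out.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    return np.asarray(sorted(set(out)), dtype=int)


def _enforce_refractory(idx: np.ndarray, x: np.ndarray, fs: float) -> np.ndarray:
    """Greedy merge of detections closer than the refractory period,
    keeping the larger |amplitude| member of each near-coincident pair."""
    if idx.size == 0:
        return idx
    refr = int(round(REFRACTORY_S * fs))
    kept: list[int] = []
    for i in np.sort(idx):
        if kept and i - kept[-1] < refr:
            if abs(x[i]) > abs(x[kept[-1]]):
                kept[-1] = int(i)
        else:
            kept.append(int(i))
    return np.asarray(kept, dtype=int)


def detect_r_peaks_pan_tompkins(lead_signal: np.ndarray, fs: float) -> RPeakSeries:
    """Classic Pan–Tompkins QRS detector with adaptive thresholds."""
    x = np.asarray(lead_signal, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if np.ptp(x) == 0:
        return RPeakSeries(np.array([], dtype=int), fs)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # five-point derivative of the original formulation
    kernel = np.array([1, 2, 0, -2, -1]) * fs / 8.0
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    squared = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refr = int(round(REFRACTORY_S * fs))
    peaks, _ = sps.find_peaks(mwi, distance=refr)
    if peaks.size == 0:
        return RPeakSeries(np.array([], dtype=int), fs)

    # adaptive dual thresholds (signal/noise running estimates)
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    accepted: list[int] = []
    rr_history: list[float] = []
    for p in peaks:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[p] > thr1:
            accepted.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(accepted) >= 2:
                rr_history.append(accepted[-1] - accepted[-2])
                rr_history = rr_history[-8:]
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
    # search-back over long gaps with the lower threshold
    if rr_history:
        rr_avg = float(np.mean(rr_history))
        thr2 = 0.5 * (npki + 0.25 * (spki - npki))
        filled: list[int] = []
        prev = None
        for a in accepted:
            if prev is not None and a - prev > 1.66 * rr_avg:
                gap = peaks[(peaks > prev + refr) & (peaks < a - refr)]
                if gap.size:
                    best = gap[np.argmax(mwi[gap])]
                    if mwi[best] > thr2:
                        filled.append(int(best))
            filled.append(int(a))
            prev = a
        accepted = sorted(filled)

    cand = _relocate(np.asarray(accepted, dtype=int), bp, fs)
    return RPeakSeries(_enforce_refractory(cand, bp, fs), fs)


def shannon_energy_envelope(lead_signal: np.ndarray, fs: float) -> np.ndarray:
    """Smoothed Shannon energy of the normalised first difference."""
    x = np.asarray(lead_signal, dtype=float)
    # limit to the QRS band first: the differentiator amplifies wide-band
    # noise, which would lift the envelope floor between beats
    sos = sps.butter(2, [2.5, 20.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    d = np.diff(x, prepend=x[0])
    peak = np.max(np.abs(d))
    if peak == 0:
        return np.zeros_like(x)
    u = d / peak
    v2 = np.clip(u ** 2, 1e-12, None)
    se = -v2 * np.log(v2)
    win = max(1, int(round(0.120 * fs)))
    return np.convolve(se, np.ones(win) / win, mode="same")


def detect_r_peaks_shannon(lead_signal: np.ndarray, fs: float) -> RPeakSeries:
    """Shannon-energy envelope detector; robust to wide/narrow QRS widths."""
    x = np.asarray(lead_signal, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if np.ptp(x) == 0:
        return RPeakSeries(np.array([], dtype=int), fs)
    env = shannon_energy_envelope(x, fs)
    refr = int(round(REFRACTORY_S * fs))
    # adaptive height: a fraction of a robust upper quantile of the envelope
    height = 0.35 * np.quantile(env, 0.98)
    peaks, _ = sps.find_peaks(env, distance=refr, height=height)
    cand = _relocate(peaks, x, fs)
    return RPeakSeries(_enforce_refractory(cand, x, fs), fs)


def detect_r_peaks_combined(lead_signal: np.ndarray, fs: float) -> RPeakSeries:
    """Union of the Pan–Tompkins and Shannon-energy candidate sets.

    Near-coincident candidates (within the 200 ms refractory period) are
    merged to the member with the larger absolute amplitude.
    """
    x = np.asarray(lead_signal, dtype=float)
    pt = detect_r_peaks_pan_tompkins(x, fs)
    sh = detect_r_peaks_shannon(x, fs)
    merged = np.union1d(pt.indices, sh.indices)
    return RPeakSeries(_enforce_refractory(merged, x, fs), fs)


def detection_quality(detected: RPeakSeries, truth_indices,
                      tol_s: float = 0.05) -> tuple[float, float]:
    """(sensitivity, positive predictivity) of detections vs ground truth.

    A detection matches a true R-peak when within ``tol_s`` seconds; each
    truth and each detection is used at most once (greedy nearest match).
    """
    truth = np.asarray(sorted(truth_indices), dtype=int)
    det = np.asarray(detected.indices, dtype=int)
    if truth.size == 0:
        return (1.0, 1.0 if det.size == 0 else 0.0)
    if det.size == 0:
        return (0.0, 1.0)
    tol = tol_s * detected.fs
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in truth:
        j = int(np.argmin(np.abs(det - t)))
        if not used[j] and abs(det[j] - t) <= tol:
            used[j] = True
            tp += 1
    return tp / truth.size, tp / det.size
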