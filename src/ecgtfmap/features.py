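"""Stacked 12-lead STFT time-frequency feature maps.

Each lead of a representative three-beat window is transformed with a
short-time Fourier transform using 300-sample (600 ms at 500 Hz) segments
overlapping by 270 samples (540 ms, i.e. a 30-sample hop), giving a
frequency resolution of fs/300 = 1.667 Hz. Only the 0–50 Hz band is kept
(31 bins), the 12 per-lead magnitude spectrograms are stacked vertically in
canonical lead order (12 x 31 = 372 rows), and the stack is resized to
120 x 120 with separable linear interpolation and min-max normalised to
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.transform import resize

from .clustering import BeatSequence

MAP_SIZE = 120


@dataclass
class StftParams:
    """STFT analysis parameters.

    ``overlap_is_hop`` flips the interpretation of ``overlap`` from
    "samples shared between segments" (default: 270 shared, hop 30) to
    "hop size in samples".
    """

    n_per_segment: int = 300
    overlap: int = 270
    window_fn: str = "hann"
    freq_min_hz: float = 0.0
    freq_max_hz: float = 50.0
    fs: float = 500.0
    overlap_is_hop: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.overlap < self.n_per_segment:
            raise ValueError(
                f"need 0 < overlap ({self.overlap}) < segment "
                f"({self.n_per_segment})"
            )
        if self.freq_max_hz > self.fs / 2:
            raise ValueError(f"freq_max_hz {self.freq_max_hz} above Nyquist")

    @property
    def noverlap(self) -> int:
        return self.n_per_segment - self.overlap if self.overlap_is_hop else self.overlap

    @property
    def hop(self) -> int:
        return self.n_per_segment - self.noverlap

    @property
    def freq_resolution_hz(self) -> float:
        """Frequency bin spacing, fs / segment length."""
        return self.fs / self.n_per_segment

    def seconds_to_samples(self, seconds: float) -> int:
        return int(round(seconds * self.fs))

    def samples_to_seconds(self, samples: int) -> float:
        return samples / self.fs


@dataclass
class TimeFrequencyMap:
    """The 120 x 120 stacked-lead map fed to the CNN; values in [0, 1]."""

    values: np.ndarray
    source_record_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (MAP_SIZE, MAP_SIZE):
            raise ValueError(f"expected {MAP_SIZE}x{MAP_SIZE}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")


def stft_spectrogram(signal: np.ndarray, params: StftParams | None = None
                     ) -> np.ndarray:
    """One-sided magnitude spectrogram (freq bins x time frames).

    Magnitudes are those of the windowed-segment DFT normalised by the
    window sum, so a unit-amplitude mid-band sinusoid contributes ~0.5 to
    its bin. Rows are frequency bins spaced fs / n_per_segment apart.
    """
    params = params or StftParams()
    x = np.asarray(signal, dtype=float)
    if x.size < params.n_per_segment:
        raise ValueError(
            f"signal length {x.size} shorter than one segment "
            f"({params.n_per_segment})"
        )
    _, _, Z = sps.stft(
        x, fs=params.fs, window=params.window_fn,
        nperseg=params.n_per_segment, noverlap=params.noverlap,
        boundary=None, padded=False, detrend=False, return_onesided=True,
    )
    return np.abs(Z)


def crop_band(spectrogram: np.ndarray, params: StftParams | None = None
              ) -> np.ndarray:
    """Restrict rows to bins whose centre frequency is inside the band."""
    params = params or StftParams()
    freqs = np.arange(spectrogram.shape[0]) * params.freq_resolution_hz
    keep = (freqs >= params.freq_min_hz) & (freqs <= params.freq_max_hz)
    return spectrogram[keep]


def stack_lead_spectrograms(sequence: BeatSequence | np.ndarray,
                            params: StftParams | None = None) -> np.ndarray:
    """Per-lead cropped spectrograms stacked vertically in lead order."""
    params = params or StftParams()
    matrix = np.asarray(getattr(sequence, "resampled", sequence), dtype=float)
    blocks = [crop_band(stft_spectrogram(matrix[lead], params), params)
              for lead in range(matrix.shape[0])]
    return np.vstack(blocks)


def build_feature_map(sequence: BeatSequence | np.ndarray,
                      params: StftParams | None = None) -> TimeFrequencyMap:
    """Full map: stack leads, resize to 120 x 120, min-max normalise."""
    params = params or StftParams()
    stacked = stack_lead_spectrograms(sequence, params)
    resized = resize(stacked, (MAP_SIZE, MAP_SIZE), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    lo, hi = float(resized.min()), float(resized.max())
    if hi - lo < 1e-15:  # constant map: normalise to zeros, not NaN
        values = np.zeros_like(resized)
    else:
        values = (resized - lo) / (hi - lo)
    return TimeFrequencyMap(
        values=values,
        source_record_id=getattr(sequence, "source_record_id", ""),
    )
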