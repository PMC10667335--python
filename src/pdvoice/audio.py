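"""WAV I/O and telephone-voice preprocessing.

The pipeline works on mono 16-bit PCM recordings of a sustained /a/ vowel,
digitized at 8 kHz as a telephone voicemail system would produce them.
Preprocessing mirrors the front end of the analysis: rescale amplitudes to
[-1, 1], trim leading/trailing silence by short-time energy, and drop any
recording with less than ``min_duration`` seconds of signal left.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy.io import wavfile

from .exceptions import DegenerateSignalError, FormatError, PdVoiceError

#: Quantization step of a 16-bit codeword mapped onto [-1, 1].
QUANT_STEP = 2.0 ** -15

# Sex-dependent pitch-search bounds in Hz.  These are the canonical
# sex-specific F0 ranges for sustained phonation; they bound the lag search
# of the autocorrelation pitch tracker.
PITCH_BOUNDS_HZ = {"male": (75.0, 300.0), "female": (100.0, 600.0)}


@dataclass(frozen=True)
class VoiceSample:
    """A digitized voice recording.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes in [-1, 1] (after rescaling).
    fs : int
        Sampling frequency in Hz; telephone voicemail digitizes at 8000.
    bit_depth : int
        Codeword width of the source stream (16 for telephone voicemail).
    provenance : object, optional
        Either the :class:`~pdvoice.synth.PhonationParams` that generated the
        signal or the source file path.
    """

    samples: np.ndarray
    fs: int = 8000
    bit_depth: int = 16
    provenance: object = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        # zero length is tolerated only as the all-silent result of
        # trim_silence; every analysis entry point rejects it
        if samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    trim_window
        Width of the short-time-energy window in samples (100 samples =
        12.5 ms at 8 kHz).  Windows are scanned without overlap.
    energy_threshold
        Fraction of the peak window energy below which edge windows count
        as silence.  1% is robust for quantized telephone signals whose
        noise floor sits well below the vowel.
    min_duration
        Minimum retained duration in seconds; shorter recordings are
        rejected from the analysis.
    pitch_floor_ceiling
        Sex-keyed (floor, ceiling) Hz pairs consumed by F0 estimation.
    """

    trim_window: int = 100
    energy_threshold: float = 0.01
    min_duration: float = 1.5
    pitch_floor_ceiling: dict = field(
        default_factory=lambda: dict(PITCH_BOUNDS_HZ)
    )

    def __post_init__(self) -> None:
        if self.trim_window < 1:
            raise ValueError("trim_window must be >= 1")
        if not 0.0 < self.energy_threshold < 1.0:
            raise ValueError("energy_threshold must be in (0, 1)")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        for sex, (lo, hi) in self.pitch_floor_ceiling.items():
            if not lo < hi:
                raise ValueError(f"pitch bounds for {sex!r} must satisfy floor < ceiling")


def read_wav(path) -> VoiceSample:
    """Read a mono 16-bit RIFF PCM file into a :class:`VoiceSample`.

    Integer codewords are mapped onto [-1, 1) by dividing by 2**15, so a
    write/read round trip is exact up to one quantization step.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(str(path))
    except (ValueError, EOFError) as exc:
        raise FormatError(f"{path}: not a readable RIFF PCM file ({exc})") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype != np.int16:
        raise FormatError(f"{path}: expected 16-bit PCM, got dtype {data.dtype}")
    if data.size == 0:
        raise FormatError(f"{path}: zero-length payload")
    samples = data.astype(np.float64) / 32768.0
    return VoiceSample(samples=samples, fs=int(fs), bit_depth=16, provenance=str(path))


def write_wav(sample: VoiceSample, path) -> None:
    """Write a :class:`VoiceSample` as mono 16-bit RIFF PCM."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clipped = np.clip(sample.samples, -1.0, 1.0 - QUANT_STEP)
    codes = np.round(clipped * 32768.0).astype(np.int16)
    wavfile.write(str(path), int(sample.fs), codes)


def rescale_amplitude(sample: VoiceSample) -> VoiceSample:
    """Rescale so the largest absolute amplitude is exactly 1.

    The waveform shape is preserved: output = input / max|input|.
    """
    peak = float(np.max(np.abs(sample.samples)))
    if peak == 0.0:
        raise DegenerateSignalError("cannot rescale an all-zero signal")
    return replace(sample, samples=sample.samples / peak)


def _window_energies(x: np.ndarray, window: int) -> np.ndarray:
    n_windows = x.size // window
    if n_windows == 0:
        return np.empty(0)
    trimmed = x[: n_windows * window]
    return np.sum(trimmed.reshape(n_windows, window) ** 2, axis=1)


def trim_silence(sample: VoiceSample, cfg: Optional[PreprocessConfig] = None) -> VoiceSample:
    """Remove leading/trailing silence by thresholded short-time energy.

    The signal is scanned in non-overlapping windows of ``cfg.trim_window``
    samples; leading and trailing runs of windows whose energy falls below
    ``cfg.energy_threshold`` x (peak window energy) are dropped.  The
    retained interior is returned untouched, cut on window boundaries, which
    makes the operation idempotent.  If every window is below threshold the
    result is empty and the caller decides rejection.
    """
    cfg = cfg or PreprocessConfig()
    energies = _window_energies(sample.samples, cfg.trim_window)
    if energies.size == 0:
        return replace(sample, samples=sample.samples[:0])
    peak = float(energies.max())
    if peak == 0.0:
        return replace(sample, samples=sample.samples[:0])
    above = energies >= cfg.energy_threshold * peak
    if not above.any():
        return replace(sample, samples=sample.samples[:0])
    first = int(np.argmax(above))
    last = int(len(above) - 1 - np.argmax(above[::-1]))
    w = cfg.trim_window
    return replace(sample, samples=sample.samples[first * w : (last + 1) * w])


def duration_filter(sample: VoiceSample, cfg: Optional[PreprocessConfig] = None) -> bool:
    """Return True (keep) iff the trimmed recording lasts >= min_duration."""
    cfg = cfg or PreprocessConfig()
    return sample.samples.size / sample.fs >= cfg.min_duration


def truncate_to(sample: VoiceSample, seconds: float) -> VoiceSample:
    """Keep only the first ``seconds`` of the recording.

    Used to make spectrogram images directly comparable across subjects
    (exactly 1.5 s of voiced vowel each).
    """
    n = int(round(seconds * sample.fs))
    if sample.samples.size < n:
        raise PdVoiceError(
            f"recording is {sample.duration:.3f} s, shorter than requested {seconds} s"
        )
    return replace(sample, samples=sample.samples[:n])


def preprocess(
    sample: VoiceSample, cfg: Optional[PreprocessConfig] = None
) -> Tuple[Optional[VoiceSample], bool]:
    """Full front end: rescale, trim silence, apply the duration filter.

    Returns ``(processed, keep)``; ``processed`` is None when the recording
    is rejected (all-silent or too short after trimming).
    """
    cfg = cfg or PreprocessConfig()
    try:
        rescaled = rescale_amplitude(sample)
    except DegenerateSignalError:
        return None, False
    trimmed = trim_silence(rescaled, cfg)
    if trimmed.samples.size == 0 or not duration_filter(trimmed, cfg):
        return None, False
    return trimmed, True
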