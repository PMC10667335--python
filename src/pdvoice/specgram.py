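"""Normalized spectrograms of the first 1.5 s and 600x600 image rendering.

The short-time Fourier transform uses the same framing as the spectral
features (256-sample windows, 50% overlap -> 92 windows in 1.5 s at 8 kHz),
a Hann taper and a zero-padded 1024-point FFT.  Energies are normalized to
the global maximum on a decibel scale, 10*log10(|S| / max|S|), so the
matrix maximum is exactly 0 and the map is invariant to the overall
recording level.  Images are rendered without axes or margins at exactly
600x600 pixels, in color (viridis) or grayscale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.fft import rfft

from .audio import VoiceSample
from .exceptions import PdVoiceError
from .spectral import frame_signal

NFFT = 1024
WINDOW = 256
OVERLAP = 0.5
SEGMENT_S = 1.5
EPS = 1e-12
DEFAULT_COLORMAP = "viridis"
IMAGE_SIZE = 600


@dataclass(frozen=True)
class Spectrogram:
    """One-sided STFT with dB normalization to the global peak."""

    S: np.ndarray        # complex, (n_freq, n_frames)
    norm_db: np.ndarray  # real, same shape, max exactly 0
    freq_axis: np.ndarray
    time_axis: np.ndarray


@dataclass(frozen=True)
class SpectrogramImage:
    """A rendered 600x600 raster and its provenance."""

    pixels: np.ndarray  # uint8, (H, W) grayscale or (H, W, 3) color
    mode: str
    colormap: str
    source_id: str = ""


def compute_spectrogram(
    sample: VoiceSample,
    window: int = WINDOW,
    overlap: float = OVERLAP,
    nfft: int = NFFT,
    expected_duration: Optional[float] = SEGMENT_S,
) -> Spectrogram:
    """STFT of a fixed-duration segment with peak-normalized dB energies.

    ``expected_duration`` (1.5 s by default) is enforced so that images are
    directly comparable across subjects; pass None to lift the check.
    """
    if expected_duration is not None:
        expected = int(round(expected_duration * sample.fs))
        if sample.samples.size != expected:
            raise PdVoiceError(
                f"expected exactly {expected} samples ({expected_duration} s at "
                f"{sample.fs} Hz), got {sample.samples.size}; truncate first"
            )
    frames = frame_signal(sample, window, overlap)
    taper = np.hanning(window)
    S = rfft(frames.frames * taper, n=nfft, axis=1).T  # (nfft//2+1, n_frames)
    mag = np.abs(S)
    peak = mag.max()
    if peak <= 0:
        raise PdVoiceError("all-zero signal has no spectrogram")
    norm_db = 10.0 * np.log10(np.maximum(mag, EPS * peak) / peak)
    freq_axis = np.arange(nfft // 2 + 1) * sample.fs / nfft
    time_axis = (np.arange(frames.n_frames) * frames.hop + window / 2) / sample.fs
    return Spectrogram(S=S, norm_db=norm_db, freq_axis=freq_axis, time_axis=time_axis)


def render_image(
    spec: Spectrogram,
    mode: str = "color",
    out_path=None,
    size: int = IMAGE_SIZE,
    colormap: str = DEFAULT_COLORMAP,
    source_id: str = "",
    db_floor: float = -80.0,
) -> SpectrogramImage:
    """Render the normalized dB field as a size x size raster.

    The dB field is clipped to [db_floor, 0] and mapped to [0, 1]; grayscale
    uses that intensity directly, color maps it through ``colormap``.
    Frequency increases upward and time rightward; the raster has no axes,
    margins or decorations, and rendering is deterministic.
    """
    if mode not in ("color", "grayscale"):
        raise PdVoiceError(f"mode must be 'color' or 'grayscale', got {mode!r}")
    field = np.clip(spec.norm_db, db_floor, 0.0)
    intensity = (field - db_floor) / (-db_floor)  # 0..1
    intensity = np.flipud(intensity)  # frequency axis upward
    if mode == "grayscale":
        img8 = np.round(intensity * 255.0).astype(np.uint8)
        image = Image.fromarray(img8, mode="L")
    else:
        cmap = colormaps[colormap]
        rgba = cmap(intensity)
        img8 = np.round(rgba[:, :, :3] * 255.0).astype(np.uint8)
        image = Image.fromarray(img8, mode="RGB")
    image = image.resize((size, size), resample=Image.BILINEAR)
    pixels = np.asarray(image)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        image.save(out_path)
    return SpectrogramImage(
        pixels=pixels, mode=mode, colormap=colormap if mode == "color" else "gray",
        source_id=source_id,
    )
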