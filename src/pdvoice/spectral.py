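"""Windowed spectral features: LPC, LAR, cepstral and mel-cepstral vectors.

The recording is cut into 32 ms (256-sample) windows with 50% overlap.  Each
window is fitted with an order-10 autoregressive model by solving the
Yule-Walker equations with the Levinson-Durbin recursion; the recursion's
reflection (partial-correlation) coefficients feed the log-area-ratio
transform, and the prediction coefficients feed the cepstral recursion.
Mel-frequency cepstral coefficients come from a 26-filter triangular mel
bank over 0-4 kHz followed by a DCT.  Per-recording feature vectors are the
elementwise mean and (sample) variance of each family across windows.

Sign convention, used consistently here and by the formant tracker: the
prediction polynomial is A(z) = 1 - sum_{k=1}^{p} a_k z^{-k}, i.e. a_k are
the *predictor* coefficients with x_t ~ sum a_k x_{t-k}.  Under this
convention the first cepstral coefficient of the model spectrum equals a_1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.fft import dct, rfft

from .audio import VoiceSample
from .exceptions import ConditioningError, DegenerateSignalError, PdVoiceError

LPC_ORDER = 10
FRAME_LENGTH = 256  # 32 ms at 8 kHz
FRAME_OVERLAP = 0.5
N_CEPSTRUM = 12
N_MFCC = 13  # includes the 0th (energy) coefficient
N_MEL_FILTERS = 26
LOG_FLOOR = 1e-12

FAMILIES = ("lpc", "lar", "cep", "mfcc")


@dataclass(frozen=True)
class FrameSet:
    """Fixed-length analysis windows of one recording."""

    frames: np.ndarray  # (n_frames, frame_length)
    frame_length: int
    hop: int
    fs: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SpectralFrameFeatures:
    """All coefficient families of a single analysis window."""

    lpc: np.ndarray
    reflection: np.ndarray
    lar: np.ndarray
    cep: np.ndarray
    mfcc: np.ndarray
    prediction_error: float


@dataclass(frozen=True)
class SpectralSummary:
    """Mean and sample-variance vectors of each family across windows."""

    means: Dict[str, np.ndarray]
    variances: Dict[str, np.ndarray]
    n_frames: int

    def vector(self, family: str, pool: str) -> np.ndarray:
        """One pooled feature vector, e.g. vector('mfcc', 'var')."""
        if family not in FAMILIES:
            raise PdVoiceError(f"unknown family {family!r}")
        if pool == "mean":
            return self.means[family]
        if pool == "var":
            return self.variances[family]
        raise PdVoiceError(f"unknown pool {pool!r}; use 'mean' or 'var'")


def frame_signal(
    sample: VoiceSample,
    frame_length: int = FRAME_LENGTH,
    overlap: float = FRAME_OVERLAP,
) -> FrameSet:
    """Slice into fixed windows; a trailing partial window is discarded.

    With the defaults (256 samples, 50% overlap) a 1.5 s recording at 8 kHz
    yields exactly 92 windows.
    """
    x = sample.samples
    if x.size < frame_length:
        raise PdVoiceError(
            f"signal of {x.size} samples shorter than one {frame_length}-sample frame"
        )
    hop = int(round(frame_length * (1.0 - overlap)))
    if hop < 1:
        raise PdVoiceError("overlap leaves a hop of zero samples")
    n_frames = (x.size - frame_length) // hop + 1
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameSet(frames=x[idx], frame_length=frame_length, hop=hop, fs=sample.fs)


def levinson_durbin(
    autocorr: Sequence[float], p: int
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Solve the order-p Yule-Walker equations by Levinson-Durbin recursion.

    Parameters
    ----------
    autocorr : sequence of length >= p + 1
        Autocorrelation values r(0)..r(p); r(0) must be positive.
    p : int
        Model order.

    Returns
    -------
    a : ndarray, shape (p,)
        Predictor coefficients in the 1 - sum a_k z^-k convention.
    reflection : ndarray, shape (p,)
        Per-stage reflection (partial-correlation) coefficients c_k.
    prediction_error : float
        Final residual power.

    Raises
    ------
    ConditioningError
        If the sequence is not positive definite (some |c_k| >= 1).
    """
    r = np.asarray(autocorr, dtype=float)
    if r.size < p + 1:
        raise PdVoiceError(f"need lags 0..{p}, got {r.size} values")
    if p < 1:
        raise PdVoiceError("order must be >= 1")
    if r[0] <= 0:
        raise ConditioningError("autocorrelation at lag 0 must be positive")
    a = np.zeros(p)
    reflection = np.zeros(p)
    err = r[0]
    for k in range(p):
        acc = r[k + 1] - np.dot(a[:k], r[k:0:-1])
        c = acc / err
        if not np.isfinite(c) or abs(c) >= 1.0:
            raise ConditioningError(
                f"reflection coefficient |c_{k+1}| >= 1: non-positive-definite sequence"
            )
        reflection[k] = c
        a_new = a.copy()
        a_new[k] = c
        a_new[:k] = a[:k] - c * a[k - 1 :: -1] if k > 0 else a_new[:k]
        a = a_new
        err *= 1.0 - c * c
    return a, reflection, float(err)


def lar_transform(reflection: Sequence[float]) -> np.ndarray:
    """Log-area ratios g_k = log((1 - c_k) / (1 + c_k)); requires |c_k| < 1."""
    c = np.asarray(reflection, dtype=float)
    if np.any(np.abs(c) >= 1.0):
        raise PdVoiceError("log-area ratio undefined for |c_k| >= 1")
    return np.log((1.0 - c) / (1.0 + c))


def lpc_to_cepstrum(
    lpc: Sequence[float], prediction_error: float = 1.0, n_coeffs: int = N_CEPSTRUM
) -> np.ndarray:
    """Cepstral coefficients of the all-pole model spectrum, by recursion.

    With A(z) = 1 - sum a_k z^-k the cepstrum of the model magnitude
    spectrum sqrt(err)/|A| satisfies

        cep_n = a_n + (1/n) * sum_{m=1}^{n-1} m * cep_m * a_{n-m},

    with a_n = 0 for n > p.  The gain term log(sqrt(err)) is not included
    in the returned vector (coefficients 1..n_coeffs).
    """
    a = np.asarray(lpc, dtype=float)
    p = a.size
    cep = np.zeros(n_coeffs)
    for n in range(1, n_coeffs + 1):
        acc = a[n - 1] if n <= p else 0.0
        for m in range(1, n):
            if n - m <= p:
                acc += (m / n) * cep[m - 1] * a[n - m - 1]
        cep[n - 1] = acc
    return cep


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    fs: int, n_fft: int, n_filters: int = N_MEL_FILTERS,
    f_min: float = 0.0, f_max: Optional[float] = None,
) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, n_fft//2 + 1)."""
    f_max = f_max if f_max is not None else fs / 2.0
    mel_edges = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_filters + 2)
    hz_edges = mel_to_hz(mel_edges)
    bins = np.floor((n_fft + 1) * hz_edges / fs).astype(int)
    n_bins = n_fft // 2 + 1
    bank = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        for b in range(lo, mid):
            if mid > lo:
                bank[i, b] = (b - lo) / (mid - lo)
        for b in range(mid, hi):
            if hi > mid:
                bank[i, b] = (hi - b) / (hi - mid)
    return bank


def mfcc(
    frame: np.ndarray,
    fs: int,
    n_filters: int = N_MEL_FILTERS,
    n_coeffs: int = N_MFCC,
    n_fft: Optional[int] = None,
) -> np.ndarray:
    """Mel-frequency cepstral coefficients of one window.

    Magnitude spectrum -> triangular mel filterbank (0 to fs/2) -> log
    energies (floored at a tiny epsilon) -> orthonormal DCT-II -> first
    ``n_coeffs`` coefficients, the 0th being the overall log energy.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size < 2:
        raise PdVoiceError("frame too short for a spectrum")
    if not frame.any():
        raise DegenerateSignalError("all-zero frame: mel log-energies undefined")
    n_fft = n_fft or frame.size
    spectrum = np.abs(rfft(frame * np.hamming(frame.size), n=n_fft))
    bank = mel_filterbank(fs, n_fft, n_filters)
    energies = bank @ (spectrum**2)
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    coeffs = dct(log_e, type=2, norm="ortho")
    return coeffs[:n_coeffs]


def frame_features(
    frame: np.ndarray, fs: int, order: int = LPC_ORDER,
    n_cep: int = N_CEPSTRUM, n_mfcc: int = N_MFCC,
) -> SpectralFrameFeatures:
    """All four coefficient families for one analysis window.

    The AR fit uses the biased autocorrelation estimate (divide by N), which
    guarantees a positive-semidefinite sequence and hence |c_k| < 1; no
    taper is applied before the AR fit.
    """
    frame = np.asarray(frame, dtype=float)
    n = frame.size
    full = np.correlate(frame, frame, mode="full")
    r = full[n - 1 : n + order] / n
    if r[0] <= 0:
        raise DegenerateSignalError("all-zero frame: AR model undefined")
    a, c, err = levinson_durbin(r, order)
    return SpectralFrameFeatures(
        lpc=a,
        reflection=c,
        lar=lar_transform(c),
        cep=lpc_to_cepstrum(a, err, n_cep),
        mfcc=mfcc(frame, fs, n_coeffs=n_mfcc),
        prediction_error=err,
    )


def summarize_spectral(features: Sequence[SpectralFrameFeatures]) -> SpectralSummary:
    """Elementwise mean and sample variance (ddof=1) across windows."""
    if len(features) < 2:
        raise PdVoiceError("need >= 2 frames for a variance vector")
    means: Dict[str, np.ndarray] = {}
    variances: Dict[str, np.ndarray] = {}
    for family in FAMILIES:
        stack = np.vstack([getattr(f, family) for f in features])
        means[family] = stack.mean(axis=0)
        variances[family] = stack.var(axis=0, ddof=1)
    return SpectralSummary(means=means, variances=variances, n_frames=len(features))


def extract_spectral_summary(
    sample: VoiceSample,
    frame_length: int = FRAME_LENGTH,
    overlap: float = FRAME_OVERLAP,
    order: int = LPC_ORDER,
) -> SpectralSummary:
    """Frame a recording and pool all families into one SpectralSummary."""
    frames = frame_signal(sample, frame_length, overlap)
    feats = []
    for frame in frames.frames:
        if not frame.any():
            continue  # silent frames carry no spectral envelope
        feats.append(frame_features(frame, sample.fs, order))
    return summarize_spectral(feats)
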