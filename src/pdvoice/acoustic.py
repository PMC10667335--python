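"""Phonation (acoustic-signal) features of a sustained vowel.

Twenty-three features per recording: F0 mean/SD, means and SDs of the first
four formants, harmonics-to-noise ratio, five jitter measures, six shimmer
measures, and the vowel duration.  Pitch and HNR come from a normalized
autocorrelation tracker; jitter and shimmer from glottal cycles located by
F0-guided peak picking with parabolic (sub-sample) refinement; formants from
the roots of a per-frame linear-prediction polynomial.

The jitter and shimmer variants follow the standard phonetics definitions:
the *local* measures compare adjacent cycles, the *perturbation quotients*
(rap/ppq5, apq3/apq5/apq11) compare each cycle against a moving k-point
neighbourhood mean, and ddp/dda are fixed multiples (3x rap, 3x apq3) kept
for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import resample_poly

from .audio import PITCH_BOUNDS_HZ, VoiceSample
from .exceptions import (
    PdVoiceError,
    TooFewCyclesError,
    UnvoicedRecordingError,
)
from .spectral import levinson_durbin

# Pitch-tracker defaults: 40 ms analysis frames every 10 ms, frames whose
# normalized autocorrelation peak is below 0.45 count as unvoiced.
F0_FRAME_S = 0.040
F0_HOP_S = 0.010
VOICING_THRESHOLD = 0.45
HNR_CAP_DB = 40.0

# Formant analysis defaults: LPC order 10 at 8 kHz (2 + fs/1000 rule),
# pre-emphasis 0.97, candidate roots must have bandwidth < 400 Hz.
FORMANT_LPC_ORDER = 10
PREEMPHASIS = 0.97
FORMANT_BW_CUTOFF_HZ = 400.0
FORMANT_MIN_HZ = 150.0

FEATURE_NAMES = (
    "f0_mean", "f0_sd",
    "f1_mean", "f1_sd", "f2_mean", "f2_sd",
    "f3_mean", "f3_sd", "f4_mean", "f4_sd",
    "hnr",
    "jitter_local", "jitter_local_abs", "jitter_rap", "jitter_ppq5", "jitter_ddp",
    "shimmer_local", "shimmer_local_db", "shimmer_apq3", "shimmer_apq5",
    "shimmer_apq11", "shimmer_dda",
    "duration",
)

JITTER_NAMES = ("jitter_local", "jitter_local_abs", "jitter_rap", "jitter_ppq5", "jitter_ddp")
SHIMMER_NAMES = (
    "shimmer_local", "shimmer_local_db", "shimmer_apq3", "shimmer_apq5",
    "shimmer_apq11", "shimmer_dda",
)


@dataclass(frozen=True)
class CycleSequence:
    """Glottal cycle lengths (s) and per-cycle peak amplitudes."""

    period_lengths: np.ndarray
    peak_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        periods = np.asarray(self.period_lengths, dtype=float)
        amps = np.asarray(self.peak_amplitudes, dtype=float)
        object.__setattr__(self, "period_lengths", periods)
        object.__setattr__(self, "peak_amplitudes", amps)
        if periods.size != amps.size or periods.size < 2:
            raise ValueError("need >= 2 cycles with matching period/amplitude counts")
        if (periods <= 0).any() or (amps < 0).any():
            raise ValueError("periods must be positive and amplitudes non-negative")


@dataclass(frozen=True)
class AcousticFeatureVector:
    """The 23 phonation features of one recording (2+8+1+5+6+1)."""

    f0_mean: float
    f0_sd: float
    f1_mean: float
    f1_sd: float
    f2_mean: float
    f2_sd: float
    f3_mean: float
    f3_sd: float
    f4_mean: float
    f4_sd: float
    hnr: float
    jitter_local: float
    jitter_local_abs: float
    jitter_rap: float
    jitter_ppq5: float
    jitter_ddp: float
    shimmer_local: float
    shimmer_local_db: float
    shimmer_apq3: float
    shimmer_apq5: float
    shimmer_apq11: float
    shimmer_dda: float
    duration: float

    def __post_init__(self) -> None:
        values = self.to_array()
        if not np.all(np.isfinite(values)):
            raise ValueError("all 23 features must be finite")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    @staticmethod
    def names() -> Tuple[str, ...]:
        return FEATURE_NAMES


def _autocorr_coeffs(frame: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation r(tau) for tau = 0..max_lag.

    Each lag is normalized as a true correlation coefficient between the
    overlapping segments, so r stays in [-1, 1] and does not decay with lag
    as the biased estimator would.  Computed via FFT.
    """
    x = frame - frame.mean()
    n = x.size
    spec = np.fft.rfft(x, 2 * n)
    full = np.fft.irfft(spec * np.conj(spec))[: max_lag + 1]
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    r = np.zeros(max_lag + 1)
    r[0] = 1.0
    if full[0] <= 0:
        return r
    taus = np.arange(1, max_lag + 1)
    denom = np.sqrt(csum[n - taus] * (csum[n] - csum[taus]))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, full[1:] / np.maximum(denom, 1e-300), 0.0)
    r[1:] = vals
    return r


#: A candidate within this absolute height of the frame's best peak is
#: treated as equally credible; the smallest-lag such candidate wins.  For a
#: truly periodic frame every multiple of the period peaks equally high, so
#: the smallest credible lag is the period; the tight tolerance keeps
#: half-period (octave-up) peaks, which sit visibly lower, from winning.
CANDIDATE_TOLERANCE = 0.04


def _pitch_candidates(r: np.ndarray, lag_min: int, lag_max: int):
    """Parabolically refined local maxima of r in the admissible lag band,
    as a list of (refined_lag, height) sorted by lag."""
    band = r[lag_min : lag_max + 1]
    interior = band[1:-1]
    is_max = (interior >= band[:-2]) & (interior >= band[2:]) & (interior > 0)
    out = []
    for rel in np.nonzero(is_max)[0]:
        lag, height = _parabolic_refine(r, lag_min + 1 + int(rel))
        out.append((lag, height))
    if not out:
        peak = lag_min + int(np.argmax(band))
        lag, height = _parabolic_refine(r, peak)
        out.append((lag, height))
    return out


def _pick_candidate(cands, target_lag: Optional[float] = None):
    """Best (lag, height) from a candidate list.

    Without a target, the smallest lag within CANDIDATE_TOLERANCE of the
    frame's best peak.  With a target lag (second pass / HNR), the
    candidate nearest the target in log-lag.
    """
    if target_lag is not None:
        return min(cands, key=lambda c: abs(np.log(c[0] / target_lag)))
    best = max(h for _, h in cands)
    eligible = [c for c in cands if c[1] >= best - CANDIDATE_TOLERANCE]
    return min(eligible, key=lambda c: c[0])


def _parabolic_refine(y: np.ndarray, i: int) -> Tuple[float, float]:
    """Sub-sample peak location/height via a 3-point parabola around i."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i), float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = b - 0.25 * (a - c) * delta
    return i + delta, float(height)


def estimate_f0_contour(
    sample: VoiceSample,
    floor: float = 75.0,
    ceiling: float = 300.0,
    frame_s: float = F0_FRAME_S,
    hop_s: float = F0_HOP_S,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Autocorrelation pitch track.

    Returns ``(times, f0, voiced)`` where ``f0`` holds one value per frame
    (NaN where unvoiced) and ``voiced`` is the boolean voicing mask.

    Raises
    ------
    UnvoicedRecordingError
        If no frame reaches the voicing threshold (e.g. white noise).
    """
    fs = sample.fs
    if not floor < ceiling < fs / 2:
        raise PdVoiceError("need floor < ceiling < fs/2 for the pitch search")
    frame_len = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    x = sample.samples
    if x.size < frame_len:
        raise UnvoicedRecordingError("recording shorter than one pitch frame")
    lag_min = max(2, int(np.floor(fs / ceiling)))
    lag_max = min(frame_len - 2, int(np.ceil(fs / floor)))
    if lag_min >= lag_max:
        raise PdVoiceError("pitch bounds leave no admissible lag range")

    n_frames = 1 + (x.size - frame_len) // hop
    times = np.empty(n_frames)
    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    all_cands = []
    for k in range(n_frames):
        frame = x[k * hop : k * hop + frame_len]
        times[k] = (k * hop + frame_len / 2) / fs
        r = _autocorr_coeffs(frame, lag_max)
        cands = _pitch_candidates(r, lag_min, lag_max)
        all_cands.append(cands)
        lag_ref, height = _pick_candidate(cands)
        if height >= voicing_threshold:
            voiced[k] = True
            f0[k] = fs / lag_ref
    if not voiced.any():
        raise UnvoicedRecordingError("no voiced frames found in recording")
    # second pass: a sustained vowel has one stable pitch, so snap each
    # frame to the candidate nearest the contour median; repairs octave slips.
    median_lag = fs / float(np.nanmedian(f0[voiced]))
    for k, cands in enumerate(all_cands):
        lag_ref, height = _pick_candidate(cands, target_lag=median_lag)
        if height >= voicing_threshold:
            voiced[k] = True
            f0[k] = fs / lag_ref
        else:
            voiced[k] = False
            f0[k] = np.nan
    if not voiced.any():
        raise UnvoicedRecordingError("no voiced frames found in recording")
    return times, f0, voiced


def extract_cycles(
    sample: VoiceSample,
    f0_contour: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
    floor: float = 75.0,
    ceiling: float = 300.0,
) -> CycleSequence:
    """Locate glottal cycles by F0-guided peak picking.

    Starting from the strongest extremum of the first pitch period, each
    subsequent cycle peak is searched in a window of 0.7-1.3 local periods
    after the previous one.  The waveform is sinc-upsampled eightfold first
    and peaks are refined with a three-point parabola, so periods and peak
    amplitudes are measured far below the 125 us telephone sampling grid
    (sub-sample accuracy is essential: one sample is ~1.5% of a 120 Hz
    period, the same order as pathological jitter itself).
    """
    if f0_contour is None:
        f0_contour = estimate_f0_contour(sample, floor, ceiling)
    times, f0, voiced = f0_contour
    up = 8
    fs = sample.fs * up
    med_f0 = float(np.nanmedian(f0[voiced]))
    t0 = fs / med_f0  # samples per median period

    x = resample_poly(sample.samples, up, 1)
    # choose the polarity with the stronger extremes
    if -x.min() > x.max():
        x = -x
    start_region = x[: int(np.ceil(1.5 * t0)) + 1]
    if start_region.size < 3:
        raise TooFewCyclesError("recording too short for cycle extraction")
    i = int(np.argmax(start_region))

    def local_period(pos_samples: float) -> float:
        t = pos_samples / fs
        k = int(np.argmin(np.abs(times - t)))
        if voiced[k]:
            return fs / f0[k]
        return t0

    positions = []
    amplitudes = []
    pos, amp = _parabolic_refine(x, i)
    positions.append(pos)
    amplitudes.append(amp)
    while True:
        period = local_period(positions[-1])
        lo = int(np.floor(positions[-1] + 0.7 * period))
        hi = int(np.ceil(positions[-1] + 1.3 * period))
        if hi >= x.size - 1:
            break
        window = x[lo : hi + 1]
        j = lo + int(np.argmax(window))
        pos, amp = _parabolic_refine(x, j)
        positions.append(pos)
        amplitudes.append(max(amp, 0.0))
    if len(positions) < 2:
        raise TooFewCyclesError("fewer than 2 glottal cycles detected")
    periods = np.diff(np.asarray(positions)) / fs
    amps = np.asarray(amplitudes[1:])
    return CycleSequence(period_lengths=periods, peak_amplitudes=amps)


def _perturbation_quotient(values: np.ndarray, k: int) -> float:
    """Mean |value - k-point neighbourhood mean|, relative to the mean value."""
    n = values.size
    half = k // 2
    if n < k:
        raise TooFewCyclesError(f"need >= {k} cycles for a {k}-point quotient")
    devs = [
        abs(values[i] - values[i - half : i + half + 1].mean())
        for i in range(half, n - half)
    ]
    return float(np.mean(devs) / values.mean())


def jitter_measures(cycles: CycleSequence) -> dict:
    """Five standard jitter measures from a cycle sequence.

    local and the quotients are in percent of the mean period, local_abs in
    seconds; ddp = 3 x rap by definition.
    """
    periods = cycles.period_lengths
    if periods.size < 6:
        raise TooFewCyclesError("jitter needs at least 6 cycles (ppq5)")
    mean_t = periods.mean()
    abs_diff = np.abs(np.diff(periods)).mean()
    rap = _perturbation_quotient(periods, 3) * 100.0
    ppq5 = _perturbation_quotient(periods, 5) * 100.0
    return {
        "jitter_local": float(abs_diff / mean_t * 100.0),
        "jitter_local_abs": float(abs_diff),
        "jitter_rap": rap,
        "jitter_ppq5": ppq5,
        "jitter_ddp": 3.0 * rap,
    }


def shimmer_measures(cycles: CycleSequence) -> dict:
    """Six standard shimmer measures; dda = 3 x apq3 by definition."""
    amps = cycles.peak_amplitudes
    if amps.size < 11:
        raise TooFewCyclesError("shimmer needs at least 11 cycles (apq11)")
    if (amps <= 0).any():
        raise PdVoiceError("zero cycle amplitude: shimmer dB undefined")
    mean_a = amps.mean()
    abs_diff = np.abs(np.diff(amps)).mean()
    local_db = float(np.mean(np.abs(20.0 * np.log10(amps[1:] / amps[:-1]))))
    apq3 = _perturbation_quotient(amps, 3) * 100.0
    apq5 = _perturbation_quotient(amps, 5) * 100.0
    apq11 = _perturbation_quotient(amps, 11) * 100.0
    return {
        "shimmer_local": float(abs_diff / mean_a * 100.0),
        "shimmer_local_db": local_db,
        "shimmer_apq3": apq3,
        "shimmer_apq5": apq5,
        "shimmer_apq11": apq11,
        "shimmer_dda": 3.0 * apq3,
    }


def harmonics_to_noise_ratio(
    sample: VoiceSample,
    floor: float = 75.0,
    ceiling: float = 300.0,
    cap_db: float = HNR_CAP_DB,
) -> float:
    """Mean per-frame HNR in dB over voiced frames.

    Per frame, with r the normalized autocorrelation at the pitch lag,
    HNR = 10 log10(r / (1 - r)); a perfectly periodic frame (r -> 1) is
    capped at ``cap_db`` to avoid infinities on noiseless synthetic input.
    The frame is sinc-upsampled eightfold before the autocorrelation: at
    8 kHz the true (fractional) pitch lag falls between samples and the
    on-grid peak underestimates r badly for a wideband voice.
    """
    up = 8
    if sample.samples.size < int(round(F0_FRAME_S * sample.fs)):
        raise UnvoicedRecordingError("recording shorter than one analysis frame")
    _, f0_track, voiced_mask = estimate_f0_contour(sample, floor, ceiling)
    median_f0 = float(np.nanmedian(f0_track[voiced_mask]))
    fs = sample.fs * up
    frame_len = int(round(F0_FRAME_S * fs))
    hop = int(round(F0_HOP_S * fs))
    x = resample_poly(sample.samples, up, 1)
    lag_min = max(2, int(np.floor(fs / ceiling)))
    lag_max = min(frame_len - 2, int(np.ceil(fs / floor)))
    target_lag = np.clip(fs / median_f0, lag_min + 1, lag_max - 1)
    values = []
    n_frames = 1 + (x.size - frame_len) // hop
    for k in range(n_frames):
        frame = x[k * hop : k * hop + frame_len]
        r = _autocorr_coeffs(frame, lag_max)
        cands = _pitch_candidates(r, lag_min, lag_max)
        _, height = _pick_candidate(cands, target_lag=target_lag)
        if height < VOICING_THRESHOLD:
            continue
        height = min(height, 1.0 - 1e-12)
        hnr = 10.0 * np.log10(height / (1.0 - height))
        values.append(min(hnr, cap_db))
    if not values:
        raise UnvoicedRecordingError("no voiced frames: HNR undefined")
    return float(np.mean(values))


def _lpc_roots_to_formants(a: np.ndarray, fs: float) -> np.ndarray:
    """Formant candidates (Hz, ascending) from LPC coefficients.

    ``a`` are predictor coefficients in the A(z) = 1 - sum a_k z^-k
    convention.  Roots with positive imaginary part, bandwidth below the
    cutoff and frequency above the floor are kept.
    """
    poly = np.concatenate([[1.0], -a])
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 1e-8]
    freqs = np.angle(roots) / (2.0 * np.pi) * fs
    mags = np.abs(roots)
    mags = np.clip(mags, 1e-12, 1.0 - 1e-12)
    bws = -np.log(mags) * fs / np.pi
    keep = (bws < FORMANT_BW_CUTOFF_HZ) & (freqs > FORMANT_MIN_HZ) & (freqs < fs / 2 - 50)
    return np.sort(freqs[keep])


def formant_frequencies(
    sample: VoiceSample,
    order: int = FORMANT_LPC_ORDER,
    frame_s: float = 0.030,
    hop_s: float = F0_HOP_S,
) -> dict:
    """Means and SDs of the first four formants via per-frame LPC root finding."""
    fs = sample.fs
    x = np.append(sample.samples[0], sample.samples[1:] - PREEMPHASIS * sample.samples[:-1])
    frame_len = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    if x.size < frame_len:
        raise PdVoiceError("recording shorter than one formant frame")
    window = np.hamming(frame_len)
    per_frame = []
    n_frames = 1 + (x.size - frame_len) // hop
    for k in range(n_frames):
        frame = x[k * hop : k * hop + frame_len] * window
        if not frame.any():
            continue
        full = np.correlate(frame, frame, mode="full")
        r = full[frame.size - 1 : frame.size + order] / frame.size
        if r[0] <= 0:
            continue
        try:
            a, _, _ = levinson_durbin(r, order)
        except PdVoiceError:
            continue
        formants = _lpc_roots_to_formants(a, fs)
        if formants.size >= 4:
            per_frame.append(formants[:4])
    if not per_frame:
        raise PdVoiceError("no frame yielded four admissible formants")
    arr = np.asarray(per_frame)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(4)
    out = {}
    for j in range(4):
        out[f"f{j+1}_mean"] = float(means[j])
        out[f"f{j+1}_sd"] = float(sds[j])
    return out


def assemble_feature_vector(
    f0_stats: Tuple[float, float],
    formants: dict,
    hnr: float,
    jitter: dict,
    shimmer: dict,
    duration: float,
) -> AcousticFeatureVector:
    """Combine sub-features into the canonical 23-entry vector."""
    return AcousticFeatureVector(
        f0_mean=f0_stats[0],
        f0_sd=f0_stats[1],
        hnr=hnr,
        duration=duration,
        **formants,
        **jitter,
        **shimmer,
    )


def extract_acoustic_features(
    sample: VoiceSample,
    sex: str = "male",
    pitch_bounds: Optional[Tuple[float, float]] = None,
) -> AcousticFeatureVector:
    """All 23 phonation features of one (preprocessed) recording.

    The pitch-search bounds default to the sex-specific ranges
    (75-300 Hz male, 100-600 Hz female).
    """
    floor, ceiling = pitch_bounds or PITCH_BOUNDS_HZ[sex]
    ceiling = min(ceiling, sample.fs / 2 - 1)
    contour = estimate_f0_contour(sample, floor, ceiling)
    _, f0, voiced = contour
    voiced_f0 = f0[voiced]
    f0_stats = (float(voiced_f0.mean()), float(voiced_f0.std(ddof=1)) if voiced_f0.size > 1 else 0.0)
    cycles = extract_cycles(sample, contour, floor, ceiling)
    jitter = jitter_measures(cycles)
    shimmer = shimmer_measures(cycles)
    hnr = harmonics_to_noise_ratio(sample, floor, ceiling)
    formants = formant_frequencies(sample)
    return assemble_feature_vector(
        f0_stats, formants, hnr, jitter, shimmer, sample.duration
    )
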