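"""Synthetic sustained-vowel cohorts with known phonation ground truth.

A source-filter synthesizer stands in for human telephone recordings: a
glottal pulse train with per-cycle period perturbation (jitter), per-cycle
amplitude perturbation (shimmer) and slow pitch drift excites a cascade of
second-order formant resonators; aspiration noise is mixed in to hit a
target harmonics-to-noise ratio; the result is band-limited to the
telephone passband and quantized to 16 bits.  Because every perturbation is
parametric, downstream estimators can be validated against ground truth.

Group-conditional parameter distributions emulate Parkinsonian dysphonia:
PD voices draw higher jitter, shimmer and F0 variability and lower HNR than
healthy controls, with sex-dependent F0 ranges (female F0 centred ~1.56x
male).  The magnitudes are configuration, not estimates of any human
cohort: elevated perturbation and depressed HNR in PD are the documented
effect directions, and the default effect sizes are chosen to make an
n=40+40 cohort clearly separable by a random-forest classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import signal as sps

from .audio import QUANT_STEP, VoiceSample
from .exceptions import PdVoiceError

GROUPS = ("HC", "PD")
SEXES = ("male", "female")


@dataclass(frozen=True)
class PhonationParams:
    """Ground-truth parameters of one synthetic sustained vowel.

    f0_mean/f0_sd are the centre and slow-drift SD of the pitch in Hz;
    jitter_pct and shimmer_pct are the relative SDs (in %) of the
    cycle-to-cycle period and amplitude perturbations; hnr_target is the
    harmonics-to-noise ratio of the source in dB; formants are given as
    four (frequency, bandwidth) pairs in Hz.
    """

    f0_mean: float
    f0_sd: float
    jitter_pct: float
    shimmer_pct: float
    hnr_target: float
    formant_freqs: Tuple[float, float, float, float]
    formant_bandwidths: Tuple[float, float, float, float]
    duration: float
    amplitude: float = 0.9

    def __post_init__(self) -> None:
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be positive")
        if not (0 <= self.jitter_pct < 20 and 0 <= self.shimmer_pct < 20):
            raise ValueError("jitter/shimmer percentages must lie in [0, 20)")
        freqs = tuple(self.formant_freqs)
        if list(freqs) != sorted(freqs) or len(set(freqs)) != 4:
            raise ValueError("formant_freqs must be strictly increasing")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and group label of one (synthetic) participant."""

    subject_id: str
    group: str
    sex: str
    age: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass(frozen=True)
class CohortDefaults:
    """Every default distribution of the generator in one block.

    Perturbation magnitudes (jitter, shimmer, f0_sd in % / Hz) are drawn
    log-normally around the group medians below; HNR is Gaussian.  Ages and
    sex ratios reproduce the study demographics (HC 16M/24F, 47.9 +/- 14.5 y;
    PD 21M/19F, 66.6 +/- 9.0 y).  Durations make PD vowels slightly shorter,
    mirroring reduced phonation time in hypophonia.
    """

    # group -> median of the log-normal draw
    jitter_median: Dict[str, float] = field(
        default_factory=lambda: {"HC": 0.5, "PD": 1.5}
    )
    shimmer_median: Dict[str, float] = field(
        default_factory=lambda: {"HC": 3.0, "PD": 6.5}
    )
    f0_sd_median: Dict[str, float] = field(
        default_factory=lambda: {"HC": 1.5, "PD": 4.0}
    )
    lognormal_sigma: float = 0.35
    # group -> (mean, sd) of Gaussian HNR in dB
    hnr: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"HC": (22.0, 2.5), "PD": (14.0, 2.5)}
    )
    # sex -> (mean, sd) of Gaussian F0 in Hz; 180/115 ~ 1.57x female/male
    f0_mean: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"male": (115.0, 10.0), "female": (180.0, 15.0)}
    )
    # sex -> four (freq, bandwidth) pairs for the /a/ vocal tract
    formants: Dict[str, Tuple[Tuple[float, float], ...]] = field(
        default_factory=lambda: {
            "male": ((710, 80), (1150, 100), (2500, 140), (3300, 180)),
            "female": ((820, 90), (1300, 110), (2750, 150), (3500, 200)),
        }
    )
    formant_jitter_hz: float = 25.0  # per-subject SD around the table values
    # group -> (mean, sd, minimum) of Gaussian vowel duration in s
    duration: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {"HC": (2.8, 0.4, 1.8), "PD": (2.2, 0.4, 1.8)}
    )
    # group -> (age mean, age sd); truncated to [18, 95]
    age: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"HC": (47.9, 14.5), "PD": (66.6, 9.0)}
    )
    # group -> probability of drawing a male subject (16/40 HC, 21/40 PD)
    p_male: Dict[str, float] = field(
        default_factory=lambda: {"HC": 16 / 40, "PD": 21 / 40}
    )


DEFAULTS = CohortDefaults()

#: Telephone channel passband edges in Hz.
TELEPHONE_BAND = (300.0, 3400.0)


def _check_group_sex(group: str, sex: str) -> None:
    if group not in GROUPS:
        raise PdVoiceError(f"unknown group {group!r}; expected one of {GROUPS}")
    if sex not in SEXES:
        raise PdVoiceError(f"unknown sex {sex!r}; expected one of {SEXES}")


def sample_phonation_params(
    group: str,
    sex: str,
    rng_seed: int,
    defaults: CohortDefaults = DEFAULTS,
) -> PhonationParams:
    """Draw one subject's phonation parameters.

    Deterministic given (group, sex, rng_seed).  PD draws stochastically
    dominate HC draws in jitter, shimmer and F0 drift and are dominated in
    HNR; female F0 is centred well above male F0.
    """
    _check_group_sex(group, sex)
    rng = np.random.default_rng(rng_seed)

    sigma = defaults.lognormal_sigma
    jitter = float(
        np.clip(defaults.jitter_median[group] * np.exp(sigma * rng.standard_normal()), 0.02, 8.0)
    )
    shimmer = float(
        np.clip(defaults.shimmer_median[group] * np.exp(sigma * rng.standard_normal()), 0.1, 15.0)
    )
    f0_sd = float(
        defaults.f0_sd_median[group] * np.exp(sigma * rng.standard_normal())
    )
    hnr_mu, hnr_sd = defaults.hnr[group]
    hnr = float(rng.normal(hnr_mu, hnr_sd))
    f0_mu, f0_sigma = defaults.f0_mean[sex]
    f0 = float(np.clip(rng.normal(f0_mu, f0_sigma), 70.0, 350.0))

    pairs = defaults.formants[sex]
    freqs = []
    bands = []
    for f, b in pairs:
        freqs.append(float(f + defaults.formant_jitter_hz * rng.standard_normal()))
        bands.append(float(b))
    freqs = sorted(freqs)

    dur_mu, dur_sd, dur_min = defaults.duration[group]
    duration = float(max(rng.normal(dur_mu, dur_sd), dur_min))

    return PhonationParams(
        f0_mean=f0,
        f0_sd=f0_sd,
        jitter_pct=jitter,
        shimmer_pct=shimmer,
        hnr_target=hnr,
        formant_freqs=tuple(freqs),
        formant_bandwidths=tuple(bands),
        duration=duration,
    )


def _glottal_cycles(
    params: PhonationParams, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Continuous-time cycle onsets and per-cycle amplitudes.

    F0 drifts slowly via an AR(1) process scaled to SD ``f0_sd``; on top of
    the drift each period receives an i.i.d. multiplicative Gaussian
    perturbation with relative SD ``jitter_pct`` and each amplitude one with
    relative SD ``shimmer_pct``.
    """
    n_max = int(np.ceil(params.duration * params.f0_mean * 1.5)) + 4
    phi = 0.97  # AR(1) pole: drift correlation time ~ 30 cycles
    innov_sd = params.f0_sd * np.sqrt(1.0 - phi**2)
    drift = np.empty(n_max)
    drift[0] = params.f0_sd * rng.standard_normal()
    for i in range(1, n_max):
        drift[i] = phi * drift[i - 1] + innov_sd * rng.standard_normal()
    f0_i = np.clip(params.f0_mean + drift, 40.0, 500.0)
    periods = (1.0 / f0_i) * (
        1.0 + (params.jitter_pct / 100.0) * rng.standard_normal(n_max)
    )
    periods = np.clip(periods, 0.2 / f0_i, 3.0 / f0_i)
    onsets = np.concatenate([[0.0], np.cumsum(periods)])[:-1]
    keep = onsets < params.duration
    onsets = onsets[keep]
    amps = 1.0 + (params.shimmer_pct / 100.0) * rng.standard_normal(onsets.size)
    amps = np.clip(amps, 0.05, None)
    return onsets, amps


def _formant_filter(x: np.ndarray, params: PhonationParams, fs: float) -> np.ndarray:
    """Cascade of second-order resonators at the formant frequencies."""
    y = x
    for f, bw in zip(params.formant_freqs, params.formant_bandwidths):
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * f / fs
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [1.0 - r]  # keeps per-stage gain moderate
        y = sps.lfilter(b, a, y)
    return y


def synthesize_vowel(
    params: PhonationParams,
    fs: int = 8000,
    rng_seed: int = 0,
    telephone: bool = True,
) -> VoiceSample:
    """Render one sustained vowel from phonation parameters.

    The pulse train is laid down with sub-sample onset accuracy (each
    impulse is split linearly across the two neighbouring samples) so that
    the synthesized jitter is not floored by the 125 us sampling grid.
    Aspiration noise is filtered through the same vocal tract and scaled
    after filtering so the harmonic-to-noise power ratio equals
    ``hnr_target`` dB exactly at the filter output.  With ``telephone``
    the result is band-passed to 300-3400 Hz and quantized to 16 bits.
    """
    max_f = max(params.formant_freqs)
    if fs < 2 * max_f:
        raise PdVoiceError(
            f"fs={fs} cannot represent a formant at {max_f} Hz (Nyquist {fs/2})"
        )
    rng = np.random.default_rng(rng_seed)
    onsets, amps = _glottal_cycles(params, rng)

    # Band-limited pulse train: each glottal impulse is a windowed sinc
    # centred at its (continuous-time) onset, so every cycle carries the
    # identical waveform up to an exact fractional delay.  A linearly split
    # impulse would instead apply a different low-pass per cycle and leak
    # spurious cycle-to-cycle variability into jitter/shimmer/HNR.
    n = int(round(params.duration * fs))
    half = 16
    source = np.zeros(n + 2 * half + 2)
    offsets = np.arange(-half, half + 1)
    taper = 0.5 * (1.0 + np.cos(np.pi * offsets / (half + 1)))
    for pos, amp in zip(onsets * fs + half, amps):
        k0 = int(np.round(pos))
        kk = k0 + offsets
        source[kk] += amp * np.sinc(kk - pos) * np.interp(
            kk - pos, offsets, taper
        )
    source = source[half : half + n]

    harmonic = _formant_filter(source, params, fs)
    noise = _formant_filter(rng.standard_normal(n), params, fs)
    p_h = float(np.mean(harmonic**2))
    p_n = float(np.mean(noise**2))
    target_ratio = 10.0 ** (params.hnr_target / 10.0)
    noise *= np.sqrt(p_h / (p_n * target_ratio)) if p_n > 0 else 0.0
    y = harmonic + noise

    if telephone:
        sos = sps.butter(4, TELEPHONE_BAND, btype="bandpass", fs=fs, output="sos")
        y = sps.sosfilt(sos, y)

    peak = np.max(np.abs(y))
    if peak > 0:
        y = y / peak * params.amplitude
    y = np.round(np.clip(y, -1.0, 1.0 - QUANT_STEP) * 32768.0) / 32768.0
    return VoiceSample(samples=y, fs=fs, bit_depth=16, provenance=params)


def generate_cohort(
    n_hc: int,
    n_pd: int,
    rng_seed: int,
    fs: int = 8000,
    defaults: CohortDefaults = DEFAULTS,
    telephone: bool = True,
) -> List[Tuple[VoiceSample, SubjectRecord]]:
    """Generate a two-group cohort of synthetic sustained vowels.

    Sexes and ages are drawn from the group-conditional demographics in
    ``defaults``; each subject gets independent phonation parameters and an
    independently seeded waveform.  Bit-identical given the same seed.
    """
    if n_hc < 1 or n_pd < 1:
        raise PdVoiceError("cohort needs at least one subject per group")
    master = np.random.default_rng(rng_seed)
    cohort: List[Tuple[VoiceSample, SubjectRecord]] = []
    for group, count in (("HC", n_hc), ("PD", n_pd)):
        for i in range(count):
            sex = "male" if master.random() < defaults.p_male[group] else "female"
            mu, sd = defaults.age[group]
            age = float(mu + sd * master.standard_normal())
            while not 18.0 <= age <= 95.0:
                age = float(mu + sd * master.standard_normal())
            param_seed = int(master.integers(0, 2**31 - 1))
            wave_seed = int(master.integers(0, 2**31 - 1))
            params = sample_phonation_params(group, sex, param_seed, defaults)
            sample = synthesize_vowel(params, fs=fs, rng_seed=wave_seed, telephone=telephone)
            record = SubjectRecord(
                subject_id=f"{group}{i:03d}", group=group, sex=sex, age=age
            )
            cohort.append((sample, record))
    return cohort
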