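"""Synthetic annotated-speech + EEG datasets with the statistical structure
both assays look for.

The generator emulates the study conditions: a ~148 s narration whose
phoneme durations follow a truncated log-normal with mean 79.5 ms (range
30-320 ms) over five manner classes drawn with the stimulus's class
frequencies; a slow speech envelope derived from per-phoneme intensity; and
250 Hz multichannel EEG made of 1/f-shaped band-limited noise plus,
optionally, class-specific evoked bumps, an envelope-following component at
a configurable lag, and artifact bursts. With all effect amplitudes at
zero (the default) the data are a calibrated null for both pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special
from scipy.ndimage import gaussian_filter1d

from .io_formats import AudioSignal, PhonemeAnnotation, Recording, default_class_map
from .nse_tracking import EnvelopeSignal
from .preprocess import bandpass_series, standardize_series

import pandas as pd

#: Phoneme label pools per manner class (ARPAbet).
CLASS_PHONEMES = {
    "A": ("L", "R", "W", "Y"),
    "F": ("F", "V", "S", "Z", "SH", "TH", "DH", "HH", "ZH"),
    "N": ("M", "N", "NG"),
    "P": ("B", "D", "G", "K", "P", "T"),
    "V": ("AA", "AE", "AH", "AO", "AW", "AY", "EH", "ER", "EY",
          "IH", "IY", "OW", "OY", "UH", "UW"),
}

#: Class frequencies of the stimulus passage (A, F, N, P, V).
STIMULUS_CLASS_COUNTS = {"A": 163, "F": 264, "N": 147, "P": 355, "V": 617}

#: 10-20 montage labels (19 standard positions plus 18 extended), so up to
#: 37 channels mirror the recording montage.
MONTAGE_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4",
    "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
    "F9", "F10", "FC5", "FC1", "FC2", "FC6", "T9", "T10", "CP5", "CP1",
    "CP2", "CP6", "P9", "P10", "PO3", "PO4", "Oz", "Iz",
)


@dataclass
class ClassEffect:
    """An evoked component tied to one phoneme class.

    A half-sine bump of the given amplitude (in trial-SD units), centered
    ``latency_ms`` after phoneme onset with the given width, projected onto
    channels by ``channel_weights`` (defaults to uniform weight 1).
    """

    amplitude_sd: float
    latency_ms: float
    duration_ms: float = 60.0
    channel_weights: np.ndarray | None = None


@dataclass
class EnvelopeCoupling:
    """Envelope-following EEG component: the standardized envelope passed
    through a half-sine kernel peaking at ``lag_ms`` (width ``width_ms``),
    scaled by ``amplitude_sd``."""

    amplitude_sd: float
    lag_ms: float
    width_ms: float = 24.0
    channel_weights: np.ndarray | None = None


@dataclass
class ArtifactSpec:
    count: int = 0
    duration_s: float = 1.0
    amplitude_sd: float = 30.0


@dataclass
class SyntheticConfig:
    seed: int = 0
    duration_s: float = 148.0
    rate_hz: float = 250.0
    audio_rate_hz: float = 44100.0
    n_channels: int = 8
    #: truncated log-normal phoneme-duration model
    mean_duration_s: float = 0.0795
    min_duration_s: float = 0.030
    max_duration_s: float = 0.320
    duration_sigma: float = 0.45
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            c: n / sum(STIMULUS_CLASS_COUNTS.values())
            for c, n in STIMULUS_CLASS_COUNTS.items()
        })
    #: per-phoneme-class envelope intensity (arbitrary units; vowels loud)
    class_levels: dict[str, float] = field(
        default_factory=lambda: {"A": 0.7, "F": 0.5, "N": 0.6, "P": 0.4,
                                 "V": 1.0})
    class_effects: dict[str, ClassEffect] = field(default_factory=dict)
    envelope_coupling: EnvelopeCoupling | None = None
    noise_slope: float = 1.0  # spectral exponent of the 1/f^slope noise power
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if not (0 < self.min_duration_s < self.max_duration_s):
            raise ValueError("bad duration truncation bounds")
        for eff in self.class_effects.values():
            if eff.amplitude_sd < 0:
                raise ValueError("effect amplitude must be >= 0")

    def channel_labels(self) -> list[str]:
        if self.n_channels > len(MONTAGE_1020):
            raise ValueError(f"at most {len(MONTAGE_1020)} channels supported")
        return list(MONTAGE_1020[: self.n_channels])


# ---------------------------------------------------------------------------
# Phoneme durations: truncated log-normal calibrated to the target mean


def _phi(z: np.ndarray) -> np.ndarray:
    return 0.5 * special.erfc(-z / np.sqrt(2.0))


def _truncated_lognormal_mean(mu: float, sigma: float, a: float, b: float) -> float:
    la, lb = np.log(a), np.log(b)
    denom = _phi((lb - mu) / sigma) - _phi((la - mu) / sigma)
    num = _phi((lb - mu - sigma ** 2) / sigma) - _phi((la - mu - sigma ** 2) / sigma)
    return float(np.exp(mu + sigma ** 2 / 2) * num / denom)


def _solve_duration_mu(cfg: SyntheticConfig) -> float:
    """Location parameter giving the target mean after truncation."""
    def f(mu: float) -> float:
        return (_truncated_lognormal_mean(mu, cfg.duration_sigma,
                                          cfg.min_duration_s,
                                          cfg.max_duration_s)
                - cfg.mean_duration_s)
    return optimize.brentq(f, np.log(cfg.min_duration_s),
                           np.log(cfg.max_duration_s), xtol=1e-12)


def sample_durations(cfg: SyntheticConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of the truncated log-normal duration model."""
    mu, sigma = _solve_duration_mu(cfg), cfg.duration_sigma
    lo = _phi((np.log(cfg.min_duration_s) - mu) / sigma)
    hi = _phi((np.log(cfg.max_duration_s) - mu) / sigma)
    u = rng.uniform(lo, hi, size=n)
    z = -np.sqrt(2.0) * special.erfcinv(2.0 * u)
    return np.exp(mu + sigma * z)


# ---------------------------------------------------------------------------
# Generators


def generate_annotation(cfg: SyntheticConfig,
                        seed: int | None = None) -> PhonemeAnnotation:
    """Contiguous phoneme intervals tiling [0, duration_s].

    Durations follow the truncated log-normal model; class labels are drawn
    with the stimulus's class frequencies, and a concrete ARPAbet phoneme
    of that class is assigned so the standard class map applies. The final
    interval is clipped to the stimulus end.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    # oversample, then trim to the stimulus duration
    est = int(cfg.duration_s / cfg.min_duration_s) + 16
    durations = sample_durations(cfg, est, rng)
    ends = np.cumsum(durations)
    n = int(np.searchsorted(ends, cfg.duration_s)) + 1
    durations = durations[:n]
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    ends = np.minimum(starts + durations, cfg.duration_s)
    keep = ends - starts > 1e-6
    starts, ends = starts[keep], ends[keep]
    classes = list(cfg.class_probs)
    probs = np.array([cfg.class_probs[c] for c in classes])
    drawn = rng.choice(len(classes), size=len(starts), p=probs)
    labels = [
        CLASS_PHONEMES[classes[k]][rng.integers(len(CLASS_PHONEMES[classes[k]]))]
        for k in drawn
    ]
    df = pd.DataFrame({"start_s": starts, "end_s": ends,
                       "phoneme_label": labels})
    return PhonemeAnnotation(intervals=df, class_map=default_class_map())


def generate_envelope(annot: PhonemeAnnotation, cfg: SyntheticConfig,
                      seed: int | None = None,
                      ) -> tuple[EnvelopeSignal, AudioSignal]:
    """Speech envelope and a carrier-modulated WAV rendering.

    The envelope is a smoothed per-phoneme intensity profile: each phoneme
    contributes its class's base level jittered log-normally, smoothed with
    a 20 ms Gaussian. It is nonnegative and returned unstandardized at the
    EEG rate; the audio is the envelope (interpolated to the audio rate)
    modulating a fixed tone, duplicated to two identical binaural channels.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    n = int(round(cfg.duration_s * cfg.rate_hz))
    env = np.zeros(n)
    mapped = annot.mapped()
    for start_s, end_s, cls in zip(mapped.start_s, mapped.end_s,
                                   mapped["class"]):
        level = cfg.class_levels.get(cls, 0.5)
        level *= float(np.exp(0.25 * rng.standard_normal()))
        i0 = int(round(start_s * cfg.rate_hz))
        i1 = min(int(round(end_s * cfg.rate_hz)), n)
        env[i0:i1] = level
    env = gaussian_filter1d(env, sigma=0.020 * cfg.rate_hz)
    t_env = np.arange(n) / cfg.rate_hz
    n_audio = int(round(cfg.duration_s * cfg.audio_rate_hz))
    t_audio = np.arange(n_audio) / cfg.audio_rate_hz
    amp = np.interp(t_audio, t_env, env)
    carrier = np.sin(2 * np.pi * 220.0 * t_audio)
    wave = amp * carrier
    audio = AudioSignal(rate_hz=cfg.audio_rate_hz,
                        data=np.vstack([wave, wave]))
    return EnvelopeSignal(values=env, rate_hz=cfg.rate_hz), audio


def _half_sine(duration_ms: float, rate_hz: float) -> np.ndarray:
    n = max(int(round(duration_ms / 1000.0 * rate_hz)), 1)
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def _channel_weights(weights: np.ndarray | None, n_channels: int) -> np.ndarray:
    if weights is None:
        return np.ones(n_channels)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_channels,):
        raise ValueError(f"channel weights must have length {n_channels}")
    return w


def one_over_f_noise(n_channels: int, n_samples: int, rate_hz: float,
                     rng: np.random.Generator, slope: float = 1.0) -> np.ndarray:
    """1/f^slope-power Gaussian noise, band-passed to 2-15 Hz, unit variance."""
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-slope / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n_samples,
                          axis=1)
    out = np.empty_like(shaped)
    for c in range(n_channels):
        out[c] = bandpass_series(shaped[c], rate_hz)
        out[c] = standardize_series(out[c])
    return out


def generate_eeg(annot: PhonemeAnnotation, envelope: EnvelopeSignal,
                 cfg: SyntheticConfig, seed: int | None = None,
                 ) -> Recording:
    """EEG = band-limited 1/f noise + class-locked bumps + lagged envelope
    component + optional artifact bursts.

    Effect amplitudes are in units of the noise SD (1 by construction).
    The artifact ground truth is returned as the recording's mask.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    n = int(round(cfg.duration_s * cfg.rate_hz))
    data = one_over_f_noise(cfg.n_channels, n, cfg.rate_hz, rng,
                            slope=cfg.noise_slope)

    mapped = annot.mapped()
    for cls, eff in cfg.class_effects.items():
        if eff.amplitude_sd == 0:
            continue
        w = _channel_weights(eff.channel_weights, cfg.n_channels)
        bump = eff.amplitude_sd * _half_sine(eff.duration_ms, cfg.rate_hz)
        start_off = int(round((eff.latency_ms - eff.duration_ms / 2.0)
                              / 1000.0 * cfg.rate_hz))
        onsets = np.round(
            mapped.loc[mapped["class"] == cls, "start_s"].to_numpy()
            * cfg.rate_hz).astype(int)
        for o in onsets:
            i0 = o + start_off
            i1 = i0 + len(bump)
            b0, b1 = max(0, -i0), len(bump) - max(0, i1 - n)
            if b1 <= b0:
                continue
            data[:, max(0, i0):min(n, i1)] += np.outer(w, bump[b0:b1])

    if cfg.envelope_coupling is not None and cfg.envelope_coupling.amplitude_sd:
        coup = cfg.envelope_coupling
        w = _channel_weights(coup.channel_weights, cfg.n_channels)
        env_std = standardize_series(
            bandpass_series(envelope.values, cfg.rate_hz))
        kernel = _half_sine(coup.width_ms, cfg.rate_hz)
        kernel /= kernel.sum()
        lag = int(round(coup.lag_ms / 1000.0 * cfg.rate_hz))
        smoothed = np.convolve(env_std, kernel, mode="same")
        delayed = np.zeros(n)
        delayed[lag:] = smoothed[: n - lag]
        data += coup.amplitude_sd * np.outer(w, delayed)

    mask = np.zeros(n, dtype=bool)
    if cfg.artifact.count > 0:
        burst_len = int(round(cfg.artifact.duration_s * cfg.rate_hz))
        for _ in range(cfg.artifact.count):
            i0 = int(rng.integers(0, max(n - burst_len, 1)))
            window = np.hanning(burst_len) * cfg.artifact.amplitude_sd
            signs = rng.choice([-1.0, 1.0], size=cfg.n_channels)
            data[:, i0:i0 + burst_len] += np.outer(signs, window)
            mask[i0:i0 + burst_len] = True

    return Recording(channel_labels=cfg.channel_labels(),
                     rate_hz=cfg.rate_hz, data=data, artifact_mask=mask)


def generate_dataset(cfg: SyntheticConfig, seed: int | None = None,
                     ) -> dict:
    """Annotation + envelope + audio + EEG for one synthetic trial."""
    base = cfg.seed if seed is None else seed
    annot = generate_annotation(cfg, seed=base)
    env, audio = generate_envelope(annot, cfg, seed=base)
    rec = generate_eeg(annot, env, cfg, seed=base)
    return {"annotation": annot, "envelope": env, "audio": audio,
            "recording": rec, "config": replace(cfg, seed=base)}
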