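"""Preprocessing applied identically before both analyses.

Order of operations for a trial: 60 Hz notch, 2-15 Hz band-pass, per-channel
standardization to zero mean / unit variance, then artifact masking. All
filters are zero-phase (forward-backward IIR) so the evoked latencies that
the analyses interpret are not shifted. Artifacts are handled by masking and
downstream exclusion rather than sample deletion, which keeps annotation
time to sample index alignment exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import Recording


@dataclass
class PreprocessConfig:
    notch_hz: float = 60.0
    band_low_hz: float = 2.0
    band_high_hz: float = 15.0
    epoch_reject_sd: float = 10.0
    rate_hz: float = 250.0

    def __post_init__(self) -> None:
        nyq = self.rate_hz / 2
        if not (0 < self.band_low_hz < self.band_high_hz < nyq):
            raise ValueError("need 0 < band_low_hz < band_high_hz < rate_hz/2")
        if not (0 < self.notch_hz < nyq):
            raise ValueError("need 0 < notch_hz < rate_hz/2")
        if self.epoch_reject_sd <= 0:
            raise ValueError("epoch_reject_sd must be positive")


def _notch_sos(cfg: PreprocessConfig, rate_hz: float) -> np.ndarray:
    # 4th-order Butterworth band-stop, +/-2 Hz about the mains frequency.
    return signal.butter(2, [cfg.notch_hz - 2.0, cfg.notch_hz + 2.0],
                         btype="bandstop", fs=rate_hz, output="sos")


def _bandpass_sos(cfg: PreprocessConfig, rate_hz: float) -> np.ndarray:
    return signal.butter(4, [cfg.band_low_hz, cfg.band_high_hz],
                         btype="bandpass", fs=rate_hz, output="sos")


def notch_filter(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase notch at the mains frequency (default 60 Hz)."""
    cfg = cfg or PreprocessConfig(rate_hz=rec.rate_hz)
    if rec.rate_hz <= 2 * cfg.notch_hz:
        raise ValueError("sampling rate must exceed twice the notch frequency")
    sos = _notch_sos(cfg, rec.rate_hz)
    return rec.copy_with(data=signal.sosfiltfilt(sos, rec.data, axis=1))


def bandpass_filter(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase 2-15 Hz band-pass (forward-backward Butterworth)."""
    cfg = cfg or PreprocessConfig(rate_hz=rec.rate_hz)
    sos = _bandpass_sos(cfg, rec.rate_hz)
    return rec.copy_with(data=signal.sosfiltfilt(sos, rec.data, axis=1))


def bandpass_series(x: np.ndarray, rate_hz: float,
                    cfg: PreprocessConfig | None = None) -> np.ndarray:
    """The same band-pass applied to a bare 1-D series (used for the
    speech envelope, which shares the EEG preprocessing contract)."""
    cfg = cfg or PreprocessConfig(rate_hz=rate_hz)
    sos = _bandpass_sos(cfg, rate_hz)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def standardize(rec: Recording) -> Recording:
    """Standardize each channel to zero mean and unit variance.

    Moments are computed over non-artifact samples only, so masked bursts
    cannot inflate the scale; the affine transform is applied to the whole
    channel to preserve continuity.
    """
    good = ~rec.artifact_mask
    if good.sum() < 2:
        raise ValueError("fewer than 2 artifact-free samples")
    mean = rec.data[:, good].mean(axis=1)
    sd = rec.data[:, good].std(axis=1)
    zero = np.flatnonzero(sd < 1e-15)
    if zero.size:
        names = [rec.channel_labels[i] for i in zero]
        raise ValueError(f"zero-variance channel(s): {names}")
    return rec.copy_with(data=(rec.data - mean[:, None]) / sd[:, None])


def standardize_series(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-15:
        raise ValueError("zero-variance signal")
    return (x - x.mean()) / sd


def apply_artifact_mask(rec: Recording,
                        intervals_s: list[tuple[float, float]]) -> Recording:
    """Mark half-open [start, end) second intervals as artifact.

    The samples stay in place; epoching and segmentation later exclude any
    window that touches a masked sample.
    """
    mask = rec.artifact_mask.copy()
    n = rec.n_samples
    for start, end in intervals_s:
        if start < 0 or end > rec.duration_s + 1e-9 or end <= start:
            raise ValueError(f"artifact interval [{start}, {end}) outside record "
                             f"of duration {rec.duration_s:g} s")
        i0 = int(round(start * rec.rate_hz))
        i1 = min(int(round(end * rec.rate_hz)), n)
        mask[i0:i1] = True
    return rec.copy_with(artifact_mask=mask)


def trial_passes_screen(rec: Recording, max_artifact_s: float = 15.0) -> bool:
    """Trial-screening rule: keep trials with at most ~15 s of artifact."""
    return rec.artifact_mask.sum() / rec.rate_hz <= max_artifact_s + 1e-9


def preprocess_trial(rec: Recording, cfg: PreprocessConfig | None = None,
                     artifact_intervals_s: list[tuple[float, float]] | None = None,
                     ) -> Recording:
    """Full preprocessing chain: notch -> band-pass -> standardize -> mask."""
    cfg = cfg or PreprocessConfig(rate_hz=rec.rate_hz)
    out = notch_filter(rec, cfg)
    out = bandpass_filter(out, cfg)
    if artifact_intervals_s:
        out = apply_artifact_mask(out, artifact_intervals_s)
    return standardize(out)
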