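"""Natural speech envelope (NSE) tracking.

The assay: extract the slow amplitude modulation of the speech waveform
(mono mix -> analytic-signal magnitude -> resample to the EEG rate ->
2-15 Hz band-pass -> standardize), cut EEG and envelope into paired
2-second non-overlapping segments, and at each (channel, lag) compute the
mean over segments of the Pearson correlation between the envelope and
the EEG delayed by that lag (0-500 ms, EEG after audio). Significance is
empirical: the segment pairing is permuted 10,000 times, two-tailed
p-values are read off the shuffled statistic's distribution, and
Benjamini-Hochberg FDR is applied across lags within each channel.
"""

from __future__ import annotations

from fractions import Fraction
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, sparse

from .dpr_mapping import bh_fdr_mask
from .io_formats import AudioSignal, FrequencyMap, Recording
from .preprocess import PreprocessConfig, bandpass_series, standardize_series


@dataclass
class EnvelopeSignal:
    """Speech envelope on the EEG sampling grid (dimensionless after
    standardization)."""

    values: np.ndarray
    rate_hz: float = 250.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass
class SegmentSet:
    """Index-paired EEG and envelope segments.

    eeg: n_segments x channels x seg_len; env: n_segments x seg_len.
    """

    eeg: np.ndarray
    env: np.ndarray
    segment_indices: np.ndarray
    rate_hz: float
    channel_labels: list[str]

    @property
    def n_segments(self) -> int:
        return self.eeg.shape[0]

    @property
    def seg_len(self) -> int:
        return self.eeg.shape[2]


@dataclass
class CrossCorrResult:
    statistic: np.ndarray      # channels x n_lags, in [-1, 1]
    lags_ms: np.ndarray
    null: np.ndarray           # n_shuffles x channels x n_lags
    p_values: np.ndarray
    mask: np.ndarray
    alpha: float = 0.05
    correction_scope: str = "within_channel"
    channel_labels: list[str] = field(default_factory=list)

    def frequency_map(self) -> FrequencyMap:
        labels = self.channel_labels or [f"ch{i}"
                                         for i in range(self.mask.shape[0])]
        return FrequencyMap(
            channel_labels=labels, points_ms=self.lags_ms,
            values=self.mask.astype(float), level="trial", axis_kind="lag",
            chance_level=self.alpha / self.mask.shape[1],
        )


def compute_envelope(audio: AudioSignal, cfg: PreprocessConfig | None = None,
                     eeg_rate_hz: float = 250.0,
                     use_raw_audio: bool = False) -> EnvelopeSignal:
    """Envelope of the stimulus on the EEG grid, preprocessed like the EEG.

    ``use_raw_audio=True`` skips the analytic-signal magnitude and
    band-passes the resampled waveform itself instead (for comparison with
    correlating against the raw audio rather than its envelope).
    """
    mono = audio.mono()
    if np.abs(mono).max() < 1e-12:
        raise ValueError("silent (all-zero) audio has no envelope")
    x = mono if use_raw_audio else np.abs(signal.hilbert(mono))
    frac = Fraction(int(round(eeg_rate_hz * 1000)),
                    int(round(audio.rate_hz * 1000)))
    y = signal.resample_poly(x, frac.numerator, frac.denominator)
    y = bandpass_series(y, eeg_rate_hz, cfg)
    return EnvelopeSignal(values=standardize_series(y), rate_hz=eeg_rate_hz)


def raw_envelope(audio: AudioSignal) -> np.ndarray:
    """Analytic-signal magnitude at the audio rate (pre-filter, nonnegative)."""
    return np.abs(signal.hilbert(audio.mono()))


def segment_pairs(rec: Recording, env: EnvelopeSignal,
                  seg_s: float = 2.0) -> SegmentSet:
    """Cut EEG and envelope into paired non-overlapping segments.

    Segments overlapping any artifact-masked sample are excluded; a
    trailing remainder shorter than one segment is dropped.
    """
    if abs(rec.rate_hz - env.rate_hz) > 1e-9:
        raise ValueError("EEG and envelope must share a sampling rate")
    n = min(rec.n_samples, env.n_samples)
    if rec.n_samples != env.n_samples:
        raise ValueError("EEG and envelope must be aligned and equal length")
    seg_len = int(round(seg_s * rec.rate_hz))
    n_seg = n // seg_len
    if n_seg == 0:
        raise ValueError(f"record shorter than one {seg_s:g} s segment")
    keep = []
    for i in range(n_seg):
        sl = slice(i * seg_len, (i + 1) * seg_len)
        if not rec.artifact_mask[sl].any():
            keep.append(i)
    idx = np.array(keep, dtype=int)
    eeg = np.stack([rec.data[:, i * seg_len:(i + 1) * seg_len] for i in idx]) \
        if idx.size else np.empty((0, rec.n_channels, seg_len))
    envs = np.stack([env.values[i * seg_len:(i + 1) * seg_len] for i in idx]) \
        if idx.size else np.empty((0, seg_len))
    return SegmentSet(eeg=eeg, env=envs, segment_indices=idx,
                      rate_hz=rec.rate_hz, channel_labels=list(rec.channel_labels))


def lag_axis_ms(rate_hz: float = 250.0, max_lag_ms: float = 500.0) -> np.ndarray:
    """Non-negative lags 0, 4, ..., 500 ms (126 lags at 250 Hz)."""
    n = int(round(max_lag_ms / 1000.0 * rate_hz)) + 1
    return np.arange(n) * 1000.0 / rate_hz


def _normalize(x: np.ndarray, axis: int) -> np.ndarray:
    x = x - x.mean(axis=axis, keepdims=True)
    norm = np.sqrt((x ** 2).sum(axis=axis, keepdims=True))
    norm[norm < 1e-300] = np.inf  # zero-variance slices correlate as 0
    return x / norm


def segment_correlation_tensor(segments: SegmentSet,
                               max_lag_ms: float = 500.0) -> np.ndarray:
    """All segment-by-segment correlations: channels x lags x env_seg x eeg_seg.

    Entry [c, L, i, j] is the Pearson correlation between envelope segment i
    (truncated to the overlap) and EEG segment j of channel c delayed by L
    samples. The diagonal over (i, j) gives the observed statistic; shuffles
    are means over permuted diagonals, so the full tensor lets 10,000
    shuffles be evaluated with one sparse matrix product.
    """
    if segments.n_segments < 1:
        raise ValueError("need at least one segment")
    lags = np.round(lag_axis_ms(segments.rate_hz, max_lag_ms)
                    * segments.rate_hz / 1000.0).astype(int)
    n_seg, n_ch, T = (segments.n_segments, segments.eeg.shape[1],
                      segments.seg_len)
    R = np.empty((n_ch, len(lags), n_seg, n_seg))
    for li, L in enumerate(lags):
        m = T - L
        e = _normalize(segments.env[:, :m], axis=1)          # (seg, m)
        g = _normalize(segments.eeg[:, :, L:], axis=2)       # (seg, ch, m)
        # (ch, env_seg, eeg_seg) <- e . g
        R[:, li] = np.einsum("im,jcm->cij", e, g, optimize=True)
    return R


def xcorr_statistic(segments: SegmentSet,
                    max_lag_ms: float = 500.0,
                    corr_tensor: np.ndarray | None = None) -> np.ndarray:
    """Observed statistic: mean over segments of the paired-segment
    correlation, per channel and lag (channels x n_lags, in [-1, 1])."""
    R = corr_tensor if corr_tensor is not None \
        else segment_correlation_tensor(segments, max_lag_ms)
    n = R.shape[2]
    diag = R[:, :, np.arange(n), np.arange(n)]
    return diag.mean(axis=2)


def shuffle_null(segments: SegmentSet, n_shuffles: int = 10000,
                 seed: int | np.random.Generator = 0,
                 max_lag_ms: float = 500.0,
                 corr_tensor: np.ndarray | None = None) -> np.ndarray:
    """Empirical null: the statistic recomputed under random re-pairings.

    Each shuffle pairs EEG segment i with envelope segment pi(i) for a
    uniform random permutation pi; the identity permutation is re-drawn so
    the observed pairing never contaminates the null. Returns
    n_shuffles x channels x n_lags, deterministic given the seed.
    """
    import warnings

    n = segments.n_segments
    if n < 3:
        raise ValueError("need at least 3 segments for a usable shuffle null")
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles: unstable null tail")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    R = corr_tensor if corr_tensor is not None \
        else segment_correlation_tensor(segments, max_lag_ms)
    n_ch, n_lags = R.shape[:2]
    identity = np.arange(n)
    perms = np.empty((n_shuffles, n), dtype=np.int64)
    for s in range(n_shuffles):
        p = rng.permutation(n)
        while (p == identity).all():
            p = rng.permutation(n)
        perms[s] = p
    # one sparse product evaluates every shuffle: rows select the n
    # (env_seg i, eeg_seg pi(i)) entries of the flattened (i, j) plane
    flat = R.reshape(n_ch * n_lags, n * n)
    cols = (identity[None, :] * n + perms).ravel()
    rows = np.repeat(np.arange(n_shuffles), n)
    P = sparse.csr_matrix(
        (np.full(n_shuffles * n, 1.0 / n), (rows, cols)),
        shape=(n_shuffles, n * n),
    )
    null = P @ flat.T  # (n_shuffles, n_ch * n_lags)
    return np.ascontiguousarray(null).reshape(n_shuffles, n_ch, n_lags)


def empirical_significance(obs: np.ndarray, null: np.ndarray,
                           alpha: float = 0.05,
                           scope: str = "within_channel",
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed empirical p-values and their BH-FDR mask.

    p = (1 + #{shuffles with |null| >= |obs|}) / (n_shuffles + 1); the +1
    keeps p strictly positive and accounts for the observed statistic
    itself. FDR is applied across lags within each channel (shared with
    the phoneme-class analysis).
    """
    n_shuffles = null.shape[0]
    exceed = (np.abs(null) >= np.abs(obs)[None]).sum(axis=0)
    p = (1.0 + exceed) / (n_shuffles + 1.0)
    mask = bh_fdr_mask(p, alpha=alpha, scope=scope)
    return p, mask


def nse_analysis(rec: Recording, env: EnvelopeSignal, n_shuffles: int = 10000,
                 seed: int | np.random.Generator = 0, seg_s: float = 2.0,
                 max_lag_ms: float = 500.0, alpha: float = 0.05,
                 scope: str = "within_channel") -> CrossCorrResult:
    """Full envelope-tracking analysis of one preprocessed trial."""
    segments = segment_pairs(rec, env, seg_s=seg_s)
    R = segment_correlation_tensor(segments, max_lag_ms)
    obs = xcorr_statistic(segments, max_lag_ms, corr_tensor=R)
    null = shuffle_null(segments, n_shuffles=n_shuffles, seed=seed,
                        max_lag_ms=max_lag_ms, corr_tensor=R)
    p, mask = empirical_significance(obs, null, alpha=alpha, scope=scope)
    return CrossCorrResult(
        statistic=obs, lags_ms=lag_axis_ms(segments.rate_hz, max_lag_ms),
        null=null, p_values=p, mask=mask, alpha=alpha,
        correction_scope=scope, channel_labels=segments.channel_labels,
    )
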