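"""Differential phoneme-class response (DPR) mapping.

The assay: cut the preprocessed EEG into 500 ms epochs locked to every
phoneme onset, group epochs by manner-of-articulation class, and at each
(channel, timepoint) compare the amplitude distributions of two classes
with a two-tailed Wilcoxon rank-sum test. Per channel, p-values are
corrected across the 125 timepoints with the Benjamini-Hochberg step-up
procedure at alpha = 0.05, so random data yields on average ~0.05
false-positive points per channel (an overall significant-cell frequency
of ~0.0004). The 10 pairwise masks from the 5 classes are then averaged
into a frequency map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import PHONEME_CLASSES, FrequencyMap, PhonemeAnnotation, Recording

#: All C(5,2) = 10 unordered class pairs, in canonical order.
ALL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(PHONEME_CLASSES, 2)
)

#: Sub-intervals of the 500 ms window used for spatial summaries, in ms.
DEFAULT_SUBINTERVALS_MS: tuple[tuple[float, float], ...] = (
    (0, 80), (84, 148), (152, 300), (304, 400), (404, 500),
)


@dataclass
class EpochSet:
    """Onset-locked epochs of one phoneme class: n_epochs x channels x samples."""

    class_label: str
    epochs: np.ndarray
    onset_samples: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.onset_samples = np.asarray(self.onset_samples, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x channels x samples")
        if len(self.onset_samples) != self.epochs.shape[0]:
            raise ValueError("one onset index per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class EpochReport:
    """Bookkeeping for epoch extraction/rejection; every annotated phoneme is
    accounted for: kept + boundary_dropped + artifact_excluded + unmapped
    (+ amplitude_rejected after rejection)."""

    total_annotated: int = 0
    kept: int = 0
    boundary_dropped: int = 0
    artifact_excluded: int = 0
    unmapped: int = 0
    amplitude_rejected: int = 0


@dataclass
class PairResult:
    """Rank-sum p-values and FDR mask for one unordered class pair."""

    pair: tuple[str, str]
    p_values: np.ndarray  # channels x timepoints, in (0, 1]
    mask: np.ndarray      # boolean, same shape
    correction_scope: str = "within_channel"
    alpha: float = 0.05
    n_epochs: dict = field(default_factory=dict)


def time_axis_ms(rate_hz: float = 250.0, window_ms: float = 500.0) -> np.ndarray:
    """Epoch timepoints in ms post-onset: 0, 4, ..., 496 at 250 Hz."""
    n = int(round(window_ms / 1000.0 * rate_hz))
    return np.arange(n) * 1000.0 / rate_hz


def extract_epochs(rec: Recording, annot: PhonemeAnnotation,
                   window_ms: float = 500.0,
                   report: EpochReport | None = None,
                   ) -> dict[str, EpochSet]:
    """Cut onset-locked epochs for each phoneme class.

    One epoch per annotated phoneme whose window fits inside the record and
    touches no artifact-masked sample. Onsets map to the nearest sample.
    Windows overlap freely (phonemes are much shorter than the window).
    """
    n_win = int(round(window_ms / 1000.0 * rec.rate_hz))
    report = report if report is not None else EpochReport()
    report.total_annotated += len(annot)
    report.unmapped += int(annot.classes.isna().sum())
    mapped = annot.mapped()
    # prefix sums make "any masked sample in window" O(1) per epoch
    mask_cum = np.concatenate([[0], np.cumsum(rec.artifact_mask)])
    out: dict[str, EpochSet] = {}
    for cls in PHONEME_CLASSES:
        onsets = np.round(
            mapped.loc[mapped["class"] == cls, "start_s"].to_numpy() * rec.rate_hz
        ).astype(int)
        fits = (onsets >= 0) & (onsets + n_win <= rec.n_samples)
        report.boundary_dropped += int((~fits).sum())
        onsets = onsets[fits]
        clean = (mask_cum[onsets + n_win] - mask_cum[onsets]) == 0
        report.artifact_excluded += int((~clean).sum())
        onsets = onsets[clean]
        report.kept += len(onsets)
        if len(onsets):
            epochs = np.stack([rec.data[:, o:o + n_win] for o in onsets], axis=0)
        else:
            epochs = np.empty((0, rec.n_channels, n_win))
        out[cls] = EpochSet(class_label=cls, epochs=epochs, onset_samples=onsets)
    return out


def reject_epochs(epoch_sets: dict[str, EpochSet], sd_threshold: float = 10.0,
                  report: EpochReport | None = None) -> dict[str, EpochSet]:
    """Drop epochs containing any sample beyond ``sd_threshold``.

    Input channels are expected to be standardized to unit variance, so the
    threshold is in standard-deviation units of the whole trial.
    """
    out: dict[str, EpochSet] = {}
    for cls, es in epoch_sets.items():
        if es.n_epochs == 0:
            out[cls] = es
            continue
        keep = np.abs(es.epochs).max(axis=(1, 2)) <= sd_threshold
        if report is not None:
            report.amplitude_rejected += int((~keep).sum())
            report.kept -= int((~keep).sum())
        out[cls] = EpochSet(class_label=cls, epochs=es.epochs[keep],
                            onset_samples=es.onset_samples[keep])
    return out


# ---------------------------------------------------------------------------
# Rank-sum testing

#: Largest group size for which the exact permutation distribution is used.
EXACT_MAX_N = 8


def ranksum_pvalues(epochs_a: np.ndarray, epochs_b: np.ndarray) -> np.ndarray:
    """Two-tailed Wilcoxon rank-sum p at every (channel, timepoint).

    For group sizes up to 8 the exact permutation distribution of the
    rank-sum statistic (midranks, so ties are handled) is enumerated;
    larger groups use the normal approximation with tie and continuity
    corrections. Cells where all amplitudes are identical get p = 1.
    """
    a = np.asarray(epochs_a, dtype=float)
    b = np.asarray(epochs_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("epoch arrays must be n x channels x samples, same grid")
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 epochs")
    if max(n1, n2) <= EXACT_MAX_N:
        return _ranksum_exact(a, b)
    return _ranksum_normal(a, b)


def _midranks(stacked: np.ndarray) -> np.ndarray:
    """Midranks along axis 0 of an (N, cells) array."""
    return stats.rankdata(stacked, axis=0)


def _ranksum_exact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[0], b.shape[0]
    shape = a.shape[1:]
    stacked = np.concatenate([a, b], axis=0).reshape(n1 + n2, -1)
    ranks = _midranks(stacked)
    mu = n1 * (n1 + n2 + 1) / 2.0
    w_obs = ranks[:n1].sum(axis=0)
    # all C(n1+n2, n1) assignments of the observed (possibly tied) values
    combos = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    sel = np.zeros((len(combos), n1 + n2))
    sel[np.arange(len(combos))[:, None], combos] = 1.0
    w_all = sel @ ranks  # (n_combos, cells)
    dev_obs = np.abs(w_obs - mu)
    p = (np.abs(w_all - mu) >= dev_obs - 1e-9).mean(axis=0)
    return p.reshape(shape)


def _ranksum_normal(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[0], b.shape[0]
    shape = a.shape[1:]
    N = n1 + n2
    stacked = np.concatenate([a, b], axis=0).reshape(N, -1)
    ranks = _midranks(stacked)
    w = ranks[:n1].sum(axis=0)
    mu = n1 * (N + 1) / 2.0
    # tie correction: sum of (t^3 - t) over tie groups, per cell; only
    # computed for cells that actually contain ties (continuous EEG
    # amplitudes essentially never tie)
    tie_term = np.zeros(stacked.shape[1])
    sorted_vals = np.sort(stacked, axis=0)
    has_tie = (sorted_vals[1:] == sorted_vals[:-1]).any(axis=0)
    for j in np.flatnonzero(has_tie):
        _, counts = np.unique(stacked[:, j], return_counts=True)
        tie_term[j] = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    p = np.ones(stacked.shape[1])
    ok = var > 0
    dev = np.abs(w[ok] - mu)
    z = np.maximum(dev - 0.5, 0.0) / np.sqrt(var[ok])  # continuity correction
    p[ok] = special.erfc(z / np.sqrt(2.0))
    return np.minimum(p, 1.0).reshape(shape)


# ---------------------------------------------------------------------------
# FDR correction


def bh_fdr_mask(p_matrix: np.ndarray, alpha: float = 0.05,
                scope: str = "within_channel") -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask.

    ``scope='within_channel'`` corrects each channel's row (the primary
    analysis: FDR across timepoints, separately per channel);
    ``scope='global'`` treats all channels x timepoints as one family.
    """
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim != 2:
        raise ValueError("p-matrix must be channels x points")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if scope == "global":
        rej, *_ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
        return rej.reshape(p.shape)
    if scope == "within_channel":
        mask = np.empty_like(p, dtype=bool)
        for c in range(p.shape[0]):
            mask[c], *_ = multipletests(p[c], alpha=alpha, method="fdr_bh")
        return mask
    raise ValueError(f"unknown correction scope {scope!r}")


def pair_result(epoch_sets: dict[str, EpochSet], pair: tuple[str, str],
                alpha: float = 0.05, scope: str = "within_channel") -> PairResult:
    """Rank-sum + FDR significance map for one unordered class pair."""
    a, b = pair
    if a == b:
        raise ValueError("pair classes must differ")
    for cls in pair:
        if cls not in epoch_sets:
            raise KeyError(f"no epochs for class {cls!r}")
    p = ranksum_pvalues(epoch_sets[a].epochs, epoch_sets[b].epochs)
    mask = bh_fdr_mask(p, alpha=alpha, scope=scope)
    return PairResult(pair=tuple(sorted(pair)), p_values=p, mask=mask,
                      correction_scope=scope, alpha=alpha,
                      n_epochs={a: epoch_sets[a].n_epochs,
                                b: epoch_sets[b].n_epochs})


def pair_map(rec: Recording, annot: PhonemeAnnotation, pair: tuple[str, str],
             alpha: float = 0.05, scope: str = "within_channel",
             sd_threshold: float = 10.0, window_ms: float = 500.0) -> PairResult:
    """End-to-end pair analysis on a preprocessed recording."""
    report = EpochReport()
    sets = extract_epochs(rec, annot, window_ms=window_ms, report=report)
    sets = reject_epochs(sets, sd_threshold=sd_threshold, report=report)
    return pair_result(sets, pair, alpha=alpha, scope=scope)


def average_pair_maps(pair_results: list[PairResult],
                      channel_labels: list[str] | None = None,
                      rate_hz: float = 250.0) -> FrequencyMap:
    """Average the 10 pairwise masks into a trial-level frequency map.

    Requires exactly the 10 distinct pairs from the 5 classes; each cell
    becomes the fraction of pairs significant there (multiples of 0.1).
    """
    pairs = sorted(tuple(sorted(r.pair)) for r in pair_results)
    if pairs != sorted(ALL_PAIRS):
        raise ValueError(
            f"need exactly the {len(ALL_PAIRS)} distinct class pairs, got {pairs}"
        )
    masks = np.stack([r.mask for r in pair_results]).astype(float)
    values = masks.mean(axis=0)
    n_ch, n_pts = values.shape
    labels = channel_labels or [f"ch{i}" for i in range(n_ch)]
    return FrequencyMap(
        channel_labels=labels,
        points_ms=np.arange(n_pts) * 1000.0 / rate_hz,
        values=values,
        level="trial",
        axis_kind="time",
        chance_level=0.05 / n_pts,
    )


def temporal_profile(fmap: FrequencyMap) -> np.ndarray:
    """Mean frequency over channels, per timepoint."""
    return fmap.values.mean(axis=0)


def spatial_profile(fmap: FrequencyMap) -> np.ndarray:
    """Mean frequency over timepoints, per channel."""
    return fmap.values.mean(axis=1)


def subinterval_summary(fmap: FrequencyMap,
                        bins_ms: tuple[tuple[float, float], ...]
                        = DEFAULT_SUBINTERVALS_MS) -> np.ndarray:
    """Per-channel mean frequency within each sub-interval (channels x bins).

    Bin edges must sit on the map's sampling grid; both edges are inclusive
    on that grid (0-80 ms covers 21 timepoints at 4 ms spacing), and the
    final edge is clipped to the last available timepoint.
    """
    step = np.diff(fmap.points_ms)[0] if len(fmap.points_ms) > 1 else 4.0
    out = np.empty((fmap.values.shape[0], len(bins_ms)))
    for j, (lo, hi) in enumerate(bins_ms):
        for edge in (lo, hi):
            if edge <= fmap.points_ms[-1] and abs(edge / step - round(edge / step)) > 1e-9:
                raise ValueError(f"bin edge {edge} ms is off the {step:g} ms grid")
        sel = (fmap.points_ms >= lo - 1e-9) & (fmap.points_ms <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"bin [{lo}, {hi}] ms contains no timepoints")
        out[:, j] = fmap.values[:, sel].mean(axis=1)
    return out
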