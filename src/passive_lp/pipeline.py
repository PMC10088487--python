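"""End-to-end orchestration: preprocess -> analyses -> aggregation, plus the
null-calibration experiment as a first-class operation.

The calibration runs are the package's internal control: on pure-noise
data the phoneme-class stage must produce ~0.05 false-positive timepoints
per channel (alpha of the within-channel BH correction) and both stages an
overall significant-cell frequency of ~0.0004.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import aggregation, dpr_mapping, nse_tracking
from .io_formats import (FrequencyMap, PhonemeAnnotation, Recording,
                         read_map, read_subject_table, write_map)
from .preprocess import PreprocessConfig, preprocess_trial, trial_passes_screen
from .synthetic import SyntheticConfig, generate_dataset


@dataclass
class RunConfig:
    """One trial run: which analyses to execute and with what settings."""

    run_dpr: bool = True
    run_nse: bool = True
    scope: str = "within_channel"
    alpha: float = 0.05
    n_shuffles: int = 10000
    seed: int | None = None
    window_ms: float = 500.0
    max_lag_ms: float = 500.0
    seg_s: float = 2.0
    subintervals_ms: tuple = dpr_mapping.DEFAULT_SUBINTERVALS_MS
    preprocess: PreprocessConfig | None = None
    max_artifact_s: float = 15.0

    def __post_init__(self) -> None:
        if not (self.run_dpr or self.run_nse):
            raise ValueError("at least one analysis must be enabled")
        if self.run_nse and self.seed is None:
            raise ValueError("a seed is required when the shuffle null runs")


@dataclass
class TrialResult:
    pair_results: list[dpr_mapping.PairResult] = field(default_factory=list)
    dpr_map: FrequencyMap | None = None
    nse_result: nse_tracking.CrossCorrResult | None = None
    epoch_report: dpr_mapping.EpochReport | None = None
    screened_out: bool = False
    log: dict = field(default_factory=dict)


def run_trial(rec: Recording, annot: PhonemeAnnotation | None,
              envelope: nse_tracking.EnvelopeSignal | None,
              config: RunConfig,
              artifact_intervals_s: list[tuple[float, float]] | None = None,
              already_preprocessed: bool = False) -> TrialResult:
    """Preprocess one trial and run the enabled analyses.

    The recording is notch/band-pass filtered and standardized unless
    ``already_preprocessed``. Trials failing the ~15 s artifact screen are
    returned flagged with no analysis output.
    """
    result = TrialResult()
    if already_preprocessed:
        if artifact_intervals_s:
            from .preprocess import apply_artifact_mask
            rec = apply_artifact_mask(rec, artifact_intervals_s)
    else:
        rec = preprocess_trial(rec, config.preprocess, artifact_intervals_s)
    if not trial_passes_screen(rec, config.max_artifact_s):
        result.screened_out = True
        result.log["screened_out"] = True
        result.log["artifact_s"] = float(rec.artifact_mask.sum() / rec.rate_hz)
        return result

    if config.run_dpr:
        if annot is None:
            raise ValueError("phoneme-class analysis requires an annotation")
        report = dpr_mapping.EpochReport()
        sets = dpr_mapping.extract_epochs(rec, annot,
                                          window_ms=config.window_ms,
                                          report=report)
        thr = (config.preprocess.epoch_reject_sd if config.preprocess
               else PreprocessConfig().epoch_reject_sd)
        sets = dpr_mapping.reject_epochs(sets, sd_threshold=thr, report=report)
        result.epoch_report = report
        result.pair_results = [
            dpr_mapping.pair_result(sets, pair, alpha=config.alpha,
                                    scope=config.scope)
            for pair in dpr_mapping.ALL_PAIRS
        ]
        result.dpr_map = dpr_mapping.average_pair_maps(
            result.pair_results, channel_labels=rec.channel_labels,
            rate_hz=rec.rate_hz)
        result.log["epochs"] = {
            "total_annotated": report.total_annotated,
            "kept": report.kept,
            "boundary_dropped": report.boundary_dropped,
            "artifact_excluded": report.artifact_excluded,
            "amplitude_rejected": report.amplitude_rejected,
            "unmapped": report.unmapped,
        }
        if report.total_annotated:
            result.log["artifact_excluded_pct"] = round(
                100.0 * report.artifact_excluded / report.total_annotated, 4)
            result.log["amplitude_rejected_pct"] = round(
                100.0 * report.amplitude_rejected / report.total_annotated, 4)

    if config.run_nse:
        if envelope is None:
            raise ValueError("envelope tracking requires a stimulus envelope")
        result.nse_result = nse_tracking.nse_analysis(
            rec, envelope, n_shuffles=config.n_shuffles, seed=config.seed,
            seg_s=config.seg_s, max_lag_ms=config.max_lag_ms,
            alpha=config.alpha, scope=config.scope)
        result.log["nse_n_shuffles"] = int(result.nse_result.null.shape[0])
    return result


# ---------------------------------------------------------------------------
# Null calibration


def dpr_null_calibration(n_replicates: int = 20, seed: int = 0,
                         n_channels: int = 8, n_timepoints: int = 125,
                         epochs_per_class: tuple[int, int] = (150, 300),
                         n_pairs: int = 10, alpha: float = 0.05,
                         scope: str = "within_channel") -> dict:
    """False-positive behaviour of the rank-sum + FDR stage on white noise.

    Simulates epochs with no class effect and randomly assigned labels, and
    reports the mean number of significant timepoints per channel-map and
    the overall significant-cell frequency, with Monte-Carlo standard
    errors over channel-maps.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    n1, n2 = epochs_per_class
    fp_counts = []
    for _ in range(n_replicates):
        for _pair in range(n_pairs):
            a = rng.standard_normal((n1, n_channels, n_timepoints))
            b = rng.standard_normal((n2, n_channels, n_timepoints))
            p = dpr_mapping.ranksum_pvalues(a, b)
            mask = dpr_mapping.bh_fdr_mask(p, alpha=alpha, scope=scope)
            fp_counts.extend(mask.sum(axis=1).tolist())
    fp = np.asarray(fp_counts, dtype=float)
    return {
        "mean_fp_per_channel": float(fp.mean()),
        "se_fp_per_channel": float(fp.std(ddof=1) / np.sqrt(len(fp))),
        "cell_frequency": float(fp.mean() / n_timepoints),
        "n_channel_maps": len(fp),
        "n_timepoints": n_timepoints,
    }


def nse_null_calibration(n_replicates: int = 20, seed: int = 0,
                         n_shuffles: int = 10000, n_channels: int = 8,
                         duration_s: float = 148.0, alpha: float = 0.05,
                         scope: str = "within_channel") -> dict:
    """Significant-cell frequency of the envelope-tracking stage when the
    EEG is noise unrelated to the envelope."""
    from .preprocess import bandpass_series, standardize_series
    from .synthetic import generate_annotation, generate_envelope, generate_eeg

    rng = np.random.default_rng(seed)
    freqs = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        cfg = SyntheticConfig(seed=rep_seed, duration_s=duration_s,
                              n_channels=n_channels)
        annot = generate_annotation(cfg)
        env, _audio = generate_envelope(annot, cfg)
        rec = generate_eeg(annot, env, cfg)  # zero coupling: noise only
        rec = rec.copy_with(data=np.vstack(
            [standardize_series(ch) for ch in rec.data]))
        env_p = nse_tracking.EnvelopeSignal(
            values=standardize_series(
                bandpass_series(env.values, cfg.rate_hz)),
            rate_hz=cfg.rate_hz)
        res = nse_tracking.nse_analysis(rec, env_p, n_shuffles=n_shuffles,
                                        seed=rep_seed + 1, alpha=alpha,
                                        scope=scope)
        freqs.append(res.mask.mean())
    freqs = np.asarray(freqs)
    return {
        "cell_frequency": float(freqs.mean()),
        "se_cell_frequency": float(freqs.std(ddof=1) / np.sqrt(len(freqs))
                                   if len(freqs) > 1 else np.nan),
        "n_replicates": n_replicates,
        "n_shuffles": n_shuffles,
    }


def run_null_calibration(n_replicates: int = 20, seed: int = 0,
                         n_shuffles: int = 10000,
                         analyses: tuple[str, ...] = ("dpr", "nse")) -> dict:
    """Both calibration experiments; see the per-analysis functions."""
    if n_replicates < 10:
        raise ValueError("need at least 10 replicates for a stable estimate")
    report: dict = {"n_replicates": n_replicates, "seed": seed}
    if "dpr" in analyses:
        report["dpr"] = dpr_null_calibration(n_replicates, seed=seed)
    if "nse" in analyses:
        report["nse"] = nse_null_calibration(n_replicates, seed=seed + 1,
                                             n_shuffles=n_shuffles)
    return report


# ---------------------------------------------------------------------------
# Group stage


def run_group(metadata_path: str | Path,
              trial_map_paths: dict[str, dict[str, list[str | Path]]],
              out_dir: str | Path | None = None) -> dict[str, FrequencyMap]:
    """Combine per-trial maps into per-category group maps.

    ``trial_map_paths`` maps subject_id -> visit label -> list of trial map
    files. Trials are averaged within a subject (across all visits), then
    subjects are averaged with equal weight within each behavioural class
    and CF/LP category.
    """
    metadata = read_subject_table(metadata_path)
    subject_maps: dict[str, FrequencyMap] = {}
    n_visits: dict[str, int] = {}
    for sid, visits in trial_map_paths.items():
        trial_maps = [read_map(p) for paths in visits.values() for p in paths]
        subject_maps[sid] = aggregation.combine_trials(trial_maps)
        n_visits[sid] = len(visits)
    groups = aggregation.group_maps_by_category(subject_maps, metadata,
                                                n_visits)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, fmap in groups.items():
            write_map(fmap, out_dir / f"group_{name.replace('/', '_')}.tsv")
        counts = aggregation.count_categories(metadata)
        with open(out_dir / "category_counts.json", "w") as fh:
            json.dump({k: v for k, v in counts.items() if k != "assignments"},
                      fh, indent=2)
    return groups
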