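"""Readers and writers for every external artifact of the pipeline.

EEG comes in as EDF or as a plain delimited matrix with a small metadata
header; audio as WAV; phoneme annotations as tab-separated start/end/label
tables (or Praat TextGrid interval tiers); phoneme-to-class maps, subject
metadata and result maps as tab-separated tables.

Conventions: times are seconds, sample indices are 0-based, and intervals
are half-open ``[start, end)``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

#: The five phoneme classes by manner of articulation:
#: approximants, fricatives, nasals, plosives, vowels.
PHONEME_CLASSES = ("A", "F", "N", "P", "V")

#: Behavioural (bedside) diagnostic categories plus healthy controls.
BEHAVIOURAL_CLASSES = ("VS/UWS", "MCS-", "MCS+", "eMCS", "HC")

#: Allowed values of a command-following flag.
CF_FLAGS = ("pos", "neg", "not_done")


class FormatError(ValueError):
    """Raised when a file violates its declared format."""


# ---------------------------------------------------------------------------
# Recording


@dataclass
class Recording:
    """Multichannel EEG: channels x samples, with an artifact mask.

    Amplitudes are microvolts before standardization and dimensionless
    afterwards. ``artifact_mask`` is True at contaminated samples.
    """

    channel_labels: list[str]
    rate_hz: float
    data: np.ndarray
    reference_label: str = "FCz"
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            dupes = sorted(
                {c for c in self.channel_labels if self.channel_labels.count(c) > 1}
            )
            raise FormatError(f"duplicate channel labels: {dupes}")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.data.shape[1],):
                raise ValueError("artifact_mask length must equal sample count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def copy_with(self, data: np.ndarray | None = None,
                  artifact_mask: np.ndarray | None = None) -> "Recording":
        return Recording(
            channel_labels=list(self.channel_labels),
            rate_hz=self.rate_hz,
            data=self.data.copy() if data is None else data,
            reference_label=self.reference_label,
            artifact_mask=(self.artifact_mask.copy()
                           if artifact_mask is None else artifact_mask),
        )


def read_eeg(path: str | Path, format_hint: str | None = None) -> Recording:
    """Read an EEG recording from EDF or the delimited-matrix dialect.

    The format is taken from ``format_hint`` ("edf" or "delimited") or,
    if absent, from the file suffix. The returned artifact mask is all
    False; artifact intervals are applied separately.
    """
    path = Path(path)
    fmt = format_hint or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        return _read_delimited_eeg(path)
    raise ValueError(f"unknown EEG format {fmt!r}")


def _read_edf(path: Path) -> Recording:
    import mne

    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate channel labels in {path}")
    data = raw.get_data() * 1e6  # mne returns volts; store microvolts
    return Recording(channel_labels=labels, rate_hz=float(raw.info["sfreq"]),
                     data=data)


def _read_delimited_eeg(path: Path) -> Recording:
    """Delimited EEG dialect: '#'-prefixed header (rate_hz, labels,
    optionally reference), then one tab-separated row per channel."""
    meta: dict[str, str] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                rows.append(np.array(line.split("\t"), dtype=float))
    if "rate_hz" not in meta:
        raise FormatError(f"{path}: missing 'rate_hz' header line")
    if "labels" not in meta:
        raise FormatError(f"{path}: missing 'labels' header line")
    labels = meta["labels"].split("\t") if "\t" in meta["labels"] \
        else meta["labels"].split(",")
    labels = [l.strip() for l in labels]
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate channel labels in {path}")
    if len(rows) != len(labels):
        raise FormatError(
            f"{path}: header declares {len(labels)} channels but file has "
            f"{len(rows)} data rows"
        )
    data = np.vstack(rows)
    return Recording(channel_labels=labels, rate_hz=float(meta["rate_hz"]),
                     data=data, reference_label=meta.get("reference", "FCz"))


def write_eeg(rec: Recording, path: str | Path,
              format_hint: str | None = None) -> None:
    """Write a recording as EDF (16-bit) or the delimited dialect.

    EDF stores whole one-second records, so recordings whose length is not
    a multiple of the rate are zero-padded on disk; the delimited dialect
    is exact.
    """
    path = Path(path)
    fmt = format_hint or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "delimited":
        with open(path, "w") as fh:
            fh.write(f"# rate_hz: {rec.rate_hz:g}\n")
            fh.write("# labels: " + "\t".join(rec.channel_labels) + "\n")
            fh.write(f"# reference: {rec.reference_label}\n")
            for row in rec.data:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown EEG format {fmt!r}")


def _write_edf(rec: Recording, path: Path) -> None:
    # Minimal EDF writer: one 1 s data record per second, 16-bit samples,
    # per-channel physical scaling. Sufficient for round-tripping through
    # standard EDF readers.
    data = rec.data
    nch = rec.n_channels
    spr = int(round(rec.rate_hz))
    if abs(spr - rec.rate_hz) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    nrec = int(np.ceil(data.shape[1] / spr)) if data.shape[1] else 1
    padded = np.zeros((nch, nrec * spr))
    padded[:, : data.shape[1]] = data
    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    pmax = np.where(pmax - pmin < 1e-9, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    def pack(values, width) -> bytes:
        out = b""
        for v in values:
            s = str(v).encode("ascii")[:width]
            out += s.ljust(width)
        return out

    hdr = b"0".ljust(8)
    hdr += b"".ljust(80)                       # patient id
    hdr += b"".ljust(80)                       # recording id
    hdr += b"01.01.20" + b"00.00.00"           # start date/time
    hdr += str(256 * (1 + nch)).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(nrec).encode().ljust(8)
    hdr += b"1".ljust(8)                       # record duration, seconds
    hdr += str(nch).encode().ljust(4)
    hdr += pack(rec.channel_labels, 16)
    hdr += pack([""] * nch, 80)                # transducer
    hdr += pack(["uV"] * nch, 8)
    hdr += pack([f"{v:.6g}"[:8] for v in pmin], 8)
    hdr += pack([f"{v:.6g}"[:8] for v in pmax], 8)
    hdr += pack([dmin] * nch, 8)
    hdr += pack([dmax] * nch, 8)
    hdr += pack([""] * nch, 80)                # prefiltering
    hdr += pack([spr] * nch, 8)
    hdr += pack([""] * nch, 32)
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(nrec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Phoneme annotations


@dataclass
class PhonemeAnnotation:
    """Timed phoneme intervals plus a phoneme -> class map over {A,F,N,P,V}."""

    intervals: pd.DataFrame  # columns start_s, end_s, phoneme_label (sorted)
    class_map: dict[str, str]

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        required = {"start_s", "end_s", "phoneme_label"}
        if not required.issubset(df.columns):
            raise FormatError(f"annotation table needs columns {sorted(required)}")
        if (df.start_s < 0).any():
            raise FormatError("negative start time in annotation")
        bad = df.end_s <= df.start_s
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"interval {i}: end {df.end_s[i]} <= start {df.start_s[i]}"
            )
        if not df.start_s.is_monotonic_increasing:
            warnings.warn("annotation intervals unsorted; sorting by start time")
            df = df.sort_values("start_s", kind="stable").reset_index(drop=True)
        bad_classes = set(self.class_map.values()) - set(PHONEME_CLASSES)
        if bad_classes:
            raise FormatError(f"unknown phoneme classes in map: {sorted(bad_classes)}")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def classes(self) -> pd.Series:
        """Per-interval class label; NaN where the phoneme is unmapped."""
        return self.intervals.phoneme_label.map(self.class_map)

    @property
    def unmapped_labels(self) -> list[str]:
        used = set(self.intervals.phoneme_label)
        return sorted(used - set(self.class_map))

    def mapped(self) -> pd.DataFrame:
        """Intervals restricted to mapped phonemes, with a 'class' column."""
        out = self.intervals.copy()
        out["class"] = self.classes
        return out[out["class"].notna()].reset_index(drop=True)


def default_class_map() -> dict[str, str]:
    """The packaged ARPAbet manner-of-articulation map.

    Affricates (CH, JH) are intentionally absent: their manner class is
    genuinely ambiguous (plosive release into a fricative), so they are
    reported as unmapped rather than silently assigned.
    """
    with resources.files("passive_lp.data").joinpath(
            "arpabet_classes.tsv").open() as fh:
        return read_class_map(fh)


def read_class_map(path_or_file) -> dict[str, str]:
    df = pd.read_csv(path_or_file, sep="\t", dtype=str)
    if not {"phoneme_label", "class"}.issubset(df.columns):
        raise FormatError("class map needs columns phoneme_label, class")
    return dict(zip(df.phoneme_label, df["class"]))


def read_phoneme_annotation(path: str | Path,
                            class_map: dict[str, str] | str | Path | None = None,
                            ) -> PhonemeAnnotation:
    """Read a phoneme annotation from TSV (start_s/end_s/phoneme_label) or
    from a Praat TextGrid interval tier.

    ``class_map`` may be a dict, a path to a class-map TSV, or None for the
    packaged ARPAbet default. Trailing stress digits (AA1 -> AA) are
    stripped before class lookup, as forced aligners emit stressed vowels.
    """
    path = Path(path)
    if class_map is None:
        cmap = default_class_map()
    elif isinstance(class_map, (str, Path)):
        cmap = read_class_map(class_map)
    else:
        cmap = dict(class_map)
    if path.suffix.lower() == ".textgrid":
        df = _read_textgrid_intervals(path)
    else:
        df = pd.read_csv(path, sep="\t")
        df = df[["start_s", "end_s", "phoneme_label"]]
    df["phoneme_label"] = (
        df.phoneme_label.astype(str).str.strip().str.upper()
        .str.replace(r"\d+$", "", regex=True)
    )
    df = df[df.phoneme_label != ""].reset_index(drop=True)
    return PhonemeAnnotation(intervals=df, class_map=cmap)


def write_phoneme_annotation(annot: PhonemeAnnotation, path: str | Path) -> None:
    annot.intervals.to_csv(path, sep="\t", index=False,
                           columns=["start_s", "end_s", "phoneme_label"])


def _read_textgrid_intervals(path: Path, tier: str | None = None) -> pd.DataFrame:
    """Parse the first (or named) interval tier of a long-format TextGrid."""
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    rows = []
    current_tier = None
    in_wanted = False
    xmin = xmax = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("name ="):
            current_tier = line.split("=", 1)[1].strip().strip('"')
            in_wanted = (tier is None and not rows) or (current_tier == tier)
        elif in_wanted and line.startswith("xmin ="):
            xmin = float(line.split("=", 1)[1])
        elif in_wanted and line.startswith("xmax ="):
            xmax = float(line.split("=", 1)[1])
        elif in_wanted and line.startswith("text ="):
            label = line.split("=", 1)[1].strip().strip('"')
            if label and xmin is not None and xmax is not None and xmax > xmin:
                rows.append((xmin, xmax, label))
    if not rows:
        raise FormatError(f"{path}: no labelled intervals found")
    return pd.DataFrame(rows, columns=["start_s", "end_s", "phoneme_label"])


# ---------------------------------------------------------------------------
# Audio


@dataclass
class AudioSignal:
    """Audio waveform, channels x samples (1 = mono, 2 = binaural)."""

    rate_hz: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.data.shape[0] > 2:
            raise ValueError("audio must have 1 or 2 channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def mono(self) -> np.ndarray:
        """Average of the (binaural) channels."""
        return self.data.mean(axis=0)


def read_audio(path: str | Path) -> AudioSignal:
    """Read a WAV file; integer PCM is rescaled to [-1, 1]."""
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise FormatError(f"{path}: not a readable WAV file ({exc})") from exc
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    data = data.T if data.ndim == 2 else data[None, :]
    return AudioSignal(rate_hz=float(rate), data=data)


def write_audio(audio: AudioSignal, path: str | Path) -> None:
    peak = np.abs(audio.data).max()
    scaled = audio.data / peak if peak > 0 else audio.data
    pcm = np.round(scaled.T * 32767).astype(np.int16)
    wavfile.write(str(path), int(round(audio.rate_hz)), pcm)


# ---------------------------------------------------------------------------
# Frequency maps


@dataclass
class FrequencyMap:
    """Channels x points map of the frequency of significant responses.

    ``points_ms`` is time after phoneme onset for the phoneme-class
    analysis, or cross-correlation lag for envelope tracking. Values lie
    in [0, 1]: the fraction of pairs / trials / subjects significant at
    each cell. ``chance_level`` is the expected value under the null
    (~0.05 false positives over ~125 points -> ~0.0004).
    """

    channel_labels: list[str]
    points_ms: np.ndarray
    values: np.ndarray
    level: str = "pair"  # pair | trial | subject | group
    axis_kind: str = "time"  # time | lag
    chance_level: float = 0.05 / 125
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points_ms = np.asarray(self.points_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channel_labels), len(self.points_ms)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.channel_labels)} channels x {len(self.points_ms)} points"
            )
        if ((self.values < -1e-12) | (self.values > 1 + 1e-12)).any():
            raise ValueError("frequency-map values must lie in [0, 1]")
        if self.level not in ("pair", "trial", "subject", "group"):
            raise ValueError(f"unknown level {self.level!r}")


def write_map(fmap: FrequencyMap, path: str | Path) -> None:
    """Write a frequency map as a delimited table with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# level: {fmap.level}\n")
        fh.write(f"# axis_kind: {fmap.axis_kind}\n")
        fh.write(f"# chance_level: {fmap.chance_level:.12g}\n")
        fh.write(f"# n_channels: {len(fmap.channel_labels)}\n")
        for key, value in sorted(fmap.metadata.items()):
            fh.write(f"# meta.{key}: {value}\n")
        fh.write("channel\t" + "\t".join(f"{t:g}" for t in fmap.points_ms) + "\n")
        for label, row in zip(fmap.channel_labels, fmap.values):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_map(path: str | Path) -> FrequencyMap:
    meta: dict[str, str] = {}
    extra: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                key = key.strip()
                if key.startswith("meta."):
                    extra[key[5:]] = value.strip()
                else:
                    meta[key] = value.strip()
            elif line.strip():
                body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t",
                     float_precision="round_trip")
    labels = df["channel"].astype(str).tolist()
    declared = int(meta.get("n_channels", len(labels)))
    if declared != len(labels):
        raise FormatError(
            f"{path}: header declares {declared} channels, found {len(labels)} rows"
        )
    points = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return FrequencyMap(
        channel_labels=labels,
        points_ms=points,
        values=values,
        level=meta.get("level", "pair"),
        axis_kind=meta.get("axis_kind", "time"),
        chance_level=float(meta.get("chance_level", 0.05 / 125)),
        metadata=extra,
    )


# ---------------------------------------------------------------------------
# Subject metadata


def read_subject_table(path_or_file) -> pd.DataFrame:
    """Read the subject/visit metadata table (one row per visit).

    Columns: subject_id, visit_index, behavioural_class, eeg_cf, fmri_cf.
    Healthy controls must have both command-following flags 'not_done'
    (the motor-imagery assays are only administered to patients).
    """
    df = pd.read_csv(path_or_file, sep="\t", dtype=str)
    required = ["subject_id", "visit_index", "behavioural_class",
                "eeg_cf", "fmri_cf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"subject table missing columns {missing}")
    df = df[required].copy()
    df["visit_index"] = df.visit_index.astype(int)
    if (df.visit_index < 1).any():
        raise FormatError("visit_index must be >= 1")
    bad = set(df.behavioural_class) - set(BEHAVIOURAL_CLASSES)
    if bad:
        raise FormatError(f"unknown behavioural classes: {sorted(bad)}")
    for col in ("eeg_cf", "fmri_cf"):
        badf = set(df[col]) - set(CF_FLAGS)
        if badf:
            raise FormatError(f"unknown {col} values: {sorted(badf)}")
    hc = df[df.behavioural_class == "HC"]
    if ((hc.eeg_cf != "not_done") | (hc.fmri_cf != "not_done")).any():
        raise FormatError("healthy-control rows must have eeg_cf = fmri_cf = not_done")
    return df


def study_cohort() -> pd.DataFrame:
    """The packaged study-cohort metadata fixture (24 patients, 8 controls)."""
    with resources.files("passive_lp.data").joinpath(
            "study_cohort.tsv").open() as fh:
        return read_subject_table(fh)
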