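"""Combining maps across trials and subjects, and patient categorization.

Maps are averaged cellwise: first across trials within a subject, then
across subjects with equal subject weight (a subject's map counts once no
matter how many trials it came from).

Categorization implements the decision tree over the subject metadata:
a patient is CF+ if any visit shows command-following on the EEG or fMRI
motor-imagery assay; LP+ (evidence of language processing) if CF+ or if
any visit's bedside classification implies behavioural command-following
(MCS+ or eMCS); otherwise LP-. 'not_done' contributes no evidence either
way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BEHAVIOURAL_CLASSES, FrequencyMap

#: Bedside classes that constitute behavioural evidence of command-following.
BEHAVIOURAL_CF_CLASSES = ("MCS+", "eMCS")


@dataclass
class CategoryAssignment:
    subject_id: str
    cf_status: str             # CF+ | CF-
    lp_status: str             # LP+ | LP-
    basis: list[str] = field(default_factory=list)  # which evidence triggered
    visit_labels: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cf_status == "CF+" and self.lp_status != "LP+":
            raise ValueError("CF+ implies LP+")


def _check_axes(maps: list[FrequencyMap]) -> None:
    first = maps[0]
    for m in maps[1:]:
        if (m.channel_labels != first.channel_labels
                or len(m.points_ms) != len(first.points_ms)
                or not np.allclose(m.points_ms, first.points_ms)
                or m.axis_kind != first.axis_kind):
            raise ValueError("maps do not share axes")


def combine_trials(trial_maps: list[FrequencyMap]) -> FrequencyMap:
    """Cellwise mean of a subject's trial maps (level -> subject)."""
    if not trial_maps:
        raise ValueError("no trial maps")
    _check_axes(trial_maps)
    first = trial_maps[0]
    values = np.mean([m.values for m in trial_maps], axis=0)
    return FrequencyMap(
        channel_labels=list(first.channel_labels), points_ms=first.points_ms,
        values=values, level="subject", axis_kind=first.axis_kind,
        chance_level=first.chance_level,
        metadata={"n_trials": len(trial_maps)},
    )


def combine_subjects(subject_maps: dict[str, FrequencyMap],
                     n_visits: dict[str, int] | None = None) -> FrequencyMap:
    """Cellwise mean over subjects, each subject weighted equally.

    ``subject_maps`` is keyed by subject id (duplicates are impossible by
    construction of the dict; passing a list would not be). Metadata
    records n_s (subjects) and, when supplied, n_v (visits).
    """
    if not subject_maps:
        raise ValueError("no subject maps")
    maps = list(subject_maps.values())
    _check_axes(maps)
    first = maps[0]
    values = np.mean([m.values for m in maps], axis=0)
    meta = {"n_s": len(subject_maps)}
    if n_visits is not None:
        meta["n_v"] = sum(n_visits.get(s, 1) for s in subject_maps)
    return FrequencyMap(
        channel_labels=list(first.channel_labels), points_ms=first.points_ms,
        values=values, level="group", axis_kind=first.axis_kind,
        chance_level=first.chance_level, metadata=meta,
    )


def categorize_visit(behavioural_class: str, eeg_cf: str, fmri_cf: str) -> dict:
    """Per-visit evidence flags (the figures also count visits)."""
    if behavioural_class not in BEHAVIOURAL_CLASSES:
        raise ValueError(f"unknown behavioural class {behavioural_class!r}")
    cf = eeg_cf == "pos" or fmri_cf == "pos"
    behavioural = behavioural_class in BEHAVIOURAL_CF_CLASSES
    return {
        "behavioural_class": behavioural_class,
        "cf": cf,
        "lp": cf or behavioural,
        "behavioural_cf": behavioural,
    }


def categorize_subject(visits: pd.DataFrame) -> CategoryAssignment:
    """Apply the decision tree to all of one subject's visits.

    Any-visit evidence counts: a single positive motor-imagery result or a
    single MCS+/eMCS classification at any visit makes the subject CF+ or
    LP+ respectively.
    """
    if len(visits) == 0:
        raise ValueError("subject has no visit rows")
    ids = visits.subject_id.unique()
    if len(ids) != 1:
        raise ValueError(f"expected one subject, got {list(ids)}")
    per_visit = {
        int(row.visit_index): categorize_visit(row.behavioural_class,
                                               row.eeg_cf, row.fmri_cf)
        for row in visits.itertuples()
    }
    basis = []
    if (visits.eeg_cf == "pos").any():
        basis.append("EEG")
    if (visits.fmri_cf == "pos").any():
        basis.append("fMRI")
    cf = bool(basis)
    if visits.behavioural_class.isin(BEHAVIOURAL_CF_CLASSES).any():
        basis.append("behavioural")
    lp = bool(basis)
    return CategoryAssignment(
        subject_id=str(ids[0]),
        cf_status="CF+" if cf else "CF-",
        lp_status="LP+" if lp else "LP-",
        basis=basis,
        visit_labels=per_visit,
    )


def count_categories(metadata: pd.DataFrame) -> dict:
    """Tallies per category and behavioural class, at subject and visit level.

    Subject level uses any-visit evidence; visit level classifies each
    visit on its own row. Healthy controls are tallied separately and do
    not enter the patient categories.
    """
    counts = {
        "subjects": {"CF+": 0, "CF-": 0, "LP+": 0, "LP-": 0, "HC": 0},
        "visits": {"CF+": 0, "CF-": 0, "LP+": 0, "LP-": 0, "HC": 0},
        "behavioural_subjects": {c: 0 for c in BEHAVIOURAL_CLASSES},
        "behavioural_visits": {c: 0 for c in BEHAVIOURAL_CLASSES},
        "assignments": {},
    }
    if len(metadata) == 0:
        return counts
    for sid, visits in metadata.groupby("subject_id", sort=True):
        if (visits.behavioural_class == "HC").all():
            counts["subjects"]["HC"] += 1
            counts["visits"]["HC"] += len(visits)
            counts["behavioural_subjects"]["HC"] += 1
            counts["behavioural_visits"]["HC"] += len(visits)
            continue
        assignment = categorize_subject(visits)
        counts["assignments"][sid] = assignment
        counts["subjects"][assignment.cf_status] += 1
        counts["subjects"][assignment.lp_status] += 1
        for flags in assignment.visit_labels.values():
            counts["visits"]["CF+" if flags["cf"] else "CF-"] += 1
            counts["visits"]["LP+" if flags["lp"] else "LP-"] += 1
            counts["behavioural_visits"][flags["behavioural_class"]] += 1
        classes = visits.behavioural_class.unique()
        for c in classes:
            counts["behavioural_subjects"][c] += 1
    return counts


def group_maps_by_category(subject_maps: dict[str, FrequencyMap],
                           metadata: pd.DataFrame,
                           n_visits: dict[str, int] | None = None,
                           ) -> dict[str, FrequencyMap]:
    """Group-level maps for behavioural classes and CF/LP categories.

    ``subject_maps`` holds one trial-averaged map per subject. Every
    subject present in the maps must appear in the metadata.
    """
    known = set(metadata.subject_id)
    missing = sorted(set(subject_maps) - known)
    if missing:
        raise ValueError(f"subjects missing from metadata: {missing}")
    groups: dict[str, dict[str, FrequencyMap]] = {}

    def add(group: str, sid: str) -> None:
        groups.setdefault(group, {})[sid] = subject_maps[sid]

    for sid, fmap in subject_maps.items():
        visits = metadata[metadata.subject_id == sid]
        if (visits.behavioural_class == "HC").all():
            add("HC", sid)
            continue
        for cls in visits.behavioural_class.unique():
            add(cls, sid)
        assignment = categorize_subject(visits)
        if assignment.cf_status == "CF+":
            add("CF+", sid)
        add(assignment.lp_status, sid)
    return {
        group: combine_subjects(members, n_visits)
        for group, members in sorted(groups.items())
    }
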