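"""Glue from subjects and windows to rectangular feature tables.

A feature table is a pandas DataFrame with one row per window: feature
columns plus ``subject_id``, ``center_s``, ``arousal`` and ``valence``.
Tables from the three extractors share this format, so the evaluation
module is agnostic to where the features came from.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .eda import traditional_feature_vector
from .graph import DEFAULT_Q, graph_from_window
from .graph_features import edagraph_feature_vector
from .preprocess import Window, make_windows
from .synthetic import SyntheticSubject

__all__ = [
    "windows_for_subject",
    "graph_feature_table",
    "traditional_feature_table",
    "feature_table",
]


def windows_for_subject(
    subject: SyntheticSubject,
    win_len_s: float = 60.0,
    overlap: float = 0.5,
    label_mode: str = "center",
) -> list[Window]:
    return make_windows(
        subject.channels,
        subject.annotations,
        win_len_s=win_len_s,
        overlap=overlap,
        subject_id=subject.subject_id,
        label_mode=label_mode,
    )


def _meta(w: Window) -> dict:
    return {
        "subject_id": w.subject_id,
        "center_s": w.center_s,
        "arousal": w.arousal,
        "valence": w.valence,
    }


def graph_feature_table(
    subjects: Iterable[SyntheticSubject],
    Q: float = DEFAULT_Q,
    k: int | None = None,
    win_len_s: float = 60.0,
    overlap: float = 0.5,
    label_mode: str = "center",
) -> pd.DataFrame:
    """EDA-graph features (frozen 66-name manifest) for every window of
    every subject."""
    rows = []
    for s in subjects:
        for w in windows_for_subject(s, win_len_s, overlap, label_mode):
            g = graph_from_window(w.series("eda"), Q=Q, k=k)
            rows.append({**edagraph_feature_vector(g), **_meta(w)})
    return pd.DataFrame(rows)


def traditional_feature_table(
    subjects: Iterable[SyntheticSubject],
    win_len_s: float = 60.0,
    overlap: float = 0.5,
    label_mode: str = "center",
) -> pd.DataFrame:
    """Traditional 19-feature EDA battery for every window."""
    rows = []
    for s in subjects:
        for w in windows_for_subject(s, win_len_s, overlap, label_mode):
            rows.append({**traditional_feature_vector(w.series("eda")), **_meta(w)})
    return pd.DataFrame(rows)


def feature_table(subjects: Sequence[SyntheticSubject], modality: str = "edagraph",
                  **kwargs) -> pd.DataFrame:
    """Dispatch on modality: ``edagraph``, ``traditional`` or ``combined``
    (both extractors, columns concatenated)."""
    if modality == "edagraph":
        return graph_feature_table(subjects, **kwargs)
    if modality == "traditional":
        return traditional_feature_table(subjects, **kwargs)
    if modality == "combined":
        g = graph_feature_table(subjects, **kwargs)
        t = traditional_feature_table(subjects)
        meta = ["subject_id", "center_s", "arousal", "valence"]
        return pd.concat([g.drop(columns=meta), t], axis=1)
    raise ValueError(f"unknown modality {modality!r}")
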