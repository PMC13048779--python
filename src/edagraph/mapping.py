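"""Continuous-to-class affect mapping.

Continuous (arousal, valence) predictions on the 0.5-9.5 rating scale are
mapped to the discrete label sets of three evaluation settings with a fixed
midpoint threshold θ = 5.0:

* MED scheme — positive / negative / mixed emotion;
* DEAP scheme — Relaxed / Amused / Bored / Scared / Neutral, after an affine
  rescale of the 0.5-9.5 scale onto DEAP's 1-9 scale (midpoints aligned) and
  with the Neutral band (within one unit of the scale center) checked first;
* stress scheme — Stress / NoStress from arousal alone.

Boundary semantics follow the printed inequalities exactly (>= θ vs < θ).
Also provides multi-class classification metrics and a θ-sensitivity probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "THETA",
    "AffectLabel",
    "ClassDecision",
    "map_med",
    "map_deap",
    "map_stress",
    "rescale_case_to_deap",
    "classification_metrics",
    "theta_sensitivity",
]

#: Scale-midpoint classification threshold, fixed a priori.
THETA = 5.0

SCHEME_CLASSES = {
    "MED": ("positive", "negative", "mixed"),
    "DEAP": ("Relaxed", "Amused", "Bored", "Scared", "Neutral"),
    "STRESS": ("Stress", "NoStress"),
}


@dataclass(frozen=True)
class AffectLabel:
    """A continuous (arousal, valence) pair, clipped to the rating scale."""

    arousal: float
    valence: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "arousal", float(np.clip(self.arousal, 0.5, 9.5)))
        object.__setattr__(self, "valence", float(np.clip(self.valence, 0.5, 9.5)))


@dataclass(frozen=True)
class ClassDecision:
    scheme: str
    label: str
    arousal: float
    valence: float

    def __post_init__(self) -> None:
        if self.label not in SCHEME_CLASSES[self.scheme]:
            raise ValueError(f"{self.label!r} not a {self.scheme} class")


def map_med(label: AffectLabel, theta: float = THETA) -> ClassDecision:
    """MED rule: negative iff valence < θ; positive iff arousal < θ and
    valence >= θ; mixed iff both >= θ."""
    if label.valence < theta:
        cls = "negative"
    elif label.arousal < theta:
        cls = "positive"
    else:
        cls = "mixed"
    return ClassDecision("MED", cls, label.arousal, label.valence)


def rescale_case_to_deap(value: float) -> float:
    """Affine map of the 0.5-9.5 rating scale onto DEAP's 1-9 scale; the
    midpoints (5.0) coincide and ordering is preserved."""
    v = float(np.clip(value, 0.5, 9.5))
    return 1.0 + (v - 0.5) * 8.0 / 9.0


def map_deap(label: AffectLabel, theta: float = THETA,
             neutral_halfwidth: float = 1.0, rescale: bool = True) -> ClassDecision:
    """DEAP rule: Neutral when both dimensions lie within one unit of the
    scale center (evaluated before the quadrant split), else Relaxed
    (A < θ, V >= θ), Amused (A >= θ, V >= θ), Bored (A < θ, V < θ), or
    Scared (A >= θ, V < θ). Inputs on the 0.5-9.5 scale are rescaled to 1-9
    first unless ``rescale=False``."""
    a = rescale_case_to_deap(label.arousal) if rescale else label.arousal
    v = rescale_case_to_deap(label.valence) if rescale else label.valence
    if abs(a - 5.0) < neutral_halfwidth and abs(v - 5.0) < neutral_halfwidth:
        cls = "Neutral"
    elif a < theta and v >= theta:
        cls = "Relaxed"
    elif a >= theta and v >= theta:
        cls = "Amused"
    elif a < theta and v < theta:
        cls = "Bored"
    else:
        cls = "Scared"
    return ClassDecision("DEAP", cls, a, v)


def map_stress(label: AffectLabel, theta: float = THETA) -> ClassDecision:
    """Stress rule: Stress iff arousal >= θ (elevated activation)."""
    cls = "Stress" if label.arousal >= theta else "NoStress"
    return ClassDecision("STRESS", cls, label.arousal, label.valence)


_MAPPERS = {"MED": map_med, "DEAP": map_deap, "STRESS": map_stress}


def map_labels(scheme: str, labels: Sequence[AffectLabel], **kwargs) -> list[str]:
    """Vector form: class names for a sequence of labels under one scheme."""
    mapper = _MAPPERS[scheme.upper()]
    return [mapper(lab, **kwargs).label for lab in labels]


def classification_metrics(
    true_classes: Sequence[str], predicted_classes: Sequence[str]
) -> dict:
    """Accuracy plus per-class and macro precision/recall/F1.

    Classes absent from the truth get NaN precision/recall/F1 (flagged in
    ``unseen_predictions`` when they appear in the predictions); macro
    averages run over classes present in the truth.
    """
    t = list(true_classes)
    p = list(predicted_classes)
    if len(t) != len(p):
        raise ValueError("class sequences must have equal length")
    classes = sorted(set(t))
    unseen = sorted(set(p) - set(t))
    accuracy = float(np.mean([a == b for a, b in zip(t, p)])) if t else math.nan
    per_class = {}
    for c in classes:
        tp = sum(1 for a, b in zip(t, p) if a == c and b == c)
        fp = sum(1 for a, b in zip(t, p) if a != c and b == c)
        fn = sum(1 for a, b in zip(t, p) if a == c and b != c)
        prec = tp / (tp + fp) if tp + fp else math.nan
        rec = tp / (tp + fn) if tp + fn else math.nan
        if not math.isnan(prec) and not math.isnan(rec) and prec + rec > 0:
            f1 = 2 * prec * rec / (prec + rec)
        elif prec == 0 or rec == 0:
            f1 = 0.0
        else:
            f1 = math.nan
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1}
    macro = {
        m: float(np.nanmean([per_class[c][m] for c in classes])) if classes else math.nan
        for m in ("precision", "recall", "f1")
    }
    return {"accuracy": accuracy, "per_class": per_class, "macro": macro,
            "unseen_predictions": unseen}


def theta_sensitivity(
    labels: Sequence[AffectLabel],
    true_classes: Sequence[str],
    scheme: str,
    deltas: Sequence[float] = (-0.5, 0.5),
    **kwargs,
) -> dict[float, float]:
    """Absolute accuracy change when the threshold moves by each delta.

    Re-maps every label at θ + δ against the supplied ground-truth classes;
    δ = 0 gives a change of exactly zero by construction.
    """
    base_acc = classification_metrics(
        true_classes, map_labels(scheme, labels, **kwargs))["accuracy"]
    out = {}
    for d in deltas:
        acc = classification_metrics(
            true_classes, map_labels(scheme, labels, theta=THETA + d, **kwargs)
        )["accuracy"]
        out[d] = abs(acc - base_acc)
    return out
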