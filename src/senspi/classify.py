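"""Sensitivity / resilience classification against prediction intervals.

A subject whose observed trait lies beyond their personal conditional
prediction interval in the adverse direction is "sensitive"; beyond it in the
protective direction, "resilient"; inside, "neutral". Two labelling modes are
supported: single-visit (one examination, MDCS-style) and persistent
(identical classification at two examinations ~10 years apart, VHU-style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SensitivityLabel",
    "classify_observation",
    "classify_batch",
    "persistence_label",
    "label_cohort",
    "DEFAULT_ADVERSE_DIRECTIONS",
]

LABELS = ("sensitive", "resilient", "neutral")

#: Higher values are adverse for every cardiometabolic trait except HDL-C.
DEFAULT_ADVERSE_DIRECTIONS = {
    "bmi": "high", "sbp": "high", "dbp": "high", "tc": "high", "tg": "high",
    "ldl": "high", "fg": "high", "2hg": "high", "hdl": "low", "trait": "high",
}


@dataclass(frozen=True)
class SensitivityLabel:
    subject_id: object
    trait: str
    label: str
    mode: str  # single_visit | persistent


def classify_observation(observed, pi, adverse_direction: str = "high"):
    """Label one observation against its prediction interval.

    adverse_direction="high": above the upper bound -> sensitive, below the
    lower bound -> resilient, inside -> neutral. For traits where low values
    are adverse (HDL-C) the mapping is mirrored. Boundary equality counts as
    inside (the interval is closed). A missing observation returns None.
    """
    if adverse_direction not in ("high", "low"):
        raise ValueError("adverse_direction must be 'high' or 'low'")
    if observed is None or (isinstance(observed, float) and np.isnan(observed)):
        return None
    lower, upper = (pi.lower, pi.upper) if hasattr(pi, "lower") else (pi[0], pi[1])
    if observed > upper:
        return "sensitive" if adverse_direction == "high" else "resilient"
    if observed < lower:
        return "resilient" if adverse_direction == "high" else "sensitive"
    return "neutral"


def classify_batch(observed, intervals, adverse_direction: str = "high") -> np.ndarray:
    """Vectorized labels for an (n,) observation vector and (n, 2) intervals.

    Missing observations get the label None.
    """
    if adverse_direction not in ("high", "low"):
        raise ValueError("adverse_direction must be 'high' or 'low'")
    observed = np.asarray(observed, dtype=float)
    intervals = np.asarray(intervals, dtype=float)
    above = observed > intervals[:, 1]
    below = observed < intervals[:, 0]
    hi, lo = ("sensitive", "resilient") if adverse_direction == "high" else ("resilient", "sensitive")
    out = np.where(above, hi, np.where(below, lo, "neutral")).astype(object)
    out[np.isnan(observed)] = None
    return out


def persistence_label(label_visit1, label_visit2):
    """Persistent label over two examinations.

    The common label when both visits agree; any discordant pair is neutral
    (the strictest reading of persistence). Either visit unlabeled -> None.
    """
    if label_visit1 is None or label_visit2 is None:
        return None
    return label_visit1 if label_visit1 == label_visit2 else "neutral"


def label_cohort(
    subject_ids,
    observed_by_visit: dict[int, np.ndarray],
    intervals_by_visit: dict[int, np.ndarray],
    trait: str,
    adverse_direction: str = "high",
    mode: str = "persistent",
) -> pd.DataFrame:
    """Label table (subject_id, trait, mode, label) for one trait.

    mode="persistent" requires visits 1 and 2 in the inputs and applies
    :func:`persistence_label`; mode="single_visit" uses visit 1 only.
    """
    if mode not in ("persistent", "single_visit"):
        raise ValueError("mode must be 'persistent' or 'single_visit'")
    l1 = classify_batch(observed_by_visit[1], intervals_by_visit[1], adverse_direction)
    if mode == "single_visit":
        labels = l1
    else:
        l2 = classify_batch(observed_by_visit[2], intervals_by_visit[2], adverse_direction)
        labels = np.array([persistence_label(a, b) for a, b in zip(l1, l2)], dtype=object)
    return pd.DataFrame(
        {"subject_id": subject_ids, "trait": trait, "mode": mode, "label": labels}
    )
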