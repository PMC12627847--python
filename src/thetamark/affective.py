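"""Affective-task scoring: the behavioural predictors.

Patients rate positive, neutral and negative images on 0–100 visual
analog scales for valence and arousal.  Two summary scores are derived:
the neutral-controlled score (mean target-condition rating minus mean
neutral rating) and the negative emotional bias
(mean(positive) − mean(negative)) / mean(neutral), conventionally
computed on the arousal dimension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["neutral_controlled", "negative_emotional_bias", "score_patients"]

_CONDITIONS = ("positive", "neutral", "negative")


def _cell_mean(ratings: pd.DataFrame, condition: str, dimension: str) -> float:
    cell = ratings.loc[
        (ratings["condition"] == condition)
        & (ratings["dimension"] == dimension), "rating"
    ]
    if cell.empty:
        raise ValueError(f"empty rating cell ({condition}, {dimension})")
    vals = cell.to_numpy(float)
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("ratings must lie in [0, 100]")
    return float(vals.mean())


def neutral_controlled(ratings: pd.DataFrame, dimension: str,
                       target: str = "negative") -> float:
    """Neutral-controlled rating: mean(target) − mean(neutral).

    A difference of means rather than a ratio, which is unstable when the
    neutral mean is small.
    """
    return _cell_mean(ratings, target, dimension) - _cell_mean(
        ratings, "neutral", dimension)


def negative_emotional_bias(ratings: pd.DataFrame,
                            dimension: str = "arousal") -> float:
    """Negative emotional bias: (mean(pos) − mean(neg)) / mean(neutral).

    The score *rises* when positive images are rated more arousing than
    negative ones; "lower negative bias" in clinical shorthand means lower
    arousal to negative relative to positive images, i.e. this score read
    with the printed formula's sign.
    """
    means = {c: _cell_mean(ratings, c, dimension) for c in _CONDITIONS}
    if means["neutral"] == 0:
        raise ValueError("mean neutral rating is zero; bias undefined")
    return (means["positive"] - means["negative"]) / means["neutral"]


def score_patients(ratings_by_patient: dict) -> pd.DataFrame:
    """Per-patient behavioural score table from trial-level rating tables.

    ``ratings_by_patient``: patient id -> trial DataFrame.  Returns one
    row per patient with the bias score and the four neutral-controlled
    scores.
    """
    rows = []
    for pid, tbl in ratings_by_patient.items():
        rows.append({
            "patient_id": pid,
            "negative_bias": negative_emotional_bias(tbl),
            "nc_negative_arousal": neutral_controlled(tbl, "arousal", "negative"),
            "nc_positive_arousal": neutral_controlled(tbl, "arousal", "positive"),
            "nc_negative_valence": neutral_controlled(tbl, "valence", "negative"),
            "nc_positive_valence": neutral_controlled(tbl, "valence", "positive"),
        })
    return pd.DataFrame(rows)
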