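"""Pathway-sharing benchmark of the fused similarity score.

A metabolite and a drug that share at least one disease-related pathway are
taken to hold a similar function (positive); pairs where both entities are
annotated but share no disease-related pathway are negatives; pairs where
either entity has no annotation record are unlabeled and excluded from
precision.  Precision above a score threshold is then
``positives / (positives + negatives)`` over the labeled pairs passing the
threshold, reported with its counts so the ``k/n`` form is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class PathwayAnnotation:
    """Pathway membership of one entity, with the disease-related subset."""

    entity_id: str
    pathways: frozenset[str]
    disease_related: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.disease_related <= self.pathways:
            raise ValueError(
                f"{self.entity_id}: disease_related must be a subset of pathways"
            )


def label_pairs(
    pairs: pd.DataFrame, annotations: Mapping[str, PathwayAnnotation]
) -> pd.DataFrame:
    """Attach a benchmark label column to a scored pair table.

    positive — both entities annotated and sharing >=1 disease-related
    pathway; negative — both annotated, sharing none; unlabeled — either
    entity missing from the annotation set.  Labelling is total: every row
    receives exactly one label.
    """
    labels = []
    for m, d in zip(pairs["metabolite_id"], pairs["drug_id"]):
        am, ad = annotations.get(m), annotations.get(d)
        if am is None or ad is None:
            labels.append(UNLABELED)
        elif am.disease_related & ad.disease_related:
            labels.append(POSITIVE)
        else:
            labels.append(NEGATIVE)
    out = pairs.copy()
    out["label"] = labels
    return out


def precision_above(
    labeled: pd.DataFrame, threshold: float, inclusive: bool = False
) -> tuple[Optional[float], int, int]:
    """Precision over labeled pairs scoring above a threshold.

    ``inclusive=False`` (default) means strictly ``score > threshold``;
    flip to count ``score >= threshold``.  Returns
    ``(precision, n_positive, n_scored)`` with precision ``None`` when no
    labeled pair passes the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    lab = labeled[labeled["label"] != UNLABELED]
    passed = lab[lab["score"] >= threshold] if inclusive else lab[lab["score"] > threshold]
    n_scored = len(passed)
    n_pos = int((passed["label"] == POSITIVE).sum())
    if n_scored == 0:
        return None, 0, 0
    return n_pos / n_scored, n_pos, n_scored


def precision_curve(
    labeled: pd.DataFrame,
    thresholds: Sequence[float] = (0.9, 0.8, 0.7, 0.6),
    inclusive: bool = False,
) -> pd.DataFrame:
    """Precision at a descending ladder of score thresholds.

    One row per threshold; the ``one_minus_threshold`` column matches the
    convention of plotting precision against 1 − score.  Thresholds must be
    sorted descending so the scored slices are cumulative down the table.
    """
    thresholds = list(thresholds)
    if any(a <= b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted strictly descending")
    rows = []
    for t in thresholds:
        p, n_pos, n_scored = precision_above(labeled, t, inclusive=inclusive)
        rows.append((t, 1.0 - t, np.nan if p is None else p, n_pos, n_scored))
    return pd.DataFrame(
        rows,
        columns=["threshold", "one_minus_threshold", "precision",
                 "n_positive", "n_scored"],
    )


def label_counts(labeled: pd.DataFrame) -> dict[str, int]:
    """Counts of positive / negative / unlabeled rows (they partition the table)."""
    vc = labeled["label"].value_counts()
    return {k: int(vc.get(k, 0)) for k in (POSITIVE, NEGATIVE, UNLABELED)}
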