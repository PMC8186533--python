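"""Greedy backward input-ablation feature importance.

Starting from a trained network, each round evaluates the model with every
remaining kinematic input individually masked (fixed to 0 — the
standardized mean, weight-equivalent to severing the neuron at its expected
value; no retraining), permanently removes the one whose removal hurts
accuracy least, and records accuracy/sensitivity/specificity. Subtest
indicator inputs are never masked. The result is an importance ordering
(least important removed first) and a metrics-vs-retained-features curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MaskError
from .features import ALL_FEATURES, KINEMATIC_FEATURES
from .mlp import Metrics, TrainedModel, evaluate

logger = logging.getLogger(__name__)

_KIN_INDEX = {f: i for i, f in enumerate(KINEMATIC_FEATURES)}


def masked_metrics(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    masked: set[str] | frozenset[str],
) -> Metrics:
    """Evaluate with the given kinematic inputs fixed to 0 (no retraining).

    ``X`` must already be standardized with the model's scaler. Masking a
    subtest indicator (or an unknown name) raises :class:`MaskError`.
    """
    bad = set(masked) - set(KINEMATIC_FEATURES)
    if bad:
        raise MaskError(f"only kinematic features may be masked, got {sorted(bad)}")
    Xm = np.array(X, dtype=float, copy=True)
    for f in masked:
        Xm[:, _KIN_INDEX[f]] = 0.0
    return evaluate(model, Xm, y)


@dataclass
class AblationCurve:
    """Removal order plus metrics for every retained-feature count 12..1.

    ``metrics_by_retained_count[r]`` holds the metrics of the model with the
    ``12 - r`` least important features masked; ``r = 12`` is the unmasked
    baseline. ``all_masked_metrics`` (all 12 masked, indicators only) is kept
    as an extra diagnostic beyond the 12 curve records.
    """

    removal_order: list[str]
    metrics_by_retained_count: dict[int, Metrics]
    all_masked_metrics: Metrics

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(len(KINEMATIC_FEATURES), 0, -1):
            m = self.metrics_by_retained_count[r]
            removed = (
                "" if r == len(KINEMATIC_FEATURES)
                else self.removal_order[len(KINEMATIC_FEATURES) - r - 1]
            )
            rows.append(
                {
                    "retained_count": r,
                    "removed_feature": removed,
                    "accuracy": m.accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                }
            )
        return pd.DataFrame(rows)


def backward_elimination(
    model: TrainedModel, X: np.ndarray, y: np.ndarray
) -> AblationCurve:
    """Greedy least-impact-first removal of all 12 kinematic inputs.

    At each round the candidate whose masking yields the *highest* resulting
    accuracy is removed permanently (ties: higher resulting sensitivity,
    then earlier fixed column order). Metrics are recorded for every
    retained count from 12 (no mask) down to 1; the all-masked evaluation is
    stored separately.
    """
    baseline = masked_metrics(model, X, y, frozenset())
    remaining = list(KINEMATIC_FEATURES)
    mask: set[str] = set()
    removal_order: list[str] = []
    by_count: dict[int, Metrics] = {len(KINEMATIC_FEATURES): baseline}
    last: Metrics = baseline

    while remaining:
        best_feat: str | None = None
        best_key: tuple[float, float, int] | None = None
        best_metrics: Metrics | None = None
        for pos, f in enumerate(remaining):  # fixed column order
            m = masked_metrics(model, X, y, mask | {f})
            key = (m.accuracy, m.sensitivity, -pos)
            if best_key is None or key > best_key:
                best_key, best_feat, best_metrics = key, f, m
        assert best_feat is not None and best_metrics is not None
        mask.add(best_feat)
        remaining.remove(best_feat)
        removal_order.append(best_feat)
        retained = len(remaining)
        if retained >= 1:
            by_count[retained] = best_metrics
        last = best_metrics
        logger.info(
            "ablation: removed %s (%d retained, accuracy %.4f)",
            best_feat, retained, best_metrics.accuracy,
        )
    return AblationCurve(
        removal_order=removal_order,
        metrics_by_retained_count=by_count,
        all_masked_metrics=last,
    )
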