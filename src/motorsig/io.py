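"""Plain-text serialization: touch logs, feature tables, scaler, model.

Everything is CSV/JSON/YAML so artifacts stay diffable; writers and readers
round-trip losslessly (floats via repr, 17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import TouchLogFormatError
from .features import ALL_FEATURES, FeatureTable, ScalerParams
from .mlp import TrainedModel
from .synthetic import (
    PHASE_MOVE,
    PHASE_PRESS,
    PHASE_RELEASE,
    TouchStream,
)

TOUCH_LOG_COLUMNS = [
    "subject_id", "group", "subtest_id", "item_id", "t", "x", "y", "phase",
]
_VALID_PHASES = {PHASE_PRESS, PHASE_MOVE, PHASE_RELEASE}


def write_touch_log(streams: list[TouchStream], path) -> None:
    """Write touch streams as one CSV row per sample (documented dialect)."""
    frames = []
    for s in streams:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "subtest_id": s.subtest_id,
                    "item_id": s.item_id,
                    "t": [repr(float(v)) for v in s.t],
                    "x": [repr(float(v)) for v in s.x],
                    "y": [repr(float(v)) for v in s.y],
                    "phase": s.phase,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_touch_log(path) -> list[TouchStream]:
    """Parse a touch-log CSV back into TouchStream objects.

    Column order is free (the header names columns); malformed rows raise
    :class:`TouchLogFormatError` with a 1-based file line number.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise TouchLogFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in TOUCH_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TouchLogFormatError(f"missing header column(s): {missing}", line=1)
    streams: list[TouchStream] = []
    for i, phase in enumerate(df["phase"]):
        if phase not in _VALID_PHASES:
            raise TouchLogFormatError(
                f"invalid phase {phase!r} at line {i + 2}", line=i + 2
            )
    for col in ("t", "x", "y"):
        try:
            df[col] = df[col].astype(float)
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise TouchLogFormatError(
                f"non-numeric value in column {col!r} at line {bad + 2}",
                line=int(bad) + 2,
            ) from None
    for col in ("subtest_id", "item_id"):
        try:
            df[col] = df[col].astype(int)
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise TouchLogFormatError(
                f"non-integer value in column {col!r} at line {bad + 2}",
                line=int(bad) + 2,
            ) from None
    key_cols = ["subject_id", "group", "subtest_id", "item_id"]
    for key, sub in df.groupby(key_cols, sort=False):
        streams.append(
            TouchStream(
                subject_id=str(key[0]),
                group=str(key[1]),
                subtest_id=int(key[2]),
                item_id=int(key[3]),
                t=sub["t"].to_numpy(),
                x=sub["x"].to_numpy(),
                y=sub["y"].to_numpy(),
                phase=sub["phase"].to_numpy(dtype="<U7"),
            )
        )
    return streams


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.df.copy()
    for c in ALL_FEATURES:
        df[c] = [repr(float(v)) for v in df[c]]
    df.to_csv(path, index=False)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, dtype={"subject_id": str, "label": str})
    for c in ALL_FEATURES:
        df[c] = df[c].astype(float)
    return FeatureTable(df)


def write_scaler(params: ScalerParams, path) -> None:
    """Scaler as a flat YAML key-value file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def read_scaler(path) -> ScalerParams:
    with open(path, "r", encoding="utf-8") as fh:
        return ScalerParams.from_dict(yaml.safe_load(fh))


def write_model(model: TrainedModel, path) -> None:
    """Model weights (+ scaler if attached) as a JSON text container."""
    payload = {"weights": model.weights_dict()}
    if model.scaler is not None:
        payload["scaler"] = model.scaler.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_model(path) -> TrainedModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    scaler = (
        ScalerParams.from_dict(payload["scaler"]) if "scaler" in payload else None
    )
    return TrainedModel.from_weights_dict(payload["weights"], scaler=scaler)


def write_roc(metrics, path) -> None:
    pd.DataFrame({"fpr": metrics.roc_fpr, "tpr": metrics.roc_tpr}).to_csv(
        path, index=False
    )


def write_training_trace(trace: np.ndarray, path) -> None:
    pd.DataFrame(
        {"epoch": np.arange(1, len(trace) + 1), "mean_test_accuracy": trace}
    ).to_csv(path, index=False)
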