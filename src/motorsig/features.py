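"""Kinematic feature extraction and dataset assembly.

Twelve per-task kinematic features are computed from finite trajectories:

======================  =====================================================
MeanSpeed               mean of all step speeds pooled across the task
MaxSpeed / MinSpeed     mean over trajectories of each bout's speed extremum
sdSpeed                 sample SD of all pooled step speeds
MeanAcceleration        mean of all signed step accelerations (pooled)
MaxAcceleration /
MinAcceleration         mean over trajectories of each bout's extremum
sdAcceleration          sample SD of pooled accelerations
STH                     mean per-bout straightness (net displacement / path)
DC / sdDC               mean and sample SD of pooled directional change
                        (|heading change| per second, wrapped to (-pi, pi])
MeanLength              mean per-bout path length
======================  =====================================================

Discrete conventions: forward differences; speed_i = |p_{i+1}-p_i| / dt_i;
acceleration is the signed derivative of scalar speed; zero-length steps get
speed 0 and propagate the previous heading. Sample SD (n-1 denominator) is
used everywhere, including the standardizer. Bouts too short to define a
feature are excluded from that feature's aggregation only (no zero-filling).

Five subtest indicator columns (exactly one set to 1) complete the
17-dimensional model input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConflictingLabelError,
    ConstantColumnError,
    TaskSkippedError,
    TimestampOrderError,
)
from .synthetic import SUBTEST_CODES
from .trajectories import Trajectory

logger = logging.getLogger(__name__)

KINEMATIC_FEATURES = (
    "MeanSpeed",
    "MaxSpeed",
    "MinSpeed",
    "sdSpeed",
    "MeanAcceleration",
    "MaxAcceleration",
    "MinAcceleration",
    "sdAcceleration",
    "STH",
    "DC",
    "sdDC",
    "MeanLength",
)
INDICATOR_FEATURES = tuple(f"task_{SUBTEST_CODES[s]}" for s in range(1, 6))
ALL_FEATURES = KINEMATIC_FEATURES + INDICATOR_FEATURES

#: integer encoding used throughout the classifier
LABEL_CODES = {"ASD": 0, "TD": 1}


def _wrap_angles(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi] elementwise."""
    w = np.mod(a + np.pi, 2.0 * np.pi)
    w[w <= 0.0] += 2.0 * np.pi
    return w - np.pi


@dataclass(frozen=True)
class StepKinematics:
    """Per-step derivative series of one trajectory."""

    speed: np.ndarray               # units/s, length n-1
    acceleration: np.ndarray        # units/s^2, signed, length n-2
    heading: np.ndarray             # radians, length n-1
    directional_change: np.ndarray  # radians/s, absolute, length n-2
    path_length: float
    net_displacement: float


def step_kinematics(traj: Trajectory) -> StepKinematics:
    """Compute speed/acceleration/heading/directional-change series.

    Requires >= 2 points; duplicate timestamps raise
    :class:`TimestampOrderError` (they would divide by zero).
    """
    if len(traj) < 2:
        raise TaskSkippedError("trajectory has fewer than 2 points")
    dt = np.diff(traj.t)
    if np.any(dt <= 0):
        raise TimestampOrderError("duplicate or decreasing timestamps")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    dist = np.hypot(dx, dy)
    speed = dist / dt
    acceleration = np.diff(speed) / dt[:-1]

    heading = np.arctan2(dy, dx)
    zero = dist == 0.0
    if np.any(zero):
        # zero-length step: no direction — propagate the previous heading
        # (0.0 if the very first steps are degenerate)
        heading = heading.copy()
        heading[zero] = np.nan
        heading[0] = 0.0 if np.isnan(heading[0]) else heading[0]
        filled = pd.Series(heading).ffill().to_numpy()
        heading = filled
    dc = np.abs(_wrap_angles(np.diff(heading))) / dt[:-1]

    path_length = float(np.sum(dist))
    net = float(math.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))
    return StepKinematics(
        speed=speed,
        acceleration=acceleration,
        heading=heading,
        directional_change=dc,
        path_length=path_length,
        net_displacement=min(net, path_length),
    )


def straightness_index(traj: Trajectory) -> float | None:
    """Net displacement over path length, in [0, 1]; ``None`` if undefined.

    1.0 for a straight monotone path, 0.0 for a closed loop, ``None`` when
    the path length is zero (a stationary touch has no direction).
    """
    kin = step_kinematics(traj)
    if kin.path_length == 0.0:
        return None
    return min(1.0, kin.net_displacement / kin.path_length)


def directional_change_stats(traj: Trajectory) -> tuple[float, float] | None:
    """Mean and sample SD of the directional-change series (radians/s).

    Needs >= 3 points; returns ``None`` when undefined. A single-element
    series has SD 0.0 by convention (one heading change, no spread).
    """
    if len(traj) < 3:
        return None
    dc = step_kinematics(traj).directional_change
    sd = float(np.std(dc, ddof=1)) if len(dc) > 1 else 0.0
    return float(np.mean(dc)), sd


@dataclass(frozen=True)
class TaskFeatureVector:
    """12 kinematic features + subtest identity + label for one task."""

    subject_id: str
    label: str
    subtest_id: int
    item_id: int
    kinematics: dict[str, float]
    n_trajectories: int = 0  # auxiliary diagnostic, not a model input

    def __post_init__(self) -> None:
        missing = [f for f in KINEMATIC_FEATURES if f not in self.kinematics]
        if missing:
            raise TaskSkippedError(f"missing kinematic features: {missing}")
        if self.label not in LABEL_CODES:
            raise ConflictingLabelError(f"unknown label {self.label!r}")

    @property
    def indicator(self) -> np.ndarray:
        ind = np.zeros(5)
        ind[self.subtest_id - 1] = 1.0
        return ind

    def values(self) -> np.ndarray:
        """The 17 model inputs in fixed column order."""
        kin = np.array([self.kinematics[f] for f in KINEMATIC_FEATURES])
        return np.concatenate([kin, self.indicator])


def featurize_task(
    trajectories: list[Trajectory],
    subtest_id: int,
    label: str,
    subject_id: str = "",
    item_id: int = 0,
) -> TaskFeatureVector:
    """Aggregate a task's trajectories into one 12-feature sample.

    Pooled-step statistics (MeanSpeed, sdSpeed, MeanAcceleration,
    sdAcceleration, DC, sdDC) merge every step of every bout; extrema
    (Max/MinSpeed, Max/MinAcceleration) average each bout's own peak; STH
    and MeanLength average per-bout values. Bouts lacking the points needed
    for a feature are excluded from that feature only. If any of the 12
    features ends up with no defined value the task is skipped
    (:class:`TaskSkippedError`).
    """
    if not trajectories:
        raise TaskSkippedError("no trajectories in task")
    speeds, accs, dcs = [], [], []
    max_s, min_s, max_a, min_a = [], [], [], []
    sths, lengths = [], []
    for traj in trajectories:
        kin = step_kinematics(traj)
        speeds.append(kin.speed)
        max_s.append(float(np.max(kin.speed)))
        min_s.append(float(np.min(kin.speed)))
        lengths.append(kin.path_length)
        if kin.path_length > 0.0:
            sths.append(min(1.0, kin.net_displacement / kin.path_length))
        if len(kin.acceleration):
            accs.append(kin.acceleration)
            max_a.append(float(np.max(kin.acceleration)))
            min_a.append(float(np.min(kin.acceleration)))
        if len(kin.directional_change):
            dcs.append(kin.directional_change)

    def pooled(parts: list[np.ndarray], what: str) -> np.ndarray:
        if not parts:
            raise TaskSkippedError(f"no defined values for {what}")
        return np.concatenate(parts)

    sp = pooled(speeds, "speed")
    ac = pooled(accs, "acceleration")
    dc = pooled(dcs, "directional change")
    if len(sp) < 2 or len(ac) < 2 or len(dc) < 2:
        raise TaskSkippedError("too few steps for sample-SD features")
    if not sths:
        raise TaskSkippedError("no defined values for STH")

    kinematics = {
        "MeanSpeed": float(np.mean(sp)),
        "MaxSpeed": float(np.mean(max_s)),
        "MinSpeed": float(np.mean(min_s)),
        "sdSpeed": float(np.std(sp, ddof=1)),
        "MeanAcceleration": float(np.mean(ac)),
        "MaxAcceleration": float(np.mean(max_a)),
        "MinAcceleration": float(np.mean(min_a)),
        "sdAcceleration": float(np.std(ac, ddof=1)),
        "STH": float(np.mean(sths)),
        "DC": float(np.mean(dc)),
        "sdDC": float(np.std(dc, ddof=1)),
        "MeanLength": float(np.mean(lengths)),
    }
    return TaskFeatureVector(
        subject_id=subject_id,
        label=label,
        subtest_id=subtest_id,
        item_id=item_id,
        kinematics=kinematics,
        n_trajectories=len(trajectories),
    )


@dataclass
class FeatureTable:
    """Assembled learning dataset: 17 feature columns + label + subject_id."""

    df: pd.DataFrame

    COLUMNS = list(ALL_FEATURES) + ["label", "subject_id"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        self.df = self.df[self.COLUMNS].reset_index(drop=True)
        if self.df[list(ALL_FEATURES)].isna().any().any():
            raise ValueError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[list(ALL_FEATURES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Integer labels: ASD = 0, TD = 1."""
        return self.df["label"].map(LABEL_CODES).to_numpy(dtype=int)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.df.iloc[idx].reset_index(drop=True))


def assemble_dataset(vectors: list[TaskFeatureVector]) -> FeatureTable:
    """Stack task vectors into a :class:`FeatureTable` (fixed column order).

    Raises :class:`ConflictingLabelError` if one subject carries two labels.
    """
    if not vectors:
        raise ValueError("no feature vectors to assemble")
    seen: dict[str, str] = {}
    rows = []
    for v in vectors:
        prev = seen.setdefault(v.subject_id, v.label)
        if prev != v.label:
            raise ConflictingLabelError(
                f"subject {v.subject_id!r} labelled both {prev!r} and {v.label!r}"
            )
        row = dict(zip(ALL_FEATURES, v.values()))
        row["label"] = v.label
        row["subject_id"] = v.subject_id
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature mean/SD for the 12 kinematic columns (indicators excluded)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ConstantColumnError("scaler SD must be strictly positive")

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            f: {"mean": float(m), "sd": float(s)}
            for f, m, s in zip(KINEMATIC_FEATURES, self.mean, self.sd)
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            mean=np.array([d[f]["mean"] for f in KINEMATIC_FEATURES]),
            sd=np.array([d[f]["sd"] for f in KINEMATIC_FEATURES]),
        )


def standardize(
    table: FeatureTable, params: ScalerParams | str = "fit"
) -> tuple[FeatureTable, ScalerParams]:
    """Z-score the 12 kinematic columns; indicators pass through untouched.

    With ``params="fit"`` the mean and sample SD (n-1) are estimated from
    ``table`` and returned for reuse on held-out data; a constant column
    raises :class:`ConstantColumnError` naming it.
    """
    kin = table.df[list(KINEMATIC_FEATURES)].to_numpy(dtype=float)
    if isinstance(params, str):
        if params != "fit":
            raise ValueError(f"params must be ScalerParams or 'fit', got {params!r}")
        mean = kin.mean(axis=0)
        sd = kin.std(axis=0, ddof=1)
        flat = np.flatnonzero(sd <= 0)
        if len(flat):
            names = [KINEMATIC_FEATURES[i] for i in flat]
            raise ConstantColumnError(f"constant feature column(s): {names}")
        params = ScalerParams(mean=mean, sd=sd)
    df = table.df.copy()
    df[list(KINEMATIC_FEATURES)] = (kin - params.mean) / params.sd
    return FeatureTable(df), params
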