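"""Segmentation of raw touch streams into finite trajectories.

A finite trajectory is the contiguous run of samples from a finger press up
to and including the matching release — the unit over which all kinematic
features are computed. No smoothing, resampling or interpolation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    MalformedStreamError,
    NonFiniteCoordinateError,
    TimestampOrderError,
    TooFewPointsError,
)
from .synthetic import PHASE_MOVE, PHASE_PRESS, PHASE_RELEASE, TouchStream

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Trajectory:
    """One finite dragging bout: ordered (t, x, y) points plus parent ids."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    subject_id: str = ""
    group: str = ""
    subtest_id: int = 0
    item_id: int = 0

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SegmentationResult:
    """Trajectories from one stream plus an auditable discard log."""

    trajectories: list[Trajectory]
    n_discarded_episodes: int = 0
    n_discarded_points: int = 0
    n_orphan_moves: int = 0  # move samples outside any press..release episode

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]


def segment_finite_trajectories(
    stream: TouchStream, min_points: int = 2
) -> SegmentationResult:
    """Split a touch stream into press..release episodes.

    Episodes shorter than ``min_points`` are dropped and counted in the
    discard log. Move samples outside any episode are discarded with a
    warning (device noise). A release without a matching press raises
    :class:`MalformedStreamError` naming the sample index.
    """
    trajs: list[Trajectory] = []
    result = SegmentationResult(trajs)
    start: int | None = None
    for i, ph in enumerate(stream.phase):
        if ph == PHASE_PRESS:
            if start is not None:
                raise MalformedStreamError(
                    f"press inside an open episode at sample {i}", sample_index=i
                )
            start = i
        elif ph == PHASE_RELEASE:
            if start is None:
                raise MalformedStreamError(
                    f"release without matching press at sample {i}", sample_index=i
                )
            n = i - start + 1
            if n >= min_points:
                trajs.append(
                    Trajectory(
                        t=np.asarray(stream.t[start : i + 1], dtype=float),
                        x=np.asarray(stream.x[start : i + 1], dtype=float),
                        y=np.asarray(stream.y[start : i + 1], dtype=float),
                        subject_id=stream.subject_id,
                        group=stream.group,
                        subtest_id=stream.subtest_id,
                        item_id=stream.item_id,
                    )
                )
            else:
                result.n_discarded_episodes += 1
                result.n_discarded_points += n
            start = None
        elif ph == PHASE_MOVE:
            if start is None:
                result.n_orphan_moves += 1
        else:
            raise MalformedStreamError(
                f"unknown phase {ph!r} at sample {i}", sample_index=i
            )
    if start is not None:
        raise MalformedStreamError(
            f"stream ends inside an open episode started at sample {start}",
            sample_index=start,
        )
    if result.n_orphan_moves:
        logger.warning(
            "stream %s/%d/%d: %d move samples outside any episode discarded",
            stream.subject_id, stream.subtest_id, stream.item_id,
            result.n_orphan_moves,
        )
    return result


def validate_trajectory(traj: Trajectory) -> Trajectory:
    """Return ``traj`` unchanged if all invariants hold, else raise.

    Raises :class:`TooFewPointsError`, :class:`TimestampOrderError` or
    :class:`NonFiniteCoordinateError` — each condition gets its own type.
    """
    if len(traj) < 2:
        raise TooFewPointsError(f"trajectory has {len(traj)} point(s), need >= 2")
    if np.any(np.diff(traj.t) <= 0):
        raise TimestampOrderError("timestamps not strictly increasing")
    if not (np.all(np.isfinite(traj.x)) and np.all(np.isfinite(traj.y))
            and np.all(np.isfinite(traj.t))):
        raise NonFiniteCoordinateError("non-finite coordinate or timestamp")
    return traj
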