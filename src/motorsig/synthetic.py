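"""Synthetic touch-stream cohorts with planted two-group kinematic contrasts.

The generator emulates a tablet card-dragging study design: 60 subjects
(two equal groups), 5 subtests x 5 items, touch coordinates sampled at
40 Hz on a 1280 x 800 screen (origin top-left, x rightward, y downward,
time in seconds).

The motion model is a goal-attracted correlated walk. Per step::

    heading <- heading + goal_gain * wrap(bearing_to_goal - heading)
                       + Normal(0, heading_noise_sd)
    speed   <- bell(progress) * base_speed * LogNormal(cv=speed_cv)
               + burst state driven by Normal(0, accel_burst_sd) * dt
    step    <- speed / sample_rate, clamped so the target is never overshot

Finger lifts occur as a Poisson process (``fragmentation_rate`` expected
lifts per drag); each lift inserts a ``release`` and a fresh ``press``,
splitting the drag into several finite trajectories downstream.

Latent subject parameters map one-to-one onto the kinematic features the
pipeline extracts, so group contrasts can be planted (default preset) or
switched off entirely (null preset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import numpy as np
import yaml

from .errors import (
    EmptyRosterError,
    GoalUnreachableError,
    IncompleteConfigError,
    UnknownGroupError,
    UnknownPresetError,
)

SCREEN_WIDTH = 1280.0
SCREEN_HEIGHT = 800.0
SAMPLE_RATE = 40.0

GROUPS = ("ASD", "TD")
SUBTEST_CODES = {1: "FG", 2: "FC", 3: "CA", 4: "SO", 5: "VP"}

#: latent parameters every preset must specify for every group
LATENT_PARAMS = (
    "base_speed",
    "speed_cv",
    "heading_noise_sd",
    "goal_gain",
    "fragmentation_rate",
    "accel_burst_sd",
)

PHASE_PRESS = "press"
PHASE_MOVE = "move"
PHASE_RELEASE = "release"


def _wrap_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    a = math.fmod(a + math.pi, 2.0 * math.pi)
    if a <= 0.0:
        a += 2.0 * math.pi
    return a - math.pi


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in screen units (x, y = top-left corner)."""

    x: float
    y: float
    w: float
    h: float

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px <= self.x + self.w and self.y <= py <= self.y + self.h

    def inside_screen(self, width: float, height: float) -> bool:
        return (
            0.0 <= self.x
            and 0.0 <= self.y
            and self.x + self.w <= width
            and self.y + self.h <= height
        )

    def sample_point(self, rng: np.random.Generator) -> tuple[float, float]:
        return (
            self.x + rng.uniform(0.0, self.w),
            self.y + rng.uniform(0.0, self.h),
        )


@dataclass(frozen=True)
class TaskSpec:
    """One item of one subtest: where cards start, where they must go."""

    subtest_id: int
    item_id: int
    n_drags: int
    start_zone: Rect
    goal_zone: Rect
    screen_width: float = SCREEN_WIDTH
    screen_height: float = SCREEN_HEIGHT
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        if not 1 <= self.subtest_id <= 5:
            raise ValueError(f"subtest_id must be in 1..5, got {self.subtest_id}")
        if not 1 <= self.item_id <= 5:
            raise ValueError(f"item_id must be in 1..5, got {self.item_id}")
        if not 1 <= self.n_drags <= 5:
            raise ValueError(f"n_drags must be in 1..5, got {self.n_drags}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for zone in (self.start_zone, self.goal_zone):
            if not zone.inside_screen(self.screen_width, self.screen_height):
                raise ValueError(f"zone {zone} lies outside the screen")


@dataclass(frozen=True)
class SubjectProfile:
    """Latent motor parameters of one simulated subject."""

    subject_id: str
    group: str
    base_speed: float
    speed_cv: float
    heading_noise_sd: float
    goal_gain: float
    fragmentation_rate: float
    accel_burst_sd: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise UnknownGroupError(f"unknown group {self.group!r}")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be positive")
        for name in ("speed_cv", "heading_noise_sd", "fragmentation_rate",
                     "accel_burst_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.goal_gain <= 1.0:
            raise ValueError("goal_gain must lie in [0, 1]")


@dataclass(frozen=True)
class GroupEffectConfig:
    """Per-group mean/SD of every latent parameter.

    ``params[group][param] == (mean, sd)``.
    """

    name: str
    params: dict[str, dict[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        for group in GROUPS:
            if group not in self.params:
                raise IncompleteConfigError(f"preset {self.name!r}: group {group} missing")
            for p in LATENT_PARAMS:
                if p not in self.params[group]:
                    raise IncompleteConfigError(
                        f"preset {self.name!r}: {group}.{p} missing"
                    )
                _, sd = self.params[group][p]
                if sd < 0:
                    raise IncompleteConfigError(
                        f"preset {self.name!r}: {group}.{p} has negative sd"
                    )

    @classmethod
    def from_dict(cls, d: dict) -> "GroupEffectConfig":
        params = {
            g: {p: (float(v["mean"]), float(v["sd"])) for p, v in gp.items()}
            for g, gp in d["groups"].items()
        }
        return cls(name=str(d.get("name", "unnamed")), params=params)

    @classmethod
    def from_yaml(cls, path) -> "GroupEffectConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def preset(cls, name: str) -> "GroupEffectConfig":
        """Load a packaged preset (``default`` or ``null``)."""
        ref = resources.files("motorsig") / "presets" / f"{name}.yaml"
        if not ref.is_file():
            raise UnknownPresetError(f"no preset named {name!r}")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


# bounds to which sampled latent parameters are truncated
_PARAM_BOUNDS = {
    "base_speed": (1.0, math.inf),
    "speed_cv": (0.0, 2.0),
    "heading_noise_sd": (0.0, math.pi),
    "goal_gain": (0.01, 1.0),
    "fragmentation_rate": (0.0, 10.0),
    "accel_burst_sd": (0.0, math.inf),
}


def sample_subject_profile(
    group: str,
    effect_config: GroupEffectConfig,
    seed,
    subject_id: str | None = None,
) -> SubjectProfile:
    """Draw one subject's latent parameters from the group's distributions.

    Draws are Gaussian, truncated (clipped) to each parameter's valid range;
    reproducible given ``seed`` (an int or a ``numpy`` seed sequence).
    """
    if group not in GROUPS:
        raise UnknownGroupError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    values = {}
    for p in LATENT_PARAMS:
        mean, sd = effect_config.params[group][p]
        lo, hi = _PARAM_BOUNDS[p]
        values[p] = float(np.clip(rng.normal(mean, sd), lo, hi))
    if subject_id is None:
        subject_id = f"{group}_anon"
    return SubjectProfile(subject_id=subject_id, group=group, **values)


@dataclass
class TouchStream:
    """One subject-task recording: timestamped touch samples with phases."""

    subject_id: str
    group: str
    subtest_id: int
    item_id: int
    t: np.ndarray          # seconds, strictly increasing
    x: np.ndarray          # screen units
    y: np.ndarray
    phase: np.ndarray      # '<U7' array of press/move/release
    sample_rate: float = SAMPLE_RATE

    def __len__(self) -> int:
        return len(self.t)

    def samples(self) -> Iterator[tuple[float, float, float, str]]:
        for i in range(len(self.t)):
            yield float(self.t[i]), float(self.x[i]), float(self.y[i]), str(self.phase[i])

    def validate(self, screen_width: float = SCREEN_WIDTH,
                 screen_height: float = SCREEN_HEIGHT) -> None:
        """Raise ``ValueError`` if any TouchStream invariant is violated."""
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps not strictly increasing")
        if np.any(self.x < 0) or np.any(self.x > screen_width):
            raise ValueError("x coordinate outside screen")
        if np.any(self.y < 0) or np.any(self.y > screen_height):
            raise ValueError("y coordinate outside screen")
        depth = 0
        for i, ph in enumerate(self.phase):
            if ph == PHASE_PRESS:
                if depth:
                    raise ValueError(f"nested press at sample {i}")
                depth = 1
            elif ph == PHASE_RELEASE:
                if not depth:
                    raise ValueError(f"release without press at sample {i}")
                depth = 0
            elif ph != PHASE_MOVE:
                raise ValueError(f"unknown phase {ph!r} at sample {i}")
        if depth:
            raise ValueError("stream ends inside an open press episode")


class _Walk:
    """Mutable state of one simulated drag (helper for generate_task_stream)."""

    __slots__ = ("t", "xs", "ys", "phases")

    def __init__(self) -> None:
        self.t: list[float] = []
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.phases: list[str] = []

    def emit(self, t: float, x: float, y: float, phase: str) -> None:
        self.t.append(t)
        self.xs.append(x)
        self.ys.append(y)
        self.phases.append(phase)


def generate_task_stream(
    profile: SubjectProfile,
    task_spec: TaskSpec,
    seed,
    step_cap: int = 4000,
) -> TouchStream:
    """Simulate one subject performing one task (``n_drags`` card drags).

    Each drag runs from a random point in the start zone to a random target
    point in the goal zone and terminates when the target is reached; a step
    cap guards against runaway parameter combinations
    (:class:`GoalUnreachableError`).
    """
    if task_spec.sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / task_spec.sample_rate
    p = profile
    # lognormal multiplier with unit mean and CV = speed_cv
    sigma = math.sqrt(math.log1p(p.speed_cv ** 2))
    mu = -0.5 * sigma * sigma
    speed_floor = 0.5  # units/s, keeps every step strictly positive

    walk = _Walk()
    t = 0.0
    for _ in range(task_spec.n_drags):
        sx, sy = task_spec.start_zone.sample_point(rng)
        gx, gy = task_spec.goal_zone.sample_point(rng)
        x, y = sx, sy
        init_dist = math.hypot(gx - x, gy - y)
        heading = math.atan2(gy - y, gx - x)
        # per-step lift hazard calibrated to ~fragmentation_rate lifts/drag
        est_steps = max(4.0, init_dist / (0.75 * p.base_speed * dt))
        lift_prob = min(0.5, p.fragmentation_rate / est_steps)
        v_burst = 0.0
        walk.emit(t, x, y, PHASE_PRESS)

        # pre-drawn noise, refilled if a drag runs long
        n_noise = int(est_steps * 4) + 64
        head_noise = rng.normal(0.0, p.heading_noise_sd, n_noise)
        logn = np.exp(rng.normal(mu, sigma, n_noise))
        burst = rng.normal(0.0, p.accel_burst_sd, n_noise) * dt
        lifts = rng.random(n_noise)
        k = 0

        for step in range(step_cap):
            if k >= n_noise:
                head_noise = rng.normal(0.0, p.heading_noise_sd, n_noise)
                logn = np.exp(rng.normal(mu, sigma, n_noise))
                burst = rng.normal(0.0, p.accel_burst_sd, n_noise) * dt
                lifts = rng.random(n_noise)
                k = 0
            dist = math.hypot(gx - x, gy - y)
            progress = 1.0 - min(1.0, dist / init_dist) if init_dist > 0 else 1.0
            bell = 0.25 + 0.75 * math.sin(math.pi * min(1.0, 0.08 + 0.92 * progress))
            v_burst = 0.9 * v_burst + burst[k]
            speed = max(speed_floor, bell * p.base_speed * logn[k] + v_burst)
            bearing = math.atan2(gy - y, gx - x)
            heading = heading + p.goal_gain * _wrap_angle(bearing - heading) + head_noise[k]
            step_len = min(speed * dt, dist)  # never overshoot the target
            x = min(task_spec.screen_width, max(0.0, x + step_len * math.cos(heading)))
            y = min(task_spec.screen_height, max(0.0, y + step_len * math.sin(heading)))
            t += dt
            if task_spec.goal_zone.contains(x, y) or math.hypot(gx - x, gy - y) <= 10.0:
                walk.emit(t, x, y, PHASE_RELEASE)
                break
            if lifts[k] < lift_prob and step > 1:
                walk.emit(t, x, y, PHASE_RELEASE)
                t += 2 * dt  # brief air time before the finger lands again
                walk.emit(t, x, y, PHASE_PRESS)
            else:
                walk.emit(t, x, y, PHASE_MOVE)
            k += 1
        else:
            raise GoalUnreachableError(
                f"drag did not reach goal within {step_cap} steps "
                f"(subject {p.subject_id}, subtest {task_spec.subtest_id}, "
                f"item {task_spec.item_id})"
            )
        t += 2 * dt  # gap before the next card is picked up

    stream = TouchStream(
        subject_id=p.subject_id,
        group=p.group,
        subtest_id=task_spec.subtest_id,
        item_id=task_spec.item_id,
        t=np.asarray(walk.t),
        x=np.asarray(walk.xs),
        y=np.asarray(walk.ys),
        phase=np.asarray(walk.phases, dtype="<U7"),
        sample_rate=task_spec.sample_rate,
    )
    return stream


def default_roster() -> list[TaskSpec]:
    """The 5 subtests x 5 items task roster used by the default cohort.

    Zones vary across subtests/items so tasks differ in distance and
    direction; drag counts cycle through 1..3 cards.
    """
    roster = []
    for s in range(1, 6):
        for i in range(1, 6):
            start = Rect(60.0 + 45.0 * i, 560.0 + 18.0 * s, 120.0, 120.0)
            goal = Rect(880.0 + 24.0 * i, 60.0 + 70.0 * s, 150.0, 130.0)
            roster.append(
                TaskSpec(
                    subtest_id=s,
                    item_id=i,
                    n_drags=1 + (s + i) % 3,
                    start_zone=start,
                    goal_zone=goal,
                )
            )
    return roster


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for :func:`generate_cohort`."""

    n_per_group: int = 30
    effect_preset: str = "default"
    roster: Sequence[TaskSpec] = field(default_factory=default_roster)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if len(self.roster) == 0:
            raise EmptyRosterError("task roster is empty")


def generate_cohort(
    cohort_config: CohortConfig,
    seed,
    effect_config: GroupEffectConfig | None = None,
) -> list[TouchStream]:
    """Generate one TouchStream per subject per task.

    The master seed is fanned out with ``numpy.random.SeedSequence.spawn``:
    one child per subject (profile draw) and one grandchild per task, so any
    subject/task cell can be regenerated in isolation.
    """
    cfg = cohort_config
    if effect_config is None:
        effect_config = GroupEffectConfig.preset(cfg.effect_preset)
    if isinstance(seed, np.random.SeedSequence):
        master = seed
    else:
        master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(2 * cfg.n_per_group)
    streams: list[TouchStream] = []
    idx = 0
    for group in GROUPS:
        for j in range(cfg.n_per_group):
            sid = f"{group}{j + 1:03d}"
            ss = subject_seeds[idx]
            idx += 1
            task_seeds = ss.spawn(len(cfg.roster) + 1)
            profile = sample_subject_profile(
                group, effect_config, task_seeds[0], subject_id=sid
            )
            for k, task in enumerate(cfg.roster):
                streams.append(generate_task_stream(profile, task, task_seeds[k + 1]))
    return streams
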