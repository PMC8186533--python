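import numpy as np
import pytest

from motorsig import (
    CohortConfig,
    GroupEffectConfig,
    SubjectProfile,
    featurize_streams,
    generate_cohort,
)
from motorsig.trajectories import Trajectory

DT = 0.025  # 40 Hz


def make_traj(points, dt=DT, t=None, **ids):
    """Build a Trajectory from a list of (x, y) points at fixed dt (or given t)."""
    pts = np.asarray(points, dtype=float)
    if t is None:
        t = np.arange(len(pts)) * dt
    return Trajectory(
        t=np.asarray(t, dtype=float), x=pts[:, 0], y=pts[:, 1], **ids
    )


def clean_profile(group="TD", **overrides):
    """A deterministic profile; overrides default to a noiseless drag."""
    base = dict(
        subject_id=f"{group}001",
        group=group,
        base_speed=400.0,
        speed_cv=0.0,
        heading_noise_sd=0.0,
        goal_gain=1.0,
        fragmentation_rate=0.0,
        accel_burst_sd=0.0,
    )
    base.update(overrides)
    return SubjectProfile(**base)


def preset_mean_profile(group, preset="default"):
    """Profile pinned at the preset's group means (no sampling noise)."""
    cfg = GroupEffectConfig.preset(preset)
    return SubjectProfile(
        subject_id=f"{group}001",
        group=group,
        **{p: cfg.params[group][p][0] for p in cfg.params[group]},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full study-design cohort (30 + 30 subjects, 25 tasks), seed 123."""
    return generate_cohort(CohortConfig(), seed=123)


@pytest.fixture(scope="session")
def default_table(default_cohort):
    table, counts = featurize_streams(default_cohort)
    return table, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
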