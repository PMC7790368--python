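"""Arm-swing smoothness via the normalized jerk index (NJI).

Jerk is the third time derivative of the wrist-marker trajectory; NJI is the
trial-mean jerk magnitude divided by the peak velocity magnitude (units 1/s^2,
lower = smoother).  Reactive arm-swing strategies are asymmetric, so the side
with the higher NJI is carried into the statistical analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import lowpass

__all__ = ["NJIRecord", "jerk", "nji", "select_side"]

_EDGE_TRIM = 3  # samples dropped at each end after differentiation


@dataclass
class NJIRecord:
    subject: str
    speed: float
    side: str
    mean_abs_jerk: float  # m/s^3
    peak_velocity: float  # m/s
    nji: float  # 1/s^2
    selected: bool = False


def _filtered(trajectory: np.ndarray, fs: float, prefilter) -> np.ndarray:
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    if prefilter is not None:
        order, cutoff = prefilter
        traj = lowpass(traj, fs, order, cutoff, axis=0)
    return traj


def jerk(
    trajectory: np.ndarray,
    fs: float,
    prefilter: tuple[int, float] | None = (3, 10.0),
) -> np.ndarray:
    """Jerk magnitude series (m/s^3) of a (frames, 3) trajectory.

    Third derivative per axis by repeated central differencing on the
    low-pass-filtered trajectory; magnitude is the Euclidean norm across axes;
    three samples are trimmed from each end.
    """
    traj = _filtered(trajectory, fs, prefilter)
    if traj.shape[0] < 7:
        raise ValueError("need at least 7 samples to estimate jerk")
    dt = 1.0 / fs
    d = traj
    for _ in range(3):
        d = np.gradient(d, dt, axis=0)
    mag = np.linalg.norm(d, axis=1)
    return mag[_EDGE_TRIM:-_EDGE_TRIM]


def nji(
    trajectory: np.ndarray,
    fs: float,
    subject: str = "",
    speed: float = 0.0,
    side: str = "",
    prefilter: tuple[int, float] | None = (3, 10.0),
) -> NJIRecord:
    """Normalized jerk index: mean |jerk| over the trial / peak velocity."""
    traj = _filtered(trajectory, fs, prefilter)
    jm = jerk(traj, fs, prefilter=None)
    vel = np.gradient(traj, 1.0 / fs, axis=0)
    speed_mag = np.linalg.norm(vel, axis=1)[_EDGE_TRIM:-_EDGE_TRIM]
    peak = float(speed_mag.max())
    if peak <= 0:
        raise ValueError("zero peak velocity; NJI undefined for a static trajectory")
    return NJIRecord(
        subject=subject,
        speed=speed,
        side=side,
        mean_abs_jerk=float(jm.mean()),
        peak_velocity=peak,
        nji=float(jm.mean() / peak),
    )


def select_side(left: NJIRecord | None, right: NJIRecord | None) -> NJIRecord:
    """Return the side with the higher NJI (tie -> right).

    If one side is invalid (None), the other is returned with a warning.
    """
    if left is None and right is None:
        raise ValueError("no valid NJI record on either side")
    if left is None or right is None:
        chosen = left if right is None else right
        warnings.warn(
            f"only the {chosen.side} side has a valid NJI; selecting it",
            stacklevel=2,
        )
    else:
        chosen = right if right.nji >= left.nji else left
    chosen.selected = True
    return chosen
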