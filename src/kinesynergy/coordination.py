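"""Sagittal joint angles, Hilbert phase, continuous relative phase (CRP) and
deviation phase (DP).

CRP(t) is the pointwise difference between the phase angles of a proximal and
a distal joint's oscillation, wrapped to (-180, 180].  DP summarizes
stride-to-stride coordination variability: at each percent of the gait cycle
the sample standard deviation of CRP across strides is taken, and DP is the
mean of those SDs over the cycle; the trial-level DP averages the six sagittal
lower-limb joint pairs (Hip-Knee, Hip-Ankle, Knee-Ankle, both sides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .events import StrideEvents, detect_heel_strikes, normalize_strides
from .io import MarkerTrial

__all__ = [
    "JointAngleSeries",
    "CRPSeries",
    "DPRecord",
    "joint_angle_sagittal",
    "phase_angle",
    "crp",
    "wrap_degrees",
    "deviation_phase",
    "trial_dp",
    "PAIRS",
]

PAIRS: tuple[tuple[str, str], ...] = (("hip", "knee"), ("hip", "ankle"), ("knee", "ankle"))


@dataclass
class JointAngleSeries:
    joint: str
    side: str
    values: np.ndarray  # degrees per frame
    fs: float
    plane: str = "sagittal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("joint angles contain non-finite values")


@dataclass
class CRPSeries:
    pair: tuple[str, str, str]  # (proximal, distal, side)
    strides: np.ndarray  # (strides, n_grid), degrees wrapped to (-180, 180]


@dataclass
class DPRecord:
    subject: str
    speed: float
    pair_dp: dict[tuple[str, str, str], float] = field(default_factory=dict)

    @property
    def trial_dp(self) -> float:
        """Mean DP over the joint pairs of the trial."""
        return float(np.mean(list(self.pair_dp.values())))


def _pitch_from_vertical(v: np.ndarray) -> np.ndarray:
    """Signed sagittal pitch (deg) of a segment vector from vertical-down;
    positive when the distal end points anteriorly (+Y)."""
    return np.degrees(np.arctan2(v[:, 1], -v[:, 2]))


def _incline_from_horizontal(v: np.ndarray) -> np.ndarray:
    """Signed sagittal incline (deg) of a vector from horizontal (+Y)."""
    return np.degrees(np.arctan2(v[:, 2], v[:, 1]))


def joint_angle_sagittal(trial: MarkerTrial, joint: str, side: str) -> JointAngleSeries:
    """Sagittal-plane joint angle from marker geometry, flexion positive.

    Conventions (degrees): hip = thigh pitch from vertical; knee = thigh pitch
    minus shank pitch; ankle = shank pitch minus foot incline (dorsiflexion
    positive up to a constant offset).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    p = side[0].upper()

    def seg(a: str, b: str) -> np.ndarray:
        for lab in (a, b):
            if lab not in trial.labels:
                raise ValueError(f"missing marker {lab!r} for {side} {joint} angle")
        return trial.marker(b) - trial.marker(a)

    if joint == "hip":
        values = _pitch_from_vertical(seg(p + "HIP", p + "KNEE"))
    elif joint == "knee":
        thigh = _pitch_from_vertical(seg(p + "HIP", p + "KNEE"))
        shank = _pitch_from_vertical(seg(p + "KNEE", p + "ANK"))
        values = thigh - shank
    elif joint == "ankle":
        shank = _pitch_from_vertical(seg(p + "KNEE", p + "ANK"))
        foot = _incline_from_horizontal(seg(p + "HEEL", p + "TOE"))
        values = shank - foot
    else:
        raise ValueError(f"unknown joint {joint!r}")
    return JointAngleSeries(joint=joint, side=side, values=values, fs=trial.fs)


def phase_angle(
    values: np.ndarray, centering: str = "mean"
) -> np.ndarray:
    """Unwrapped analytic-signal phase of an oscillatory series, in degrees.

    The series is amplitude-centered (mean or midrange of min/max), the
    analytic signal is formed with the Hilbert transform, and the phase is the
    unwrapped arctangent of its imaginary over real part.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 64:
        raise ValueError("need at least 64 samples for a phase estimate")
    if np.ptp(x) < 1e-12:
        raise ValueError("phase of a constant series is undefined")
    if centering == "mean":
        x = x - x.mean()
    elif centering == "midrange":
        x = x - (x.max() + x.min()) / 2.0
    else:
        raise ValueError(f"unknown centering {centering!r}")
    analytic = hilbert(x)
    return np.degrees(np.unwrap(np.angle(analytic)))


def wrap_degrees(values: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]; ties at +/-180 map to +180."""
    w = (np.asarray(values, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w)


def crp(phi_proximal: np.ndarray, phi_distal: np.ndarray) -> np.ndarray:
    """Continuous relative phase: proximal minus distal phase, wrapped."""
    phi_proximal = np.asarray(phi_proximal, dtype=float)
    phi_distal = np.asarray(phi_distal, dtype=float)
    if phi_proximal.shape != phi_distal.shape:
        raise ValueError("phase series lengths differ")
    return wrap_degrees(phi_proximal - phi_distal)


def deviation_phase(crp_strides: np.ndarray) -> float:
    """DP of one joint pair: pointwise sample SD of CRP across strides
    (ddof=1), averaged over the gait cycle."""
    crp_strides = np.asarray(crp_strides, dtype=float)
    if crp_strides.ndim != 2 or crp_strides.shape[0] < 2:
        raise ValueError("need at least 2 strides on a common grid")
    return float(crp_strides.std(axis=0, ddof=1).mean())


def _trim_window(n: int, edge_trim: float) -> tuple[int, int]:
    a = int(np.floor(edge_trim * n))
    return a, n - a


def trial_dp(
    trial: MarkerTrial,
    events_by_side: dict[str, StrideEvents] | None = None,
    n_grid: int = 100,
    edge_trim: float = 0.10,
    pairs: tuple[tuple[str, str], ...] = PAIRS,
) -> tuple[DPRecord, dict[tuple[str, str, str], CRPSeries]]:
    """Trial-level deviation phase over the sagittal joint pairs of both sides.

    The first and last ``edge_trim`` fraction of the trial is excluded from
    stride assembly (Hilbert-transform edge distortion).  Returns the DP
    record and the per-pair stride-normalized CRP matrices.
    """
    record = DPRecord(subject=trial.subject_id, speed=trial.speed)
    series: dict[tuple[str, str, str], CRPSeries] = {}
    a, b = _trim_window(trial.n_frames, edge_trim)
    for side in ("left", "right"):
        events = (
            events_by_side[side]
            if events_by_side is not None
            else detect_heel_strikes(trial, side)
        )
        phases = {
            joint: phase_angle(joint_angle_sagittal(trial, joint, side).values)
            for joint in ("hip", "knee", "ankle")
        }
        hs = events.heel_strike_frames
        kept = hs[(hs >= a) & (hs < b)]
        if len(kept) < 3:
            raise ValueError(
                f"too few strides inside the trimmed window on the {side} side"
            )
        inner = StrideEvents(side, kept - a, trial.fs)
        for prox, dist in pairs:
            diff = phases[prox][a:b] - phases[dist][a:b]  # unwrapped difference
            strides = wrap_degrees(normalize_strides(diff, inner, n_grid))
            key = (prox, dist, side)
            series[key] = CRPSeries(pair=key, strides=strides)
            record.pair_dp[key] = deviation_phase(strides)
    return record, series
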