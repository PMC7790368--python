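"""Synthetic multi-subject treadmill-gait generator with known ground truth.

Two generation modes share one configuration object:

* **structured mode** (default, ``synergy_vectors is None``): marker motion is
  produced by an exact sagittal forward-kinematic chain (pelvis -> thigh ->
  shank -> foot, shoulder -> upper arm -> forearm) driven by sinusoidal joint
  waveforms at the stride frequency, plus a vertical torso bounce at the first
  harmonic and a mediolateral sway.  Per-stride phase jitter of the lower-limb
  joint waveforms plants a known deviation phase (DP); a high-frequency wrist
  component plants arm-swing jerk.  Every planted quantity is returned in a
  :class:`GroundTruth`.

* **explicit-synergy mode** (``synergy_vectors`` given): posture deviations are
  an exact low-rank expansion ``mean + sum_j a_j sin(2 pi f_j t + phi_j) v_j``
  over a user-supplied orthonormal basis, with amplitudes set so the planted
  variance fractions hold exactly.  This is the mode used to test principal-
  movement recovery.

The per-stride phase jitter is drawn independently per joint (hip, knee,
ankle) with standard deviation ``phase_jitter_sd_deg / sqrt(2)`` so that every
joint-pair phase difference has standard deviation ``phase_jitter_sd_deg``;
the planted trial DP therefore equals ``phase_jitter_sd_deg`` (the documented
mapping).  Jitter is applied to perturbed trials only -- normal walking is
modeled as strictly periodic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import MarkerTrial

__all__ = [
    "GaitSimConfig",
    "GroundTruth",
    "SimulationError",
    "generate_trial",
    "generate_cohort",
    "simulate_model_dataset",
    "random_synergy_basis",
    "bounce_direction",
    "MARKER_LAYOUT",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


# Mean standing posture (meters).  X mediolateral, Y anterior-posterior
# (belt direction +Y), Z vertical.  Chosen for a ~1.74 m subject.
MARKER_LAYOUT: dict[str, tuple[float, float, float]] = {
    "C7": (0.0, 0.0, 1.45),
    "SACR": (0.0, 0.0, 1.00),
    "LASI": (-0.12, 0.12, 1.00),
    "RASI": (0.12, 0.12, 1.00),
    "LHIP": (-0.10, 0.0, 0.95),
    "RHIP": (0.10, 0.0, 0.95),
    "LKNEE": (-0.10, 0.0, 0.50),
    "RKNEE": (0.10, 0.0, 0.50),
    "LANK": (-0.10, 0.0, 0.10),
    "RANK": (0.10, 0.0, 0.10),
    "LHEEL": (-0.10, -0.05, 0.05),
    "RHEEL": (0.10, -0.05, 0.05),
    "LTOE": (-0.10, 0.15, 0.05),
    "RTOE": (0.10, 0.15, 0.05),
    "LSHO": (-0.18, 0.0, 1.40),
    "RSHO": (0.18, 0.0, 1.40),
    "LELB": (-0.20, 0.0, 1.15),
    "RELB": (0.20, 0.0, 1.15),
    "LWRI": (-0.20, 0.0, 0.90),
    "RWRI": (0.20, 0.0, 0.90),
}

# segment geometry implied by the layout
_L_THIGH = 0.45
_L_SHANK = 0.40
_L_UPPER_ARM = 0.25
_L_FOREARM = 0.25
_HEEL_OFFSET = np.array([0.0, -0.05, -0.05])
_TOE_OFFSET = np.array([0.0, 0.15, -0.05])

# joint waveform amplitudes (degrees) and proximal->distal phase lags
_A_HIP = 10.0
_A_KNEE = 12.0
_A_ANKLE = 8.0
_A_ARM = 8.0
_LAG_KNEE = 45.0
_LAG_ANKLE = 90.0
_BOUNCE_AMP = 0.03  # m, vertical torso bounce at the first harmonic (typical pelvis excursion 2-5 cm)
_SWAY_AMP = 0.010  # m, mediolateral torso sway at the fundamental
_ARM_HF_FREQ = 7.0  # Hz, planted wrist jerk component
_ARM_HF_AMP = 0.002  # m at arm_jerk_scale == 1


@dataclass
class GaitSimConfig:
    """Study-condition parameters of the synthetic gait cohort.

    Defaults mirror the protocol the pipeline targets: 13 subjects walking at
    0.8/1.2/1.6 m/s, 100 Hz capture, ~50 s of steady normal walking and 8 min
    of perturbed walking per speed.  The mixed-model parameters
    (``beta_fixed``, random-effect and residual SDs) plant the cohort-level
    relation between synergy control and coordination variability.
    """

    n_subjects: int = 13
    speeds: tuple[float, ...] = (0.8, 1.2, 1.6)
    fs: float = 100.0
    duration_s: float = 50.0
    perturbed_duration_s: float = 480.0
    n_markers: int = 20
    stride_freq_base: float = 0.9  # strides/s at 1.2 m/s
    synergy_vectors: np.ndarray | None = None
    synergy_variance_fractions: tuple[float, ...] = (0.80, 0.15, 0.05)
    synergy_scale: float = 0.05  # m, total RMS posture deviation (explicit mode)
    phase_jitter_sd_deg: float = 5.0
    amp_jitter_sd: float = 0.0
    arm_jerk_scale: float = 1.0
    noise_sd: float = 0.0
    beta_fixed: float = -2.18
    re_intercept_sd: float = 1.754  # sqrt(3.08)
    re_slope_sd: float = 0.3
    resid_sd: float = 1.96  # sqrt(3.84)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SimulationError("n_subjects must be >= 1")
        if any(s <= 0 for s in self.speeds):
            raise SimulationError("speeds must be positive")
        if self.phase_jitter_sd_deg < 0 or self.noise_sd < 0:
            raise SimulationError("SDs must be nonnegative")
        if min(self.re_intercept_sd, self.re_slope_sd, self.resid_sd) < 0:
            raise SimulationError("random-effect SDs must be nonnegative")
        if self.synergy_vectors is not None:
            v = np.asarray(self.synergy_vectors, dtype=float)
            if v.ndim != 2:
                raise SimulationError("synergy_vectors must be a 2-D array (k, 3*markers)")
            gram = v @ v.T
            if not np.allclose(gram, np.eye(v.shape[0]), atol=1e-8):
                raise SimulationError(
                    "synergy_vectors are not mutually orthonormal within 1e-8"
                )
            self.synergy_vectors = v
            k = v.shape[0]
            fr = tuple(self.synergy_variance_fractions)[:k]
            if len(fr) != k:
                raise SimulationError("need one variance fraction per synergy vector")
            if any(f < 0 for f in fr) or sum(fr) > 1 + 1e-12:
                raise SimulationError("variance fractions must be nonnegative, sum <= 1")
            if any(fr[i] < fr[i + 1] for i in range(len(fr) - 1)):
                raise SimulationError("variance fractions must be sorted descending")
            self.synergy_variance_fractions = fr
        # aliasing guard: every generated frequency must sit below Nyquist
        if self.fs <= 2.0 * self.max_frequency():
            raise SimulationError(
                f"fs={self.fs} Hz cannot represent content up to "
                f"{self.max_frequency()} Hz (aliasing)"
            )

    def stride_frequency(self, speed: float) -> float:
        """Stride frequency (strides/s); scales with the square root of speed."""
        return self.stride_freq_base * np.sqrt(speed / 1.2)

    def max_frequency(self) -> float:
        f_max = max(self.stride_frequency(s) for s in self.speeds)
        if self.synergy_vectors is not None:
            k = self.synergy_vectors.shape[0]
            return f_max * (1 + (k + 1) // 2)
        return max(2.0 * f_max, _ARM_HF_FREQ)


@dataclass
class GroundTruth:
    """Planted quantities of one simulated trial."""

    heel_strike_times: dict[str, np.ndarray] = field(default_factory=dict)
    true_phase_lag: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    true_dp: float = 0.0
    joint_angles_deg: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    synergy_basis: np.ndarray | None = None
    synergy_fractions: tuple[float, ...] | None = None
    model_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side, times in self.heel_strike_times.items():
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"heel-strike times for {side} are not increasing")


def _trial_rng(config: GaitSimConfig, subject_id: str, speed: float, condition: str):
    """Deterministic per-trial generator, stable across processes."""
    subj_key = zlib.crc32(subject_id.encode()) & 0x7FFFFFFF
    entropy = [
        int(config.seed) & 0x7FFFFFFF,
        subj_key,
        int(round(speed * 1000)),
        0 if condition == "normal" else 1,
    ]
    return np.random.default_rng(entropy)


def _pitched(length: float, angle: np.ndarray) -> np.ndarray:
    """(frames, 3) segment vector of given length pitched ``angle`` rad from
    vertical-down in the sagittal (Y-Z) plane; positive = distal end forward."""
    out = np.zeros((angle.size, 3))
    out[:, 1] = length * np.sin(angle)
    out[:, 2] = -length * np.cos(angle)
    return out


def _rot_x(points: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotate (3,) offset by per-frame pitch about the mediolateral axis.

    Positive angle tips the +Y direction downward (plantar-flexion sense for
    a forward-pointing foot)."""
    y, z = points[1], points[2]
    c, s = np.cos(angle), np.sin(angle)
    out = np.zeros((angle.size, 3))
    out[:, 0] = points[0]
    out[:, 1] = c * y - s * z
    out[:, 2] = s * y + c * z
    return out


def _stride_jitter(
    rng: np.random.Generator, t: np.ndarray, f: float, sd_deg: float
) -> np.ndarray:
    """Piecewise-constant per-stride phase offsets (radians) sampled per stride."""
    idx = np.floor(t * f).astype(int)
    n_strides = idx.max() + 1
    draws = rng.normal(0.0, np.deg2rad(sd_deg), n_strides)
    return draws[idx]


def _generate_structured(
    config: GaitSimConfig,
    rng: np.random.Generator,
    speed: float,
    condition: str,
    duration: float,
    jitter_sd_deg: float | None = None,
    amplitude_scale: float = 1.0,
    bounce_scale: float = 1.0,
    arm_jerk_scale: float | None = None,
) -> tuple[np.ndarray, GroundTruth, list[str]]:
    fs = config.fs
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    f = config.stride_frequency(speed)
    omega = 2 * np.pi * f
    labels = list(MARKER_LAYOUT)
    mean = np.array([MARKER_LAYOUT[l] for l in labels])
    data = np.tile(mean, (n, 1, 1))

    if jitter_sd_deg is None:
        jitter_sd_deg = config.phase_jitter_sd_deg if condition == "perturbed" else 0.0
    joint_sd = jitter_sd_deg / np.sqrt(2.0)
    if arm_jerk_scale is None:
        arm_jerk_scale = config.arm_jerk_scale
    amp = amplitude_scale * np.sqrt(speed / 1.2)

    # torso sway and bounce (shared by pelvis, trunk, shoulders)
    sway = _SWAY_AMP * amp * np.sin(omega * t)
    # cos-phased with the stride so the bounce is coherent with the legs'
    # kinematic first harmonic (pelvis highest at mid-stance)
    bounce = _BOUNCE_AMP * bounce_scale * amp * np.cos(2 * omega * t)
    torso = ("C7", "SACR", "LASI", "RASI", "LHIP", "RHIP", "LSHO", "RSHO")
    for lab in torso:
        j = labels.index(lab)
        data[:, j, 0] += sway
        data[:, j, 2] += bounce
    # the legs are ground-referenced: stance-limb flexion absorbs the pelvis
    # bounce, so the leg chain hangs from the swayed (not bounced) hip

    truth = GroundTruth(true_dp=jitter_sd_deg, synergy_basis=None)
    idx = {lab: labels.index(lab) for lab in labels}

    for side, zeta in (("left", 0.0), ("right", np.pi)):
        p = side[0].upper()
        d_hip = _stride_jitter(rng, t, f, joint_sd) if joint_sd > 0 else np.zeros(n)
        d_knee = _stride_jitter(rng, t, f, joint_sd) if joint_sd > 0 else np.zeros(n)
        d_ank = _stride_jitter(rng, t, f, joint_sd) if joint_sd > 0 else np.zeros(n)

        theta = np.deg2rad(_A_HIP) * amp * np.sin(omega * t + zeta + d_hip)
        kappa = np.deg2rad(_A_KNEE) * amp * np.sin(
            omega * t + zeta - np.deg2rad(_LAG_KNEE) + d_knee
        )
        ank = np.deg2rad(_A_ANKLE) * amp * np.sin(
            omega * t + zeta - np.deg2rad(_LAG_ANKLE) + d_ank
        )

        hip_base = data[:, idx[p + "HIP"], :].copy()
        hip_base[:, 2] -= bounce
        knee_pos = hip_base + _pitched(_L_THIGH, theta)
        shank_pitch = theta - kappa
        ank_pos = knee_pos + _pitched(_L_SHANK, shank_pitch)
        foot_pitch = shank_pitch - ank
        data[:, idx[p + "KNEE"], :] = knee_pos
        data[:, idx[p + "ANK"], :] = ank_pos
        data[:, idx[p + "HEEL"], :] = ank_pos + _rot_x(_HEEL_OFFSET, foot_pitch)
        data[:, idx[p + "TOE"], :] = ank_pos + _rot_x(_TOE_OFFSET, foot_pitch)

        # arm counterswing + planted high-frequency wrist component
        eta = np.deg2rad(_A_ARM) * amp * np.sin(omega * t + zeta + np.pi)
        sho_pos = data[:, idx[p + "SHO"], :]
        elb_pos = sho_pos + _pitched(_L_UPPER_ARM, eta)
        wri_pos = elb_pos + _pitched(_L_FOREARM, 1.2 * eta)
        hf_phase = rng.uniform(0, 2 * np.pi)
        wri_pos = wri_pos.copy()
        wri_pos[:, 2] += (
            arm_jerk_scale * _ARM_HF_AMP * np.sin(2 * np.pi * _ARM_HF_FREQ * t + hf_phase)
        )
        data[:, idx[p + "ELB"], :] = elb_pos
        data[:, idx[p + "WRI"], :] = wri_pos

        # ground truth: planted joint waveforms and per-stride phase lags
        truth.joint_angles_deg[(side, "hip")] = np.rad2deg(theta)
        truth.joint_angles_deg[(side, "knee")] = np.rad2deg(kappa)
        truth.joint_angles_deg[(side, "ankle")] = np.rad2deg(ank)
        stride_idx = np.floor(t * f).astype(int)
        first = np.searchsorted(stride_idx, np.arange(stride_idx.max() + 1))
        for pair, a, b in (
            (("hip", "knee"), d_hip, d_knee),
            (("hip", "ankle"), d_hip, d_ank),
            (("knee", "ankle"), d_knee, d_ank),
        ):
            truth.true_phase_lag[(side, *pair)] = np.rad2deg(a[first] - b[first])

        # heel strike = anterior peak of heel relative to the sacrum
        ap = data[:, idx[p + "HEEL"], 1] - data[:, idx["SACR"], 1]
        min_dist = max(1, int(round(0.6 * fs / f)))
        peaks, _ = find_peaks(ap, distance=min_dist)
        truth.heel_strike_times[side] = peaks / fs

    return data, truth, labels


def _generate_lowrank(
    config: GaitSimConfig,
    rng: np.random.Generator,
    speed: float,
    duration: float,
) -> tuple[np.ndarray, GroundTruth, list[str]]:
    fs = config.fs
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    f = config.stride_frequency(speed)
    basis = np.asarray(config.synergy_vectors, dtype=float)
    k, dim = basis.shape
    if dim % 3 != 0:
        raise SimulationError("synergy vector length must be a multiple of 3")
    n_markers = dim // 3
    labels = list(MARKER_LAYOUT)[:n_markers]
    if n_markers > len(MARKER_LAYOUT):
        labels = [f"M{i:02d}" for i in range(n_markers)]
        mean = np.zeros((n_markers, 3))
        mean[:, 2] = np.linspace(0.1, 1.5, n_markers)
    else:
        mean = np.array([MARKER_LAYOUT[l] for l in labels])

    fractions = np.asarray(config.synergy_variance_fractions, dtype=float)
    total_var = config.synergy_scale**2
    amps = np.sqrt(2.0 * fractions * total_var)
    # frequency/phase schedule keeps distinct scores uncorrelated: the leading
    # component oscillates at the stride frequency, higher-order components at
    # successive harmonics in quadrature pairs
    flat = np.tile(mean.reshape(-1), (n, 1)).astype(float)
    scores = np.empty((n, k))
    for j in range(k):
        harmonic = 1 + (j + 1) // 2
        phase = 0.0 if j == 0 or j % 2 == 1 else np.pi / 2
        scores[:, j] = amps[j] * np.sin(2 * np.pi * harmonic * f * t + phase)
        flat += scores[:, j : j + 1] * basis[j : j + 1, :]
    data = flat.reshape(n, n_markers, 3)
    truth = GroundTruth(
        synergy_basis=basis.copy(),
        synergy_fractions=tuple(fractions),
        true_dp=0.0,
    )
    return data, truth, labels


def generate_trial(
    config: GaitSimConfig,
    subject_id: str,
    speed: float,
    condition: str,
    **overrides,
) -> tuple[MarkerTrial, GroundTruth]:
    """Generate one trial plus its ground truth.

    ``overrides`` are forwarded to the structured generator (per-subject
    amplitude/bounce scales, jitter, arm jerk) and are used by
    :func:`generate_cohort`.  Deterministic for a fixed config seed.
    """
    if speed not in config.speeds:
        raise SimulationError(f"speed {speed} not in configured speeds {config.speeds}")
    if condition not in ("normal", "perturbed"):
        raise SimulationError("condition must be 'normal' or 'perturbed'")
    rng = _trial_rng(config, subject_id, speed, condition)
    duration = (
        config.duration_s if condition == "normal" else config.perturbed_duration_s
    )
    if config.synergy_vectors is not None:
        data, truth, labels = _generate_lowrank(config, rng, speed, duration)
    else:
        data, truth, labels = _generate_structured(
            config, rng, speed, condition, duration, **overrides
        )
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, data.shape)
    truth.model_params = {
        "beta_fixed": config.beta_fixed,
        "re_intercept_var": config.re_intercept_sd**2,
        "re_slope_var": config.re_slope_sd**2,
        "resid_var": config.resid_sd**2,
    }
    trial = MarkerTrial(
        subject_id=subject_id,
        condition=condition,
        speed=speed,
        fs=config.fs,
        labels=labels,
        data=data,
    )
    return trial, truth


# baseline trial-DP level per speed; coordination variability grows with speed
def _dp_baseline(speed: float) -> float:
    return 12.0 + 3.0 * (speed - 1.2)


def generate_cohort(
    config: GaitSimConfig,
) -> tuple[list[tuple[MarkerTrial, GroundTruth]], pd.DataFrame]:
    """Generate one normal + one perturbed trial per subject x speed.

    Subject-level random effects are drawn once per subject.  Each subject
    carries a standardized "push-off control" score ``z`` (realized as a
    multiplier on the torso-bounce harmonic, the push-off-like synergy); the
    perturbed-trial phase jitter -- and hence the planted DP -- follows the
    cohort linear model ``DP = baseline(speed) + (beta + b1) z + b0 + eps``,
    clipped to a physical range.  The returned truth table has one row per
    subject x speed.
    """
    if config.n_subjects < 2:
        raise SimulationError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0x5EED])
    out: list[tuple[MarkerTrial, GroundTruth]] = []
    rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        b0 = rng.normal(0.0, config.re_intercept_sd)
        b1 = rng.normal(0.0, config.re_slope_sd)
        z = rng.normal(0.0, 1.0)  # push-off control score
        bounce_scale = 1.0 + 0.25 * z
        amp_scale = float(np.exp(rng.normal(0.0, 0.05)))
        jerk_scale = float(
            config.arm_jerk_scale * np.exp(rng.normal(0.0, 0.2))
        )
        for speed in config.speeds:
            eps = rng.normal(0.0, config.resid_sd)
            jitter = float(
                np.clip(
                    _dp_baseline(speed) + (config.beta_fixed + b1) * z + b0 + eps,
                    0.5,
                    30.0,
                )
            )
            common = dict(amplitude_scale=amp_scale, bounce_scale=bounce_scale)
            normal = generate_trial(config, sid, speed, "normal", **common)
            perturbed = generate_trial(
                config,
                sid,
                speed,
                "perturbed",
                jitter_sd_deg=jitter,
                arm_jerk_scale=jerk_scale,
                **common,
            )
            out.extend([normal, perturbed])
            rows.append(
                dict(
                    subject=sid,
                    speed=speed,
                    b0=b0,
                    b1=b1,
                    control_z=z,
                    bounce_scale=bounce_scale,
                    amp_scale=amp_scale,
                    arm_jerk_scale=jerk_scale,
                    true_dp=jitter,
                )
            )
    return out, pd.DataFrame(rows)


# normalized PA_kRMS levels typical of the push-off synergy at each speed,
# used by the tabular cohort generator below
_PA_NORM_MEANS = {0.8: 10.8, 1.2: 8.4, 1.6: 6.8}


def simulate_model_dataset(
    n_subjects: int = 13,
    speeds: Sequence[float] = (0.8, 1.2, 1.6),
    beta: float = -2.18,
    intercept: float = 46.0,
    re_intercept_sd: float = 1.754,
    re_slope_sd: float = 0.0,
    resid_sd: float = 1.96,
    re_corr: float = 0.0,
    pa_sd: float = 1.3,
    pa_means: dict[float, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a long-format cohort table directly from the mixed-model structure
    ``DP = intercept + b0 + (beta + b1) PA + eps`` with subject random effects
    ``(b0, b1)`` (correlation ``re_corr``) and i.i.d. residuals.

    This is the tabular ground-truth generator for model-recovery checks; the
    kinematic cohort generator plants the same structure through trial
    waveforms.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pa_means is None:
        pa_means = _PA_NORM_MEANS
    cov = np.array(
        [
            [re_intercept_sd**2, re_corr * re_intercept_sd * re_slope_sd],
            [re_corr * re_intercept_sd * re_slope_sd, re_slope_sd**2],
        ]
    )
    rows = []
    for i in range(n_subjects):
        b0, b1 = rng.multivariate_normal([0.0, 0.0], cov)
        for s in speeds:
            pa = rng.normal(pa_means.get(s, 9.0), pa_sd)
            dp = intercept + b0 + (beta + b1) * pa + rng.normal(0.0, resid_sd)
            rows.append(
                dict(
                    subject=f"S{i + 1:02d}",
                    speed=s,
                    trial=f"{s:g}",
                    pa=pa,
                    dp=dp,
                    b0=b0,
                    b1=b1,
                )
            )
    return pd.DataFrame(rows)


def random_synergy_basis(
    n_markers: int,
    k: int,
    seed: int | np.random.Generator = 0,
    com_free: bool = True,
) -> np.ndarray:
    """Random orthonormal synergy basis in the 3*n_markers posture space.

    With ``com_free=True`` every vector is projected to have zero net
    translation per axis (zero center-of-mass displacement), so the basis is
    invariant under the posture-matrix COM re-centering step.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dim = 3 * n_markers
    raw = rng.standard_normal((dim, k))
    if com_free:
        for ax in range(3):
            e = np.zeros(dim)
            e[ax::3] = 1.0 / np.sqrt(n_markers)
            raw -= np.outer(e, e @ raw)
    q, _ = np.linalg.qr(raw)
    return q.T[:k]


def bounce_direction(labels: Sequence[str] | None = None) -> np.ndarray:
    """COM-free unit vector of the planted torso-bounce pattern.

    The bounce lifts the trunk, pelvis and arm markers vertically while the
    ground-referenced legs stay put; the returned direction is that pattern
    after the posture-matrix center-of-mass projection, for matching recovered
    principal movements against the planted push-off-like synergy.
    """
    if labels is None:
        labels = list(MARKER_LAYOUT)
    moved = ("C7", "SACR", "LASI", "RASI", "LHIP", "RHIP", "LSHO", "RSHO",
             "LELB", "RELB", "LWRI", "RWRI")
    n = len(labels)
    v = np.zeros(3 * n)
    for lab in moved:
        if lab in labels:
            v[3 * list(labels).index(lab) + 2] = 1.0
    for ax in range(3):
        e = np.zeros(3 * n)
        e[ax::3] = 1.0 / np.sqrt(n)
        v -= e * (e @ v)
    return v / np.linalg.norm(v)
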