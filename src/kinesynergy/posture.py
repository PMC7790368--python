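"""Principal-movement analysis of pooled posture data.

Whole-body marker frames are treated as posture vectors in a 3M-dimensional
space.  Per trial, each frame is re-referenced to the body center of mass,
centered on the trial's mean posture and scaled by the trial's mean Euclidean
deviation norm, so every trial contributes equally to the pooled matrix.  A
PCA of the pooled matrix yields the principal movements PM_k (kinematic
synergies); projecting trials onto them gives principal positions PP_k whose
first and second derivatives are the principal velocities PV_k and principal
accelerations PA_k.  The speed-normalized RMS of PA_k is the per-trial
statistic summarizing the magnitude of neuromuscular control on synergy k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .io import MarkerTrial, lowpass

__all__ = [
    "PostureMatrix",
    "PMSet",
    "PMTimeSeries",
    "PARMSRecord",
    "SpectralReport",
    "build_posture_matrix",
    "compute_pms",
    "project_scores",
    "differentiate_scores",
    "spectral_noise_check",
    "pa_rms",
    "loo_validate",
    "subspace_angles_deg",
]

TrialKey = tuple[str, float, str]


@dataclass
class PostureMatrix:
    """Pooled, normalized posture-deviation matrix with back-projection data."""

    values: np.ndarray  # (pooled_frames, 3*markers)
    trial_index: dict[TrialKey, slice]
    mean_postures: dict[TrialKey, np.ndarray]
    mean_norms: dict[TrialKey, float]
    com_reference: np.ndarray  # (pooled_frames, 3)
    labels: list[str]
    fs: dict[TrialKey, float] = field(default_factory=dict)
    speeds: dict[TrialKey, float] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trial_index)

    def rows(self, key: TrialKey) -> np.ndarray:
        if key not in self.trial_index:
            raise KeyError(f"trial {key} not in posture matrix")
        return self.values[self.trial_index[key]]

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.trial_index})


@dataclass
class PMSet:
    """Orthonormal principal-movement basis with variance accounting."""

    eigenvectors: np.ndarray  # (k, 3*markers), rows are PM_k
    eigenvalues: np.ndarray  # (k,)
    variance_fractions: np.ndarray  # (k,), descending
    total_variance: float
    validation_angles: np.ndarray | None = None  # max LOO angle per PM (deg)
    validated: np.ndarray | None = None
    angle_threshold_deg: float | None = None

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[0]

    def validated_indices(self) -> np.ndarray:
        """0-based indices of validated PMs (all, if not validated yet)."""
        if self.validated is None:
            return np.arange(self.k)
        return np.flatnonzero(self.validated)


@dataclass
class PMTimeSeries:
    """PP/PV/PA score series of one trial (PP units, per s, per s^2)."""

    trial_key: TrialKey
    pp: np.ndarray  # (frames, k)
    pv: np.ndarray
    pa: np.ndarray
    fs: float


@dataclass
class PARMSRecord:
    """Speed-normalized RMS of one PA_k series for one trial."""

    subject: str
    speed: float
    k: int  # 1-based PM index
    pa_rms_raw: float
    pa_rms_norm: float


def build_posture_matrix(trials: list[MarkerTrial]) -> PostureMatrix:
    """Pool trials into one centered, normalized posture-deviation matrix.

    Per trial, in order: re-center each frame to its marker center of mass
    (unweighted mean over markers per axis), subtract the trial mean posture,
    divide by the trial's mean Euclidean deviation norm.
    """
    if not trials:
        raise ValueError("no trials given")
    labels = trials[0].labels
    for tr in trials[1:]:
        if tr.labels != labels:
            extra = set(tr.labels) ^ set(labels)
            raise ValueError(
                f"inconsistent marker sets across trials; mismatch: {sorted(extra)}"
            )
    blocks, coms = [], []
    index: dict[TrialKey, slice] = {}
    means: dict[TrialKey, np.ndarray] = {}
    norms: dict[TrialKey, float] = {}
    fss: dict[TrialKey, float] = {}
    speeds: dict[TrialKey, float] = {}
    start = 0
    for tr in trials:
        if tr.has_gaps():
            raise ValueError(f"trial {tr.key} has gaps; fill before pooling")
        if tr.key in index:
            raise ValueError(f"duplicate trial key {tr.key}")
        com = tr.data.mean(axis=1)  # (frames, 3)
        centered = tr.data - com[:, None, :]
        flat = centered.reshape(tr.n_frames, -1)
        mean_posture = flat.mean(axis=0)
        dev = flat - mean_posture
        d_bar = float(np.linalg.norm(dev, axis=1).mean())
        # a numerically static trial has no deviation scale to normalize by
        if d_bar > 1e-12 * (1.0 + np.abs(mean_posture).max()):
            dev = dev / d_bar
        blocks.append(dev)
        coms.append(com)
        index[tr.key] = slice(start, start + tr.n_frames)
        means[tr.key] = mean_posture
        norms[tr.key] = d_bar
        fss[tr.key] = tr.fs
        speeds[tr.key] = tr.speed
        start += tr.n_frames
    return PostureMatrix(
        values=np.vstack(blocks),
        trial_index=index,
        mean_postures=means,
        mean_norms=norms,
        com_reference=np.vstack(coms),
        labels=list(labels),
        fs=fss,
        speeds=speeds,
    )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude loading of each PM is positive."""
    out = vectors.copy()
    for i, v in enumerate(out):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[i] = -v
    return out


def compute_pms(matrix: PostureMatrix, k_max: int) -> PMSet:
    """Eigendecompose the pooled posture-deviation covariance via SVD.

    Returns the leading ``k_max`` principal movements sorted by descending
    eigenvalue; truncates with a warning if ``k_max`` exceeds the matrix rank.
    """
    x = matrix.values
    n = x.shape[0]
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = float(eigvals.sum())
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    k = min(k_max, rank)
    if k_max > rank:
        warnings.warn(
            f"requested {k_max} PMs but the posture matrix has rank {rank}; truncating",
            stacklevel=2,
        )
    vectors = _fix_signs(vt[:k])
    fractions = eigvals[:k] / total if total > 0 else np.zeros(k)
    return PMSet(
        eigenvectors=vectors,
        eigenvalues=eigvals[:k],
        variance_fractions=fractions,
        total_variance=total,
    )


def project_scores(pms: PMSet, matrix: PostureMatrix, trial_key: TrialKey) -> np.ndarray:
    """PP scores of one trial: deviation rows projected onto the PM basis."""
    rows = matrix.rows(trial_key)
    return rows @ pms.eigenvectors.T


def differentiate_scores(
    pp: np.ndarray,
    fs: float,
    trial_key: TrialKey = ("", 0.0, ""),
    prefilter: tuple[int, float] | None = (3, 10.0),
) -> PMTimeSeries:
    """Differentiate PP scores to PV and PA.

    The scores are low-pass filtered (default 3rd-order Butterworth, 10 Hz,
    zero-phase) before central-difference differentiation; endpoints use
    one-sided differences.  Pass ``prefilter=None`` to differentiate raw
    scores.
    """
    pp = np.asarray(pp, dtype=float)
    if pp.ndim == 1:
        pp = pp[:, None]
    if pp.shape[0] < 5:
        raise ValueError("need at least 5 samples to differentiate")
    if prefilter is not None:
        order, cutoff = prefilter
        ppf = lowpass(pp, fs, order, cutoff, axis=0)
    else:
        ppf = pp
    dt = 1.0 / fs
    pv = np.gradient(ppf, dt, axis=0)
    pa = np.gradient(pv, dt, axis=0)
    return PMTimeSeries(trial_key=trial_key, pp=ppf, pv=pv, pa=pa, fs=fs)


@dataclass
class SpectralReport:
    fraction_above: float
    cutoff_hz: float
    max_fraction: float
    passed: bool


def spectral_noise_check(
    series: np.ndarray, fs: float, cutoff_hz: float = 5.0, max_fraction: float = 0.01
) -> SpectralReport:
    """Fraction of spectral power above ``cutoff_hz`` (Hann periodogram).

    Movement data is expected to be essentially band-limited below 5 Hz;
    substantial power above that indicates residual noise.
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size < 64:
        raise ValueError("need at least 64 samples for a spectral check")
    freqs, power = periodogram(series, fs=fs, window="hann", detrend="constant")
    total = power.sum()
    frac = float(power[freqs > cutoff_hz].sum() / total) if total > 0 else 0.0
    return SpectralReport(
        fraction_above=frac,
        cutoff_hz=cutoff_hz,
        max_fraction=max_fraction,
        passed=frac <= max_fraction,
    )


def pa_rms(
    pa_series: np.ndarray, speed: float, subject: str = "", k: int = 0
) -> PARMSRecord:
    """Time-averaged RMS of a PA_k series, normalized by walking speed.

    The time-average definition makes the statistic invariant to trial
    duration; the raw value is divided by speed (m/s) exactly.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    pa_series = np.asarray(pa_series, dtype=float)
    raw = float(np.sqrt(np.mean(pa_series**2)))
    return PARMSRecord(
        subject=subject, speed=speed, k=k, pa_rms_raw=raw, pa_rms_norm=raw / speed
    )


def subspace_angles_deg(v_full: np.ndarray, v_loo: np.ndarray) -> np.ndarray:
    """Per-vector angle arccos(|v_full . v_loo|) in [0, 90] degrees."""
    dots = np.abs(np.sum(v_full * v_loo, axis=1))
    return np.degrees(np.arccos(np.clip(dots, 0.0, 1.0)))


def loo_validate(
    trials: list[MarkerTrial],
    k_max: int,
    angle_threshold_deg: float = 15.0,
) -> PMSet:
    """Leave-one-subject-out stability validation of the principal movements.

    For each subject, the PMs are recomputed without that subject's trials and
    compared to the full-cohort PMs; a PM is validated when its maximum angle
    over left-out subjects is strictly below the threshold.
    """
    subjects = sorted({tr.subject_id for tr in trials})
    if len(subjects) < 3:
        raise ValueError("leave-one-out validation needs at least 3 subjects")
    full = compute_pms(build_posture_matrix(trials), k_max)
    max_angles = np.zeros(full.k)
    for subj in subjects:
        kept = [tr for tr in trials if tr.subject_id != subj]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = compute_pms(build_posture_matrix(kept), full.k)
        k = min(full.k, loo.k)
        angles = subspace_angles_deg(full.eigenvectors[:k], loo.eigenvectors[:k])
        max_angles[:k] = np.maximum(max_angles[:k], angles)
    full.validation_angles = max_angles
    full.validated = max_angles < angle_threshold_deg
    full.angle_threshold_deg = angle_threshold_deg
    return full
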