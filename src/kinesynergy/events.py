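"""Treadmill gait-event detection and stride segmentation.

Heel strikes on a treadmill are detected kinematically as the anterior peaks
of the heel marker relative to a pelvis reference (coordinate-based
algorithm): at initial contact the foot reaches its most anterior position
relative to the pelvis before the belt carries it backward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import MarkerTrial

__all__ = ["StrideEvents", "detect_heel_strikes", "normalize_strides"]

AP_AXIS = 1  # anterior-posterior = +Y by convention


@dataclass
class StrideEvents:
    """Heel-strike frames of one side plus derived stride windows."""

    side: str
    heel_strike_frames: np.ndarray  # sorted, strictly increasing
    fs: float

    def __post_init__(self) -> None:
        self.heel_strike_frames = np.asarray(self.heel_strike_frames, dtype=int)
        if np.any(np.diff(self.heel_strike_frames) <= 0):
            raise ValueError("heel-strike frames must be strictly increasing")

    @property
    def heel_strike_times(self) -> np.ndarray:
        return self.heel_strike_frames / self.fs

    @property
    def stride_windows(self) -> list[tuple[int, int]]:
        """Half-open [hs_i, hs_{i+1}) frame intervals between same-side strikes."""
        hs = self.heel_strike_frames
        return [(int(hs[i]), int(hs[i + 1])) for i in range(len(hs) - 1)]

    @property
    def n_strides(self) -> int:
        return max(0, len(self.heel_strike_frames) - 1)

    def shifted(self, offset: int) -> "StrideEvents":
        return StrideEvents(self.side, self.heel_strike_frames - offset, self.fs)


def _resolve_marker(trial: MarkerTrial, candidates: list[str]) -> str:
    for lab in candidates:
        if lab in trial.labels:
            return lab
    raise ValueError(
        f"required marker missing: none of {candidates} present in trial "
        f"(labels: {trial.labels})"
    )


def detect_heel_strikes(
    trial: MarkerTrial,
    side: str,
    heel_marker: str | None = None,
    ref_marker: str | None = None,
    ap_axis: int = AP_AXIS,
) -> StrideEvents:
    """Detect heel strikes as anterior peaks of heel-minus-pelvis position.

    Peaks must exceed a prominence of 0.2x the signal interquartile range
    (robust against perturbation artifacts) and be separated by at least
    0.4x the median cycle duration.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    prefix = side[0].upper()
    heel = heel_marker or _resolve_marker(trial, [f"{prefix}HEEL", f"{prefix}ANK"])
    ref = ref_marker or _resolve_marker(trial, ["SACR", "PELV", f"{prefix}HIP"])
    x = trial.marker(heel)[:, ap_axis] - trial.marker(ref)[:, ap_axis]
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    prominence = 0.2 * iqr if iqr > 0 else None
    if prominence is None or prominence <= 0:
        raise ValueError("fewer than 3 cycles detected (flat AP signal)")
    first_pass, _ = find_peaks(x, prominence=prominence)
    if len(first_pass) < 3:
        raise ValueError(f"fewer than 3 cycles detected ({len(first_pass)} peaks)")
    median_cycle = float(np.median(np.diff(first_pass)))
    distance = max(1, int(round(0.4 * median_cycle)))
    peaks, _ = find_peaks(x, prominence=prominence, distance=distance)
    if len(peaks) < 3:
        raise ValueError(f"fewer than 3 cycles detected ({len(peaks)} peaks)")
    return StrideEvents(side=side, heel_strike_frames=peaks, fs=trial.fs)


def normalize_strides(
    series: np.ndarray, events: StrideEvents, n_grid: int = 100
) -> np.ndarray:
    """Time-normalize a signal to ``n_grid`` points per stride (0-100% cycle).

    Returns a (strides, n_grid) array; each stride window is linearly
    interpolated over [hs_i, hs_{i+1}].
    """
    series = np.asarray(series, dtype=float).ravel()
    if events.n_strides < 1:
        raise ValueError("need at least 2 heel strikes to form a stride")
    frames = np.arange(series.size)
    out = np.empty((events.n_strides, n_grid))
    for i, (a, b) in enumerate(events.stride_windows):
        if b >= series.size:
            raise ValueError("stride window extends past the end of the series")
        grid = np.linspace(a, b, n_grid)
        out[i] = np.interp(grid, frames, series)
    return out
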