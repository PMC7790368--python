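"""Marker-trajectory containers, TSV I/O and signal preprocessing.

The on-disk format is a plain TSV dialect: ``#``-prefixed header lines carry
trial metadata (``fs``, ``speed``, ``subject``, ``condition``), followed by a
column header of ``<label>_X``, ``<label>_Y``, ``<label>_Z`` triplets in
meters and one row per frame.  Missing samples are encoded as empty cells /
NaN and surface in :attr:`MarkerTrial.gaps`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "MarkerTrial",
    "UnsupportedFormatError",
    "read_markers",
    "write_markers",
    "fill_gaps",
    "resample_to",
    "lowpass",
    "lowpass_trial",
]


class UnsupportedFormatError(ValueError):
    """Raised when a marker-file format is not available in this build."""


@dataclass
class MarkerTrial:
    """One subject x condition x speed recording of 3-D marker trajectories.

    Attributes
    ----------
    data : ndarray, shape (frames, markers, 3)
        Marker coordinates in meters.  Axis convention: X mediolateral,
        Y anterior-posterior (belt direction +Y), Z vertical.
    gaps : ndarray of bool, shape (frames, markers)
        True where a marker sample is missing.
    """

    subject_id: str
    condition: str
    speed: float
    fs: float
    labels: list[str]
    data: np.ndarray
    gaps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("data must have shape (frames, markers, 3)")
        if self.data.shape[0] < 2:
            raise ValueError("a trial needs at least 2 frames")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("number of labels does not match data")
        if len(set(self.labels)) != len(self.labels):
            dupes = {l for l in self.labels if self.labels.count(l) > 1}
            raise ValueError(f"duplicate marker labels: {sorted(dupes)}")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.condition not in ("normal", "perturbed"):
            raise ValueError("condition must be 'normal' or 'perturbed'")
        if self.gaps is None:
            self.gaps = np.isnan(self.data).any(axis=2)
        self.gaps = np.asarray(self.gaps, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds, spanning first to last sample."""
        return (self.n_frames - 1) / self.fs

    @property
    def key(self) -> tuple[str, float, str]:
        return (self.subject_id, self.speed, self.condition)

    def has_gaps(self) -> bool:
        return bool(self.gaps.any())

    def marker(self, label: str) -> np.ndarray:
        """Return the (frames, 3) trajectory of one marker."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not in trial") from None
        return self.data[:, idx, :]


def write_markers(trial: MarkerTrial, path: str | Path) -> Path:
    """Write a trial to the TSV dialect (meters, one row per frame)."""
    path = Path(path)
    cols = [f"{lab}_{ax}" for lab in trial.labels for ax in "XYZ"]
    flat = trial.data.reshape(trial.n_frames, -1).copy()
    flat[np.repeat(trial.gaps, 3, axis=1)] = np.nan
    with open(path, "w") as fh:
        fh.write(f"# fs={trial.fs!r}\n")
        fh.write(f"# speed={trial.speed!r}\n")
        fh.write(f"# subject={trial.subject_id}\n")
        fh.write(f"# condition={trial.condition}\n")
        pd.DataFrame(flat, columns=cols).to_csv(
            fh, sep="\t", index=False, float_format="%.9g", lineterminator="\n"
        )
    return path


def _parse_tsv(path: Path) -> MarkerTrial:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    cols = list(frame.columns)
    if len(cols) % 3 != 0:
        raise ValueError("column count is not a multiple of 3")
    labels: list[str] = []
    for i in range(0, len(cols), 3):
        trip = cols[i : i + 3]
        stems = [c.rsplit("_", 1)[0] for c in trip]
        axes = [c.rsplit("_", 1)[1] for c in trip]
        if len(set(stems)) != 1 or axes != ["X", "Y", "Z"]:
            raise ValueError(f"malformed column triplet {trip}")
        if stems[0] in labels:
            raise ValueError(f"duplicate marker label: {stems[0]}")
        labels.append(stems[0])
    data = frame.to_numpy(dtype=float).reshape(len(frame), len(labels), 3)
    return MarkerTrial(
        subject_id=meta.get("subject", path.stem),
        condition=meta.get("condition", "normal"),
        speed=float(meta.get("speed", "1.0")),
        fs=float(meta["fs"]),
        labels=labels,
        data=data,
    )


def read_markers(path: str | Path, format: str = "tsv") -> MarkerTrial:
    """Read a marker trial from disk.

    Only the package's TSV dialect is supported; requesting ``c3d`` raises
    :class:`UnsupportedFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "c3d":
        raise UnsupportedFormatError(
            "C3D reading is not available in this build; convert the recording "
            "to the TSV dialect (see write_markers) first"
        )
    if format != "tsv":
        raise ValueError(f"unknown marker format: {format!r}")
    return _parse_tsv(path)


def fill_gaps(trial: MarkerTrial, max_gap: int = 10) -> MarkerTrial:
    """Linearly interpolate gaps of at most ``max_gap`` frames.

    Longer gaps abort with an error: naive interpolation over long dropouts
    would fabricate motion.
    """
    if not trial.has_gaps():
        return trial
    data = trial.data.copy()
    frames = np.arange(trial.n_frames)
    for m in range(trial.n_markers):
        mask = trial.gaps[:, m]
        if not mask.any():
            continue
        runs = _run_lengths(mask)
        if runs.max() > max_gap:
            raise ValueError(
                f"marker {trial.labels[m]!r} has a gap of {runs.max()} frames "
                f"(> {max_gap}); repair the recording before preprocessing"
            )
        if mask.all():
            raise ValueError(f"marker {trial.labels[m]!r} is entirely missing")
        for ax in range(3):
            col = data[:, m, ax]
            col[mask] = np.interp(frames[mask], frames[~mask], col[~mask])
    return replace(trial, data=data, gaps=np.zeros_like(trial.gaps))


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of consecutive True runs in a boolean vector."""
    if not mask.any():
        return np.array([0])
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return edges[1::2] - edges[::2]


def resample_to(trial: MarkerTrial, n_points: int) -> MarkerTrial:
    """Linearly interpolate every coordinate onto a uniform ``n_points`` grid.

    The grid spans the original duration, so the first and last samples are
    preserved exactly; the sampling rate becomes ``(n_points - 1) / duration``
    (the identity when ``n_points`` equals the original frame count).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if trial.has_gaps():
        raise ValueError("trial has gaps; run fill_gaps before resampling")
    if n_points == trial.n_frames:
        return replace(trial, gaps=trial.gaps.copy())
    duration = trial.duration
    t_old = np.arange(trial.n_frames) / trial.fs
    t_new = np.linspace(0.0, duration, n_points)
    flat = trial.data.reshape(trial.n_frames, -1)
    out = np.empty((n_points, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_new, t_old, flat[:, j])
    fs_new = (n_points - 1) / duration
    return replace(
        trial,
        data=out.reshape(n_points, trial.n_markers, 3),
        fs=fs_new,
        gaps=np.zeros((n_points, trial.n_markers), dtype=bool),
    )


def lowpass(
    values: np.ndarray, fs: float, order: int, cutoff_hz: float, axis: int = 0
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Forward-backward filtering doubles the effective order but removes phase
    distortion, which would otherwise corrupt phase-based measures downstream.
    """
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above the Nyquist frequency {nyq} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    values = np.asarray(values, dtype=float)
    # pad generously (~10 filter time constants) so trends pass without edge
    # transients; the default pad is too short for low cutoff/rate ratios
    padlen = min(values.shape[axis] - 1, max(3 * order + 1, int(round(10 * fs / cutoff_hz))))
    return signal.sosfiltfilt(sos, values, axis=axis, padlen=padlen)


def lowpass_trial(trial: MarkerTrial, order: int, cutoff_hz: float) -> MarkerTrial:
    """Apply :func:`lowpass` to every marker coordinate of a trial."""
    if trial.has_gaps():
        raise ValueError("trial has gaps; run fill_gaps before filtering")
    flat = trial.data.reshape(trial.n_frames, -1)
    out = lowpass(flat, trial.fs, order, cutoff_hz, axis=0)
    return replace(trial, data=out.reshape(trial.data.shape))
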