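"""Subject- and frame-level quality control for resting-state fMRI.

Implements the motion and raw-data-quality exclusion rules used in the
white-matter FCS analysis:

* Power's framewise displacement (FD): per-frame sum of absolute backward
  differences of the three translations (mm) plus the three rotations
  (radians) scaled to arc length on a 50 mm sphere.
* Frame flagging at FD > 0.5 mm (motion outliers).
* Subject exclusion by (a) surface-reconstruction Euler number converted to
  a modified Z-score (median/MAD based) with cutoff -3.5, (b) mean FD
  > 0.5 mm, and (c) outlier ratio (flagged frames / total frames) > 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .synthetic import SubjectRecord

__all__ = [
    "MotionTrace",
    "FDSeries",
    "compute_fd",
    "modified_zscore",
    "qc_subjects",
]

#: column order of a rigid-motion parameter table
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: default sphere radius (mm) converting rotations to displacements
DEFAULT_HEAD_RADIUS = 50.0

#: default FD censoring threshold (mm)
FD_THRESHOLD = 0.5


@dataclass
class MotionTrace:
    """Per-frame rigid-body motion parameters.

    ``params`` is a ``frames x 6`` array ordered as three translations in
    millimetres followed by three rotations in radians.  ``spike_frames``
    optionally records frames where a synthetic generator injected a large
    displacement (used as a test oracle; ``None`` for real data).
    """

    params: np.ndarray
    spike_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion trace must be frames x 6, got shape {self.params.shape}"
            )
        bad = ~np.isfinite(self.params)
        if bad.any():
            frame = int(np.argwhere(bad)[0, 0])
            raise ValueError(f"non-finite motion parameter at frame {frame}")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def drop_initial(self, n: int) -> "MotionTrace":
        """Remove the first ``n`` frames (keeps spike bookkeeping aligned)."""
        if n < 0 or n >= self.n_frames:
            raise ValueError(f"cannot drop {n} of {self.n_frames} frames")
        spikes = None
        if self.spike_frames is not None:
            kept = self.spike_frames[self.spike_frames >= n] - n
            spikes = kept
        return MotionTrace(self.params[n:], spikes)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.params, columns=list(MOTION_COLUMNS)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotionTrace":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in MOTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"motion file {path} lacks columns {missing}")
        return cls(df[list(MOTION_COLUMNS)].to_numpy(dtype=float))


@dataclass
class FDSeries:
    """Framewise displacement with outlier flags at a fixed threshold."""

    fd: np.ndarray
    threshold: float = FD_THRESHOLD

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1:
            raise ValueError("FD series must be one-dimensional")
        if (self.fd < 0).any():
            raise ValueError("FD must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.fd.size

    @property
    def flags(self) -> np.ndarray:
        """Boolean motion-outlier flags (FD strictly above threshold)."""
        return self.fd > self.threshold

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())

    @property
    def outlier_ratio(self) -> float:
        return float(self.flags.mean())


def compute_fd(
    trace: MotionTrace,
    head_radius: float = DEFAULT_HEAD_RADIUS,
    rotations_in_degrees: bool = False,
    threshold: float = FD_THRESHOLD,
) -> FDSeries:
    """Power's framewise displacement.

    FD(t) = sum_i |d translation_i(t)| + r * sum_j |d rotation_j(t)| for
    t >= 1 (backward differences); FD(0) = 0 by convention.  Rotations are
    radians unless ``rotations_in_degrees`` is set.
    """
    if head_radius <= 0:
        raise ValueError("head radius must be positive")
    params = trace.params.copy()
    if rotations_in_degrees:
        params[:, 3:] = np.deg2rad(params[:, 3:])
    diffs = np.abs(np.diff(params, axis=0))
    fd_tail = diffs[:, :3].sum(axis=1) + head_radius * diffs[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_tail])
    return FDSeries(fd, threshold=threshold)


def modified_zscore(values: Sequence[float]) -> np.ndarray:
    """Median/MAD-based modified Z-scores.

    score_i = 0.6745 * (x_i - median) / MAD with MAD = median(|x - median|).
    When the MAD is zero the mean absolute deviation fallback
    0.6745 * (x_i - median) / (1.253314 * meanAD) is used; all-equal input
    yields all-zero scores.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("modified_zscore requires at least 3 values")
    if not np.isfinite(x).all():
        raise ValueError("modified_zscore requires finite values")
    med = np.median(x)
    absdev = np.abs(x - med)
    mad = np.median(absdev)
    if mad > 0:
        return 0.6745 * (x - med) / mad
    mean_ad = absdev.mean()
    if mean_ad == 0:
        return np.zeros_like(x)
    return 0.6745 * (x - med) / (1.253314 * mean_ad)


def qc_subjects(
    records: "Sequence[SubjectRecord]",
    fd_series: Mapping[str, FDSeries],
    euler_threshold: float = -3.5,
    mean_fd_max: float = FD_THRESHOLD,
    ratio_max: float = 0.3,
) -> pd.DataFrame:
    """Apply the subject-level exclusion rules across a cohort.

    A subject is excluded when the Euler-number modified Z-score falls below
    ``euler_threshold``, or the mean FD exceeds ``mean_fd_max``, or the
    motion-outlier ratio exceeds ``ratio_max`` (any single rule triggers
    exclusion).  Mean FD is written back onto each record so it can serve as
    a model covariate downstream.

    Returns one row per subject with all metrics, the inclusion decision and
    the enumerated exclusion reasons.
    """
    if len(records) < 3:
        raise ValueError("QC needs at least 3 subjects for the Euler Z-score")
    for rec in records:
        if rec.subject_id not in fd_series:
            raise ValueError(f"missing FD series for subject {rec.subject_id}")

    eulers = [rec.euler_number for rec in records]
    euler_z = modified_zscore(eulers)

    rows = []
    for rec, ez in zip(records, euler_z):
        fd = fd_series[rec.subject_id]
        rec.mean_fd = fd.mean_fd
        reasons = []
        if ez < euler_threshold:
            reasons.append("euler")
        if fd.mean_fd > mean_fd_max:
            reasons.append("mean_fd")
        if fd.outlier_ratio > ratio_max:
            reasons.append("outlier_ratio")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "euler_number": rec.euler_number,
                "euler_z": ez,
                "mean_fd": fd.mean_fd,
                "outlier_ratio": fd.outlier_ratio,
                "n_frames": fd.n_frames,
                "n_outliers": int(fd.flags.sum()),
                "included": not reasons,
                "exclusion_reasons": ";".join(reasons),
            }
        )
    report = pd.DataFrame(rows)
    n_excl = int((~report["included"]).sum())
    if n_excl:
        warnings.warn(f"QC excluded {n_excl} of {len(records)} subjects")
    return report
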