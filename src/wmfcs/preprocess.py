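"""Frame-level cleaning of region time series.

The canonical order is: drop initial volumes -> framewise displacement ->
censor/interpolate motion outliers -> nuisance regression (Friston-24 motion
model plus linear and quadratic trends) -> high-pass filtering at 0.01 Hz.
Each stage records its name in the series' ``stages`` provenance tuple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .qc import FDSeries, MotionTrace, compute_fd

__all__ = [
    "RegionTimeSeries",
    "NuisanceDesign",
    "drop_initial_volumes",
    "censor_interpolate",
    "build_friston24",
    "nuisance_regress",
    "highpass",
    "clean_timeseries",
]

#: number of leading volumes discarded to let magnetisation reach steady state
DEFAULT_DROP = 5

#: high-pass cutoff in Hz
DEFAULT_CUTOFF = 0.01


@dataclass
class RegionTimeSeries:
    """Regions x frames signal matrix with per-frame provenance.

    ``frame_source`` marks each frame ``raw`` or ``interpolated``; ``stages``
    accumulates the names of cleaning stages already applied, in order.
    """

    data: np.ndarray
    region_ids: np.ndarray
    tr: float
    frame_source: np.ndarray = field(default=None)  # type: ignore[assignment]
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("region time series must be regions x frames")
        self.region_ids = np.asarray(self.region_ids)
        if self.region_ids.size != self.data.shape[0]:
            raise ValueError("region id count does not match row count")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.frame_source is None:
            self.frame_source = np.full(self.n_frames, "raw", dtype=object)
        self.frame_source = np.asarray(self.frame_source, dtype=object)
        if self.frame_source.size != self.n_frames:
            raise ValueError("frame_source length does not match frame count")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write frames x regions TSV with region ids as header."""
        pd.DataFrame(self.data.T, columns=[str(r) for r in self.region_ids]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float) -> "RegionTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float).T, np.asarray(df.columns), tr)


@dataclass
class NuisanceDesign:
    """Frames x 26 nuisance matrix: Friston-24 motion columns plus trends.

    Column order: the 6 rigid parameters, the 6 one-frame-lagged parameters
    (zero-padded at the first frame), their squares, the lagged squares, then
    a linear and a quadratic trend over the frame index.
    """

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("nuisance design contains non-finite values")
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count does not match design columns")


def drop_initial_volumes(
    ts: RegionTimeSeries, trace: MotionTrace, n: int = DEFAULT_DROP
) -> tuple[RegionTimeSeries, MotionTrace]:
    """Discard the first ``n`` frames from both signal and motion."""
    if n < 0:
        raise ValueError("number of dropped volumes must be non-negative")
    if n >= ts.n_frames:
        raise ValueError(f"cannot drop {n} of {ts.n_frames} frames")
    if trace.n_frames != ts.n_frames:
        raise ValueError("motion trace and time series disagree on frame count")
    out = replace(
        ts,
        data=ts.data[:, n:].copy(),
        frame_source=ts.frame_source[n:].copy(),
        stages=ts.stages + ("drop_initial_volumes",),
    )
    return out, (trace.drop_initial(n) if n else trace)


def censor_interpolate(
    ts: RegionTimeSeries, fd: FDSeries, threshold: float = 0.5
) -> RegionTimeSeries:
    """Replace motion-outlier frames by linear interpolation.

    Frames with FD above ``threshold`` are replaced region-wise by linear
    interpolation between the nearest unflagged neighbours; flagged frames at
    either edge take the nearest unflagged value.  Unflagged frames are left
    untouched bit-for-bit.
    """
    if fd.n_frames != ts.n_frames:
        raise ValueError("FD series and time series disagree on frame count")
    flags = fd.fd > threshold
    if flags.all():
        raise ValueError("all frames are motion outliers; cannot interpolate")
    data = ts.data.copy()
    if flags.any():
        idx = np.arange(ts.n_frames)
        good = idx[~flags]
        bad = idx[flags]
        for row in data:
            row[bad] = np.interp(bad, good, row[good])
    source = ts.frame_source.copy()
    source[flags] = "interpolated"
    return replace(
        ts, data=data, frame_source=source, stages=ts.stages + ("censor_interpolate",)
    )


def build_friston24(trace: MotionTrace) -> NuisanceDesign:
    """Friston 24-parameter motion model plus linear and quadratic trends.

    The 24 motion columns are [p(t), p(t-1), p(t)^2, p(t-1)^2] for the six
    rigid parameters, with the lagged columns zero-padded at the first frame.
    The trends are centred polynomials over the frame index.
    """
    if trace.n_frames < 2:
        raise ValueError("Friston-24 design needs at least 2 frames")
    p = trace.params
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    n = trace.n_frames
    t = np.arange(n, dtype=float)
    lin = t - t.mean()
    quad = lin**2 - (lin**2).mean()
    cols = np.column_stack([p, lag, p**2, lag**2, lin, quad])
    names = list(
        f"{base}{suffix}"
        for suffix in ("", "_lag", "_sq", "_lag_sq")
        for base in ("tx", "ty", "tz", "rx", "ry", "rz")
    ) + ["trend_lin", "trend_quad"]
    return NuisanceDesign(cols, tuple(names))


def nuisance_regress(
    ts: RegionTimeSeries, design: NuisanceDesign
) -> RegionTimeSeries:
    """Per-region ordinary least squares residualisation.

    An intercept is always included.  Rank deficiency (collinear or constant
    columns, or fewer frames than columns) is handled by the minimum-norm
    least-squares solution with a warning; residuals remain orthogonal to the
    full column space either way.
    """
    X = np.column_stack([np.ones(ts.n_frames), design.matrix])
    if X.shape[0] != ts.n_frames:
        raise ValueError("design and time series disagree on frame count")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient (rank {rank} of {X.shape[1]} columns)"
        )
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data - (X @ beta).T
    return replace(ts, data=resid, stages=ts.stages + ("nuisance_regress",))


def _dct_low_freq(n_frames: int, tr: float, cutoff: float) -> np.ndarray:
    """DCT-II basis columns with frequency below ``cutoff`` (mean excluded)."""
    t = np.arange(n_frames)
    ks = []
    for k in range(1, n_frames):
        freq = k / (2.0 * n_frames * tr)
        if freq < cutoff:
            ks.append(k)
        else:
            break
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_frames)) for k in ks]
    if not cols:
        return np.empty((n_frames, 0))
    return np.column_stack(cols)


def highpass(
    ts: RegionTimeSeries, cutoff: float = DEFAULT_CUTOFF
) -> RegionTimeSeries:
    """High-pass filter by projecting out slow discrete-cosine components.

    All DCT basis functions with frequency below ``cutoff`` (plus the mean)
    are regressed out; components at or above the cutoff pass through the
    linear projection essentially unchanged.
    """
    if ts.n_frames < 8:
        raise ValueError("high-pass filtering needs at least 8 frames")
    nyquist = 1.0 / (2.0 * ts.tr)
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist {nyquist} Hz")
    low = _dct_low_freq(ts.n_frames, ts.tr, cutoff)
    X = np.column_stack([np.ones(ts.n_frames), low])
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data - (X @ beta).T
    return replace(ts, data=resid, stages=ts.stages + ("highpass",))


def clean_timeseries(
    ts: RegionTimeSeries,
    trace: MotionTrace,
    n_drop: int = DEFAULT_DROP,
    fd_threshold: float = 0.5,
    cutoff: float = DEFAULT_CUTOFF,
    head_radius: float = 50.0,
) -> tuple[RegionTimeSeries, FDSeries]:
    """Run the full cleaning pipeline in canonical order.

    Nuisance regression and high-pass filtering are applied as a single
    joint projection (the union of the Friston-24/trend columns and the
    slow DCT basis), so the cleaned data are orthogonal to both spans;
    sequential residualisation would let the second step reintroduce
    variance along the first step's columns because the trend and slow DCT
    regressors overlap.  Returns the cleaned series together with the FD
    series computed on the volume-dropped motion trace (the same frames the
    flags index).
    """
    ts, trace = drop_initial_volumes(ts, trace, n_drop)
    fd = compute_fd(trace, head_radius=head_radius, threshold=fd_threshold)
    ts = censor_interpolate(ts, fd, threshold=fd_threshold)
    design = build_friston24(trace)
    nyquist = 1.0 / (2.0 * ts.tr)
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist {nyquist} Hz")
    low = _dct_low_freq(ts.n_frames, ts.tr, cutoff)
    joint = NuisanceDesign(
        np.column_stack([design.matrix, low]),
        design.labels + tuple(f"dct_{k + 1}" for k in range(low.shape[1])),
    )
    ts = nuisance_regress(ts, joint)
    ts = replace(ts, stages=ts.stages[:-1] + ("nuisance_regress", "highpass"))
    if not np.isfinite(ts.data).all():
        raise ValueError("non-finite values after cleaning")
    return ts, fd
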