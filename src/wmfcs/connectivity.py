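"""Fisher-z functional connectivity and region-wise connectivity strength.

The connectivity matrix is the Fisher z-transform (atanh) of the Pearson
correlation between every pair of region time series.  Two degree-like
statistics summarise it:

* WW-FCS: for each white-matter region, the mean z with the other WM regions.
* GW-FCS: for each gray-matter region, the mean z with all WM regions.

Raw z values are averaged as-is (negative values included); correlations are
clipped to |r| <= 1 - 1e-7 before atanh so z stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme
from .preprocess import RegionTimeSeries

__all__ = ["FCMatrix", "fc_matrix", "ww_fcs", "gw_fcs", "subject_fcs"]

#: correlations are clipped to +-(1 - CLIP_EPS) before the z-transform
CLIP_EPS = 1e-7


@dataclass
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix with a masked (NaN) diagonal."""

    z: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("FC matrix must be square")
        if len(self.names) != n:
            raise ValueError("name count does not match matrix size")
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(self.z[off])
        valid = ~np.isnan(self.z[off])
        if (~finite & valid).any():
            raise ValueError("FC matrix has infinite off-diagonal entries")

    @property
    def n(self) -> int:
        return self.z.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.z, columns=list(self.names)).to_csv(
            path, sep="\t", index=False
        )


def fc_matrix(ts: RegionTimeSeries, clip_eps: float = CLIP_EPS) -> FCMatrix:
    """Fisher-z transformed Pearson correlation between all region pairs.

    Zero-variance (or all-NaN) regions yield NaN rows/columns and a warning;
    |r| is clipped at 1 - ``clip_eps`` (with a warning when clipping fires on
    an off-diagonal pair).
    """
    if ts.n_frames < 3:
        raise ValueError("correlation needs at least 3 frames")
    data = ts.data
    valid = np.isfinite(data).all(axis=1) & (data.std(axis=1) > 0)
    if not valid.any():
        raise ValueError("no region has a valid, varying time series")
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} region(s) with zero variance or missing data; "
            "their FC entries are set to NaN"
        )
    n = ts.n_regions
    r = np.full((n, n), np.nan)
    sub = np.corrcoef(data[valid])
    r[np.ix_(valid, valid)] = sub
    off = ~np.eye(n, dtype=bool)
    clipped = np.abs(r[off]) > 1 - clip_eps
    if np.nansum(clipped) > 0:
        warnings.warn(
            f"{int(np.nansum(clipped))} off-diagonal correlation(s) clipped to "
            f"|r| = 1 - {clip_eps:g} before the z-transform"
        )
    r = np.clip(r, -(1 - clip_eps), 1 - clip_eps)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(z, np.nan)
    names = tuple(str(i) for i in ts.region_ids)
    return FCMatrix(z, names)


def _family_means(z_rows: np.ndarray) -> np.ndarray:
    """Row-wise mean ignoring NaN; all-NaN rows give NaN without warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(z_rows, axis=1)


def ww_fcs(fc: FCMatrix, scheme: ParcellationScheme) -> pd.Series:
    """Per-WM-region mean Fisher-z connectivity with the other WM regions.

    The self-pair is excluded (the diagonal is NaN); missing neighbours are
    dropped from the mean.  Returns a Series indexed by region name.
    """
    wm = scheme.wm_indices
    if wm.size < 2:
        raise ValueError("WW-FCS needs at least 2 WM regions")
    block = fc.z[np.ix_(wm, wm)]
    values = _family_means(block)
    return pd.Series(values, index=[scheme.names[i] for i in wm], name="ww_fcs")


def gw_fcs(fc: FCMatrix, scheme: ParcellationScheme) -> pd.Series:
    """Per-GM-region mean Fisher-z connectivity with all WM regions."""
    wm = scheme.wm_indices
    gm = scheme.gm_indices
    if wm.size < 1:
        raise ValueError("GW-FCS needs a non-empty WM family")
    block = fc.z[np.ix_(gm, wm)]
    values = _family_means(block)
    return pd.Series(values, index=[scheme.names[i] for i in gm], name="gw_fcs")


def subject_fcs(
    ts: RegionTimeSeries, scheme: ParcellationScheme, subject_id: str | None = None
) -> pd.DataFrame:
    """Long-format FCS table (region, family, value) for one subject."""
    fc = fc_matrix(ts)
    ww = ww_fcs(fc, scheme)
    gw = gw_fcs(fc, scheme)
    df = pd.concat(
        [
            pd.DataFrame({"region": ww.index, "family": "WW", "value": ww.to_numpy()}),
            pd.DataFrame({"region": gw.index, "family": "GW", "value": gw.to_numpy()}),
        ],
        ignore_index=True,
    )
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df
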