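"""Sliding-window dynamic functional connectivity (dFC).

A scan of T timepoints over r regions yields w̃ = floor((T−w)/S) + 1 windows
of length w at stride S. Each window's r × r Pearson correlation matrix is
vectorized to its upper triangle (r̃ = r(r−1)/2 entries, row-major pair
order), giving an r̃ × w̃ matrix whose columns — "frames" — are the unit of
all downstream fingerprinting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NumericalError
from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


def upper_tri_dim(r: int) -> int:
    """Number of unique region pairs, r(r−1)/2."""
    r = int(r)
    if r < 2:
        raise ConfigError(f"need at least 2 regions, got {r}")
    return r * (r - 1) // 2


def num_frames(t: int, window: int, stride: int) -> int:
    """Number of sliding windows, floor((T−w)/S) + 1.

    Trailing timepoints not covered by a full window are discarded.
    """
    t, window, stride = int(t), int(window), int(stride)
    if stride < 1:
        raise ConfigError(f"stride must be >= 1, got {stride}")
    if window < 2:
        raise ConfigError(f"window must be >= 2 timepoints, got {window}")
    if window > t:
        raise ConfigError(f"window {window} exceeds scan length {t}")
    return (t - window) // stride + 1


def seconds_to_timepoints(seconds: float, tr: float) -> int:
    """Convert a duration in seconds to timepoints by rounding seconds/TR."""
    if tr <= 0:
        raise ConfigError(f"tr must be positive, got {tr}")
    n = int(round(seconds / tr))
    if n < 1:
        raise ConfigError(f"{seconds}s is shorter than one timepoint at tr={tr}s")
    return n


def make_pair_index(region_ids) -> tuple[tuple[str, str], ...]:
    """Row-major upper-triangle pair order: (1,2), (1,3), …, (1,r), (2,3), …"""
    ids = [str(i) for i in region_ids]
    return tuple(
        (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
    )


def _regions_from_pairs(pair_index) -> tuple[str, ...]:
    # invert make_pair_index: the first r-1 pairs are (id_0, id_1..id_{r-1})
    r_tilde = len(pair_index)
    r = int(round((1 + np.sqrt(1 + 8 * r_tilde)) / 2))
    if r * (r - 1) // 2 != r_tilde:
        raise DataError(f"pair index length {r_tilde} is not a triangular number")
    if r == 2:
        return (pair_index[0][0], pair_index[0][1])
    return (pair_index[0][0],) + tuple(p[1] for p in pair_index[: r - 1])


@dataclass(frozen=True)
class DfcMatrix:
    """Vectorized sliding-window dFC for one scan.

    ``values`` is r̃ × w̃ with entries in [−1, 1]; row k of ``pair_index``
    names the region pair of row k of ``values``. ``window``/``stride``/
    ``source_t`` are in timepoints.
    """

    values: np.ndarray
    window: int
    stride: int
    source_t: int
    pair_index: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataError(f"dFC values must be 2-D, got shape {values.shape}")
        # forgive float rounding just past ±1, reject anything genuinely outside
        if np.nanmax(np.abs(values), initial=0.0) > 1.0 + 1e-9:
            raise DataError("dFC contains correlations outside [-1, 1]")
        if not np.all(np.isfinite(values)):
            raise DataError("dFC contains non-finite values")
        values = np.clip(values, -1.0, 1.0)
        object.__setattr__(self, "values", values)
        pairs = tuple((str(a), str(b)) for a, b in self.pair_index)
        object.__setattr__(self, "pair_index", pairs)
        if len(pairs) != values.shape[0]:
            raise DataError(
                f"{len(pairs)} pairs for {values.shape[0]} rows"
            )
        expected = num_frames(self.source_t, self.window, self.stride)
        if values.shape[1] != expected:
            raise DataError(
                f"{values.shape[1]} frames but floor((T-w)/S)+1 = {expected}"
            )
        _regions_from_pairs(pairs)  # validates triangular structure

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def region_ids(self) -> tuple[str, ...]:
        return _regions_from_pairs(self.pair_index)


def sliding_window_dfc(
    ts: RoiTimeSeries, window: int, stride: int, on_zero_variance: str = "raise"
) -> DfcMatrix:
    """Compute the sliding-window dFC matrix of one scan.

    Frame k covers timepoints [k·S, k·S + w). A region with zero variance
    inside a window has no defined correlation; by default this raises,
    naming the region and frame. ``on_zero_variance="zero"`` instead writes 0
    for that region's pairs and logs a warning.
    """
    if on_zero_variance not in ("raise", "zero"):
        raise ConfigError(f"on_zero_variance must be 'raise' or 'zero', got {on_zero_variance!r}")
    n_out = num_frames(ts.n_timepoints, window, stride)
    r = ts.n_regions
    iu = np.triu_indices(r, k=1)
    frames = np.empty((upper_tri_dim(r), n_out))
    for k in range(n_out):
        block = ts.data[k * stride : k * stride + window]
        # a constant column has exactly zero range; std alone can round to ~1e-16
        dead = np.flatnonzero(np.ptp(block, axis=0) == 0)
        if dead.size:
            rid = ts.region_ids[dead[0]]
            if on_zero_variance == "raise":
                raise NumericalError(
                    f"region {rid!r} has zero variance in frame {k} "
                    f"(timepoints {k * stride}..{k * stride + window})"
                )
            logger.warning(
                "zero-variance region %r in frame %d; writing 0 for its pairs", rid, k
            )
            corr = np.zeros((r, r))
            alive = np.flatnonzero(np.ptp(block, axis=0) > 0)
            if alive.size >= 2:
                sub = np.corrcoef(block[:, alive].T)
                corr[np.ix_(alive, alive)] = sub
        else:
            corr = np.corrcoef(block.T)
        frames[:, k] = corr[iu]
    np.clip(frames, -1.0, 1.0, out=frames)
    return DfcMatrix(
        values=frames,
        window=int(window),
        stride=int(stride),
        source_t=ts.n_timepoints,
        pair_index=make_pair_index(ts.region_ids),
    )


def devectorize_frame(frame: np.ndarray, pair_index) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix of one vectorized frame."""
    frame = np.asarray(frame, dtype=float).ravel()
    if frame.size != len(pair_index):
        raise DataError(
            f"frame length {frame.size} does not match pair index ({len(pair_index)})"
        )
    regions = _regions_from_pairs(tuple((str(a), str(b)) for a, b in pair_index))
    r = len(regions)
    out = np.eye(r)
    iu = np.triu_indices(r, k=1)
    out[iu] = frame
    out[(iu[1], iu[0])] = frame
    return out


# ---------------------------------------------------------------------------
# Persistence (.npz container; layout documented here and in docs/methods.md)
# ---------------------------------------------------------------------------
# keys: format_version, values (r̃ × w̃ float64), window, stride, source_t,
#       pair_a, pair_b (str arrays of length r̃)

def save_dfc(dfc: DfcMatrix, path: str | Path) -> None:
    np.savez_compressed(
        path,
        format_version=_FORMAT_VERSION,
        values=dfc.values,
        window=dfc.window,
        stride=dfc.stride,
        source_t=dfc.source_t,
        pair_a=np.array([p[0] for p in dfc.pair_index]),
        pair_b=np.array([p[1] for p in dfc.pair_index]),
    )


def load_dfc(path: str | Path) -> DfcMatrix:
    with np.load(path, allow_pickle=False) as npz:
        if int(npz["format_version"]) != _FORMAT_VERSION:
            raise DataError(f"unsupported dFC container version in {path}")
        pairs = tuple(zip(npz["pair_a"].tolist(), npz["pair_b"].tolist()))
        return DfcMatrix(
            values=npz["values"],
            window=int(npz["window"]),
            stride=int(npz["stride"]),
            source_t=int(npz["source_t"]),
            pair_index=pairs,
        )


def export_frame_tsv(dfc: DfcMatrix, frame: int, path: str | Path) -> None:
    """Write one frame as a (pair, correlation) TSV table."""
    if not 0 <= frame < dfc.n_frames:
        raise ConfigError(f"frame {frame} out of range 0..{dfc.n_frames - 1}")
    table = pd.DataFrame(
        {
            "region_a": [p[0] for p in dfc.pair_index],
            "region_b": [p[1] for p in dfc.pair_index],
            "r": dfc.values[:, frame],
        }
    )
    table.to_csv(path, sep="\t", index=False)
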