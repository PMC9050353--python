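"""Standardization, tiling, and linearization of TFR grids into feature vectors.

The four estimators produce grids with heterogeneous native binning (the
wavelet methods bin time at the sampling rate, the spectrogram at its hop,
the quadratic distributions at rates fixed by the DFT geometry).  To compare
them, every grid is resampled by bicubic interpolation onto one standard
grid (default 1 ms x 0.5 Hz bins), averaged over a rectangular tiling, and
linearized frequency-major into a fixed-length vector.  A dataset-level
normalization (global min-max or per-sample z-scoring) finishes the feature
matrix fed to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .tfr import Signal, TFRGrid, compute_tfr

__all__ = [
    "StandardGridSpec",
    "TileSpec",
    "LabeledDataset",
    "standardize_grid",
    "tile_and_linearize",
    "normalize_dataset",
    "build_dataset",
    "PROTOCOL_GRIDS",
]


@dataclass(frozen=True)
class StandardGridSpec:
    """Uniform target grid: bin sizes plus the analysis windows.

    Defaults: 1 ms time bins and 0.5 Hz frequency bins.  Bins are
    cell-centered: the axis holds ``start + (i + 0.5) * bin``.
    """

    time_window: tuple[float, float]
    freq_window: tuple[float, float]
    time_bin: float = 0.001
    freq_bin: float = 0.5

    def __post_init__(self) -> None:
        if self.time_bin <= 0 or self.freq_bin <= 0:
            raise ValueError("bin sizes must be positive")
        if self.time_window[1] <= self.time_window[0]:
            raise ValueError("time_window must be non-empty")
        if self.freq_window[1] <= self.freq_window[0]:
            raise ValueError("freq_window must be non-empty")

    def time_axis(self) -> np.ndarray:
        start, end = self.time_window
        n = int(round((end - start) / self.time_bin))
        return start + (np.arange(n) + 0.5) * self.time_bin

    def freq_axis(self) -> np.ndarray:
        start, end = self.freq_window
        n = int(round((end - start) / self.freq_bin))
        return start + (np.arange(n) + 0.5) * self.freq_bin


@dataclass(frozen=True)
class TileSpec:
    """Rectangular tiling of the standard grid (counts, not sizes)."""

    n_time_tiles: int
    n_freq_tiles: int

    def __post_init__(self) -> None:
        if self.n_time_tiles < 1 or self.n_freq_tiles < 1:
            raise ValueError("tile counts must be >= 1")

    @property
    def n_features(self) -> int:
        return self.n_time_tiles * self.n_freq_tiles


@dataclass
class LabeledDataset:
    """Linearized tile features with class labels and reshaping geometry."""

    features: np.ndarray  # (n_samples, D)
    labels: np.ndarray  # (n_samples,) integer classes
    tile_spec: TileSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("one label per feature row required")
        if self.features.shape[1] != self.tile_spec.n_features:
            raise ValueError(
                f"feature dimension {self.features.shape[1]} does not match "
                f"tiling {self.tile_spec.n_freq_tiles} x {self.tile_spec.n_time_tiles}"
            )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features[idx], self.labels[idx], self.tile_spec, dict(self.provenance)
        )


# Per-protocol standard grids and tilings; time/frequency windows and
# feature dimensionalities follow the canonical analysis geometry
# (RF: 3 s x 50-70 Hz -> 30 x 20 tiles = 600 features; SRCS: 4 s x 20 Hz band
# -> 40 x 20 = 800; EEG: 0.3-1.0 s x 5-55 Hz -> 14 x 25 = 350).
PROTOCOL_GRIDS: dict[str, tuple[StandardGridSpec, TileSpec]] = {
    "rf": (
        StandardGridSpec(time_window=(0.0, 3.0), freq_window=(50.0, 70.0)),
        TileSpec(n_time_tiles=30, n_freq_tiles=20),
    ),
    "srcs1": (
        StandardGridSpec(time_window=(0.0, 4.0), freq_window=(35.0, 55.0)),
        TileSpec(n_time_tiles=40, n_freq_tiles=20),
    ),
    "srcs2": (
        StandardGridSpec(time_window=(0.0, 4.0), freq_window=(30.0, 50.0)),
        TileSpec(n_time_tiles=40, n_freq_tiles=20),
    ),
    "eeg": (
        StandardGridSpec(time_window=(0.3, 1.0), freq_window=(5.0, 55.0)),
        TileSpec(n_time_tiles=14, n_freq_tiles=25),
    ),
}


def standardize_grid(grid: TFRGrid, spec: StandardGridSpec) -> TFRGrid:
    """Resample a grid onto the standard axes by bicubic interpolation."""
    t_new = spec.time_axis()
    f_new = spec.freq_axis()
    _check_coverage("time", t_new, grid.time_axis)
    _check_coverage("frequency", f_new, grid.freq_axis)

    kx = min(3, grid.freq_axis.size - 1)
    ky = min(3, grid.time_axis.size - 1)
    if kx < 1 or ky < 1:
        raise ValueError("grid too small to interpolate")
    spline = RectBivariateSpline(
        grid.freq_axis, grid.time_axis, grid.values, kx=kx, ky=ky, s=0
    )
    values = spline(f_new, t_new)
    return TFRGrid(
        values=values,
        freq_axis=f_new,
        time_axis=t_new,
        method=grid.method,
        params={**grid.params, "standardized": True},
    )


def _check_coverage(name: str, target: np.ndarray, source: np.ndarray) -> None:
    # half-bin slack: cell centers may poke marginally past the native axis
    slack = 0.5 * (target[1] - target[0]) + 1e-9 if target.size > 1 else 1e-9
    if target[0] < source[0] - slack or target[-1] > source[-1] + slack:
        raise ValueError(
            f"requested {name} window [{target[0]:g}, {target[-1]:g}] outside the "
            f"grid coverage [{source[0]:g}, {source[-1]:g}]"
        )


def tile_and_linearize(grid: TFRGrid, tiles: TileSpec) -> np.ndarray:
    """Average the grid over the tiling and linearize frequency-major.

    Order: frequency tiles low -> high; within each frequency band, time
    tiles low -> high.  The standard-grid shape must be divisible by the
    tile counts; a remainder smaller than one tile is trimmed from the
    trailing edge, anything larger is an error.
    """
    values = grid.values
    values = _trim_divisible(values, tiles.n_freq_tiles, axis=0)
    values = _trim_divisible(values, tiles.n_time_tiles, axis=1)
    nf, nt = tiles.n_freq_tiles, tiles.n_time_tiles
    hf, ht = values.shape[0] // nf, values.shape[1] // nt
    tiled = values.reshape(nf, hf, nt, ht).mean(axis=(1, 3))
    return tiled.reshape(-1)


def _trim_divisible(values: np.ndarray, n_tiles: int, axis: int) -> np.ndarray:
    size = values.shape[axis]
    if size < n_tiles:
        raise ValueError(
            f"grid axis of length {size} cannot be split into {n_tiles} tiles"
        )
    height = size // n_tiles
    rem = size - height * n_tiles
    if rem == 0:
        return values
    if rem >= height:
        raise ValueError(
            f"grid axis of length {size} is not divisible into {n_tiles} tiles "
            f"(remainder {rem} exceeds the tile size {height})"
        )
    slicer = [slice(None)] * values.ndim
    slicer[axis] = slice(0, height * n_tiles)
    return values[tuple(slicer)]


def normalize_dataset(ds: LabeledDataset, mode: str | tuple) -> LabeledDataset:
    """Normalize the feature matrix.

    ``mode`` is either ``("global_minmax", lo, hi)`` (one affine map over the
    whole matrix sending its global min/max to ``lo``/``hi``), the string
    ``"per_sample_zscore"`` (each row to mean 0, sd 1), or ``"none"``.
    """
    X = ds.features
    if mode == "none" or mode is None:
        return ds
    if isinstance(mode, (tuple, list)) and mode[0] == "global_minmax":
        _, lo, hi = mode
        gmin, gmax = X.min(), X.max()
        if gmax == gmin:
            raise ValueError("global min-max scaling undefined for a constant matrix")
        Xn = lo + (X - gmin) * (hi - lo) / (gmax - gmin)
        prov = {**ds.provenance, "normalize": f"global_minmax({lo}, {hi})"}
    elif mode == "per_sample_zscore":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            bad = int(np.where(sd.ravel() == 0)[0][0])
            raise ValueError(f"z-scoring undefined for constant sample row {bad}")
        Xn = (X - mu) / sd
        prov = {**ds.provenance, "normalize": "per_sample_zscore"}
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return LabeledDataset(Xn, ds.labels, ds.tile_spec, prov)


# min-max target range used for the LFP-like protocols (an arbitrary but
# fixed configuration constant); EEG-like data is z-scored per sample
LFP_MINMAX_RANGE = (-3.3823, 1.323)


def build_dataset(
    signals: Sequence[Signal],
    labels: Sequence[int],
    method: str,
    grid_spec: StandardGridSpec,
    tiles: TileSpec,
    normalize_mode: str | tuple = "none",
    method_kwargs: dict | None = None,
) -> LabeledDataset:
    """Run tfr -> standardize -> tile -> linearize per trial, then normalize.

    Wavelet methods get a native frequency axis at the standard resolution
    covering the requested frequency window; spectrogram and quadratic
    distributions compute on their native axes and are restricted to a
    slightly padded window before interpolation.  Row order preserves trial
    order.
    """
    if len(signals) != len(labels):
        raise ValueError("one label per signal required")
    if len(signals) == 0:
        raise ValueError("empty signal list")
    fs = signals[0].sampling_rate
    if any(s.sampling_rate != fs for s in signals):
        raise ValueError("all trials must share one sampling rate")

    method_kwargs = dict(method_kwargs or {})
    lo, hi = grid_spec.freq_window
    pad = 2.0 * grid_spec.freq_bin
    rows = []
    for i, sig in enumerate(signals):
        try:
            if method in ("cwt", "slt"):
                freqs = np.arange(
                    max(grid_spec.freq_bin, lo - pad), hi + pad + 1e-9, grid_spec.freq_bin
                )
                freqs = freqs[freqs < sig.nyquist]
                grid = compute_tfr(sig, method, freqs=freqs, **method_kwargs)
            else:
                grid = compute_tfr(
                    sig,
                    method,
                    freq_range=(max(0.0, lo - pad), hi + pad),
                    **method_kwargs,
                )
            std = standardize_grid(grid, grid_spec)
            rows.append(tile_and_linearize(std, tiles))
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed on trial {i}: {exc}") from exc

    ds = LabeledDataset(
        np.vstack(rows),
        np.asarray(labels, dtype=int),
        tiles,
        provenance={
            "method": method,
            "method_kwargs": method_kwargs,
            "grid_spec": grid_spec,
        },
    )
    return normalize_dataset(ds, normalize_mode)
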