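"""Gaze-stream cleaning, dwell-density maps and image-coverage curves.

Gaze is sampled at 500 Hz during the initial free viewing of each image.
After removing blinks and out-of-image samples, each retained sample carries
one sampling interval (2 ms) of dwell time.  The dwell map spreads that time
over pixels with an isotropic Gaussian kernel (sigma = 10 px, truncated at
4 sigma, renormalized within the image so total dwell is conserved), and is
downsampled mass-preservingly to the 15x15 analysis grid.  Coverage is the
percent of grid cells visited by at least one sample within a cumulative
time window from viewing onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "GazeStream",
    "GazeDensityMap",
    "CoverageCurve",
    "clean_gaze",
    "gaze_density",
    "downsample_density",
    "coverage",
    "coverage_curve",
]

SAMPLE_INTERVAL_S = 0.002  # EyeLink at 500 Hz


@dataclass
class GazeStream:
    """Time-stamped gaze samples (seconds, pixels) with validity flags."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    epoch: str = "initial_viewing"  # instructions | initial_viewing | trial

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("sample arrays must align")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def _take(self, mask: np.ndarray) -> "GazeStream":
        return GazeStream(self.t[mask], self.x[mask], self.y[mask],
                          self.valid[mask], self.epoch)

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(
            {"t_s": self.t, "x_px": self.x, "y_px": self.y,
             "valid": self.valid.astype(int)}
        ).to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_file(cls, path: str | Path, epoch: str = "initial_viewing") -> "GazeStream":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(df["t_s"].to_numpy(), df["x_px"].to_numpy(),
                   df["y_px"].to_numpy(), df["valid"].to_numpy().astype(bool),
                   epoch)


@dataclass
class GazeDensityMap:
    """Per-pixel dwell time (seconds); values are non-negative."""

    values: np.ndarray
    total_dwell: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("dwell values must be non-negative")
        self.total_dwell = float(self.values.sum())


@dataclass
class CoverageCurve:
    """Percent of image area viewed as a function of cumulative window length."""

    windows_s: np.ndarray
    coverage_pct: np.ndarray

    def __post_init__(self) -> None:
        self.windows_s = np.asarray(self.windows_s, dtype=float)
        self.coverage_pct = np.asarray(self.coverage_pct, dtype=float)
        if np.any(np.diff(self.coverage_pct) < 0):
            raise ValueError("coverage must be non-decreasing in window")
        if np.any((self.coverage_pct < 0) | (self.coverage_pct > 100)):
            raise ValueError("coverage must lie in [0, 100]")

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"window_s": self.windows_s,
                      "coverage_pct": self.coverage_pct}
                     ).to_csv(path, sep="\t", index=False)


def clean_gaze(
    stream: GazeStream, width: int = 256, height: int = 256
) -> tuple[GazeStream, float]:
    """Drop blink (invalid) samples and samples outside the image rectangle.

    Returns the cleaned stream and the retention fraction.  An empty result
    (retention 0) mirrors the manual quality exclusion of unusable blocks and
    is left to the caller to act on.
    """
    if len(stream) == 0:
        raise ValueError("stream is empty")
    inside = (stream.x >= 0) & (stream.x < width) & (stream.y >= 0) & (stream.y < height)
    keep = stream.valid & inside
    return stream._take(keep), float(keep.mean())


def gaze_density(
    stream: GazeStream,
    sigma: float = 10.0,
    width: int = 256,
    height: int = 256,
    dt: float = SAMPLE_INTERVAL_S,
) -> GazeDensityMap:
    """Gaussian kernel-density dwell map over image pixels.

    Each sample contributes ``dt`` seconds spread by an isotropic Gaussian
    (sigma in pixels, truncated at 4 sigma).  Kernels are renormalized within
    the image so that mass clipped at the border is redistributed and the
    total dwell equals ``n_samples * dt`` exactly: each sample's weight is
    divided by its kernel's in-image mass before smoothing.
    """
    hist = np.zeros((height, width))
    if len(stream) > 0:
        cx = np.clip(stream.x.astype(int), 0, width - 1)
        cy = np.clip(stream.y.astype(int), 0, height - 1)
        np.add.at(hist, (cy, cx), dt)
    if sigma <= 0:
        return GazeDensityMap(hist)
    # in-image kernel mass for a kernel centered at each pixel
    mass = gaussian_filter(np.ones_like(hist), sigma, truncate=4.0, mode="constant")
    smoothed = gaussian_filter(hist / mass, sigma, truncate=4.0, mode="constant")
    return GazeDensityMap(smoothed)


def downsample_density(
    dmap: GazeDensityMap, grid_h: int = 15, grid_w: int = 15
) -> GazeDensityMap:
    """Aggregate the per-pixel map to the analysis grid, conserving total dwell."""
    h, w = dmap.values.shape
    rows = np.minimum((np.arange(h) * grid_h) // h, grid_h - 1)
    cols = np.minimum((np.arange(w) * grid_w) // w, grid_w - 1)
    out = np.zeros((grid_h, grid_w))
    np.add.at(out, (rows[:, None], cols[None, :]), dmap.values)
    return GazeDensityMap(out)


def _visited_cells(
    stream: GazeStream, window_s: float, grid_h: int, grid_w: int,
    width: int, height: int,
) -> np.ndarray:
    t0 = stream.t[0] if len(stream) else 0.0
    sel = stream.t <= t0 + window_s
    rows = np.minimum((stream.y[sel] * grid_h / height).astype(int), grid_h - 1)
    cols = np.minimum((stream.x[sel] * grid_w / width).astype(int), grid_w - 1)
    mask = np.zeros((grid_h, grid_w), dtype=bool)
    mask[rows, cols] = True
    return mask


def coverage(
    stream: GazeStream,
    window_s: float,
    grid_h: int = 15,
    grid_w: int = 15,
    width: int = 256,
    height: int = 256,
) -> float:
    """Percent of grid cells visited by gaze within [0, window] of viewing onset.

    A cell counts as viewed when it contains at least one cleaned gaze sample
    (threshold-free visitation on the 15x15 grid).
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    mask = _visited_cells(stream, window_s, grid_h, grid_w, width, height)
    return float(100.0 * mask.sum() / mask.size)


def coverage_curve(
    stream: GazeStream,
    windows_s: np.ndarray | None = None,
    grid_h: int = 15,
    grid_w: int = 15,
    width: int = 256,
    height: int = 256,
) -> CoverageCurve:
    """Coverage at each cumulative window (default 1..10 s), truncated at stream end.

    Viewing duration is participant-determined, so windows extending past the
    last sample simply reuse all samples (the curve flattens).
    """
    if windows_s is None:
        windows_s = np.arange(1.0, 11.0)
    windows_s = np.asarray(windows_s, dtype=float)
    cov = np.array(
        [coverage(stream, w, grid_h, grid_w, width, height) for w in windows_s]
    )
    return CoverageCurve(windows_s, cov)
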