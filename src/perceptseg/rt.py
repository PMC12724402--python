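"""Reaction-time filtering, summaries and the trial-constant learning curve.

Reaction times in the cue-pair task are strongly right-skewed and shrink over
the course of a block as participants learn the sensorimotor contingencies.
This module provides the slow-tail filter (drop trials above the within-block
90th percentile of log RT), bootstrap medians, within-block z-scoring for
pooling across stimuli, sliding-window trends, the exponential learning-curve
fit RT = alpha * 2^(-t / tau) (tau = trials to halve RT), and the
consistent-vs-inconsistent response delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RTSeries",
    "RTFit",
    "filter_rts",
    "median_rt_ci",
    "zscore_by_block",
    "sliding_mean",
    "fit_trial_constant",
    "inconsistency_delay",
]


@dataclass
class RTSeries:
    """Per-trial reaction times with ordering and grouping keys."""

    rt: np.ndarray                 # seconds (or z-scores after standardization)
    trial_index: np.ndarray
    block_id: np.ndarray | None = None
    consistent: np.ndarray | None = None  # optional per-trial flags
    standardized: bool = False

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.rt.shape != self.trial_index.shape:
            raise ValueError("rt and trial_index must align")
        if not self.standardized and np.any(self.rt <= 0):
            raise ValueError("reaction times must be positive")
        if self.block_id is not None:
            self.block_id = np.asarray(self.block_id)
        if self.consistent is not None:
            self.consistent = np.asarray(self.consistent, dtype=bool)

    def _take(self, mask: np.ndarray) -> "RTSeries":
        return RTSeries(
            self.rt[mask],
            self.trial_index[mask],
            None if self.block_id is None else self.block_id[mask],
            None if self.consistent is None else self.consistent[mask],
            standardized=self.standardized,
        )

    def __len__(self) -> int:
        return self.rt.size


@dataclass
class RTFit:
    """Fitted learning curve RT = alpha * 2^(-t/tau)."""

    alpha: float     # seconds; RT scale at t = 0
    tau: float       # trials needed to halve RT
    residual_norm: float
    ci_alpha: tuple[float, float] | None = None
    ci_tau: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.alpha <= 0:
            raise ValueError("alpha and tau must be positive")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.alpha * np.power(2.0, -np.asarray(t, dtype=float) / self.tau)


def _block_groups(series: RTSeries):
    if series.block_id is None:
        yield np.ones(len(series), dtype=bool)
        return
    for b in np.unique(series.block_id):
        yield series.block_id == b


def filter_rts(series: RTSeries, per_block: bool = True) -> RTSeries:
    """Drop trials whose log RT lies strictly above the 90th percentile.

    The percentile is computed over log-transformed RTs with the
    linear-interpolation convention, within each block by default (set
    ``per_block=False`` to pool all trials).  The removed set is invariant
    to the log base and to any multiplicative rescaling of the units.
    """
    logs = np.log(series.rt)
    keep = np.ones(len(series), dtype=bool)
    groups = _block_groups(series) if per_block else [np.ones(len(series), dtype=bool)]
    for mask in groups:
        cut = np.percentile(logs[mask], 90, method="linear")
        keep &= ~(mask & (logs > cut))
    return series._take(keep)


def median_rt_ci(
    series: RTSeries | np.ndarray,
    n_boot: int = 9_999,
    ci: float = 95.0,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Sample median with a seeded percentile-bootstrap confidence interval."""
    rt = series.rt if isinstance(series, RTSeries) else np.asarray(series, dtype=float)
    if rt.size == 0:
        raise ValueError("need at least one trial")
    med = float(np.median(rt))
    rng = np.random.default_rng(seed)
    rt = np.sort(rt)  # resample the empirical distribution, not the trial order
    idx = rng.integers(0, rt.size, size=(n_boot, rt.size))
    boots = np.median(rt[idx], axis=1)
    lo, hi = np.percentile(boots, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return med, (float(lo), float(hi))


def zscore_by_block(series: RTSeries) -> tuple[RTSeries, list]:
    """Standardize RTs within each block (mean 0, sd 1).

    Removes stimulus- and presentation-specific scale confounds before
    pooling across blocks.  Blocks with zero variance cannot be standardized;
    they are excluded and their ids returned as flagged.
    """
    out = np.empty_like(series.rt)
    keep = np.ones(len(series), dtype=bool)
    flagged = []
    for mask in _block_groups(series):
        vals = series.rt[mask]
        sd = vals.std(ddof=0)
        if vals.size < 2 or sd == 0:
            keep &= ~mask
            if series.block_id is not None:
                flagged.append(series.block_id[mask][0])
            else:
                flagged.append(None)
            continue
        out[mask] = (vals - vals.mean()) / sd
    z = RTSeries(
        out[keep],
        series.trial_index[keep],
        None if series.block_id is None else series.block_id[keep],
        None if series.consistent is None else series.consistent[keep],
        standardized=True,
    )
    return z, flagged


def sliding_mean(
    series: RTSeries, window: int = 500
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Running mean and s.e.m. over trials ordered by within-block index.

    Trials from all blocks are pooled and sorted by ``trial_index`` (many
    trials share each index across blocks); the window slides over this
    pooled ordering.  Returns (center positions, mean, sem).  A window larger
    than the data degrades to a single aggregate with a warning.
    """
    order = np.argsort(series.trial_index, kind="stable")
    rt = series.rt[order]
    n = rt.size
    if window > n:
        import warnings

        warnings.warn("window exceeds number of trials; returning one aggregate")
        return (
            np.array([n / 2.0]),
            np.array([rt.mean()]),
            np.array([rt.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan]),
        )
    c = np.concatenate([[0.0], np.cumsum(rt)])
    c2 = np.concatenate([[0.0], np.cumsum(rt * rt)])
    s = c[window:] - c[:-window]
    s2 = c2[window:] - c2[:-window]
    mean = s / window
    var = np.maximum(s2 / window - mean**2, 0.0) * window / (window - 1)
    sem = np.sqrt(var / window)
    centers = np.arange(n - window + 1) + (window - 1) / 2.0
    return centers, mean, sem


def fit_trial_constant(series: RTSeries) -> RTFit:
    """Nonlinear least-squares fit of RT = alpha * 2^(-t/tau).

    tau is the "trial constant": the number of trials needed to halve the
    reaction time (at t = tau the model predicts alpha / 2).  Scale-
    equivariant: multiplying RTs by c multiplies alpha by c and leaves tau
    unchanged.
    """
    if len(series) < 3 or np.unique(series.trial_index).size < 2:
        raise ValueError("need >= 3 trials spanning >= 2 distinct indices")
    if np.any(series.rt <= 0):
        raise ValueError("reaction times must be positive")
    t = series.trial_index.astype(float)
    y = series.rt

    def model(t, alpha, tau):
        return alpha * np.power(2.0, -t / tau)

    span = t.max() - t.min()
    p0 = (float(y.max()), max(span / 4.0, 1.0))
    popt, _ = curve_fit(
        model, t, y, p0=p0,
        bounds=([1e-12, 1e-9], [np.inf, np.inf]),
        maxfev=20_000,
    )
    resid = y - model(t, *popt)
    return RTFit(alpha=float(popt[0]), tau=float(popt[1]),
                 residual_norm=float(np.linalg.norm(resid)))


def inconsistency_delay(
    series: RTSeries,
    n_boot: int = 9_999,
    ci: float = 95.0,
    seed: int | None = None,
) -> tuple[float, tuple[float, float], bool]:
    """Mean RT difference, inconsistent minus consistent trials, with bootstrap CI.

    Returns (delay, (lo, hi), degenerate); the CI is a seeded percentile
    bootstrap over trials resampled within each class.  With a single trial
    in either class the CI collapses and is flagged degenerate.
    """
    if series.consistent is None:
        raise ValueError("series has no consistency flags")
    inc = np.sort(series.rt[~series.consistent])
    con = np.sort(series.rt[series.consistent])
    if inc.size == 0 or con.size == 0:
        raise ValueError("both consistency classes must be present")
    delay = float(inc.mean() - con.mean())
    degenerate = inc.size < 2 or con.size < 2
    rng = np.random.default_rng(seed)
    bi = inc[rng.integers(0, inc.size, size=(n_boot, inc.size))].mean(axis=1)
    bc = con[rng.integers(0, con.size, size=(n_boot, con.size))].mean(axis=1)
    lo, hi = np.percentile(bi - bc, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return delay, (float(lo), float(hi)), degenerate
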