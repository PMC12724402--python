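"""Epoch-level EEG statistics: ERPs, significance windows, GFP, cluster tests.

Consumes cleaned epoched EEG (channels x time x epochs, microvolts, 512 Hz,
-500..1000 ms around trial onset) together with per-epoch reaction times.
Provides the RT-based epoch exclusion (slowest 10 percent, then RT > 2.5 s),
average re-referencing, pre-stimulus baseline correction, ERP aggregation up
to the cohort level, pointwise Welch t-test windows with a 50-ms minimum
duration criterion, Global Field Power (spatial standard deviation across
electrodes) with 50-ms-interval cohort tests, topographic frames, and a
space-time cluster permutation test with Delaunay channel adjacency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay
from scipy.stats import t as t_dist
from scipy.stats import ttest_ind

__all__ = [
    "EpochSet",
    "ERP",
    "GFPSeries",
    "SignificanceWindows",
    "ClusterResult",
    "OPO_CHANNELS",
    "exclude_by_rt",
    "rereference_average",
    "baseline_correct",
    "compute_erp",
    "grand_average",
    "pointwise_ttest_windows",
    "gfp",
    "gfp_interval_tests",
    "topomap_frame",
    "channel_adjacency",
    "cluster_permutation_test",
]

# occipital / parieto-occipital electrode set used for the visual ERP analyses
OPO_CHANNELS = ("O1", "Oz", "O2", "PO7", "PO3", "POz", "PO4", "PO8")


@dataclass
class EpochSet:
    """Epoched multichannel EEG for one block.

    ``data`` is channels x time x epochs in microvolts; ``times_ms`` spans the
    epoch window (-500..1000 ms at 512 Hz by default); ``rt`` holds one
    reaction time per epoch (seconds).
    """

    data: np.ndarray
    ch_names: list[str]
    ch_pos: np.ndarray          # (n_channels, 2) schematic scalp positions
    times_ms: np.ndarray
    rt: np.ndarray
    sfreq: float = 512.0
    participant_id: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.ch_pos = np.asarray(self.ch_pos, dtype=float)
        n_ch, n_t, n_ep = self.data.shape
        if len(self.ch_names) != n_ch or self.ch_pos.shape != (n_ch, 2):
            raise ValueError("channel metadata must match data")
        if self.times_ms.size != n_t:
            raise ValueError("time axis must match data")
        if self.rt.size != n_ep:
            raise ValueError("one reaction time per epoch required")
        if np.any(self.rt <= 0):
            raise ValueError("reaction times must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    def _take_epochs(self, idx: np.ndarray) -> "EpochSet":
        return replace(self, data=self.data[:, :, idx], rt=self.rt[idx])

    # -------------------------------------------------------------- I/O
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("rt", data=self.rt)
            f.create_dataset("time_ms", data=self.times_ms)
            f.create_dataset("ch_pos", data=self.ch_pos)
            f.create_dataset(
                "ch_names", data=np.array(self.ch_names, dtype="S16")
            )
            f.attrs["sfreq"] = self.sfreq
            f.attrs["participant_id"] = self.participant_id
            f.attrs["cohort"] = self.cohort

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                ch_names=[n.decode() for n in f["ch_names"][()]],
                ch_pos=f["ch_pos"][()],
                times_ms=f["time_ms"][()],
                rt=f["rt"][()],
                sfreq=float(f.attrs["sfreq"]),
                participant_id=str(f.attrs["participant_id"]),
                cohort=str(f.attrs["cohort"]),
            )

    @classmethod
    def from_long_table(cls, table_path, ch_pos: np.ndarray, rt: np.ndarray,
                        sfreq: float = 512.0, **meta) -> "EpochSet":
        """Adapter for small text fixtures: columns epoch, channel, time_ms, uv."""
        import pandas as pd

        df = pd.read_csv(table_path, sep="\t")
        chans = list(dict.fromkeys(df["channel"]))
        times = np.sort(df["time_ms"].unique())
        epoch_ids = np.sort(df["epoch"].unique())
        ci = df["channel"].map({c: i for i, c in enumerate(chans)}).to_numpy()
        ti = np.searchsorted(times, df["time_ms"].to_numpy())
        ei = np.searchsorted(epoch_ids, df["epoch"].to_numpy())
        cube = np.zeros((len(chans), times.size, epoch_ids.size))
        cube[ci, ti, ei] = df["uv"].to_numpy()
        return cls(cube, chans, ch_pos, times, rt, sfreq=sfreq, **meta)


@dataclass
class ERP:
    """Across-epoch average, channels x time (or a single averaged trace)."""

    data: np.ndarray            # (n_channels, n_times) or (n_times,)
    times_ms: np.ndarray
    n_epochs: int
    level: str = "block"        # block | participant | cohort
    channels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ERP values must be finite")


@dataclass
class GFPSeries:
    """Global Field Power over time with sampled cohort-test results."""

    times_ms: np.ndarray
    gfp: np.ndarray
    test_times_ms: np.ndarray | None = None
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.gfp) < 0):
            raise ValueError("GFP is non-negative")


@dataclass
class SignificanceWindows:
    """Ordered, non-overlapping (start_ms, end_ms) runs surviving the duration rule."""

    windows: list[tuple[float, float]]
    alpha: float
    min_duration_ms: float


@dataclass
class ClusterResult:
    clusters: list[np.ndarray]  # boolean masks, (n_channels, n_times)
    masses: np.ndarray          # summed t within each cluster
    p_values: np.ndarray
    t_obs: np.ndarray


# --------------------------------------------------------------------------
# epoch-level preprocessing


def exclude_by_rt(epochs: EpochSet, slow_fraction: float = 0.10,
                  rt_cap_s: float = 2.5) -> EpochSet:
    """Two-stage exclusion: slowest 10 percent of RTs, then any RT > 2.5 s.

    The slow-tail stage drops ``ceil(slow_fraction * n)`` epochs; ties in RT
    break by epoch order (later epochs dropped first among equals).
    """
    n = epochs.n_epochs
    k = math.ceil(slow_fraction * n)
    order = np.argsort(epochs.rt, kind="stable")
    keep = np.ones(n, dtype=bool)
    if k > 0:
        keep[order[n - k:]] = False
    keep &= epochs.rt <= rt_cap_s
    if not keep.any():
        raise ValueError("all epochs excluded by reaction-time rules")
    return epochs._take_epochs(np.flatnonzero(keep))


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the global average: subtract the cross-channel mean."""
    if epochs.data.shape[0] < 2:
        raise ValueError("average reference needs >= 2 channels")
    return replace(epochs, data=epochs.data - epochs.data.mean(axis=0, keepdims=True))


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Subtract each channel's mean over the pre-stimulus window, per epoch."""
    lo, hi = window_ms
    sel = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, sel, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - base)


# --------------------------------------------------------------------------
# ERP aggregation


def compute_erp(epochs: EpochSet, channels: list[str] | None = None,
                level: str = "block") -> ERP:
    """Across-epoch mean, optionally averaged over a named channel subset."""
    mean = epochs.data.mean(axis=2)
    if channels is not None:
        if len(channels) == 0:
            raise ValueError("channel subset must not be empty")
        idx = [epochs.ch_names.index(c) for c in channels]
        mean = mean[idx].mean(axis=0)
    return ERP(mean, epochs.times_ms, epochs.n_epochs, level=level,
               channels=list(channels) if channels else None)


def grand_average(erps: list[ERP], level: str = "cohort") -> ERP:
    """Equal-weight average of ERPs (one unit per participant at cohort level)."""
    if not erps:
        raise ValueError("no ERPs to average")
    data = np.mean([e.data for e in erps], axis=0)
    return ERP(data, erps[0].times_ms, sum(e.n_epochs for e in erps),
               level=level, channels=erps[0].channels)


# --------------------------------------------------------------------------
# pointwise statistics


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop inclusive."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def pointwise_ttest_windows(
    group_a: np.ndarray,
    group_b: np.ndarray,
    times_ms: np.ndarray,
    alpha: float = 0.05,
    min_duration_ms: float = 50.0,
) -> SignificanceWindows:
    """Windows where two cohorts' subject-level traces differ pointwise.

    ``group_a`` and ``group_b`` are (n_subjects, n_times) arrays of subject-
    level ERP waveforms.  A Welch two-sample t-test runs at each time sample;
    contiguous runs of p < alpha shorter than ``min_duration_ms`` are
    discarded to suppress transient fluctuations.  Time points with
    degenerate variance in both groups get p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 units per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = ttest_ind(a, b, axis=0, equal_var=False)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    sig = p < alpha
    dt = float(np.median(np.diff(times_ms)))
    windows = []
    for i, j in _runs(sig):
        dur = (j - i + 1) * dt
        if dur >= min_duration_ms:
            windows.append((float(times_ms[i]), float(times_ms[j])))
    return SignificanceWindows(windows, alpha=alpha, min_duration_ms=min_duration_ms)


def gfp(data: np.ndarray, times_ms: np.ndarray | None = None) -> GFPSeries | np.ndarray:
    """Global Field Power: spatial standard deviation across electrodes.

    Implements sqrt(mean((amplitude - mean(amplitude))^2)) over channels at
    each time point (population convention).  Reference-free: adding a common
    time-varying offset to all channels leaves GFP unchanged.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("GFP needs >= 2 channels")
    values = data.std(axis=0, ddof=0)
    if times_ms is None:
        return values
    return GFPSeries(np.asarray(times_ms, dtype=float), values)


def gfp_interval_tests(
    group_a: np.ndarray,
    group_b: np.ndarray,
    times_ms: np.ndarray,
    step_ms: float = 50.0,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cohort t-tests of per-participant GFP at times sampled every 50 ms.

    ``group_a``/``group_b`` are (n_subjects, n_times) GFP series.  Sampling
    starts at the first multiple of ``step_ms`` inside the time axis.  Flags
    are uncorrected (p < alpha).  Returns (test times, p-values, flags).
    """
    times_ms = np.asarray(times_ms, dtype=float)
    start = math.ceil(times_ms[0] / step_ms) * step_ms
    targets = np.arange(start, times_ms[-1] + 1e-9, step_ms)
    idx = np.array([np.argmin(np.abs(times_ms - tt)) for tt in targets])
    with np.errstate(divide="ignore", invalid="ignore"):
        res = ttest_ind(group_a[:, idx], group_b[:, idx], axis=0, equal_var=False)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    return times_ms[idx], p, p < alpha


def topomap_frame(
    erp: ERP, ch_pos: np.ndarray, time_ms: float, clip_uv: float = 10.0
) -> dict:
    """Per-channel values at the nearest sample, clipped for display.

    Returns raw and clipped (+-clip_uv) channel values together with the 2-D
    positions; difference frames are obtained by passing an ERP of A - B.
    """
    if erp.data.ndim != 2:
        raise ValueError("topomap needs a channels x time ERP")
    if not (erp.times_ms[0] <= time_ms <= erp.times_ms[-1]):
        raise ValueError("time point outside the epoch")
    i = int(np.argmin(np.abs(erp.times_ms - time_ms)))
    raw = erp.data[:, i].copy()
    return {
        "time_ms": float(erp.times_ms[i]),
        "raw": raw,
        "display": np.clip(raw, -clip_uv, clip_uv),
        "positions": np.asarray(ch_pos, dtype=float),
    }


# --------------------------------------------------------------------------
# cluster permutation test


def channel_adjacency(ch_pos: np.ndarray) -> sparse.csr_matrix:
    """Channel neighborhood graph from Delaunay triangulation of 2-D positions."""
    ch_pos = np.asarray(ch_pos, dtype=float)
    n = ch_pos.shape[0]
    tri = Delaunay(ch_pos)
    rows, cols = [], []
    for simplex in tri.simplices:
        for i in range(3):
            for j in range(i + 1, 3):
                rows += [simplex[i], simplex[j]]
                cols += [simplex[j], simplex[i]]
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj.data[:] = 1.0
    return adj


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t-statistic along axis 0 for stacked (n_obs, ...) arrays."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(np.isfinite(t), t, 0.0)


def _clusters_from_t(
    t_map: np.ndarray, threshold: float, adjacency: sparse.csr_matrix
) -> tuple[list[np.ndarray], np.ndarray]:
    """Space-time clusters of supra-threshold |t| values and their masses.

    Nodes are (channel, time) samples above threshold; edges join adjacent
    time samples on a channel and adjacent channels at a time, with same-sign
    t required within a cluster.
    """
    n_ch, n_t = t_map.shape
    supra = np.abs(t_map) > threshold
    sign = np.sign(t_map)
    idx = -np.ones(t_map.shape, dtype=int)
    nodes = np.flatnonzero(supra.ravel())
    if nodes.size == 0:
        return [], np.array([])
    idx.ravel()[nodes] = np.arange(nodes.size)

    rows, cols = [], []
    ch_of = nodes // n_t
    t_of = nodes % n_t
    # temporal neighbors
    for k, (c, tt) in enumerate(zip(ch_of, t_of)):
        if tt + 1 < n_t and supra[c, tt + 1] and sign[c, tt + 1] == sign[c, tt]:
            rows.append(k)
            cols.append(idx[c, tt + 1])
    # spatial neighbors
    adj = adjacency.tocoo()
    for ci, cj in zip(adj.row, adj.col):
        if ci < cj:
            both = supra[ci] & supra[cj] & (sign[ci] == sign[cj])
            for tt in np.flatnonzero(both):
                rows.append(idx[ci, tt])
                cols.append(idx[cj, tt])
    g = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(nodes.size, nodes.size)
    )
    n_comp, labels = connected_components(g, directed=False)
    clusters, masses = [], []
    for c in range(n_comp):
        members = nodes[labels == c]
        mask = np.zeros(t_map.shape, dtype=bool)
        mask.ravel()[members] = True
        clusters.append(mask)
        masses.append(float(t_map[mask].sum()))
    return clusters, np.asarray(masses)


def cluster_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    adjacency: sparse.csr_matrix,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-based permutation test over channels x time.

    ``group_a``/``group_b`` are (n_subjects, n_channels, n_times) stacks of
    subject-level ERPs.  Welch t-tests form clusters of same-sign samples
    exceeding the two-sided p < ``cluster_alpha`` threshold, connected through
    channel adjacency and temporal contiguity; cluster mass is the summed t.
    The null permutes cohort labels; each permutation contributes its maximum
    absolute cluster mass.  Cluster p-values use the add-one convention
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 units per group")
    na = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    n = pooled.shape[0]
    df = min(a.shape[0], b.shape[0]) - 1  # conservative df for the threshold
    threshold = float(t_dist.ppf(1.0 - cluster_alpha / 2.0, df))

    t_obs = _welch_t(a, b)
    clusters, masses = _clusters_from_t(t_obs, threshold, adjacency)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        pa, pb = pooled[perm[:na]], pooled[perm[na:]]
        t_perm = _welch_t(pa, pb)
        _, m = _clusters_from_t(t_perm, threshold, adjacency)
        null[i] = np.max(np.abs(m)) if m.size else 0.0

    if masses.size:
        p = (1 + (null[None, :] >= np.abs(masses)[:, None] - 1e-12).sum(axis=1)) / (
            n_perm + 1
        )
    else:
        p = np.array([])
    return ClusterResult(clusters=clusters, masses=masses, p_values=p, t_obs=t_obs)
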