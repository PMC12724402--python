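"""Segmentation-map data types and information-theoretic map statistics.

A participant's perceptual segmentation of an image is summarized on a coarse
grid (15x15 by default) as a per-cell probability distribution over K segment
labels (:class:`ProbSegMap`).  From it derive the hard label map (argmax), the
per-cell Shannon entropy ("perceptual uncertainty"), and pairwise map-similarity
statistics: mutual information between co-located labels and the percent
Information Gain (IG) over a spatial-shuffle permutation null.

All logarithms are base 2; entropies and mutual information are in bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ProbSegMap",
    "SegMap",
    "EntropyMap",
    "IGResult",
    "argmax_map",
    "entropy_map",
    "mean_uncertainty",
    "mutual_information",
    "quantize_map",
    "information_gain",
]

_PROB_TOL = 1e-9


class MapValidationError(ValueError):
    """Raised when a map violates its structural invariants."""


@dataclass
class ProbSegMap:
    """Per-cell probability distribution over K segment labels.

    ``probs`` has shape ``(grid_h, grid_w, K)``; each cell's vector is
    non-negative and sums to 1 (within 1e-9).
    """

    probs: np.ndarray
    grid_h: int = field(init=False)
    grid_w: int = field(init=False)
    K: int = field(init=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise MapValidationError("probs must be (grid_h, grid_w, K)")
        self.grid_h, self.grid_w, self.K = self.probs.shape
        self.validate()

    def validate(self) -> None:
        if self.K < 2:
            raise MapValidationError("K must be >= 2")
        if self.grid_h < 2 or self.grid_w < 2:
            raise MapValidationError("grid dimensions must be >= 2")
        if not np.all(np.isfinite(self.probs)):
            raise MapValidationError("probabilities must be finite")
        if np.any(self.probs < 0):
            raise MapValidationError("probabilities must be non-negative")
        sums = self.probs.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > _PROB_TOL):
            raise MapValidationError("cell probabilities must sum to 1")

    # ------------------------------------------------------------------ I/O
    def to_files(self, table_path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write one row per cell (row, col, K probabilities) plus JSON sidecar."""
        table_path = Path(table_path)
        rows, cols = np.mgrid[0 : self.grid_h, 0 : self.grid_w]
        flat = self.probs.reshape(-1, self.K)
        data = np.column_stack([rows.ravel(), cols.ravel(), flat])
        header = "row\tcol\t" + "\t".join(f"p{k + 1}" for k in range(self.K))
        np.savetxt(table_path, data, delimiter="\t", header=header, comments="")
        meta = {"grid_h": self.grid_h, "grid_w": self.grid_w, "K": self.K, "kind": "prob"}
        meta_path = Path(meta_path) if meta_path else table_path.with_suffix(".json")
        meta_path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_files(cls, table_path: str | Path, meta_path: str | Path | None = None) -> "ProbSegMap":
        table_path = Path(table_path)
        meta_path = Path(meta_path) if meta_path else table_path.with_suffix(".json")
        meta = json.loads(meta_path.read_text())
        data = np.loadtxt(table_path, delimiter="\t", skiprows=1)
        h, w, k = meta["grid_h"], meta["grid_w"], meta["K"]
        probs = np.empty((h, w, k))
        r = data[:, 0].astype(int)
        c = data[:, 1].astype(int)
        probs[r, c] = data[:, 2:]
        return cls(probs)


@dataclass
class SegMap:
    """Hard segmentation: one integer label in {1..K} per grid cell."""

    labels: np.ndarray
    K: int
    grid_h: int = field(init=False)
    grid_w: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise MapValidationError("labels must be 2-D")
        self.grid_h, self.grid_w = self.labels.shape
        if self.K < 2:
            raise MapValidationError("K must be >= 2")
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise MapValidationError("labels must lie in {1..K}")

    def to_files(self, table_path: str | Path, meta_path: str | Path | None = None) -> None:
        table_path = Path(table_path)
        rows, cols = np.mgrid[0 : self.grid_h, 0 : self.grid_w]
        data = np.column_stack([rows.ravel(), cols.ravel(), self.labels.ravel()])
        np.savetxt(table_path, data, fmt="%d", delimiter="\t",
                   header="row\tcol\tlabel", comments="")
        meta = {"grid_h": self.grid_h, "grid_w": self.grid_w, "K": self.K, "kind": "label"}
        meta_path = Path(meta_path) if meta_path else table_path.with_suffix(".json")
        meta_path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_files(cls, table_path: str | Path, meta_path: str | Path | None = None) -> "SegMap":
        table_path = Path(table_path)
        meta_path = Path(meta_path) if meta_path else table_path.with_suffix(".json")
        meta = json.loads(meta_path.read_text())
        data = np.loadtxt(table_path, delimiter="\t", skiprows=1).astype(int)
        labels = np.empty((meta["grid_h"], meta["grid_w"]), dtype=int)
        labels[data[:, 0], data[:, 1]] = data[:, 2]
        return cls(labels, K=meta["K"])


@dataclass
class EntropyMap:
    """Per-cell Shannon entropy (bits) of the label distribution."""

    values: np.ndarray
    K: int
    grid_h: int = field(init=False)
    grid_w: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MapValidationError("values must be 2-D")
        self.grid_h, self.grid_w = self.values.shape
        hmax = np.log2(self.K) + 1e-9
        if np.any(self.values < -1e-9) or np.any(self.values > hmax):
            raise MapValidationError("entropies must lie in [0, log2 K]")


@dataclass
class IGResult:
    """Information-Gain statistic of one map pair against its shuffle null."""

    mi_observed: float
    null_mean: float
    null_sd: float
    ig_percent: float
    p_value: float
    n_perm: int
    degenerate: bool
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "IGResult":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# operations


def argmax_map(pmap: ProbSegMap) -> SegMap:
    """Hard map: each cell takes its maximal-probability label.

    Ties break to the lowest label index (``np.argmax`` convention), so the
    output is deterministic and stable under label ordering.
    """
    pmap.validate()
    return SegMap(np.argmax(pmap.probs, axis=2) + 1, K=pmap.K)


def entropy_map(pmap: ProbSegMap) -> EntropyMap:
    """Per-cell Shannon entropy in bits; 0*log(0) contributes 0."""
    pmap.validate()
    p = pmap.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    values = np.clip(terms.sum(axis=2), 0.0, np.log2(pmap.K))
    return EntropyMap(values, K=pmap.K)


def mean_uncertainty(emap: EntropyMap, K: int | None = None) -> float:
    """Mean cell entropy as a percent of the maximum log2(K).

    100 means every cell is maximally uncertain (uniform over K labels),
    0 means every cell is fully certain (one-hot).
    """
    K = emap.K if K is None else K
    if K < 2:
        raise MapValidationError("K must be >= 2")
    return float(100.0 * emap.values.mean() / np.log2(K))


def _joint_mi_bits(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    """MI (bits) of the joint histogram of two co-located integer arrays."""
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(float)
    n = joint.sum()
    joint = joint.reshape(ka, kb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    outer = pa[:, None] * pb[None, :]
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mutual_information(a: SegMap, b: SegMap) -> float:
    """Mutual information (bits) between co-located cell labels of two maps.

    Computed from the joint label histogram over cells; empty joint bins
    contribute zero.  Symmetric in its arguments and invariant to any
    relabeling of segment indices within either map.
    """
    if (a.grid_h, a.grid_w) != (b.grid_h, b.grid_w):
        raise MapValidationError("maps must share grid dimensions")
    return _joint_mi_bits(a.labels.ravel() - 1, b.labels.ravel() - 1, a.K, b.K)


def quantize_map(emap: EntropyMap, other: EntropyMap, n_bins: int = 8) -> tuple[SegMap, SegMap]:
    """Discretize two continuous maps into equal-width bins over their pooled range.

    MI needs discrete marginals; the same binning is applied to both maps so
    that identical maps quantize identically.  A pooled zero range collapses
    to a single bin (constant maps).
    """
    lo = min(emap.values.min(), other.values.min())
    hi = max(emap.values.max(), other.values.max())
    if hi - lo <= 0:
        z = np.ones(emap.values.shape, dtype=int)
        return SegMap(z, K=n_bins), SegMap(np.ones(other.values.shape, dtype=int), K=n_bins)
    edges = np.linspace(lo, hi, n_bins + 1)
    qa = np.clip(np.digitize(emap.values, edges[1:-1]) + 1, 1, n_bins)
    qb = np.clip(np.digitize(other.values, edges[1:-1]) + 1, 1, n_bins)
    return SegMap(qa, K=n_bins), SegMap(qb, K=n_bins)


def information_gain(
    a: SegMap | EntropyMap,
    b: SegMap | EntropyMap,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> IGResult:
    """Percent information gained from spatial structure, with permutation null.

    The null distribution holds the marginal label histograms fixed while
    destroying spatial structure: the cell values of the first map are
    uniformly permuted across locations and MI with the (unshuffled) second
    map is recomputed ``n_perm`` times.  Then::

        IG% = 100 * (MI_obs - mean(MI_null)) / mean(MI_null)

    so IG of 0% means the two maps are not more similar than two random maps.
    The one-tailed p-value uses the add-one convention
    ``p = (1 + #{null >= observed}) / (n_perm + 1)`` and is therefore never 0.

    Continuous (entropy) maps are first quantized into 8 equal-width bins over
    the pooled range of both maps.

    When the null mean is zero (e.g. one map is constant) the result is
    flagged ``degenerate`` with ``ig_percent = 0``.
    """
    if isinstance(a, EntropyMap) or isinstance(b, EntropyMap):
        if not (isinstance(a, EntropyMap) and isinstance(b, EntropyMap)):
            raise MapValidationError("both maps must be the same kind")
        a, b = quantize_map(a, b)
    if (a.grid_h, a.grid_w) != (b.grid_h, b.grid_w):
        raise MapValidationError("maps must share grid dimensions")
    if n_perm < 1:
        raise MapValidationError("n_perm must be >= 1")

    av = a.labels.ravel() - 1
    bv = b.labels.ravel() - 1
    mi_obs = _joint_mi_bits(av, bv, a.K, b.K)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _joint_mi_bits(rng.permutation(av), bv, a.K, b.K)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    n_ge = int(np.sum(null >= mi_obs - 1e-15))
    p = (1 + n_ge) / (n_perm + 1)
    degenerate = null_mean <= 0.0
    ig = 0.0 if degenerate else 100.0 * (mi_obs - null_mean) / null_mean
    return IGResult(
        mi_observed=mi_obs,
        null_mean=null_mean,
        null_sd=null_sd,
        ig_percent=float(ig),
        p_value=float(p),
        n_perm=n_perm,
        degenerate=degenerate,
        seed=seed,
    )
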