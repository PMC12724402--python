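"""Reconstruction of probabilistic segmentation maps from same/different trials.

On each trial two image locations are cued and the participant reports whether
they belong to the same perceptual segment.  Collecting many cue pairs over a
block constrains a per-cell distribution over K segment labels on a coarse
grid.  The estimator here models the probability of a "same" response for cue
cells i and j as the label-match probability

    P(same | i, j) = sum_k p_{i,k} p_{j,k}

and maximizes the Bernoulli log-likelihood of the observed responses minus a
spatial-smoothness penalty ``lambda * sum_{4-neighbors} ||p_i - p_j||^2``
(default lambda = 5).  Cell distributions are parametrized by unconstrained
scores through a softmax so the probability-simplex constraint is implicit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, minimize

from .maps import ProbSegMap, SegMap, argmax_map

__all__ = [
    "Stimulus",
    "TrialRecord",
    "BlockData",
    "FitConfig",
    "FitDiagnostics",
    "trial_schedule",
    "generate_cue_pairs",
    "cue_to_cell",
    "fit_prob_map",
    "classify_consistency",
    "inconsistency_rate",
    "exclusion_percentage",
    "shuffle_responses",
    "flag_structureless_block",
    "match_labels",
    "label_agreement",
]

GRID_DEFAULT = 15


@dataclass
class Stimulus:
    stim_id: str
    K: int
    width: int = 256
    height: int = 256
    category: str = "natural"  # natural | texture

    def __post_init__(self) -> None:
        if not 2 <= self.K <= 5:
            raise ValueError("K must be in {2..5}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("stimulus dimensions must be positive")


@dataclass
class TrialRecord:
    trial_index: int          # 1-based order within the block
    cue_a: tuple[float, float]  # pixel (x, y)
    cue_b: tuple[float, float]
    response: str             # "same" | "different"
    rt: float                 # seconds from image offset to key press

    def __post_init__(self) -> None:
        if self.response not in ("same", "different"):
            raise ValueError("response must be 'same' or 'different'")
        if self.rt <= 0:
            raise ValueError("rt must be positive")


@dataclass
class BlockData:
    """One participant x image experimental block."""

    participant_id: str
    cohort: str               # "NT" | "ASD"
    stimulus: Stimulus
    trials: list[TrialRecord]

    def __post_init__(self) -> None:
        if not self.cohort:
            raise ValueError("cohort label required")
        idx = [t.trial_index for t in self.trials]
        if len(set(idx)) != len(idx):
            raise ValueError("trial_index must be unique within a block")
        for t in self.trials:
            for x, y in (t.cue_a, t.cue_b):
                if not (0 <= x < self.stimulus.width and 0 <= y < self.stimulus.height):
                    raise ValueError(f"cue ({x}, {y}) outside image")

    # -------------------------------------------------------------- I/O
    def to_files(self, table_path: str | Path, meta_path: str | Path | None = None) -> None:
        table_path = Path(table_path)
        df = pd.DataFrame(
            {
                "trial_index": [t.trial_index for t in self.trials],
                "cue_a_x": [t.cue_a[0] for t in self.trials],
                "cue_a_y": [t.cue_a[1] for t in self.trials],
                "cue_b_x": [t.cue_b[0] for t in self.trials],
                "cue_b_y": [t.cue_b[1] for t in self.trials],
                "response": [t.response for t in self.trials],
                "rt_s": [t.rt for t in self.trials],
            }
        )
        df.to_csv(table_path, sep="\t", index=False, float_format="%.17g")
        meta = {
            "participant_id": self.participant_id,
            "cohort": self.cohort,
            "stimulus": self.stimulus.__dict__,
        }
        meta_path = Path(meta_path) if meta_path else table_path.with_suffix(".json")
        meta_path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_files(cls, table_path: str | Path, meta_path: str | Path | None = None) -> "BlockData":
        table_path = Path(table_path)
        meta_path = Path(meta_path) if meta_path else table_path.with_suffix(".json")
        meta = json.loads(meta_path.read_text())
        df = pd.read_csv(table_path, sep="\t", float_precision="round_trip")
        trials = [
            TrialRecord(
                trial_index=int(r.trial_index),
                cue_a=(float(r.cue_a_x), float(r.cue_a_y)),
                cue_b=(float(r.cue_b_x), float(r.cue_b_y)),
                response=str(r.response),
                rt=float(r.rt_s),
            )
            for r in df.itertuples()
        ]
        return cls(
            participant_id=meta["participant_id"],
            cohort=meta["cohort"],
            stimulus=Stimulus(**meta["stimulus"]),
            trials=trials,
        )


@dataclass
class FitConfig:
    grid_h: int = GRID_DEFAULT
    grid_w: int = GRID_DEFAULT
    lambda_smooth: float = 5.0   # spatial smoothing weight
    max_iter: int = 2000
    tol: float = 1e-6            # relative objective tolerance
    seed: int = 0
    init_noise: float = 0.5      # symmetry-breaking noise on the scores

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FitDiagnostics:
    objective: float            # final penalized log-likelihood (maximized)
    n_iter: int
    converged: bool
    objective_trace: np.ndarray = field(repr=False, default=None)


# --------------------------------------------------------------------------
# schedule / geometry


def trial_schedule(K: int, grid_h: int = GRID_DEFAULT, grid_w: int = GRID_DEFAULT) -> int:
    """Minimum trial count to constrain a grid map with K segments.

    Each cell contributes K-1 free probabilities, so the schedule is
    ``grid_cells * (K - 1)``: 225, 450, 675, 900 trials for K = 2..5 on the
    default 15x15 grid.
    """
    if not 2 <= K <= 5:
        raise ValueError("K must be in {2..5}")
    return grid_h * grid_w * (K - 1)


def cue_to_cell(
    cue: tuple[float, float],
    stimulus: Stimulus,
    grid_h: int = GRID_DEFAULT,
    grid_w: int = GRID_DEFAULT,
) -> tuple[int, int]:
    """Map a pixel coordinate (x, y) to its (row, col) cell.

    Cells are the uniform partition of the image area, half-open with the
    final edge closed, so every in-image pixel maps to a valid cell.
    """
    x, y = cue
    if not (0 <= x < stimulus.width and 0 <= y < stimulus.height):
        raise ValueError(f"cue ({x}, {y}) outside image")
    col = min(int(x * grid_w / stimulus.width), grid_w - 1)
    row = min(int(y * grid_h / stimulus.height), grid_h - 1)
    return row, col


def _cell_center(row: int, col: int, stimulus: Stimulus, grid_h: int, grid_w: int) -> tuple[float, float]:
    x = (col + 0.5) * stimulus.width / grid_w
    y = (row + 0.5) * stimulus.height / grid_h
    return x, y


def generate_cue_pairs(
    n_trials: int,
    stimulus: Stimulus,
    grid_h: int = GRID_DEFAULT,
    grid_w: int = GRID_DEFAULT,
    seed: int | None = None,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Seeded pseudorandom cue pairs with balanced cell coverage.

    Cue endpoints are drawn by cycling shuffled permutations of all cells, so
    per-cell usage counts differ by at most 2 after pairing; each cell is
    rendered as its center pixel.  The two cells of a pair are always
    distinct.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n_cells = grid_h * grid_w
    n_endpoints = 2 * n_trials

    # stratified endpoint stream: concatenated random permutations of all cells
    reps = int(np.ceil(n_endpoints / n_cells)) + 1
    stream = np.concatenate([rng.permutation(n_cells) for _ in range(reps)])

    pairs: list[tuple[tuple[float, float], tuple[float, float]]] = []
    pos = 0
    for _ in range(n_trials):
        a = stream[pos]
        pos += 1
        # skip ahead until the partner cell is distinct
        while stream[pos] == a:
            pos += 1
        b = stream[pos]
        pos += 1
        ra, ca = divmod(int(a), grid_w)
        rb, cb = divmod(int(b), grid_w)
        pairs.append(
            (
                _cell_center(ra, ca, stimulus, grid_h, grid_w),
                _cell_center(rb, cb, stimulus, grid_h, grid_w),
            )
        )
    return pairs


# --------------------------------------------------------------------------
# estimator


def _neighbor_pairs(grid_h: int, grid_w: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices of all 4-neighborhood (right and down) cell pairs."""
    idx = np.arange(grid_h * grid_w).reshape(grid_h, grid_w)
    right = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    down = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    both = np.concatenate([right, down], axis=1)
    return both[0], both[1]


_EPS = 1e-9


def fit_prob_map(
    block: BlockData,
    config: FitConfig | None = None,
) -> tuple[ProbSegMap, FitDiagnostics]:
    """Fit the probabilistic segmentation map for one block.

    Maximizes the penalized Bernoulli log-likelihood (module docstring) over
    softmax-parametrized cell scores with L-BFGS and an analytic gradient.
    Initialization is uniform probabilities plus seeded score noise of
    magnitude ``config.init_noise`` to break label symmetry; the fit is
    deterministic given ``config.seed``.  Non-convergence within ``max_iter``
    is reported through the diagnostics flag, not an exception.
    """
    if config is None:
        config = FitConfig()
    if not block.trials:
        raise ValueError("block must contain at least one trial")
    K = block.stimulus.K
    H, W = config.grid_h, config.grid_w
    n_cells = H * W

    cell_i = np.empty(len(block.trials), dtype=int)
    cell_j = np.empty(len(block.trials), dtype=int)
    same = np.empty(len(block.trials), dtype=float)
    for t, trial in enumerate(block.trials):
        ra, ca = cue_to_cell(trial.cue_a, block.stimulus, H, W)
        rb, cb = cue_to_cell(trial.cue_b, block.stimulus, H, W)
        cell_i[t] = ra * W + ca
        cell_j[t] = rb * W + cb
        same[t] = 1.0 if trial.response == "same" else 0.0

    nb_i, nb_j = _neighbor_pairs(H, W)
    lam = config.lambda_smooth

    def unpack(z: np.ndarray) -> np.ndarray:
        z = z.reshape(n_cells, K)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def neg_objective(zflat: np.ndarray) -> tuple[float, np.ndarray]:
        p = unpack(zflat)
        pi = p[cell_i]
        pj = p[cell_j]
        s = np.clip((pi * pj).sum(axis=1), _EPS, 1.0 - _EPS)
        loglik = float(np.sum(same * np.log(s) + (1.0 - same) * np.log1p(-s)))

        diff = p[nb_i] - p[nb_j]
        penalty = lam * float(np.sum(diff * diff))
        obj = loglik - penalty

        # gradient wrt p
        coef = same / s - (1.0 - same) / (1.0 - s)
        g = np.zeros_like(p)
        np.add.at(g, cell_i, coef[:, None] * pj)
        np.add.at(g, cell_j, coef[:, None] * pi)
        np.add.at(g, nb_i, -2.0 * lam * diff)
        np.add.at(g, nb_j, 2.0 * lam * diff)

        # softmax backprop: dJ/dz = p * (g - sum_l g_l p_l)
        gz = p * (g - (g * p).sum(axis=1, keepdims=True))
        return -obj, -gz.ravel()

    rng = np.random.default_rng(config.seed)
    z0 = config.init_noise * rng.standard_normal((n_cells, K))

    trace: list[float] = []

    def track(zk: np.ndarray) -> None:
        trace.append(-neg_objective(zk)[0])

    res = minimize(
        neg_objective,
        z0.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=track,
        options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-8},
    )
    probs = unpack(res.x).reshape(H, W, K)
    # renormalization guard against floating-point drift
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=2, keepdims=True)
    diag = FitDiagnostics(
        objective=float(-res.fun),
        n_iter=int(res.nit),
        converged=bool(res.success) or res.status == 0,
        objective_trace=np.asarray(trace),
    )
    return ProbSegMap(probs), diag


# --------------------------------------------------------------------------
# consistency & exclusion


def classify_consistency(
    block: BlockData, seg: SegMap
) -> tuple[np.ndarray, float]:
    """Flag each trial as consistent with the hard map; return flags and rate.

    A trial is consistent iff its same/different response matches whether the
    argmax labels of the two cued cells are equal.  The inconsistency rate is
    the fraction of inconsistent trials.
    """
    flags = np.empty(len(block.trials), dtype=bool)
    for t, trial in enumerate(block.trials):
        ra, ca = cue_to_cell(trial.cue_a, block.stimulus, seg.grid_h, seg.grid_w)
        rb, cb = cue_to_cell(trial.cue_b, block.stimulus, seg.grid_h, seg.grid_w)
        same_label = seg.labels[ra, ca] == seg.labels[rb, cb]
        flags[t] = (trial.response == "same") == same_label
    rate = inconsistency_rate(int(np.sum(~flags)), len(flags))
    return flags, rate


def inconsistency_rate(n_inconsistent: int, n_total: int) -> float:
    """Proportion of trials whose response contradicts the participant's map."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return n_inconsistent / n_total


def exclusion_percentage(n_excluded: int, n_total: int) -> float:
    """Percent of experimental blocks excluded, e.g. for structureless maps."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_excluded / n_total


def shuffle_responses(block: BlockData, seed: int | None = None) -> BlockData:
    """Surrogate block: responses permuted uniformly across trials.

    Cues, reaction times and trial order are unchanged, so the surrogate
    preserves the marginal count of "same" responses while destroying any
    relation between responses and cue locations.
    """
    if len(block.trials) < 2:
        raise ValueError("need at least 2 trials to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(block.trials))
    trials = [
        replace(t, response=block.trials[p].response)
        for t, p in zip(block.trials, perm)
    ]
    return BlockData(block.participant_id, block.cohort, block.stimulus, trials)


@dataclass
class StructureTestResult:
    """Cross-validated response-predictability test behind the exclusion rule."""

    ll_observed: float          # held-out log-likelihood under the half-fit maps
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int


def _predict_same_prob(
    pmap: ProbSegMap, trials: list[TrialRecord], stimulus: Stimulus
) -> tuple[np.ndarray, np.ndarray]:
    """Model P(same) for each trial's cue pair, plus the observed responses."""
    H, W = pmap.grid_h, pmap.grid_w
    flat = pmap.probs.reshape(-1, pmap.K)
    s = np.empty(len(trials))
    r = np.empty(len(trials))
    for t, trial in enumerate(trials):
        ra, ca = cue_to_cell(trial.cue_a, stimulus, H, W)
        rb, cb = cue_to_cell(trial.cue_b, stimulus, H, W)
        s[t] = np.dot(flat[ra * W + ca], flat[rb * W + cb])
        r[t] = 1.0 if trial.response == "same" else 0.0
    return np.clip(s, _EPS, 1.0 - _EPS), r


def flag_structureless_block(
    block: BlockData,
    config: FitConfig | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    seg: SegMap | None = None,
) -> tuple[bool, StructureTestResult | None]:
    """Flag a block whose fitted map lacks reproducible spatial structure.

    Mirrors the exclusion rule for participants who responded at random
    (responses unrelated to the cue positions).  The block's trials are split
    into odd and even halves and a probabilistic map is fitted to each half.
    Each half-map then predicts the held-out half's responses; the observed
    out-of-sample Bernoulli log-likelihood is compared with a permutation
    null in which the held-out responses are shuffled across their trials
    (add-one one-tailed p).  A participant who truly segmented the image
    yields predictable held-out responses (small p); random responding is
    unpredictable no matter what spatial structure the estimator hallucinates
    into each half-map, so p > alpha and the block is flagged.  A fitted map
    collapsed onto a single label is flagged outright.

    Returns ``(flagged, result)``; ``result`` is None for the single-label
    shortcut.
    """
    if config is None:
        config = FitConfig()
    if seg is None:
        pmap, _ = fit_prob_map(block, config)
        seg = argmax_map(pmap)
    if np.unique(seg.labels).size < 2:
        return True, None

    halves = (list(block.trials[0::2]), list(block.trials[1::2]))
    rng = np.random.default_rng(seed)
    ll_obs = 0.0
    null = np.zeros(n_perm)
    for i in (0, 1):
        train, test = halves[i], halves[1 - i]
        half = BlockData(block.participant_id, block.cohort, block.stimulus, train)
        pm, _ = fit_prob_map(half, replace(config, seed=config.seed + 1 + i))
        s, r = _predict_same_prob(pm, test, block.stimulus)
        # LL = r . a + const with a = logit(s); only the dot product varies
        # under response permutation
        a = np.log(s) - np.log1p(-s)
        const = float(np.log1p(-s).sum())
        ll_obs += float(r @ a) + const
        perm_r = np.tile(r, (n_perm, 1))
        rng.permuted(perm_r, axis=1, out=perm_r)
        null += perm_r @ a + const
    p = (1 + int(np.sum(null >= ll_obs - 1e-12))) / (n_perm + 1)
    result = StructureTestResult(
        ll_observed=float(ll_obs),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        p_value=float(p),
        n_perm=n_perm,
    )
    return bool(p > alpha), result


# --------------------------------------------------------------------------
# evaluation helpers (never applied to participant-facing outputs)


def match_labels(fitted: SegMap, truth: SegMap) -> SegMap:
    """Relabel ``fitted`` by the bijection maximizing cell agreement with ``truth``.

    Segment labels are arbitrary (the estimator cannot know which index the
    ground truth used), so evaluation first solves the assignment problem on
    the label-confusion matrix.
    """
    K = max(fitted.K, truth.K)
    conf = np.zeros((K, K))
    np.add.at(conf, (fitted.labels.ravel() - 1, truth.labels.ravel() - 1), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.arange(K)
    mapping[rows] = cols
    return SegMap(mapping[fitted.labels - 1] + 1, K=K)


def label_agreement(fitted: SegMap, truth: SegMap) -> float:
    """Fraction of cells agreeing with truth after optimal label matching."""
    matched = match_labels(fitted, truth)
    return float(np.mean(matched.labels == truth.labels))
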