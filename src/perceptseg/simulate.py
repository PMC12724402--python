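"""Seedable generators for every input the analysis pipeline consumes.

The generators emulate one experimental block of the cue-pair segmentation
task: a compact K-segment ground-truth map on the 15x15 grid, oriented-noise
texture stimuli, a noisy same/different observer with lapses and an
exponentially shrinking reaction time, a fixation-based gaze stream with
cohort-dependent spread, and 64-channel epoched EEG carrying a posterior
evoked component with cohort-dependent latency and amplitude.

Cohort presets ("NT" and "ASD") encode the qualitative contrast directions of
the study populations: ASD-like observers respond more slowly with a longer
learning trial constant, explore the image more widely, and show a later,
smaller posterior evoked response.  Every generator is bit-reproducible given
its parameters and seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .eeg import EpochSet
from .gaze import GazeStream
from .inference import BlockData, Stimulus, TrialRecord, generate_cue_pairs, trial_schedule
from .maps import SegMap

__all__ = [
    "ObserverParams",
    "EEGSimParams",
    "load_montage",
    "make_ground_truth_map",
    "make_texture_stimulus",
    "simulate_observer_block",
    "simulate_gaze",
    "simulate_epochs",
    "observer_preset",
    "gaze_preset",
    "eeg_preset",
]


# --------------------------------------------------------------------------
# montage

_ROW_Y = {
    "Fp": 0.90, "AF": 0.74, "F": 0.56, "FC": 0.29, "C": 0.0,
    "CP": -0.29, "P": -0.56, "PO": -0.74, "O": -0.90, "I": -1.0,
    "T": 0.0, "FT": 0.29, "TP": -0.29,
}
_LAT_X = {"z": 0.0, "1": -0.16, "2": 0.16, "3": -0.33, "4": 0.33,
          "5": -0.50, "6": 0.50, "7": -0.68, "8": 0.68, "9": -0.82, "10": 0.82}

BIOSEMI64_NAMES = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]


def _schematic_position(name: str) -> tuple[float, float]:
    """Schematic 10-20-style 2-D coordinate for one electrode label."""
    # split the label into row letters and lateral suffix
    i = len(name)
    while i > 0 and (name[i - 1].isdigit()):
        i -= 1
    row, suffix = name[:i], name[i:]
    if suffix == "" and row.endswith("z"):
        row, suffix = row[:-1], "z"
    y = _ROW_Y[row]
    lat = _LAT_X[suffix] if suffix != "z" else 0.0
    if row == "T":  # temporal electrodes sit on the widest part of the head
        lat = -0.85 if suffix == "7" else 0.85
    x = lat * np.sqrt(max(0.15, 1.15 - y * y))
    return round(float(x), 4), round(float(y), 4)


def write_montage_fixture(path: str | Path) -> None:
    """Regenerate the packaged schematic 64-channel coordinate table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y"])
        for name in BIOSEMI64_NAMES:
            x, y = _schematic_position(name)
            w.writerow([name, x, y])


def load_montage() -> tuple[list[str], np.ndarray]:
    """Packaged schematic 64-channel 10-20-style montage: names and 2-D positions."""
    ref = resources.files("perceptseg").joinpath("data/biosemi64_2d.csv")
    names, pos = [], []
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            names.append(row["name"])
            pos.append((float(row["x"]), float(row["y"])))
    return names, np.asarray(pos)


# --------------------------------------------------------------------------
# parameters


@dataclass
class ObserverParams:
    """Response process of a simulated participant.

    Each cue samples a segment label from its cell: the true label with
    probability ``certainty``, otherwise uniform over the remaining labels.
    The response is "same" iff the two sampled labels match; with probability
    ``lapse`` the response is replaced by a fair coin.  Reaction times follow
    ``rt_floor + rt_alpha * 2^(-t / rt_tau)`` times multiplicative lognormal
    noise (sd on the log scale).
    """

    ground_truth: SegMap
    certainty: float = 0.9
    lapse: float = 0.05
    rt_alpha: float = 0.5       # seconds
    rt_tau: float = 20.0        # trials to halve the decaying part
    rt_noise_sd: float = 0.2    # log scale
    rt_floor: float = 0.0       # asymptotic RT (seconds)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 / self.ground_truth.K) <= self.certainty <= 1.0:
            raise ValueError("certainty must lie in [1/K, 1]")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")


@dataclass
class EEGSimParams:
    """Evoked components plus 1/f noise for one cohort's epochs."""

    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(350.0, 10.0, 50.0)]
    )  # (latency ms, amplitude uV, width ms)
    n_channels: int = 64
    sfreq: float = 512.0
    t_start_ms: float = -500.0
    t_end_ms: float = 1000.0
    posterior_center: tuple[float, float] = (0.0, -0.80)
    posterior_sigma: float = 0.35
    noise_sd: float = 8.0       # uV, per sample after spectral shaping
    noise_slope: float = 1.0    # 1/f exponent
    white_frac: float = 0.2     # white-floor share of noise power
    n_epochs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for lat, amp, width in self.components:
            if not self.t_start_ms <= lat <= self.t_end_ms:
                raise ValueError("component latency outside the epoch")
            if not np.isfinite(amp) or width <= 0:
                raise ValueError("component amplitude/width invalid")


# --------------------------------------------------------------------------
# generators


def make_ground_truth_map(
    K: int, grid_h: int = 15, grid_w: int = 15, seed: int | None = None,
    style: str = "voronoi",
) -> SegMap:
    """Spatially compact K-region partition of the grid (seeded Voronoi).

    K distinct seed cells are drawn and every cell takes the label of its
    nearest seed (ties to the lower label), so each label forms one compact,
    connected region and every label is present.  Site sets whose smallest
    region would cover less than half an equal share of the grid are redrawn:
    perceptual segments occupy a substantial part of the image, and a
    few-cell sliver could not be resolved by the trial schedule anyway.
    """
    if not 2 <= K <= 5:
        raise ValueError("K must be in {2..5}")
    if grid_h * grid_w < K:
        raise ValueError("grid too small for K regions")
    if style != "voronoi":
        raise ValueError(f"unknown style: {style}")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:grid_h, 0:grid_w]
    min_size = max(1, int(0.5 * grid_h * grid_w / K))
    for _ in range(200):
        sites = rng.choice(grid_h * grid_w, size=K, replace=False)
        sr, sc = np.divmod(sites, grid_w)
        d2 = (rows[..., None] - sr) ** 2 + (cols[..., None] - sc) ** 2
        labels = np.argmin(d2, axis=2) + 1
        if np.bincount(labels.ravel())[1:].min() >= min_size:
            return SegMap(labels, K=K)
    raise RuntimeError("could not draw a balanced partition")


def _oriented_bandpass(shape: tuple[int, int], orientation_deg: float,
                       freq_cpp: float, bw_freq: float, bw_ori_deg: float) -> np.ndarray:
    """Frequency-domain oriented band-pass weights (symmetric in +-f)."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fx, fy)
    phi = np.arctan2(fy, fx)
    theta = np.deg2rad(orientation_deg)
    # angular distance on the orientation circle (period pi)
    d = np.angle(np.exp(2j * (phi - theta))) / 2.0
    radial = np.exp(-((rho - freq_cpp) ** 2) / (2.0 * bw_freq**2))
    angular = np.exp(-(d**2) / (2.0 * np.deg2rad(bw_ori_deg) ** 2))
    w = radial * angular
    w[0, 0] = 0.0
    return w


def make_texture_stimulus(
    partition: SegMap,
    orientations_deg: list[float],
    freqs_cpp: list[float] | float = 0.15,
    size: int = 256,
    seam_sigma_px: float = 4.0,
    bw_freq: float = 0.04,
    bw_ori_deg: float = 15.0,
    seed: int | None = None,
) -> np.ndarray:
    """Oriented band-pass noise texture with one spectral band per region.

    A single white Gaussian noise image is filtered with a spatially dependent
    oriented band-pass filter: each region of the (pixel-upsampled) partition
    selects its own orientation/frequency band, and region masks are softened
    over ``seam_sigma_px`` so seams are continuous.  ``orientations_deg`` give
    the dominant spectral orientation (direction of the Fourier-domain energy
    peak) per region.  The output is zero-mean, unit-variance, ``size x size``.
    """
    K = partition.K
    if len(orientations_deg) != K:
        raise ValueError("one orientation per region required")
    freqs = [freqs_cpp] * K if np.isscalar(freqs_cpp) else list(freqs_cpp)
    if len(freqs) != K:
        raise ValueError("one frequency per region required")
    if any(not 0 < f < 0.5 for f in freqs):
        raise ValueError("frequencies must lie in (0, 0.5) cycles/pixel")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((size, size))
    spectrum = np.fft.fft2(noise)

    # nearest-neighbor upsample of the partition to pixel resolution
    ri = np.minimum((np.arange(size) * partition.grid_h) // size, partition.grid_h - 1)
    ci = np.minimum((np.arange(size) * partition.grid_w) // size, partition.grid_w - 1)
    labels_px = partition.labels[np.ix_(ri, ci)]

    masks = np.stack([
        gaussian_filter((labels_px == k + 1).astype(float), seam_sigma_px)
        for k in range(K)
    ])
    masks /= masks.sum(axis=0, keepdims=True)

    image = np.zeros((size, size))
    for k in range(K):
        w = _oriented_bandpass((size, size), orientations_deg[k], freqs[k],
                               bw_freq, bw_ori_deg)
        tex = np.real(np.fft.ifft2(spectrum * w))
        sd = tex.std()
        if sd > 0:
            tex /= sd
        image += masks[k] * tex
    image -= image.mean()
    sd = image.std()
    if sd > 0:
        image /= sd
    return image


def simulate_observer_block(
    params: ObserverParams,
    stimulus: Stimulus,
    n_trials: int | None = None,
    grid_h: int = 15,
    grid_w: int = 15,
    participant_id: str = "sim",
    cohort: str = "NT",
) -> BlockData:
    """One simulated block: scheduled cue pairs with model responses and RTs.

    ``n_trials`` defaults to the minimal schedule ``grid_cells * (K - 1)``.
    """
    gt = params.ground_truth
    if (gt.grid_h, gt.grid_w) != (grid_h, grid_w):
        raise ValueError("ground truth grid must match the analysis grid")
    K = stimulus.K
    if gt.K != K:
        raise ValueError("stimulus K must match the ground truth")
    if n_trials is None:
        n_trials = trial_schedule(K, grid_h, grid_w)
    rng = np.random.default_rng(params.seed)
    pair_seed = int(rng.integers(0, 2**31 - 1))
    pairs = generate_cue_pairs(n_trials, stimulus, grid_h, grid_w, seed=pair_seed)

    trials = []
    for t, (cue_a, cue_b) in enumerate(pairs, start=1):
        labs = []
        for cue in (cue_a, cue_b):
            col = min(int(cue[0] * grid_w / stimulus.width), grid_w - 1)
            row = min(int(cue[1] * grid_h / stimulus.height), grid_h - 1)
            true = gt.labels[row, col]
            if rng.random() < params.certainty:
                labs.append(true)
            else:
                others = [k for k in range(1, K + 1) if k != true]
                labs.append(others[rng.integers(0, K - 1)])
        response = "same" if labs[0] == labs[1] else "different"
        if rng.random() < params.lapse:
            response = "same" if rng.random() < 0.5 else "different"
        rt = (params.rt_floor + params.rt_alpha * 2.0 ** (-t / params.rt_tau)) * float(
            np.exp(params.rt_noise_sd * rng.standard_normal())
        )
        trials.append(TrialRecord(t, cue_a, cue_b, response, rt))
    return BlockData(participant_id, cohort, stimulus, trials)


def simulate_gaze(
    duration_s: float,
    spread_px: float,
    n_fixations: int = 20,
    width: int = 256,
    height: int = 256,
    center: tuple[float, float] | None = None,
    jitter_px: float = 1.0,
    sfreq: float = 500.0,
    seed: int | None = None,
) -> GazeStream:
    """Fixation-sequence gaze at 500 Hz with Gaussian scatter of fixations.

    Fixation centers are drawn from an isotropic Gaussian of dispersion
    ``spread_px`` around the image center (clipped inside the image);
    fixation durations are random proportions of ``duration_s``.  Samples
    carry small positional jitter; all samples are valid.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if center is None:
        center = (width / 2.0, height / 2.0)
    n_samples = max(int(round(duration_s * sfreq)), n_fixations)
    # split samples over fixations with random proportions
    props = rng.dirichlet(np.ones(n_fixations))
    counts = np.maximum(np.round(props * n_samples).astype(int), 1)
    while counts.sum() > n_samples:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_samples:
        counts[np.argmin(counts)] += 1

    fx = np.clip(center[0] + spread_px * rng.standard_normal(n_fixations), 0, width - 1)
    fy = np.clip(center[1] + spread_px * rng.standard_normal(n_fixations), 0, height - 1)
    x = np.repeat(fx, counts) + jitter_px * rng.standard_normal(n_samples)
    y = np.repeat(fy, counts) + jitter_px * rng.standard_normal(n_samples)
    x = np.clip(x, 0, width - 1)
    y = np.clip(y, 0, height - 1)
    t = np.arange(n_samples) / sfreq
    return GazeStream(t, x, y, np.ones(n_samples, dtype=bool))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_t: int,
                sfreq: float, slope: float, white_frac: float) -> np.ndarray:
    """Seeded 1/f^slope noise with a white floor, unit variance, along last axis."""
    freqs = np.fft.rfftfreq(n_t, d=1.0 / sfreq)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-slope / 2.0)
    shaping = np.sqrt((1 - white_frac) * shaping**2 / np.mean(shaping[1:] ** 2)
                      + white_frac)
    shaping[0] = 0.0
    white = rng.standard_normal(shape + (n_t,))
    spec = np.fft.rfft(white, axis=-1) * shaping
    colored = np.fft.irfft(spec, n=n_t, axis=-1)
    sd = colored.std()
    return colored / sd if sd > 0 else colored


def simulate_epochs(
    params: EEGSimParams,
    rts: np.ndarray,
    ch_names: list[str] | None = None,
    ch_pos: np.ndarray | None = None,
    participant_id: str = "sim",
    cohort: str = "NT",
) -> EpochSet:
    """Epoched EEG: posterior Gaussian-bump components plus 1/f noise.

    Every epoch contains the same evoked components (channel-weighted by a
    posterior Gaussian profile whose maximum weight is 1, so the peak
    amplitude on the best channel equals the component amplitude) plus
    independent seeded 1/f noise per channel and epoch.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size != params.n_epochs:
        raise ValueError("need one reaction time per epoch")
    if ch_names is None or ch_pos is None:
        ch_names, ch_pos = load_montage()
    if len(ch_names) != params.n_channels:
        raise ValueError("montage size must match n_channels")

    n_t = int(round((params.t_end_ms - params.t_start_ms) / 1000.0 * params.sfreq))
    times_ms = params.t_start_ms + np.arange(n_t) * 1000.0 / params.sfreq

    d2 = ((ch_pos - np.asarray(params.posterior_center)) ** 2).sum(axis=1)
    weights = np.exp(-d2 / (2.0 * params.posterior_sigma**2))
    weights /= weights.max()

    signal = np.zeros((params.n_channels, n_t))
    for lat, amp, width in params.components:
        bump = np.exp(-((times_ms - lat) ** 2) / (2.0 * width**2))
        signal += amp * weights[:, None] * bump[None, :]

    rng = np.random.default_rng(params.seed)
    noise = params.noise_sd * _pink_noise(
        rng, (params.n_channels, params.n_epochs), n_t,
        params.sfreq, params.noise_slope, params.white_frac,
    ).transpose(0, 2, 1)  # -> channels x time x epochs
    data = signal[:, :, None] + noise
    return EpochSet(data, list(ch_names), np.asarray(ch_pos), times_ms, rts,
                    sfreq=params.sfreq, participant_id=participant_id,
                    cohort=cohort)


# --------------------------------------------------------------------------
# cohort presets


def observer_preset(cohort: str, ground_truth: SegMap, seed: int = 0) -> ObserverParams:
    """Observer parameters encoding the cohorts' qualitative RT contrast.

    Both cohorts share the response-noise structure (uncertainty and
    self-consistency were comparable between the study populations); they
    differ in reaction-time level and learning speed: the ASD-like preset is
    slower (floor 0.52 s vs 0.40 s, matching the printed median ordering) and
    halves its decaying RT component more slowly (trial constant 21.9 vs 18.4
    trials).
    """
    common = dict(ground_truth=ground_truth, certainty=0.85, lapse=0.05,
                  rt_noise_sd=0.25, seed=seed)
    if cohort == "NT":
        return ObserverParams(rt_alpha=0.35, rt_tau=18.4, rt_floor=0.40, **common)
    if cohort == "ASD":
        return ObserverParams(rt_alpha=0.40, rt_tau=21.9, rt_floor=0.52, **common)
    raise ValueError("cohort must be 'NT' or 'ASD'")


def gaze_preset(cohort: str) -> dict:
    """Viewing duration and fixation spread per cohort (wider, longer in ASD)."""
    if cohort == "NT":
        return dict(duration_s=9.0, spread_px=45.0, n_fixations=27)
    if cohort == "ASD":
        return dict(duration_s=10.5, spread_px=65.0, n_fixations=32)
    raise ValueError("cohort must be 'NT' or 'ASD'")


def eeg_preset(cohort: str, seed: int = 0, n_epochs: int = 40) -> EEGSimParams:
    """Posterior evoked component per cohort: ASD-like is 75 ms later, x0.7 amplitude."""
    if cohort == "NT":
        comps = [(350.0, 10.0, 50.0)]
    elif cohort == "ASD":
        comps = [(425.0, 7.0, 50.0)]
    else:
        raise ValueError("cohort must be 'NT' or 'ASD'")
    return EEGSimParams(components=comps, n_epochs=n_epochs, seed=seed)
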