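"""End-to-end orchestration: simulate -> infer maps -> analyze -> report.

A single declarative :class:`RunConfig` (YAML-serializable) drives the whole
chain on synthetic cohorts and produces a machine-readable summary containing
every statistic family the analysis emits: per-pair Information Gain, mean
uncertainty, inconsistency rates, reaction-time medians and learning-curve
fits, gaze coverage curves, and ERP/GFP significance windows.  Per-stage
seeds derive deterministically from the master seed through a spawn-key
counter, so a config fully determines the numerical output.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field, fields
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, eeg, gaze, inference, maps, rt, simulate

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "stage_seed"]

logger = logging.getLogger("perceptseg")

_STAGES = ("simulate", "maps", "rt", "gaze", "eeg")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "perceptseg_run"
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    # experiment
    K: int = 2
    grid: int = 15
    n_participants: dict = field(default_factory=lambda: {"NT": 3, "ASD": 3})
    schedule_multiplier: float = 1.0
    # map inference / similarity
    lambda_smooth: float = 5.0
    n_perm: int = 10_000
    # reaction times
    n_boot: int = 9_999
    sliding_window: int = 500
    # gaze
    sigma_px: float = 10.0
    coverage_windows_s: list = field(default_factory=lambda: list(range(1, 11)))
    # eeg
    n_epochs: int = 40
    alpha: float = 0.05
    min_duration_ms: float = 50.0
    gfp_step_ms: float = 50.0
    cluster_n_perm: int = 200

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage: {s!r}")

    # ----------------------------------------------------------- serialization
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        for key in d:
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**d)


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed: SeedSequence(master, spawn_key=(stage, index))."""
    ss = np.random.SeedSequence(master, spawn_key=(_STAGES.index(stage), index))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# --------------------------------------------------------------------------


def _simulate_cohorts(config: RunConfig, out: Path) -> dict:
    """Generate blocks, gaze streams and epochs for both cohorts."""
    gt = simulate.make_ground_truth_map(
        config.K, config.grid, config.grid, seed=stage_seed(config.seed, "simulate")
    )
    stim = inference.Stimulus("synthetic", K=config.K)
    n_trials = int(
        round(config.schedule_multiplier * inference.trial_schedule(config.K, config.grid, config.grid))
    )
    bundle = {"ground_truth": gt, "stimulus": stim, "blocks": {}, "gaze": {}, "epochs": {}}
    idx = 1
    for cohort, n_sub in config.n_participants.items():
        for s in range(n_sub):
            pid = f"{cohort}{s + 1:02d}"
            obs = simulate.observer_preset(
                cohort, gt, seed=stage_seed(config.seed, "simulate", idx)
            )
            block = simulate.simulate_observer_block(
                obs, stim, n_trials, config.grid, config.grid,
                participant_id=pid, cohort=cohort,
            )
            gp = simulate.gaze_preset(cohort)
            stream = simulate.simulate_gaze(
                seed=stage_seed(config.seed, "simulate", 1000 + idx), **gp
            )
            ep = simulate.eeg_preset(
                cohort, seed=stage_seed(config.seed, "simulate", 2000 + idx),
                n_epochs=config.n_epochs,
            )
            rts = np.array([t.rt for t in block.trials[: config.n_epochs]])
            epochs = simulate.simulate_epochs(ep, rts, participant_id=pid, cohort=cohort)
            bundle["blocks"][pid] = block
            bundle["gaze"][pid] = stream
            bundle["epochs"][pid] = epochs
            block.to_files(out / f"block_{pid}.tsv")
            stream.to_file(out / f"gaze_{pid}.tsv")
            idx += 1
    gt.to_files(out / "ground_truth.tsv")
    return bundle


def _analyze_maps(config: RunConfig, bundle: dict, out: Path) -> dict:
    fitcfg = inference.FitConfig(
        grid_h=config.grid, grid_w=config.grid,
        lambda_smooth=config.lambda_smooth,
        seed=stage_seed(config.seed, "maps"),
    )
    summary: dict = {"uncertainty_pct": {}, "inconsistency_rate": {}, "ig_percent": {}}
    segs: dict[str, maps.SegMap] = {}
    for pid, block in bundle["blocks"].items():
        pmap, diag = inference.fit_prob_map(block, fitcfg)
        seg = maps.argmax_map(pmap)
        segs[pid] = seg
        emap = maps.entropy_map(pmap)
        summary["uncertainty_pct"][pid] = maps.mean_uncertainty(emap)
        _, rate = inference.classify_consistency(block, seg)
        summary["inconsistency_rate"][pid] = rate
        pmap.to_files(out / f"probmap_{pid}.tsv")
        seg.to_files(out / f"segmap_{pid}.tsv")
        logger.info("fitted %s: objective=%.2f iters=%d converged=%s",
                    pid, diag.objective, diag.n_iter, diag.converged)
    for cohort in bundle_cohorts(bundle):
        pids = [p for p in segs if p.startswith(cohort)]
        for i, (a, b) in enumerate(combinations(pids, 2)):
            ig = maps.information_gain(
                segs[a], segs[b], n_perm=config.n_perm,
                seed=stage_seed(config.seed, "maps", 100 + i),
            )
            summary["ig_percent"][f"{a}-{b}"] = ig.ig_percent
    bundle["segs"] = segs
    return summary


def bundle_cohorts(bundle: dict) -> list[str]:
    return sorted({b.cohort for b in bundle["blocks"].values()})


def _analyze_rt(config: RunConfig, bundle: dict) -> dict:
    summary = {}
    for cohort in bundle_cohorts(bundle):
        blocks = [b for b in bundle["blocks"].values() if b.cohort == cohort]
        rts, idxs, bids, flags = [], [], [], []
        for b in blocks:
            seg = bundle.get("segs", {}).get(b.participant_id)
            cons, _ = (inference.classify_consistency(b, seg)
                       if seg is not None else (np.ones(len(b.trials), bool), 0.0))
            for trial, c in zip(b.trials, cons):
                rts.append(trial.rt)
                idxs.append(trial.trial_index)
                bids.append(b.participant_id)
                flags.append(c)
        series = rt.RTSeries(np.array(rts), np.array(idxs), np.array(bids),
                             np.array(flags))
        filtered = rt.filter_rts(series)
        med, ci = rt.median_rt_ci(filtered, n_boot=config.n_boot,
                                  seed=stage_seed(config.seed, "rt"))
        fit = rt.fit_trial_constant(filtered)
        delay, dci, _ = rt.inconsistency_delay(
            filtered, n_boot=config.n_boot, seed=stage_seed(config.seed, "rt", 1)
        )
        summary[cohort] = {
            "median_s": med, "median_ci_s": list(ci),
            "alpha_s": fit.alpha, "tau_trials": fit.tau,
            "inconsistency_delay_s": delay, "delay_ci_s": list(dci),
        }
    return summary


def _analyze_gaze(config: RunConfig, bundle: dict, out: Path) -> dict:
    summary = {}
    for cohort in bundle_cohorts(bundle):
        curves = []
        for pid, stream in bundle["gaze"].items():
            if not pid.startswith(cohort):
                continue
            cleaned, _ = gaze.clean_gaze(stream)
            dmap = gaze.gaze_density(cleaned, sigma=config.sigma_px)
            gaze.downsample_density(dmap)
            curve = gaze.coverage_curve(cleaned, np.asarray(config.coverage_windows_s, float))
            curve.to_file(out / f"coverage_{pid}.tsv")
            curves.append(curve.coverage_pct)
        summary[cohort] = {
            "windows_s": list(map(float, config.coverage_windows_s)),
            "mean_coverage_pct": list(np.mean(curves, axis=0)),
        }
    return summary


def _analyze_eeg(config: RunConfig, bundle: dict) -> dict:
    traces: dict[str, list[np.ndarray]] = {}
    gfps: dict[str, list[np.ndarray]] = {}
    times = None
    for pid, epochs in bundle["epochs"].items():
        cleaned = eeg.exclude_by_rt(epochs)
        cleaned = eeg.rereference_average(cleaned)
        cleaned = eeg.baseline_correct(cleaned)
        erp = eeg.compute_erp(cleaned, channels=list(eeg.OPO_CHANNELS),
                              level="participant")
        full = eeg.compute_erp(cleaned, level="participant")
        cohort = epochs.cohort
        traces.setdefault(cohort, []).append(erp.data)
        gfps.setdefault(cohort, []).append(eeg.gfp(full.data))
        times = cleaned.times_ms
    cohorts = sorted(traces)
    summary: dict = {"cohorts": cohorts}
    if len(cohorts) == 2:
        a, b = cohorts
        win = eeg.pointwise_ttest_windows(
            np.array(traces[a]), np.array(traces[b]), times,
            alpha=config.alpha, min_duration_ms=config.min_duration_ms,
        )
        tt, p, flags = eeg.gfp_interval_tests(
            np.array(gfps[a]), np.array(gfps[b]), times,
            step_ms=config.gfp_step_ms, alpha=config.alpha,
        )
        summary["erp_significance_windows_ms"] = [list(w) for w in win.windows]
        summary["gfp_significant_times_ms"] = [float(t) for t in tt[flags]]
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the summary.

    Artifacts and a ``summary.json`` are written under ``config.out_dir``;
    the log records the package version, parameters and derived seeds.  A
    stage failure raises with the stage name attached; artifacts from earlier
    stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("perceptseg %s on %s", __version__, platform.python_version())
    logger.info("config: %s", json.dumps(asdict(config), sort_keys=True))

    summary: dict = {"config": asdict(config)}
    bundle = None
    try:
        if config.stages.get("simulate", True):
            bundle = _simulate_cohorts(config, out)
        if bundle is None:
            raise RuntimeError("analysis stages require the simulate stage")
        if config.stages.get("maps", True):
            summary["maps"] = _analyze_maps(config, bundle, out)
        if config.stages.get("rt", True):
            summary["rt"] = _analyze_rt(config, bundle)
        if config.stages.get("gaze", True):
            summary["gaze"] = _analyze_gaze(config, bundle, out)
        if config.stages.get("eeg", True):
            summary["eeg"] = _analyze_eeg(config, bundle)
    except Exception as exc:
        logger.error("stage failure: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


# --------------------------------------------------------------------------


def validate_inputs(paths: list[str | Path]) -> dict:
    """Schema and invariant checks on declared input files.

    Recognizes block trial tables (``block*.tsv``) and gaze streams
    (``gaze*.tsv``) by their columns.  Returns a report with itemized
    ``errors`` (violations of hard invariants, citing the row) and
    ``warnings``.
    """
    report: dict = {"errors": [], "warnings": [], "checked": []}
    for p in map(Path, paths):
        if not p.exists():
            report["errors"].append(f"{p}: file not found")
            continue
        try:
            df = pd.read_csv(p, sep="\t")
        except Exception as exc:
            report["errors"].append(f"{p}: unreadable ({exc})")
            continue
        cols = set(df.columns)
        if {"trial_index", "response", "rt_s"} <= cols:
            bad_rt = df.index[df["rt_s"] <= 0]
            for i in bad_rt:
                report["errors"].append(f"{p}: row {i}: rt_s must be positive")
            bad_resp = df.index[~df["response"].isin(["same", "different"])]
            for i in bad_resp:
                report["errors"].append(f"{p}: row {i}: invalid response")
            if df["trial_index"].duplicated().any():
                report["errors"].append(f"{p}: duplicate trial_index")
        elif {"t_s", "x_px", "y_px", "valid"} <= cols:
            t = df["t_s"].to_numpy()
            if t.size > 1 and np.any(np.diff(t) <= 0):
                row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
                report["errors"].append(f"{p}: row {row}: non-monotone timestamps")
        else:
            report["warnings"].append(f"{p}: unrecognized schema")
        report["checked"].append(str(p))
    return report
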