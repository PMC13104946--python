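"""Event-log and configuration formats, plus the end-to-end experiment runner.

The event-log format is a plain CSV with header
``t_s,patch,rewarded,block_id,variant,kappa,mean_interval_s`` — one row per
press, timestamps with six decimal places, ``rewarded`` as 0/1, and
``mean_interval_s`` the mean RAI of the pressed patch.  Logs round-trip
exactly through :func:`write_event_log` / :func:`read_event_log`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import (
    EVENT_COLUMNS,
    PATCH_ORDER,
    AgentSpec,
    SessionConfig,
    SessionLog,
    run_session,
)
from .metrics import (
    BlockMetrics,
    block_metrics,
    push_fraction,
    quality_rank_spearman,
    timeresolved_spearman,
    windowed_push_fraction,
)
from .schedules import PATCH_MEAN_INTERVALS, PatchId, Variant

__all__ = [
    "LOG_COLUMNS",
    "write_event_log",
    "read_event_log",
    "RunConfig",
    "load_run_config",
    "run_experiment",
    "save_lut_csv",
    "write_frames_png",
    "write_gif",
]

logger = logging.getLogger("patchforage")

LOG_COLUMNS = [
    "t_s",
    "patch",
    "rewarded",
    "block_id",
    "variant",
    "kappa",
    "mean_interval_s",
]


def write_event_log(log: SessionLog, path: str | Path) -> Path:
    """Write one session's events in the documented CSV format."""
    path = Path(path)
    cfg = log.config
    ev = log.events
    with open(path, "w", newline="") as fh:
        fh.write(",".join(LOG_COLUMNS) + "\n")
        for t, patch, rewarded in ev[EVENT_COLUMNS].itertuples(index=False):
            mi = cfg.mean_intervals[PatchId(patch)]
            fh.write(
                f"{t:.6f},{patch},{int(rewarded)},{cfg.block_id},"
                f"{cfg.variant.value},{cfg.kappa:.6f},{mi:.6f}\n"
            )
    return path


def read_event_log(path: str | Path) -> SessionLog:
    """Read and validate an event-log CSV; schema violations name the line."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    valid = {p.value for p in PatchId}
    for i, patch in enumerate(df["patch"]):
        if patch not in valid:
            raise ValueError(f"{path}, line {i + 2}: unknown patch label {patch!r}")
    t = df["t_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}, line {bad[0] + 3}: timestamps not strictly increasing"
        )
    mean_intervals = dict(PATCH_MEAN_INTERVALS)
    for p in PatchId:
        vals = df.loc[df["patch"] == p.value, "mean_interval_s"].unique()
        if len(vals) > 1:
            raise ValueError(f"{path}: inconsistent mean_interval_s for {p.value}")
        if len(vals) == 1:
            mean_intervals[p] = float(vals[0])
    cfg = SessionConfig(
        variant=Variant(df["variant"].iloc[0]) if len(df) else Variant.EXPONENTIAL,
        kappa=float(df["kappa"].iloc[0]) if len(df) else 1.0,
        seed=0,
        duration=float(t[-1]) if len(df) else 0.0,
        block_id=str(df["block_id"].iloc[0]) if len(df) else "block0",
        mean_intervals=mean_intervals,
    )
    events = df[EVENT_COLUMNS].copy()
    events["rewarded"] = events["rewarded"].astype(bool)
    return SessionLog(cfg, events.reset_index(drop=True))


@dataclass
class RunConfig:
    """End-to-end experiment: one variant, several reliability levels."""

    variant: Variant = Variant.GAMMA
    kappas: list[float] = field(default_factory=lambda: [0.1, 4.0])
    agent: AgentSpec = field(default_factory=lambda: AgentSpec("cue_threshold"))
    n_blocks: int = 10
    duration: float = 900.0
    seed: int = 0
    window: float = 60.0
    step: float = 10.0
    n_null: int = 1000
    out_dir: Path = Path("patchforage_out")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "variant" in raw:
        kwargs["variant"] = Variant(raw["variant"])
    for key in ("kappas", "n_blocks", "duration", "seed", "window", "step", "n_null"):
        if key in raw:
            kwargs[key] = raw[key]
    if "agent" in raw:
        kwargs["agent"] = AgentSpec(**raw["agent"])
    if "out_dir" in raw:
        kwargs["out_dir"] = Path(raw["out_dir"])
    return RunConfig(**kwargs)


def _block_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-block seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def _metrics_row(bm: BlockMetrics, cfg: SessionConfig) -> dict:
    row = {
        "block_id": bm.block_id,
        "variant": cfg.variant.value,
        "kappa": cfg.kappa,
        "spearman_rho": bm.spearman_rho,
        "spearman_p_exact": bm.spearman_p_exact,
        "p_to_fast_given_not_fast": bm.transitions.p_to_fast_given_not_fast,
    }
    for p in PATCH_ORDER:
        row[f"fraction_{p.value}"] = bm.push_fractions[p]
        row[f"ipi_median_{p.value}"] = bm.ipi[p].median
        row[f"self_transition_{p.value}"] = bm.transitions.self_transitions[p]
        row[f"norm_stay_{p.value}"] = bm.norm_stay[p]
        row[f"norm_return_{p.value}"] = bm.norm_return[p]
    return row


def run_experiment(config: RunConfig, force: bool = False) -> dict:
    """Simulate, analyze, and write all outputs for one experiment.

    Emits under ``config.out_dir``: ``events.csv`` (all blocks),
    ``block_metrics.csv``, ``pooled.json``, ``timecourse.csv``, and
    ``config.yaml`` (full provenance incl. derived per-block seeds).
    Refuses to overwrite an existing output directory unless ``force``.
    """
    out = Path(config.out_dir)
    declared = ["events.csv", "block_metrics.csv", "pooled.json", "timecourse.csv", "config.yaml"]
    if out.exists() and any((out / f).exists() for f in declared) and not force:
        raise FileExistsError(f"{out} already contains outputs; pass force=True")
    out.mkdir(parents=True, exist_ok=True)

    n_total = len(config.kappas) * config.n_blocks
    seeds = _block_seeds(config.seed, n_total)
    analysis_rng = np.random.default_rng(_block_seeds(config.seed + 1, 1)[0])

    all_events = []
    rows = []
    logs_by_kappa: dict[float, list[SessionLog]] = {k: [] for k in config.kappas}
    failures = []
    k = 0
    for kappa in config.kappas:
        for b in range(config.n_blocks):
            block_id = f"{config.variant.value}_k{kappa:g}_b{b:03d}"
            scfg = SessionConfig(
                variant=config.variant,
                kappa=kappa,
                seed=int(seeds[k]),
                duration=config.duration,
                block_id=block_id,
            )
            k += 1
            try:
                log = run_session(scfg, config.agent)
                logs_by_kappa[kappa].append(log)
                ev = log.events.copy()
                ev["block_id"] = block_id
                ev["variant"] = config.variant.value
                ev["kappa"] = kappa
                ev["mean_interval_s"] = [
                    scfg.mean_intervals[PatchId(p)] for p in ev["patch"]
                ]
                all_events.append(ev)
                rows.append(_metrics_row(block_metrics(log, config.n_null, analysis_rng), scfg))
                logger.info("block %s: %d presses", block_id, len(log.events))
            except Exception as exc:  # isolate per-block failures
                failures.append({"block_id": block_id, "error": str(exc)})
                logger.warning("block %s failed: %s", block_id, exc)

    pd.concat(all_events, ignore_index=True)[LOG_COLUMNS].to_csv(
        out / "events.csv", index=False, float_format="%.6f"
    )
    pd.DataFrame(rows).to_csv(out / "block_metrics.csv", index=False)

    pooled = {"failures": failures, "conditions": {}}
    tc_rows = []
    for kappa, logs in logs_by_kappa.items():
        if len(logs) < 2:
            continue
        sp = quality_rank_spearman([push_fraction(lg) for lg in logs])
        pooled["conditions"][f"kappa={kappa:g}"] = {
            "spearman_rho": sp.rho,
            "spearman_p": sp.p,
            "n": sp.n,
        }
        wf = windowed_push_fraction(logs, config.window, config.step)
        tr = timeresolved_spearman(logs, config.window, config.step)
        for i, t in enumerate(wf.times):
            for j, p in enumerate(PATCH_ORDER):
                tc_rows.append(
                    dict(kappa=kappa, time_s=t, patch=p.value,
                         mean=wf.mean[i, j], sem=wf.sem[i, j])
                )
            tc_rows.append(
                dict(kappa=kappa, time_s=t, patch="rho", mean=tr.mean[i], sem=tr.sem[i])
            )
    pd.DataFrame(tc_rows).to_csv(out / "timecourse.csv", index=False)
    with open(out / "pooled.json", "w") as fh:
        json.dump(pooled, fh, indent=2)

    provenance = asdict(config)
    provenance["variant"] = config.variant.value
    provenance["agent"]["kind"] = config.agent.kind
    provenance["out_dir"] = str(config.out_dir)
    provenance["block_seeds"] = [int(s) for s in seeds]
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    return pooled


def save_lut_csv(lut: np.ndarray, path: str | Path) -> Path:
    """Serialize a color LUT as ``phase_bin_low,R,G,B`` rows."""
    path = Path(path)
    n = len(lut)
    lows = -np.pi + 2.0 * np.pi * np.arange(n) / n
    with open(path, "w", newline="") as fh:
        fh.write("phase_bin_low,R,G,B\n")
        for low, (r, g, b) in zip(lows, lut):
            fh.write(f"{low:.8f},{r},{g},{b}\n")
    return path


def write_frames_png(frames: list[np.ndarray], out_dir: str | Path) -> list[Path]:
    """Write 8-bit RGB frames as frame_0000.png, frame_0001.png, ..."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i:04d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def write_gif(frames: list[np.ndarray], path: str | Path, fps: float = 20.0) -> Path:
    """Write frames as an animated GIF at the given frame rate."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, frames, duration=1000.0 / fps, loop=0)
    return path
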