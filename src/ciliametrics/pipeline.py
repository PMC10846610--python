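"""End-to-end simulate → measure → report pipeline.

A :class:`RunConfig` names the conditions of a synthetic two-(or more-)
condition study: per-condition overrides of the generator parameter blocks,
one master seed, and an output directory. :func:`run_pipeline` executes the
requested stages, materializes every intermediate (images, kymograms,
tables) to disk, and writes the group-comparison report. Two runs with
identical config and seed produce identical measurement tables.
"""

from __future__ import annotations

import dataclasses
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import ImageCalibration
from .io import write_json_sidecar, write_tiff
from .kymo import analyze_beat_video
from .regions import segment_regions, summarize_regions
from .stats import export_report
from .streaks import TrackFilterParams, binarize, extract_tracks, to_8bit, tracks_to_frame
from .synthetic import (
    BeatSimParams,
    CiliumSimParams,
    SwimFieldParams,
    simulate_beat_video,
    simulate_cilium_profile,
    simulate_cilium_timelapse,
    simulate_swim_field,
)
from .ift import detect_events, event_frequency

__all__ = ["RunConfig", "run_pipeline", "load_config"]

# measurement stages and the generator parameter block each consumes
STAGES = ("streaks", "beat", "regions", "ift")


@dataclass
class RunConfig:
    """Resolved configuration of one synthetic study run."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulate_only: bool = False
    baseline: str = "control"
    # per-condition overrides of generator parameter fields, e.g.
    # {"control": {}, "pkd2": {"swim": {"speed_mean_um_s": 96.0}}}
    conditions: dict = field(default_factory=lambda: {"control": {}})
    swim_cal: dict = field(default_factory=lambda: {"um_per_px": 1.0, "exposure_s": 1.0})
    beat_cal: dict = field(default_factory=lambda: {"um_per_px": 0.5, "fps": 1000.0})
    ift_cal: dict = field(default_factory=lambda: {"um_per_px": 0.1, "fps": 10.0})
    n_beat_cells: int = 8
    n_cilia: int = 20
    n_ift_recordings: int = 4
    track_filter: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
        if self.baseline not in self.conditions:
            raise ValueError(
                f"baseline {self.baseline!r} is not one of the conditions "
                f"{sorted(self.conditions)}"
            )


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file of flat per-module key blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if isinstance(cfg.stages, list):
        cfg.stages = tuple(cfg.stages)
    return cfg


def _condition_params(cls, overrides: dict, block: str, seed: int):
    params = cls(seed=seed)
    for key, val in (overrides.get(block) or {}).items():
        if not hasattr(params, key):
            raise ValueError(f"unknown {block} parameter {key!r}")
        setattr(params, key, val)
    params.seed = seed
    return params


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages for every condition and write the bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    # one child per (condition, stage, replicate), drawn in documented order:
    # conditions sorted, stages in STAGES order, replicates ascending
    tables: dict[str, pd.DataFrame] = {}
    rows: dict[str, list[dict]] = {s: [] for s in config.stages}

    cond_names = sorted(config.conditions)
    children = {name: np.random.SeedSequence(config.seed).spawn(len(cond_names))[i]
                for i, name in enumerate(cond_names)}

    for name in cond_names:
        overrides = config.conditions[name] or {}
        cond_dir = out / name
        cond_dir.mkdir(parents=True, exist_ok=True)
        stage_seeds = children[name].spawn(len(STAGES))
        seeds = {s: int(ss.generate_state(1)[0] % (2**31)) for s, ss in zip(STAGES, stage_seeds)}

        if "streaks" in config.stages:
            cal = ImageCalibration.from_dict(config.swim_cal)
            params = _condition_params(SwimFieldParams, overrides, "swim", seeds["streaks"])
            image, truth = simulate_swim_field(params, cal)
            write_tiff(cond_dir / "streaks.tif", image, cal.um_per_px)
            truth.to_csv(cond_dir / "streaks_truth.csv", index=False)
            if not config.simulate_only:
                fparams = TrackFilterParams(**config.track_filter)
                mask = binarize(to_8bit(image), fparams)
                tracks = extract_tracks(mask, cal, fparams)
                frame = tracks_to_frame(tracks)
                frame.to_csv(cond_dir / "streak_tracks.csv", index=False)
                for _, r in frame[~frame["flagged"]].iterrows():
                    rows["streaks"].append({
                        "group": name, "velocity_um_s": r["velocity_actual_um_s"],
                    })

        if "beat" in config.stages:
            cal = ImageCalibration.from_dict(config.beat_cal)
            base = _condition_params(BeatSimParams, overrides, "beat", seeds["beat"])
            for k in range(config.n_beat_cells):
                params = dataclasses.replace(base, seed=seeds["beat"] + k)
                stack, truth = simulate_beat_video(params, cal)
                if k == 0:
                    write_tiff(cond_dir / "beat_stack.tif", stack, cal.um_per_px)
                if not config.simulate_only:
                    metrics = analyze_beat_video(stack, cal)
                    rows["beat"].append({
                        "group": name,
                        "velocity_um_s": metrics.velocity_um_s,
                        "beat_freq_hz": metrics.beat_freq_hz,
                        "efficiency_um_per_beat": metrics.efficiency_um_per_beat,
                    })

        if "regions" in config.stages:
            base = _condition_params(CiliumSimParams, overrides, "cilium", seeds["regions"])
            segs = []
            for k in range(config.n_cilia):
                params = dataclasses.replace(base, seed=seeds["regions"] + k)
                profile, _ = simulate_cilium_profile(params)
                if k == 0:
                    profile.to_csv(cond_dir / "cilium_profile.csv", index=False)
                if not config.simulate_only:
                    seg = segment_regions(profile)
                    segs.append(seg)
                    rows["regions"].append({
                        "group": name,
                        "proximal_len_um": seg.proximal_len_um,
                        "distal_len_um": seg.distal_len_um,
                        "gap_len_um": seg.gap_len_um,
                        "ratio_distal_over_proximal": seg.ratio_distal_over_proximal,
                    })
            if any(not s.no_signal for s in segs):
                write_json_sidecar(cond_dir / "regions_summary.json", summarize_regions(segs))

        if "ift" in config.stages:
            cal = ImageCalibration.from_dict(config.ift_cal)
            base = _condition_params(CiliumSimParams, overrides, "ift", seeds["ift"])
            for k in range(config.n_ift_recordings):
                params = dataclasses.replace(base, seed=seeds["ift"] + k)
                kym, truth_events = simulate_cilium_timelapse(params)
                if k == 0:
                    write_tiff(cond_dir / "ift_kymogram.tif", kym * 1000, cal.um_per_px)
                if not config.simulate_only:
                    events = detect_events(kym, cal)
                    summary = event_frequency(events, params.duration_s)
                    rows["ift"].append({
                        "group": name,
                        "freq_events_min": summary.combined_freq_events_min,
                    })

    result: dict = {"out_dir": str(out)}
    if not config.simulate_only:
        tables = {s: pd.DataFrame(r) for s, r in rows.items() if r}
        group_map = {name: config.baseline for name in cond_names}
        metadata = {
            "ciliametrics_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
        }
        report = export_report(tables, group_map, out / "report", metadata=metadata)
        result["report"] = report
    write_json_sidecar(out / "resolved_config.json", dataclasses.asdict(config))
    return result
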