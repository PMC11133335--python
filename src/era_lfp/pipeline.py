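"""End-to-end orchestration: simulate/load -> preprocess -> select NS ->
realize -> metrics -> (optionally) group statistics.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
is reproducible from the config plus its seed alone: rerunning with an
identical config produces byte-identical stage outputs, which the
:class:`RunManifest` certifies with per-file SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .era import build_hankel_pair, era_realize, reconstruct_series
from .groups import compare_groups, make_phase_table, partition_phases
from .io import read_recording, write_changepoints, write_json, write_recording
from .metrics import channel_metrics, relative_error, windowed_power_spectrum
from .preprocessing import (
    detect_change_points,
    interpolate_to_uniform,
    moving_average_smooth,
)
from .recording import MultiChannelRecording
from .selection import SelectionConfig, select_ns
from .synthetic import SyntheticConfig, generate_synthetic_lfp

log = logging.getLogger("era_lfp.pipeline")

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    out_dir: str = "era_lfp_run"
    input_path: str | None = None
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    subject_id: str = "S1"
    phase_duration_s: float | None = None  # None: take from the recording/config
    smoothing_window: int = 5
    skip_smoothing: bool = False
    skip_changepoints: bool = False
    cp_penalty: float = 1.0
    max_cps: int | None = 5000
    target_points: int = 3000   # cap on the per-phase uniform grid
    grid_per_knot: float = 3.0  # grid points per detected knot (adaptive grid)
    min_grid: int = 32
    center: bool = True  # remove each phase's per-channel mean before ERA
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    spectrogram_window_s: float = 30.0
    spectrogram_hop_s: float = 15.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.input_path is None and self.synthetic is None:
            raise ValueError("config needs either input_path or a synthetic block")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError(
                f"smoothing_window must be a positive odd integer, "
                f"got {self.smoothing_window}"
            )
        if self.cp_penalty <= 0:
            raise ValueError("cp_penalty must be positive")
        if self.target_points < 2:
            raise ValueError("target_points must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["synthetic"].items()
            })
        if "selection" in d and isinstance(d["selection"], dict):
            d["selection"] = SelectionConfig(**d["selection"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)
        return path


@dataclass
class RunManifest:
    """Per-stage outputs (with SHA-256 checksums), timings and warnings."""

    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = __version__

    def add_stage(self, name: str, outputs: list[Path], seconds: float,
                  warnings: list[str] | None = None) -> None:
        self.stages[name] = {
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            "seconds": seconds,
            "warnings": warnings or [],
        }
        self.warnings.extend(warnings or [])

    def checksums(self) -> dict[str, str]:
        """Flat {filename: sha256} over all stages (timings excluded)."""
        out: dict[str, str] = {}
        for stage in self.stages.values():
            out.update(stage["outputs"])
        return out

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _phase_series(recording: MultiChannelRecording, config: RunConfig):
    """Preprocess one phase: smooth, change-point downsample, regrid.

    The uniform grid is adaptive: ``grid_per_knot`` points per detected
    interior knot (averaged over channels), clamped to
    ``[min_grid, target_points]`` — a phase reduced to a handful of knots is
    resampled on a short grid, a knot-dense phase on a fine one, so the
    series length (and with it the stack-count scale) reflects the phase's
    detected complexity. Returns the (q, m') series handed to NS selection.
    With both skip flags set the raw phase samples pass through untouched.
    """
    y = recording.samples
    if not config.skip_smoothing:
        y = moving_average_smooth(y, config.smoothing_window)
    if config.skip_changepoints:
        if config.center:
            y = y - y.mean(axis=1, keepdims=True)
        return y, []
    cp_sets = []
    for c in range(recording.n_channels):
        cp_sets.append(
            detect_change_points(
                y[c],
                rate=recording.rate,
                penalty=config.cp_penalty,
                max_cps=config.max_cps,
                channel_id=recording.channel_labels[c],
            )
        )
    mean_knots = float(np.mean([cp.n_interior for cp in cp_sets]))
    target = int(round(config.grid_per_knot * mean_knots))
    target = max(config.min_grid, min(target, config.target_points,
                                      recording.n_samples))
    uniform = interpolate_to_uniform(cp_sets, target)
    series = uniform.samples
    if config.center:
        series = series - series.mean(axis=1, keepdims=True)
    return series, cp_sets


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages under ``config.out_dir`` and return the manifest.

    Any stage failure aborts with the stage name; the partial manifest is
    persisted as ``manifest.json`` either way.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    stage = "configure"
    try:
        t0 = time.perf_counter()
        cfg_path = config.to_yaml(out_dir / "config.yaml")
        manifest.add_stage(stage, [cfg_path], time.perf_counter() - t0)

        stage = "acquire"
        t0 = time.perf_counter()
        if config.input_path is not None:
            recording = read_recording(config.input_path)
        else:
            synth = config.synthetic
            if synth.seed != config.seed:
                synth = replace(synth, seed=config.seed)
            recording = generate_synthetic_lfp(synth)
        rec_path = write_recording(recording, out_dir / "recording.csv")
        manifest.add_stage(stage, [rec_path], time.perf_counter() - t0)
        log.info("acquired %d channels x %d samples at %.6g Hz",
                 recording.n_channels, recording.n_samples, recording.rate)

        stage = "partition"
        t0 = time.perf_counter()
        phase_duration = config.phase_duration_s
        if phase_duration is None:
            phase_duration = (
                config.synthetic.phase_duration
                if config.input_path is None
                else min(300.0, recording.duration)
            )
        segments = partition_phases(recording, phase_duration)
        warn = [
            f"phase {s.index} flagged as short remainder"
            for s in segments if s.flagged
        ]
        manifest.add_stage(stage, [], time.perf_counter() - t0, warn)

        stage = "phases"
        t0 = time.perf_counter()
        phase_outputs: list[Path] = []
        rows = []
        warn = []
        for seg in segments:
            series, cp_sets = _phase_series(seg.recording, config)
            if cp_sets:
                phase_outputs.append(
                    write_changepoints(cp_sets, out_dir / f"phase{seg.index}_cps.csv")
                )
            sel = select_ns(series, config.selection)
            if sel.strategy == "distant":
                warn.append(f"phase {seg.index}: distant-values NS selection")
            pair = build_hankel_pair(series, sel.ns_selected)
            real = era_realize(
                pair,
                rank_rtol=config.selection.rank_rtol,
                r_max=config.selection.r_max,
            )
            rec_series = reconstruct_series(real, series.shape[1])
            report = {
                "phase": seg.index,
                "flagged": seg.flagged,
                "selection": sel.to_dict(),
                "rel_err": relative_error(series, rec_series),
                "per_channel": [
                    {"channel": cm.channel_id, "mse": cm.mse, "corr": cm.corr}
                    for cm in channel_metrics(
                        series, rec_series, recording.channel_labels
                    )
                ],
            }
            phase_outputs.append(
                write_json(report, out_dir / f"phase{seg.index}_report.json")
            )
            rows.append({
                "subject_id": config.subject_id,
                "group": recording.group,
                "phase": seg.index,
                "ns": sel.ns_selected,
                "rel_err": sel.rel_err,
                "strategy": sel.strategy,
            })
            if seg.recording.duration >= config.spectrogram_window_s:
                spec = windowed_power_spectrum(
                    seg.recording.samples,
                    seg.recording.rate,
                    config.spectrogram_window_s,
                    config.spectrogram_hop_s,
                )
                phase_outputs.append(write_json(
                    {
                        "freqs": spec.freqs,
                        "times": spec.times,
                        "power_db": spec.power_db,
                    },
                    out_dir / f"phase{seg.index}_spectrogram.json",
                ))
            else:
                warn.append(
                    f"phase {seg.index}: too short for a "
                    f"{config.spectrogram_window_s}-s spectrogram window"
                )
            log.info("phase %d: NS=%d (%s) rel_err=%.4g", seg.index,
                     sel.ns_selected, sel.strategy, sel.rel_err)
        manifest.add_stage(stage, phase_outputs, time.perf_counter() - t0, warn)

        stage = "table"
        t0 = time.perf_counter()
        table = make_phase_table(rows)
        table_path = out_dir / "phase_table.csv"
        table.to_csv(table_path, index=False)
        manifest.add_stage(stage, [table_path], time.perf_counter() - t0)

        stage = "stats"
        t0 = time.perf_counter()
        groups_present = set(table["group"])
        if {"AW", "AN"} <= groups_present:
            comparisons = []
            for phase in sorted(table["phase"].unique()):
                mw, wt = compare_groups(table, phase)
                comparisons.extend([mw.to_dict(), wt.to_dict()])
            stats_path = write_json({"comparisons": comparisons},
                                    out_dir / "group_stats.json")
            manifest.add_stage(stage, [stats_path], time.perf_counter() - t0)
        else:
            manifest.add_stage(
                stage, [], time.perf_counter() - t0,
                ["group statistics skipped: need both AW and AN subjects"],
            )
    except Exception as exc:
        write_json(manifest.to_dict(), out_dir / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_json(manifest.to_dict(), out_dir / "manifest.json")
    return manifest
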