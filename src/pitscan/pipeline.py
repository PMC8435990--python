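"""End-to-end analysis: stack → axis → profiles → 3D pits → metrics → reports.

:func:`analyze_volume` is the library entry point (binary volume in, result
object out, nothing written); :func:`analyze` is the batch entry point used by
the CLI: it reads a stack from disk, optionally binarizes it, runs the chain
and writes the report files. Both are fully deterministic — rerunning on the
same input and configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .axis_correction import CenterLine, estimate_center_line
from .errors import InputError, PitScanError
from .metrics import AnalysisConfig, SpecimenMetrics, compute_metrics
from .pit_tracker import (bond_segments, extract_segments, filter_pits,
                          measure_pits, pits_to_frame)
from .slice_profile import profile_slice
from .volume_io import BinaryVolume, GrayVolume, binarize, export_heatmap, read_stack


@dataclass
class AnalysisResult:
    """Everything one run produces, before any file is written."""

    config: AnalysisConfig
    center_line: CenterLine
    profiles: list = field(repr=False)
    pits: list = field(repr=False)
    metrics: SpecimenMetrics
    heatmap: np.ndarray = field(repr=False)  # layers × 180, penetration from r0
    warnings: list[str] = field(default_factory=list)

    def deepest_points_um(self) -> np.ndarray:
        """(x, y, z) of every pit's deepest point, in µm, for 3D rendering."""
        vox = self.config.voxel_size_um
        r1 = {p.layer: p.r1_um for p in self.profiles}
        pts = []
        for pit in self.pits:
            layer, idx, depth = pit.deepest_point
            r_pt = r1[layer] - depth
            ang = math.radians(idx * 2.0)
            cx, cy = self.center_line.center(layer)
            pts.append((cx * vox + r_pt * math.cos(ang),
                        cy * vox + r_pt * math.sin(ang),
                        layer * vox))
        return np.asarray(pts, dtype=float).reshape(-1, 3)


def analyze_volume(volume: BinaryVolume, config: AnalysisConfig | None = None,
                   hydrogen_volume_ml: float | None = None) -> AnalysisResult:
    """Run the full pit-detection chain on a binary volume."""
    config = config or AnalysisConfig()
    if volume.voxel_size_um != config.voxel_size_um:
        config = AnalysisConfig(**{**config.__dict__,
                                   "voxel_size_um": volume.voxel_size_um})
    center_line = estimate_center_line(volume, config.center_slices)
    profiles = [
        profile_slice(volume.data[i], center_line.center(i),
                      r0_um=config.r0_um, voxel_size_um=config.voxel_size_um,
                      material_ratio=config.material_ratio,
                      on_threshold_um=config.on_threshold_um, layer=i)
        for i in range(volume.n_slices)
    ]
    segments = extract_segments(profiles)
    pits = bond_segments(segments, min_overlap=config.min_overlap)
    pits = filter_pits(pits, min_depth_um=config.min_pit_depth_um)
    measure_pits(pits, profiles, voxel_size_um=config.voxel_size_um,
                 angular_step_deg=config.angular_step_deg,
                 mid_depth_arc=config.mid_depth_arc)
    metrics = compute_metrics(
        profiles, pits, config,
        gauge_length_um=volume.n_slices * config.voxel_size_um,
        core_volume_um3=volume.core_volume_um3(),
        hydrogen_volume_ml=hydrogen_volume_ml)

    warnings = list(metrics.warnings)
    extreme = [p.layer for p in profiles if p.r1_um < 0.1 * config.r0_um]
    if extreme:
        warnings.append(f"extreme radius loss (>90%) in layers {extreme}")

    heatmap = np.stack([p.total_penetration for p in profiles])
    return AnalysisResult(config=config, center_line=center_line,
                          profiles=profiles, pits=pits, metrics=metrics,
                          heatmap=heatmap, warnings=warnings)


def _write_reports(result: AnalysisResult, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out_dir / "metrics.json",
        "pits": out_dir / "pits.csv",
        "heatmap_csv": out_dir / "heatmap.csv",
        "heatmap_png": out_dir / "heatmap.png",
        "deepest": out_dir / "deepest_points.xyz",
        "log": out_dir / "run.log",
    }
    payload = {
        "tool": "pitscan",
        "version": __version__,
        "config": {k: v for k, v in result.config.__dict__.items()},
        "metrics": result.metrics.to_dict(),
        "center_line": {"p1": list(result.center_line.p1),
                        "p2": list(result.center_line.p2),
                        "n_slices": result.center_line.n_slices},
        "warnings": result.warnings,
    }
    paths["metrics"].write_text(json.dumps(payload, indent=2, sort_keys=True,
                                           allow_nan=True))
    pits_to_frame(result.pits).to_csv(paths["pits"], index=False)
    export_heatmap(result.heatmap, paths["heatmap_csv"], paths["heatmap_png"])
    pts = result.deepest_points_um()
    with open(paths["deepest"], "w") as fh:
        for x, y, z in pts:
            fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")
    log_lines = [f"pitscan {__version__}"]
    log_lines += [f"config.{k} = {v}" for k, v in sorted(result.config.__dict__.items())]
    log_lines += [f"warning: {w}" for w in result.warnings]
    log_lines += [f"output: {p.name}" for k, p in paths.items() if k != "log"]
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths


def analyze(input_path, out_dir, config: AnalysisConfig | None = None,
            threshold: float | None = None, gaussian_sigma_px: float = 2.0,
            hydrogen_volume_ml: float | None = None) -> AnalysisResult:
    """Read a stack, run the chain, write all report files into ``out_dir``.

    Grayscale stacks require ``threshold`` (scan-specific; no automatic rule
    is assumed). On any stage failure, partially written outputs are removed
    and the error names the failing stage.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    written: dict[str, Path] = {}
    stage = "read"
    try:
        volume = read_stack(input_path, voxel_size_um=config.voxel_size_um)
        if isinstance(volume, GrayVolume):
            stage = "binarize"
            if threshold is None:
                raise InputError("grayscale input needs an explicit --threshold")
            volume = binarize(volume, threshold, gaussian_sigma_px)
        stage = "analysis"
        result = analyze_volume(volume, config,
                                hydrogen_volume_ml=hydrogen_volume_ml)
        stage = "report"
        written = _write_reports(result, out_dir)
        return result
    except PitScanError as e:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise PitScanError(f"stage {stage!r} failed: {e}") from e
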