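"""End-to-end pipeline: flatten -> segment -> trace -> measure, plus the
simulate-and-write entry point. Deterministic given the run seed."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import nanomap
from nanomap.imageproc import HeightImage, flatten, segment
from nanomap.labelcall import MoleculeMeasurement, measure_molecule
from nanomap.simgen import render_frame, simulate_molecule
from nanomap.tracing import trace_molecule
from nanomap.iface.config import RunConfig, config_hash
from nanomap.iface.io import read_height_image, write_height_image, write_measurements_tsv

log = logging.getLogger("nanomap")


@dataclass
class AnalysisResult:
    measurements: list[MoleculeMeasurement]
    flagged: list = field(default_factory=list)  # traces excluded by quality flags
    errors: list[str] = field(default_factory=list)

    @property
    def n_detected(self) -> int:
        return len(self.measurements) + len(self.flagged)


def analyze_image(img: HeightImage, cfg: RunConfig, frame_id: str = "frame") -> AnalysisResult:
    """Run the measurement pipeline on one (possibly stitched) image.

    Stage failures are logged per molecule and the run continues over the
    remaining components.
    """
    flat = flatten(img, line_order=cfg.flatten.line_order)
    comps = segment(flat, min_area_px=cfg.min_area_px, threshold_cfg=cfg.segment)
    result = AnalysisResult([], [], [])
    cal = cfg.calibration()
    for comp_id in comps.component_ids():
        mol_id = f"{frame_id}:{comp_id}"
        try:
            trace = trace_molecule(comps, comp_id, flat, cfg.trace)
            if trace.flags:
                result.flagged.append(trace)
                continue
            meas = measure_molecule(flat, trace, cfg.detect, cal, molecule_id=mol_id)
            result.measurements.append(meas)
        except Exception as exc:  # noqa: BLE001 - molecule-level fault isolation
            log.warning("molecule %s failed: %s", mol_id, exc)
            result.errors.append(f"{mol_id}: {exc}")
    return result


def simulate_frames(cfg: RunConfig, out_dir, overwrite: bool = False) -> list[Path]:
    """Generate labeled synthetic frames + truth TSVs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    written = []
    mols = [
        simulate_molecule(f"mol{i}", cfg.molecule_length_bp, cfg.sim, rng)
        for i in range(cfg.n_molecules)
    ]
    # pack molecules into as many frames as needed
    frame_idx = 0
    remaining = list(mols)
    while remaining:
        batch, rest = _take_fitting(remaining, cfg)
        frame_id = f"frame{frame_idx:03d}"
        img, truth = render_frame(batch, cfg.sim, rng, frame_id=frame_id)
        path = out / f"{frame_id}.tif"
        write_height_image(img, path, overwrite=overwrite)
        truth.to_tsv(out / f"{frame_id}.truth.tsv")
        written.append(path)
        remaining = rest
        frame_idx += 1
    return written


def _take_fitting(mols: list, cfg: RunConfig, per_frame: int | None = None):
    """Greedy packing: limit molecules per frame by a bounding-box heuristic
    so rejection-sampled placement stays cheap."""
    if per_frame is None:
        frame_nm2 = (cfg.sim.frame_size_px[0] * cfg.sim.pixel_size_nm) * (
            cfg.sim.frame_size_px[1] * cfg.sim.pixel_size_nm
        )
        arc = mols[0].arc_length_nm() if mols else 1.0
        box_nm2 = max((0.7 * arc) ** 2, 1.0)
        per_frame = int(np.clip(frame_nm2 / box_nm2 / 4, 1, 40))
    return mols[:per_frame], mols[per_frame:]


def run_pipeline(cfg: RunConfig, out_dir=None, overwrite: bool = False) -> dict:
    """Analyze all frames in ``cfg.input_dir`` and write run artifacts.

    Writes ``measurements.tsv`` and ``report.json`` (library version, config
    hash, per-frame counts). Empty input is a warning, not an error.
    """
    out = Path(out_dir or cfg.output_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    if cfg.input_dir:
        base = Path(cfg.input_dir)
        frames = sorted(
            p for p in base.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".txt", ".asc")
        )
    if not frames:
        warnings.warn("no input frames found; writing empty outputs", RuntimeWarning, stacklevel=2)
    all_meas = []
    counts = {}
    errors = []
    for path in frames:
        img = read_height_image(path)
        res = analyze_image(img, cfg, frame_id=path.stem)
        all_meas.extend(res.measurements)
        errors.extend(res.errors)
        counts[path.name] = dict(
            measured=len(res.measurements), flagged=len(res.flagged), errors=len(res.errors)
        )
    meas_path = out / "measurements.tsv"
    write_measurements_tsv(all_meas, meas_path, cal=cfg.calibration(), overwrite=overwrite)
    report = dict(
        nanomap_version=nanomap.__version__,
        config_hash=config_hash(cfg),
        seed=cfg.seed,
        n_frames=len(frames),
        n_molecules_measured=len(all_meas),
        per_frame=counts,
        errors=errors,
    )
    report_path = out / "report.json"
    if report_path.exists() and not overwrite:
        raise FileExistsError(f"{report_path} exists; pass overwrite=True to replace")
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
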