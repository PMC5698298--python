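"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from nanomap.imageproc import flatten, segment
from nanomap.labelcall import measure_molecule
from nanomap.mapmatch import ReferenceMap, Site
from nanomap.simgen import SimConfig, SimMolecule, apply_labels, render_frame, sample_wlc_chain
from nanomap.tracing import trace_molecule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_cfg():
    """Noise-free rendering configuration."""
    return SimConfig(noise_sd_nm=0.0, line_offset_sd_nm=0.0)


@pytest.fixture
def noisy_cfg():
    """Standard noisy configuration (0.1 nm pixel noise + line offsets)."""
    return SimConfig(noise_sd_nm=0.1, line_offset_sd_nm=0.1)


@pytest.fixture
def tert_map():
    """Two-perfect-site map of a short amplicon."""
    return ReferenceMap("tert", 680, [Site(200, "perfect"), Site(340, "perfect")])


def simulate_and_measure(
    length_bp: int,
    cfg: SimConfig,
    seed: int,
    refmap: ReferenceMap | None = None,
    frame_size_px=(300, 300),
    auto_size: bool = False,
):
    """End-to-end helper: one molecule -> frame -> flatten -> segment ->
    trace -> measure. Returns (molecule, truth, trace or None, measurement or
    None, reason)."""
    rng = np.random.default_rng(seed)
    mol = SimMolecule(f"mol{seed}", length_bp, sample_wlc_chain(length_bp, cfg, rng))
    if refmap is not None:
        mol = apply_labels(mol, refmap, cfg, rng)
    kwargs = dict(auto_size=True) if auto_size else dict(frame_size_px=frame_size_px)
    img, truth = render_frame([mol], cfg, rng, **kwargs)
    flat = flatten(img)
    comps = segment(flat)
    if comps.n_components != 1:
        return mol, truth, None, None, f"{comps.n_components} components"
    trace = trace_molecule(comps, 1, flat)
    if trace.flags:
        return mol, truth, trace, None, f"flags={sorted(trace.flags)}"
    meas = measure_molecule(flat, trace)
    return mol, truth, trace, meas, ""
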