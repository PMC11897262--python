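"""Shared fixtures: small geometries and (session-scoped) simulated studies."""

from __future__ import annotations

import numpy as np
import pytest

from vasomap.config import NoiseConfig, RunConfig, default_config, tiny_config
from vasomap.geometry import make_domain_map, make_patch_geometry, make_vascular_map
from vasomap.glm import (
    block_peak_responses,
    build_design_matrix,
    fit_glm,
    preference_map,
    stimulus_t_maps,
)
from vasomap.pipeline import build_study, simulate_run
from vasomap.preproc import average_runs, preprocess_interleaved, tsnr_map


@pytest.fixture(scope="session")
def slab():
    """Small flat-slab geometry with three GM depth samples."""
    return make_patch_geometry(shape=(16, 12, 8), voxel_mm=1.2, wm_mm=2.4)


@pytest.fixture(scope="session")
def slab_domains(slab):
    return make_domain_map(slab, pattern="stripes", lambda_mm=4.8, graded=False)


@pytest.fixture(scope="session")
def slab_vasc(slab):
    return make_vascular_map(slab, seed=0)


@pytest.fixture(scope="session")
def tiny_zero_study():
    """Zero-noise tiny study with one simulated run (binary stripes)."""
    cfg = tiny_config()
    cfg.noise = NoiseConfig(zero_noise=True)
    cfg.n_runs = 1
    cfg.domains.graded = False
    study = build_study(cfg)
    run = simulate_run(study, 0)
    return {"config": cfg, "study": study, "run": run}


def _analyse_branches(study, vaso, bold):
    out = {}
    for tag, series in (("vaso", vaso), ("bold", bold)):
        design = build_design_matrix(study.timeline, series.n_volumes, series.dt)
        result = fit_glm(series, design)
        out[tag] = {
            "series": series,
            "tmaps": stimulus_t_maps(result, series.tag),
            "preference": preference_map(
                block_peak_responses(series, study.timeline)
            ),
        }
    return out


@pytest.fixture(scope="session")
def default_run():
    """Default-condition study: 4 simulated runs, preprocessed and mapped.

    This is the configuration every calibration/ordering check uses; built
    once per session.
    """
    cfg = default_config()
    study = build_study(cfg)
    vaso_runs, bold_runs = [], []
    for r in range(cfg.n_runs):
        vaso, bold = preprocess_interleaved(simulate_run(study, r))
        vaso_runs.append(vaso)
        bold_runs.append(bold)
    vaso_mean = average_runs(vaso_runs)
    bold_mean = average_runs(bold_runs)
    gm = study.geometry.gm_mask
    return {
        "config": cfg,
        "study": study,
        "gm": gm,
        "tsnr_vaso_run0": tsnr_map(vaso_runs[0]),
        "tsnr_bold_run0": tsnr_map(bold_runs[0]),
        "branches": _analyse_branches(study, vaso_mean, bold_mean),
    }


@pytest.fixture(scope="session")
def zero_noise_default():
    """Default-grid zero-noise single run, preprocessed through the full
    chain, with preference maps for both branches."""
    cfg = default_config()
    cfg.noise = NoiseConfig(zero_noise=True)
    cfg.n_runs = 1
    study = build_study(cfg)
    run = simulate_run(study, 0)
    vaso, bold = preprocess_interleaved(run)
    branches = _analyse_branches(study, vaso, bold)
    return {"config": cfg, "study": study, "run": run, "branches": branches}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
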