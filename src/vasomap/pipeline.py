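"""End-to-end orchestration: simulate -> preprocess -> map -> layers ->
quantify -> report, with file outputs, a manifest and reproducible seeding.

Every stage is callable on an output directory; deterministic inputs
(geometry, domains, timeline) are rebuilt from the saved config, while the
stochastic simulated runs are passed between stages as NIfTI files.  The
manifest records written files with SHA-256 hashes of their voxel data, the
stage log, warnings and the summary numbers the report displays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acquire import (
    InterleavedSeries,
    default_noise_sigmas,
    simulate_acquisition,
)
from .config import RunConfig, default_config, tiny_config
from .geometry import GM, make_domain_map, make_patch_geometry, make_vascular_map
from .glm import (
    block_peak_responses,
    build_design_matrix,
    fit_glm,
    preference_map,
    stimulus_t_maps,
)
from .hemo import HemodynamicParams
from .io import load_volume, read_json, save_volume, sha256_array, write_json, write_tsv
from .laminar import depth_profile, equivolume_depth, flatten_map
from .modularity import (
    collapse_profile,
    compare_contrasts,
    fit_sinusoid,
    principal_axis,
    sens_spec_maps,
)
from .preproc import ContrastSeries, average_runs, preprocess_interleaved, tsnr_map
from .stimulus import build_block_timeline, timeline_to_frame

__all__ = [
    "StudyContext",
    "build_study",
    "run_pipeline",
    "make_fixtures",
    "write_report",
    "STAGES",
]


@dataclass
class StudyContext:
    """Deterministic study inputs derived from a RunConfig."""

    config: RunConfig
    geometry: object
    domains: object
    vasc: object
    timeline: object
    hemo: HemodynamicParams
    noise_sigma: tuple
    run_seeds: list
    warnings: list


def build_study(config: RunConfig) -> StudyContext:
    """Instantiate geometry, ground truth, vasculature, timeline and noise."""
    g = config.geometry
    captured = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        geometry = make_patch_geometry(
            shape=tuple(g.shape),
            voxel_mm=g.voxel_mm,
            wm_mm=g.wm_mm,
            thickness_mm=g.thickness_mm,
            kind=g.kind,
            fold_amp_mm=g.fold_amp_mm,
            fold_period_mm=g.fold_period_mm,
        )
        domains = make_domain_map(
            geometry,
            pattern=config.domains.pattern,
            lambda_mm=config.domains.lambda_mm,
            seed=config.seed,
            graded=config.domains.graded,
        )
        vasc = make_vascular_map(
            geometry,
            w_deep=config.vascular.w_deep,
            w_rise=config.vascular.w_rise,
            w_surface=config.vascular.w_surface,
            csf_extent_mm=config.vascular.csf_extent_mm,
            pooling_fwhm_mm=config.vascular.pooling_fwhm_mm,
            hotspot_density_per_cm2=config.vascular.hotspot_density_per_cm2,
            hotspot_gain=config.vascular.hotspot_gain,
            hotspot_sigma_mm=config.vascular.hotspot_sigma_mm,
            seed=config.seed,
        )
        timeline = build_block_timeline(
            tr_pair=config.timeline.tr_pair,
            n_initial_rest=config.timeline.n_initial_rest,
            block_dur=config.timeline.block_dur,
            n_blocks=config.timeline.n_blocks,
            condition_order=tuple(config.timeline.condition_order),
            reversal_interval=config.timeline.reversal_interval,
        )
        captured = [str(w.message) for w in caught]
    if config.noise.zero_noise:
        sigmas = (0.0, 0.0)
    else:
        sigmas = default_noise_sigmas(
            tsnr_vaso=config.noise.tsnr_vaso,
            tsnr_bold=config.noise.tsnr_bold,
            margin=config.noise.margin,
        )
    seeds = [
        int(s % (2**31))
        for s in np.random.SeedSequence(config.seed).generate_state(config.n_runs)
    ]
    return StudyContext(
        config=config,
        geometry=geometry,
        domains=domains,
        vasc=vasc,
        timeline=timeline,
        hemo=HemodynamicParams(),
        noise_sigma=sigmas,
        run_seeds=seeds,
        warnings=captured,
    )


def simulate_run(study: StudyContext, run: int) -> InterleavedSeries:
    cfg = study.config
    return simulate_acquisition(
        study.geometry,
        study.domains,
        study.vasc,
        study.timeline,
        hemo=study.hemo,
        noise_sigma=study.noise_sigma,
        amplitudes=(cfg.vascular.delta_cbv, cfg.vascular.delta_bold),
        seed=study.run_seeds[run],
        drift_per_run=cfg.vascular.drift_per_run,
        run_id=run,
    )


# ---------------------------------------------------------------------------
# Manifest helpers


def _manifest_path(out: Path) -> Path:
    return Path(out) / "manifest.json"


def _load_manifest(out: Path) -> dict:
    path = _manifest_path(out)
    if path.exists():
        return read_json(path)
    return {
        "version": __version__,
        "stages": [],
        "files": {},
        "warnings": [],
        "summary": {},
    }


def _record(manifest: dict, name: str, path: Path, data=None) -> None:
    entry = {"path": str(path)}
    if data is not None:
        entry["sha256"] = sha256_array(np.asarray(data, dtype=np.float32))
    manifest["files"][name] = entry


def _save_manifest(manifest: dict, out: Path) -> None:
    write_json(manifest, _manifest_path(out))


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig, out: Path) -> dict:
    """Write ground truth, geometry and the simulated interleaved runs."""
    out = Path(out)
    study = build_study(config)
    manifest = _load_manifest(out)
    manifest["warnings"].extend(study.warnings)
    vox = config.geometry.voxel_mm
    geo = study.geometry
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    truth = {
        "labels": geo.labels.astype(np.int16),
        "depth": geo.depth,
        "u": geo.u,
        "v": geo.v,
        "kappa": geo.kappa,
        "domain_p": study.domains.p,
        "vasc_m": study.vasc.m,
        "vasc_w_vein": study.vasc.w_vein,
    }
    for name, vol in truth.items():
        path = save_volume(out / f"truth_{name}.nii", vol, vox)
        _record(manifest, f"truth_{name}", path, vol)
    write_tsv(timeline_to_frame(study.timeline), out / "timeline.tsv")
    _record(manifest, "timeline", out / "timeline.tsv")
    write_json(
        {
            "seed": config.seed,
            "run_seeds": study.run_seeds,
            "noise_sigma": list(study.noise_sigma),
            "lambda_mm": config.domains.lambda_mm,
        },
        out / "ground_truth.json",
    )
    _record(manifest, "ground_truth", out / "ground_truth.json")

    for r in range(config.n_runs):
        series = simulate_run(study, r)
        for tag, data in (("nulled", series.nulled), ("notnulled", series.not_nulled)):
            path = save_volume(
                out / f"run{r:02d}_{tag}.nii", data, vox, tr=config.timeline.tr_pair
            )
            _record(manifest, f"run{r:02d}_{tag}", path, data)
    manifest["stages"].append("simulate")
    _save_manifest(manifest, out)
    return manifest


def _load_runs(config: RunConfig, out: Path) -> list:
    runs = []
    for r in range(config.n_runs):
        nulled, _ = load_volume(Path(out) / f"run{r:02d}_nulled.nii")
        notnulled, _ = load_volume(Path(out) / f"run{r:02d}_notnulled.nii")
        runs.append(
            InterleavedSeries(
                nulled=np.asarray(nulled, dtype=np.float64),
                not_nulled=np.asarray(notnulled, dtype=np.float64),
                tr_pair=config.timeline.tr_pair,
                run_id=r,
            )
        )
    return runs


def stage_preprocess(config: RunConfig, out: Path) -> dict:
    """Separate, clean, upsample, align and BOLD-correct each run; average."""
    out = Path(out)
    manifest = _load_manifest(out)
    study = build_study(config)
    gm = study.geometry.gm_mask
    vox = config.geometry.voxel_mm

    vaso_runs, bold_runs = [], []
    for series in _load_runs(config, out):
        vaso, bold = preprocess_interleaved(
            series, n_replace=config.n_replace, upsample_factor=config.upsample_factor
        )
        vaso_runs.append(vaso)
        bold_runs.append(bold)
    vaso_mean = average_runs(vaso_runs)
    bold_mean = average_runs(bold_runs)

    qc_rows = []
    for name, series in (
        ("vaso_run0", vaso_runs[0]),
        ("bold_run0", bold_runs[0]),
        ("vaso_mean", vaso_mean),
        ("bold_mean", bold_mean),
    ):
        tsnr = tsnr_map(series)
        path = save_volume(out / f"tsnr_{name}.nii", tsnr, vox)
        _record(manifest, f"tsnr_{name}", path, tsnr)
        vals = tsnr[gm & np.isfinite(tsnr)]
        qc_rows.append(
            {
                "series": name,
                "median": np.median(vals),
                "q25": np.percentile(vals, 25),
                "q75": np.percentile(vals, 75),
                "n_gm_voxels": int(vals.size),
            }
        )
    qc = pd.DataFrame(qc_rows)
    write_tsv(qc, out / "qc_tsnr.tsv")
    _record(manifest, "qc_tsnr", out / "qc_tsnr.tsv")

    for tag, series in (("vaso", vaso_mean), ("bold", bold_mean)):
        path = save_volume(
            out / f"{tag}_mean.nii", series.data, vox, tr=series.dt
        )
        _record(manifest, f"{tag}_mean", path, series.data)
    write_json(
        {"vaso": list(vaso_mean.log), "bold": list(bold_mean.log)},
        out / "step_log.json",
    )
    _record(manifest, "step_log", out / "step_log.json")
    manifest["summary"]["tsnr"] = {
        row["series"]: float(row["median"]) for row in qc_rows
    }
    manifest["stages"].append("preprocess")
    _save_manifest(manifest, out)
    return manifest


def _mean_series(config: RunConfig, out: Path, tag: str) -> ContrastSeries:
    data, _ = load_volume(Path(out) / f"{tag}_mean.nii")
    dt = config.timeline.tr_pair / config.upsample_factor
    series_tag = "vaso_corrected" if tag == "vaso" else "bold"
    return ContrastSeries(
        data=np.asarray(data, dtype=np.float64), tag=series_tag, dt=dt
    )


def stage_map(config: RunConfig, out: Path) -> dict:
    """GLM t maps and block-peak curvature-preference maps per branch."""
    out = Path(out)
    manifest = _load_manifest(out)
    study = build_study(config)
    vox = config.geometry.voxel_mm

    for tag in ("vaso", "bold"):
        series = _mean_series(config, out, tag)
        design = build_design_matrix(study.timeline, series.n_volumes, series.dt)
        result = fit_glm(series, design)
        tmaps = stimulus_t_maps(result, series.tag)
        for name, tmap in tmaps.items():
            path = save_volume(out / f"{tag}_{name}.nii", tmap, vox)
            _record(manifest, f"{tag}_{name}", path, tmap)
        table = block_peak_responses(
            series,
            study.timeline,
            peak_window=tuple(config.peak_window),
            baseline_s=config.baseline_s,
        )
        pref = preference_map(table)
        path = save_volume(out / f"{tag}_preference.nii", pref.t, vox)
        _record(manifest, f"{tag}_preference", path, pref.t)
    manifest["stages"].append("map")
    _save_manifest(manifest, out)
    return manifest


def stage_layers(config: RunConfig, out: Path) -> dict:
    """Equi-volume depths, depth-binned flat maps and columnarity."""
    out = Path(out)
    manifest = _load_manifest(out)
    study = build_study(config)
    vox = config.geometry.voxel_mm
    depths = equivolume_depth(study.geometry)
    path = save_volume(out / "depth_equivolume.nii", depths.d_ev, vox)
    _record(manifest, "depth_equivolume", path, depths.d_ev)

    columnarity = {}
    for tag in ("vaso", "bold"):
        pref, _ = load_volume(out / f"{tag}_preference.nii")
        pref = np.asarray(pref, dtype=np.float64)
        profile = depth_profile(
            study.geometry, pref, n_bins=config.n_depth_bins, depth_field=depths
        )
        columnarity[tag] = profile.columnarity
        for i, fm in enumerate(profile.flatmaps):
            tsv = write_tsv(fm.frame(), out / f"{tag}_flat_depthbin{i}.tsv")
            _record(manifest, f"{tag}_flat_depthbin{i}", tsv)
        full = flatten_map(study.geometry, pref, depth_field=depths)
        tsv = write_tsv(full.frame(), out / f"{tag}_flat_full.tsv")
        _record(manifest, f"{tag}_flat_full", tsv)
    manifest["summary"]["columnarity"] = columnarity
    manifest["stages"].append("layers")
    _save_manifest(manifest, out)
    return manifest


def stage_quantify(config: RunConfig, out: Path) -> dict:
    """PCA collapse with sinusoid fit, and sensitivity/specificity indices."""
    out = Path(out)
    manifest = _load_manifest(out)
    study = build_study(config)
    geometry = study.geometry
    depths = equivolume_depth(geometry)
    gm = geometry.gm_mask

    fits = {}
    profiles = {}
    for tag in ("vaso", "bold"):
        pref, _ = load_volume(out / f"{tag}_preference.nii")
        pref = np.asarray(pref, dtype=np.float64)
        fm = flatten_map(geometry, pref, depth_field=depths)
        ok = np.isfinite(fm.values)
        u, v = fm.cell_centers
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            axis = principal_axis(np.column_stack([u[ok], v[ok]]))
        manifest["warnings"].extend(str(w.message) for w in caught)
        profile = collapse_profile(fm, axis)
        fit = fit_sinusoid(profile)
        fits[tag] = fit
        profiles[tag] = profile
        write_tsv(
            pd.DataFrame(
                {
                    "position_mm": profile.bin_centers,
                    "mean_preference_t": profile.values,
                    "n_voxels": profile.counts,
                }
            ),
            out / f"{tag}_profile.tsv",
        )
        _record(manifest, f"{tag}_profile", out / f"{tag}_profile.tsv")

    fit_frame = pd.DataFrame(
        [
            {
                "contrast": tag,
                "period_mm": fits[tag].period,
                "amplitude": fits[tag].amplitude,
                "phase_rad": fits[tag].phase,
                "r2": fits[tag].r2,
                "axis_u": profiles[tag].axis[0],
                "axis_v": profiles[tag].axis[1],
            }
            for tag in ("vaso", "bold")
        ]
    )
    write_tsv(fit_frame, out / "sinusoid_fits.tsv")
    _record(manifest, "sinusoid_fits", out / "sinusoid_fits.tsv")

    maps = {}
    scatter_rows = []
    for tag in ("vaso", "bold"):
        t0, _ = load_volume(out / f"{tag}_t_rf0.nii")
        t4, _ = load_volume(out / f"{tag}_t_rf4.nii")
        maps[tag] = sens_spec_maps(
            np.asarray(t0, float), np.asarray(t4, float), tag=tag, roi=gm
        )
        path = save_volume(
            out / f"{tag}_sensitivity.nii", maps[tag].sensitivity, config.geometry.voxel_mm
        )
        _record(manifest, f"{tag}_sensitivity", path, maps[tag].sensitivity)
        path = save_volume(
            out / f"{tag}_specificity.nii", maps[tag].specificity, config.geometry.voxel_mm
        )
        _record(manifest, f"{tag}_specificity", path, maps[tag].specificity)
        idx = np.flatnonzero(gm.ravel())
        scatter_rows.append(
            pd.DataFrame(
                {
                    "voxel_index": idx,
                    "sensitivity": maps[tag].sensitivity.ravel()[idx],
                    "specificity": maps[tag].specificity.ravel()[idx],
                    "contrast": tag,
                }
            )
        )
    write_tsv(pd.concat(scatter_rows, ignore_index=True), out / "sens_spec_scatter.tsv")
    _record(manifest, "sens_spec_scatter", out / "sens_spec_scatter.tsv")
    summary = compare_contrasts(maps["bold"], maps["vaso"])
    write_tsv(summary, out / "sens_spec_summary.tsv")
    _record(manifest, "sens_spec_summary", out / "sens_spec_summary.tsv")

    manifest["summary"]["sinusoid"] = {
        tag: {"period_mm": fits[tag].period, "amplitude": fits[tag].amplitude, "r2": fits[tag].r2}
        for tag in ("vaso", "bold")
    }
    manifest["summary"]["sens_spec"] = {
        f"{row['contrast']}_{row['index']}": {
            "median": float(row["median"]),
            "iqr": float(row["iqr"]),
        }
        for _, row in summary.iterrows()
    }
    manifest["stages"].append("quantify")
    _save_manifest(manifest, out)
    return manifest


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "map": stage_map,
    "layers": stage_layers,
    "quantify": stage_quantify,
}


def run_pipeline(config: RunConfig, out) -> dict:
    """Execute every stage plus the report; abort naming the failed stage."""
    out = Path(out)
    for name, stage in STAGES.items():
        try:
            manifest = stage(config, out)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    write_report(out)
    manifest = _load_manifest(out)
    return manifest


def make_fixtures(scale: str = "tiny", out=None, seed: int = 1234) -> Path:
    """Write a simulated fixture directory (tiny or default scale) with its
    RunConfig sidecar."""
    if scale == "tiny":
        config = tiny_config(seed)
    elif scale == "default":
        config = default_config(seed)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    out = Path(out if out is not None else f"fixtures_{scale}")
    stage_simulate(config, out)
    return out


# ---------------------------------------------------------------------------
# Report


def _report_figures(out: Path, manifest: dict) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    try:
        fig, ax = plt.subplots(figsize=(7, 4))
        for tag, color in (("vaso", "tab:blue"), ("bold", "tab:red")):
            prof = pd.read_csv(out / f"{tag}_profile.tsv", sep="\t")
            ax.plot(prof["position_mm"], prof["mean_preference_t"], color=color, label=tag.upper())
        ax.set_xlabel("position along lead axis (mm)")
        ax.set_ylabel("mean preference t")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fig_profiles.png", dpi=110)
        plt.close(fig)
        made.append("fig_profiles.png")
    except Exception:
        pass
    try:
        scatter = pd.read_csv(out / "sens_spec_scatter.tsv", sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, tag, color in zip(axes, ("bold", "vaso"), ("tab:red", "tab:blue")):
            sub = scatter[scatter["contrast"] == tag]
            ax.scatter(sub["sensitivity"], sub["specificity"], s=4, alpha=0.4, color=color)
            ax.set_title(tag.upper())
            ax.set_xlabel("sensitivity")
        axes[0].set_ylabel("specificity")
        fig.tight_layout()
        fig.savefig(out / "fig_sens_spec.png", dpi=110)
        plt.close(fig)
        made.append("fig_sens_spec.png")
    except Exception:
        pass
    return made


def write_report(out) -> Path:
    """Render a markdown report of the run from its manifest and tables."""
    out = Path(out)
    manifest = _load_manifest(out)
    lines = ["# Curvature-domain mapping report", ""]
    missing = []

    if not manifest["stages"]:
        lines += ["## Errors", "", "Empty manifest: no pipeline stages have run."]
        path = out / "report.md"
        path.write_text("\n".join(lines) + "\n")
        return path

    lines += [f"Stages completed: {', '.join(manifest['stages'])}", ""]

    tsnr = manifest["summary"].get("tsnr")
    if tsnr:
        lines += ["## Temporal SNR (GM median)", ""]
        lines += ["| series | median tSNR |", "|---|---|"]
        lines += [f"| {k} | {v:.2f} |" for k, v in tsnr.items()]
        lines.append("")
    else:
        missing.append("tSNR summary")

    sinusoid = manifest["summary"].get("sinusoid")
    if sinusoid:
        lines += ["## Collapsed profiles (sinusoid fits)", ""]
        lines += ["| contrast | period (mm) | amplitude | R2 |", "|---|---|---|---|"]
        for tag, fit in sinusoid.items():
            lines.append(
                f"| {tag} | {fit['period_mm']:.3f} | {fit['amplitude']:.3f} | {fit['r2']:.3f} |"
            )
        lines.append("")
    else:
        missing.append("collapsed profiles")

    sens = manifest["summary"].get("sens_spec")
    if sens:
        lines += ["## Sensitivity / specificity", ""]
        lines += ["| contrast & index | median | IQR |", "|---|---|---|"]
        for key, stats in sens.items():
            lines.append(f"| {key} | {stats['median']:.4f} | {stats['iqr']:.4f} |")
        lines.append("")
    else:
        missing.append("sensitivity/specificity")

    columnarity = manifest["summary"].get("columnarity")
    if columnarity:
        lines += ["## Depth-bin columnarity", ""]
        lines += ["| contrast | mean pairwise r |", "|---|---|"]
        lines += [f"| {k} | {v:.3f} |" for k, v in columnarity.items()]
        lines.append("")
    else:
        missing.append("columnarity")

    for fig in _report_figures(out, manifest):
        lines += [f"![{fig}]({fig})", ""]

    if manifest["warnings"]:
        lines += ["## Warnings", ""]
        lines += [f"- {w}" for w in dict.fromkeys(manifest["warnings"])]
        lines.append("")
    if missing:
        lines += ["## Missing outputs", ""]
        lines += [f"- {m}" for m in missing]
        lines.append("")

    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    manifest["files"]["report"] = {"path": str(path)}
    _save_manifest(manifest, out)
    return path
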