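"""Simulation of interleaved nulled (VASO) / not-nulled (BOLD) acquisitions.

Signal model per voxel x and volume-pair time t:

    drive_c(x)      = (1 + p)/2 for RF0, (1 - p)/2 for RF4   (column preference p)
    D_CBV(x, t)     = m(x)    * sum_c drive_c(x)      * h_c^CBV(t)
    D_BOLD(x, t)    = w_vein(x) * sum_c drive_c^pool(x) * h_c^BOLD(t)
    bold_factor     = 1 + dBOLD * D_BOLD
    not_nulled(x,t) = S0(x) * bold_factor * trend(t)            (+ noise)
    nulled(x,t)     = S0(x) * (1 - dCBV * D_CBV) * bold_factor * trend(t)  (+ noise)

so the BOLD contamination of the nulled series is exactly multiplicative and
dynamic division is an exact inverse.  The BOLD drive uses an in-plane pooled
copy of the preference map (draining veins integrate blood across columns),
which is what erodes BOLD specificity relative to VASO.

The noiseless CBV ratio and the noiseless not-nulled signal are quantised to
single precision before multiplication: two 24-bit significands multiply
exactly in double precision, so at zero noise the voxelwise division
``nulled / not_nulled`` returns the stored CBV component bit-identically.
Gaussian thermal noise is added afterwards in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import CSF, GM, WM, DomainMap, PatchGeometry, VascularMap
from .hemo import HemodynamicParams, hemodynamic_response
from .stimulus import RF0, RF4, BlockTimeline

__all__ = [
    "InterleavedSeries",
    "simulate_acquisition",
    "calibrate_noise",
    "default_noise_sigmas",
    "S0_DEFAULTS",
]

#: Baseline signal per tissue class (arbitrary units, shared between series).
S0_DEFAULTS = {WM: 80.0, GM: 100.0, CSF: 120.0}


@dataclass
class InterleavedSeries:
    """Paired nulled/not-nulled 4D time series with acquisition metadata.

    ``cbv_component`` is the simulator's noiseless CBV ratio
    ``1 - dCBV * D_CBV`` (the ground truth that BOLD correction recovers).
    """

    nulled: np.ndarray
    not_nulled: np.ndarray
    tr_pair: float
    ti1_ms: float = 1145.0
    ti2_ms: float = 2115.0
    run_id: int = 0
    seed: int | None = None
    cbv_component: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_pairs(self) -> int:
        return self.nulled.shape[-1]


def calibrate_noise(s0: float, target_tsnr: float) -> float:
    """Noise standard deviation giving ``target_tsnr`` on a constant series.

    tSNR = mean / sd, so ``sigma = s0 / target_tsnr``.
    """
    if target_tsnr <= 0:
        raise ValueError("target tSNR must be positive")
    return s0 / target_tsnr


def default_noise_sigmas(
    s0_gm: float = S0_DEFAULTS[GM],
    tsnr_vaso: float = 25.0,
    tsnr_bold: float = 40.0,
    margin: float = 1.25,
) -> tuple:
    """Calibrated (sigma_nulled, sigma_not_nulled) for the default simulation.

    The BOLD target applies to the not-nulled series directly.  The VASO
    target applies to the *BOLD-corrected* series (the series whose tSNR the
    QC literature quotes); since the relative noise of a ratio adds in
    quadrature, the nulled sigma is back-computed as

        sigma_n = s0 * sqrt(1/(tsnr_vaso*margin)**2 - 1/(tsnr_bold*margin)**2).

    ``margin`` keeps the measured medians above the floors ("well above"),
    leaving headroom for stimulus-evoked variance.
    """
    tv, tb = tsnr_vaso * margin, tsnr_bold * margin
    if tv >= tb:
        raise ValueError("VASO tSNR target must be below the BOLD target")
    sigma_b = calibrate_noise(s0_gm, tb)
    sigma_n = s0_gm * np.sqrt(1.0 / tv**2 - 1.0 / tb**2)
    return sigma_n, sigma_b


def _f32(x: np.ndarray) -> np.ndarray:
    """Round to single precision, kept in double (24-bit significand)."""
    return x.astype(np.float32).astype(np.float64)


def _condition_drive(p: np.ndarray, condition: str) -> np.ndarray:
    if condition == RF0:
        return (1.0 + p) / 2.0
    if condition == RF4:
        return (1.0 - p) / 2.0
    raise ValueError(f"unknown condition {condition!r}")


def condition_time_courses(
    timeline: BlockTimeline,
    t: np.ndarray,
    hemo: HemodynamicParams,
    contrast: str,
) -> dict:
    """Summed block responses per condition on time grid ``t``."""
    courses = {RF0: np.zeros_like(t), RF4: np.zeros_like(t)}
    for onset, cond in zip(timeline.block_onsets, timeline.block_conditions):
        courses[cond] += hemodynamic_response(
            t, onset, timeline.block_dur, hemo, contrast=contrast
        )
    return courses


def simulate_acquisition(
    geometry: PatchGeometry,
    domains: DomainMap,
    vasc: VascularMap,
    timeline: BlockTimeline,
    hemo: HemodynamicParams = HemodynamicParams(),
    noise_sigma: tuple = (0.0, 0.0),
    amplitudes: tuple = (0.02, 0.04),
    seed: int | None = None,
    drift_per_run: float = 0.001,
    s0_by_tissue: dict | None = None,
    run_id: int = 0,
) -> InterleavedSeries:
    """Simulate one run of the interleaved acquisition.

    Parameters
    ----------
    noise_sigma : (float, float)
        Gaussian noise sd for the (nulled, not-nulled) series, in signal units.
    amplitudes : (float, float)
        Peak relative response (dCBV_rel, dBOLD_rel); both must lie in
        [0, 0.5].
    drift_per_run : float
        Peak relative amplitude of a multiplicative linear trend across the
        run (exercises the GLM ramp regressor).
    """
    d_cbv, d_bold = amplitudes
    if not (0.0 <= d_cbv <= 0.5 and 0.0 <= d_bold <= 0.5):
        raise ValueError("amplitudes must lie in [0, 0.5]")
    if geometry.shape != domains.p.shape or geometry.shape != vasc.m.shape:
        raise ValueError("geometry, domain map and vascular map grids differ")
    s0_by_tissue = dict(S0_DEFAULTS if s0_by_tissue is None else s0_by_tissue)

    t = timeline.times
    h_cbv = condition_time_courses(timeline, t, hemo, "CBV")
    h_bold = condition_time_courses(timeline, t, hemo, "BOLD")

    p = domains.p
    if vasc.pooling_fwhm_mm > 0:
        sigma_vox = vasc.pooling_fwhm_mm / 2.3548 / geometry.voxel_mm
        p_pool = gaussian_filter(p, sigma=(sigma_vox, sigma_vox, 0.0), mode="nearest")
    else:
        p_pool = p

    s0 = np.zeros(geometry.shape)
    for tissue, value in s0_by_tissue.items():
        s0[geometry.labels == tissue] = value

    def drive(weight, pref, courses):
        return weight[..., None] * (
            _condition_drive(pref, RF0)[..., None] * courses[RF0]
            + _condition_drive(pref, RF4)[..., None] * courses[RF4]
        )

    cbv_ratio = 1.0 - d_cbv * drive(vasc.m, p, h_cbv)
    bold_factor = 1.0 + d_bold * drive(vasc.w_vein, p_pool, h_bold)
    trend = 1.0 + drift_per_run * (t / t[-1] if len(t) > 1 else t)

    not_nulled_clean = _f32(s0[..., None] * bold_factor * trend)
    cbv_ratio = _f32(cbv_ratio)
    nulled_clean = cbv_ratio * not_nulled_clean  # exact product of f32 values

    rng = np.random.default_rng(seed)
    sig_n, sig_b = noise_sigma
    nulled = nulled_clean + (rng.normal(0.0, sig_n, nulled_clean.shape) if sig_n else 0.0)
    not_nulled = not_nulled_clean + (
        rng.normal(0.0, sig_b, not_nulled_clean.shape) if sig_b else 0.0
    )
    return InterleavedSeries(
        nulled=nulled,
        not_nulled=not_nulled,
        tr_pair=timeline.tr_pair,
        run_id=run_id,
        seed=seed,
        cbv_component=cbv_ratio,
    )
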