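"""Preprocessing of interleaved VASO/BOLD series: separation, non-steady-state
replacement, temporal upsampling, nulled alignment, BOLD correction by dynamic
division (BOCO), run averaging and tSNR quality control.

Each series carries an append-only provenance log; operations check the log so
the chain can only be applied in the intended order
(separate -> replace_nonsteady -> temporal_upsample -> align_nulled -> boco ->
average).  BOLD correction may also be applied directly to the separated
series, which on the simulator's equal-time grids is an exact inverse of the
multiplicative contamination model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.interpolate import CubicSpline

from .acquire import InterleavedSeries

__all__ = [
    "ContrastSeries",
    "separate_contrasts",
    "replace_nonsteady",
    "temporal_upsample",
    "align_nulled",
    "boco_correct",
    "average_runs",
    "tsnr_map",
    "preprocess_interleaved",
]


@dataclass
class ContrastSeries:
    """A 4D time series tagged with its contrast mechanism.

    Attributes
    ----------
    data : np.ndarray
        4D array, time on the last axis.
    tag : str
        One of {'nulled', 'not_nulled', 'vaso_corrected', 'bold'}.
    dt : float
        Effective sampling interval (s).
    log : tuple of str
        Append-only provenance of applied steps.
    qc : dict
        Quality-control artefacts (e.g. BOCO bad-denominator mask).
    """

    data: np.ndarray
    tag: str
    dt: float
    log: tuple = ()
    qc: dict = field(default_factory=dict)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def with_step(self, step: str, data=None, **kw) -> "ContrastSeries":
        return _dc_replace(
            self,
            data=self.data if data is None else data,
            log=self.log + (step,),
            **kw,
        )


def separate_contrasts(series: InterleavedSeries):
    """Split an interleaved acquisition into nulled and not-nulled series."""
    if series.nulled.shape != series.not_nulled.shape:
        raise ValueError("nulled and not-nulled grids differ")
    if series.nulled.size == 0 or series.nulled.shape[-1] == 0:
        raise ValueError("empty input series")
    nulled = ContrastSeries(
        data=series.nulled.copy(), tag="nulled", dt=series.tr_pair, log=("separate",)
    )
    not_nulled = ContrastSeries(
        data=series.not_nulled.copy(),
        tag="not_nulled",
        dt=series.tr_pair,
        log=("separate",),
    )
    return nulled, not_nulled


def replace_nonsteady(series: ContrastSeries, n_replace: int = 4) -> ContrastSeries:
    """Replace the first ``n_replace`` volumes by the following steady-state
    volume (volume ``n_replace``)."""
    if n_replace < 0:
        raise ValueError("n_replace must be non-negative")
    if any(s.startswith("temporal_upsample") for s in series.log):
        raise ValueError("replace_nonsteady must precede temporal_upsample")
    if series.n_volumes <= n_replace:
        raise ValueError(
            f"series of {series.n_volumes} volumes too short to replace {n_replace}"
        )
    data = series.data.copy()
    if n_replace:
        data[..., :n_replace] = data[..., n_replace : n_replace + 1]
    return series.with_step(f"replace_nonsteady[{n_replace}]", data=data)


def temporal_upsample(
    series: ContrastSeries, factor: int = 2, kind: str = "cubic"
) -> ContrastSeries:
    """Temporally upsample by an integer factor (length n -> factor*n).

    Cubic-spline interpolation by default (natural boundary; exact on
    constants and linear ramps), with a linear fallback.  The effective
    sampling interval is divided by ``factor``; sample j of the output sits at
    original index j/factor, held at the last sample beyond the end.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    if "boco" in series.log:
        raise ValueError("temporal upsampling must precede BOLD correction")
    factor = int(factor)
    if factor == 1:
        return series.with_step("temporal_upsample[1]")
    n = series.n_volumes
    idx = np.arange(n, dtype=float)
    new_idx = np.clip(np.arange(n * factor) / factor, 0.0, n - 1.0)
    if kind == "cubic" and n >= 4:
        spl = CubicSpline(idx, series.data, axis=-1, bc_type="natural")
        data = spl(new_idx)
    elif kind in ("cubic", "linear"):
        flat = series.data.reshape(-1, n)
        data = np.stack([np.interp(new_idx, idx, row) for row in flat])
        data = data.reshape(series.data.shape[:-1] + (n * factor,))
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    return series.with_step(
        f"temporal_upsample[{factor}]", data=data, dt=series.dt / factor
    )


def align_nulled(series: ContrastSeries) -> ContrastSeries:
    """Duplicate the first nulled volume and drop the last, restoring temporal
    correspondence with the not-nulled series after upsampling."""
    if series.tag != "nulled":
        raise ValueError("align_nulled applies to the nulled series only")
    if not any(s.startswith("temporal_upsample") for s in series.log):
        raise ValueError("align_nulled requires a temporally upsampled series")
    if "align_nulled" in series.log:
        raise ValueError("align_nulled already applied (not idempotent)")
    data = np.concatenate([series.data[..., :1], series.data[..., :-1]], axis=-1)
    return series.with_step("align_nulled", data=data)


def _strip_align(log: tuple) -> tuple:
    return tuple(s for s in log if s != "align_nulled")


def boco_correct(
    nulled: ContrastSeries,
    not_nulled: ContrastSeries,
    guard_eps: float = 0.25,
    clip_range: tuple = (0.0, 2.0),
) -> ContrastSeries:
    """BOLD correction by dynamic division: voxelwise nulled / not-nulled.

    Denominators below ``guard_eps`` times the voxel's temporal mean reuse the
    voxel's previous ratio (1 for the first volume).  Voxels whose denominator
    is zero at every timepoint are flagged in ``qc['bad_denominator']``.  The
    output is clipped to ``clip_range``.
    """
    if nulled.data.shape != not_nulled.data.shape:
        raise ValueError("nulled and not-nulled grids differ")
    if nulled.tag != "nulled" or not_nulled.tag != "not_nulled":
        raise ValueError("boco_correct expects (nulled, not_nulled) series")
    if _strip_align(nulled.log) != _strip_align(not_nulled.log):
        raise ValueError("nulled and not-nulled series took different paths")
    if any(s.startswith("temporal_upsample") for s in nulled.log) and (
        "align_nulled" not in nulled.log
    ):
        raise ValueError("upsampled nulled series must be aligned before BOCO")

    denom = not_nulled.data
    voxel_mean = denom.mean(axis=-1)
    bad_voxel = voxel_mean == 0
    guarded = denom < guard_eps * voxel_mean[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = nulled.data / denom
    if guarded.any() or bad_voxel.any():
        guarded = guarded | bad_voxel[..., None]
        prev = np.ones(ratio.shape[:-1])
        for ti in range(ratio.shape[-1]):
            frame = ratio[..., ti]
            mask = guarded[..., ti]
            frame[mask] = prev[mask]
            prev = frame
    ratio = np.clip(ratio, *clip_range)
    out = ContrastSeries(
        data=ratio,
        tag="vaso_corrected",
        dt=nulled.dt,
        log=nulled.log + ("boco",),
        qc={"bad_denominator": bad_voxel},
    )
    return out


def average_runs(series_list) -> ContrastSeries:
    """Voxelwise arithmetic mean of identically-processed runs."""
    if not series_list:
        raise ValueError("no runs to average")
    first = series_list[0]
    for s in series_list[1:]:
        if s.tag != first.tag:
            raise ValueError("cannot average series with mixed contrast tags")
        if s.data.shape != first.data.shape:
            raise ValueError("run grids/lengths differ")
        if s.log != first.log:
            raise ValueError("runs have inconsistent processing histories")
    data = np.mean([s.data for s in series_list], axis=0)
    return first.with_step(f"average_runs[{len(series_list)}]", data=data)


def tsnr_map(series: ContrastSeries) -> np.ndarray:
    """Voxelwise temporal mean / temporal sd (ddof=1).

    Zero-variance voxels are set to the sentinel +inf (recover the QC flag
    with ``np.isinf``).
    """
    if series.n_volumes < 2:
        raise ValueError("tSNR needs at least 2 volumes")
    mean = series.data.mean(axis=-1)
    sd = series.data.std(axis=-1, ddof=1)
    out = np.full(mean.shape, np.inf)
    ok = sd > 0
    out[ok] = mean[ok] / sd[ok]
    return out


def preprocess_interleaved(
    series: InterleavedSeries,
    n_replace: int = 4,
    upsample_factor: int = 2,
    kind: str = "cubic",
):
    """Run the full chain on one interleaved run.

    Returns ``(vaso_corrected, bold)`` where ``bold`` is the upsampled
    not-nulled series re-tagged for downstream analysis.
    """
    nulled, not_nulled = separate_contrasts(series)
    nulled = replace_nonsteady(nulled, n_replace)
    not_nulled = replace_nonsteady(not_nulled, n_replace)
    nulled = temporal_upsample(nulled, upsample_factor, kind)
    not_nulled = temporal_upsample(not_nulled, upsample_factor, kind)
    nulled = align_nulled(nulled)
    vaso = boco_correct(nulled, not_nulled)
    bold = _dc_replace(not_nulled, tag="bold", log=not_nulled.log + ("retag[bold]",))
    return vaso, bold
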