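"""GLM activation mapping and block-peak curvature-preference maps.

The design matrix has four columns — DC offset, zero-mean linear ramp, and one
unconvolved boxcar per stimulus condition (RF0, RF4) — sampled at the series'
effective sampling interval.  No hemodynamic convolution is applied: CBV and
BOLD responses have different shapes, so boxcars make the two contrast
mechanisms comparable.  Voxelwise ordinary least squares yields t statistics
for arbitrary contrasts, t(c) = c'b / sqrt(s2 * c'(X'X)^-1 c).

The curvature-preference map is computed from block responses: per block, the
mean signal in a peak window (after the ~6 s rise) minus the mean of the
preceding-rest baseline window; preference is the two-sample t statistic
(Welch by default) of RF0-block versus RF4-block amplitudes, positive values
indicating preference for curvature.  CBV-weighted series are sign-inverted
first, because activation decreases the VASO signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preproc import ContrastSeries
from .stimulus import RF0, RF4, BlockTimeline

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "BlockTable",
    "PreferenceMap",
    "build_design_matrix",
    "fit_glm",
    "t_contrast",
    "stimulus_t_maps",
    "block_peak_responses",
    "preference_map",
]

#: Contrast tags whose signal decreases on activation (blood nulling).
CBV_WEIGHTED_TAGS = ("vaso_corrected", "nulled")


@dataclass
class DesignMatrix:
    """GLM design: columns (DC, ramp, RF0 boxcar, RF4 boxcar)."""

    X: np.ndarray
    names: tuple
    dt: float
    row_labels: np.ndarray = field(repr=False)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def contrast(self, weights: dict) -> np.ndarray:
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c


def build_design_matrix(
    timeline: BlockTimeline, n_timepoints: int, sampling_interval: float
) -> DesignMatrix:
    """Expand the timeline's per-pair labels to ``n_timepoints`` rows.

    ``sampling_interval`` must evenly divide the pair TR, and the expanded
    label sequence must match ``n_timepoints`` exactly.
    """
    factor = timeline.tr_pair / sampling_interval
    if abs(factor - round(factor)) > 1e-6:
        raise ValueError("sampling interval must evenly divide the pair TR")
    factor = int(round(factor))
    labels = np.repeat(timeline.labels, factor)
    if len(labels) != n_timepoints:
        raise ValueError(
            f"timeline expands to {len(labels)} rows, series has {n_timepoints}"
        )
    n = n_timepoints
    ramp = np.linspace(-1.0, 1.0, n)
    X = np.column_stack(
        [
            np.ones(n),
            ramp - ramp.mean(),
            (labels == RF0).astype(float),
            (labels == RF4).astype(float),
        ]
    )
    return DesignMatrix(
        X=X, names=("dc", "ramp", RF0, RF4), dt=sampling_interval, row_labels=labels
    )


@dataclass
class GLMResult:
    """Voxelwise OLS fit: coefficients, residual variance and df."""

    beta: np.ndarray  # (..., n_columns)
    sigma2: np.ndarray  # (...,)
    df: int
    design: DesignMatrix

    def __post_init__(self) -> None:
        X = self.design.X
        self._xtx_inv = np.linalg.inv(X.T @ X)


def fit_glm(series, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per voxel.

    ``series`` may be a ContrastSeries or a plain array with time last.
    """
    data = series.data if isinstance(series, ContrastSeries) else np.asarray(series)
    X = design.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if data.shape[-1] != X.shape[0]:
        raise ValueError("series length does not match design rows")
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    flat = data.reshape(-1, n)
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = flat.T - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    shape = data.shape[:-1]
    return GLMResult(
        beta=beta.T.reshape(shape + (p,)),
        sigma2=sigma2.reshape(shape),
        df=df,
        design=design,
    )


def t_contrast(result: GLMResult, c) -> np.ndarray:
    """t statistic map for contrast vector ``c``."""
    c = np.asarray(c, dtype=float)
    eff = result.beta @ c
    var_scale = float(c @ result._xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(result.sigma2 * var_scale)
    t[np.isnan(t)] = 0.0
    return t


def stimulus_t_maps(result: GLMResult, tag: str) -> dict:
    """Stimulus-versus-baseline t maps per condition plus the joint contrast.

    For CBV-weighted series the sign is flipped so positive t = activation.
    """
    sign = -1.0 if tag in CBV_WEIGHTED_TAGS else 1.0
    d = result.design
    return {
        "t_rf0": sign * t_contrast(result, d.contrast({RF0: 1.0})),
        "t_rf4": sign * t_contrast(result, d.contrast({RF4: 1.0})),
        "t_stim": sign * t_contrast(result, d.contrast({RF0: 0.5, RF4: 0.5})),
        "t_rf0_gt_rf4": sign * t_contrast(result, d.contrast({RF0: 1.0, RF4: -1.0})),
    }


@dataclass
class BlockTable:
    """Per-voxel per-block response amplitudes (peak minus baseline)."""

    amplitudes: np.ndarray  # (..., n_blocks)
    conditions: tuple
    tag: str
    peak_window: tuple
    baseline_s: float

    def to_frame(self) -> pd.DataFrame:
        flat = self.amplitudes.reshape(-1, self.amplitudes.shape[-1])
        rows = [
            (vox, blk, self.conditions[blk], flat[vox, blk])
            for vox in range(flat.shape[0])
            for blk in range(flat.shape[1])
        ]
        return pd.DataFrame(
            rows, columns=["voxel_index", "block_index", "condition", "amplitude"]
        )


def block_peak_responses(
    series: ContrastSeries,
    timeline: BlockTimeline,
    peak_window: tuple = (5.22, 31.32),
    baseline_s: float = 10.44,
) -> BlockTable:
    """Per-block response amplitudes relative to the preceding rest baseline.

    Peak window defaults to 5.22-31.32 s after block onset (past the ~6 s
    rise); the baseline is the mean of the last ``baseline_s`` seconds of the
    preceding rest period.  CBV-weighted series are sign-inverted so positive
    amplitudes mean activation.
    """
    lo, hi = peak_window
    if not (0.0 <= lo < hi <= timeline.block_dur):
        raise ValueError("peak window must lie within the stimulus block")
    if not (
        0.0 < baseline_s <= min(timeline.block_dur, timeline.initial_rest_duration)
    ):
        raise ValueError("baseline window exceeds the available rest period")
    sign = -1.0 if series.tag in CBV_WEIGHTED_TAGS else 1.0
    # Windows are cut on integer sample indices so every block contributes the
    # same number of samples; boolean masks on a float time grid pick up or
    # drop edge samples block-to-block through rounding jitter.
    n_peak_lo = int(np.ceil(lo / series.dt - 1e-9))
    n_peak_hi = int(np.ceil(hi / series.dt - 1e-9))
    n_base = int(round(baseline_s / series.dt))
    amps = []
    for onset in timeline.block_onsets:
        i_on = int(round(onset / series.dt))
        i_peak = np.arange(i_on + n_peak_lo, i_on + n_peak_hi)
        i_base = np.arange(i_on - n_base, i_on)
        i_peak = i_peak[(i_peak >= 0) & (i_peak < series.n_volumes)]
        i_base = i_base[(i_base >= 0) & (i_base < series.n_volumes)]
        if i_peak.size == 0 or i_base.size == 0:
            raise ValueError("analysis windows contain no samples")
        amp = series.data[..., i_peak].mean(axis=-1) - series.data[..., i_base].mean(
            axis=-1
        )
        amps.append(sign * amp)
    return BlockTable(
        amplitudes=np.stack(amps, axis=-1),
        conditions=timeline.block_conditions,
        tag=series.tag,
        peak_window=peak_window,
        baseline_s=baseline_s,
    )


@dataclass
class PreferenceMap:
    """Signed per-voxel preference t map (positive = curvature / RF0)."""

    t: np.ndarray
    tag: str
    method: str
    block_table: BlockTable | None = field(default=None, repr=False)


def _two_sample_t(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Vectorised two-sample t over the last axis, a minus b.

    Degenerate denominators give t = 0 when the means agree and +/-inf
    otherwise (the noiseless limit).
    """
    na, nb = a.shape[-1], b.shape[-1]
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va, vb = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    if method == "welch":
        se2 = va / na + vb / nb
    elif method == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    else:
        raise ValueError(f"unknown method {method!r}")
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    zero_se = se2 == 0
    with np.errstate(invalid="ignore"):
        t[zero_se] = np.sign(diff[zero_se]) * np.inf
    t[zero_se & (diff == 0)] = 0.0
    return t


def preference_map(block_table: BlockTable, method: str = "welch") -> PreferenceMap:
    """Two-sample t of RF0-block versus RF4-block amplitudes per voxel."""
    conds = np.array(block_table.conditions)
    rf0 = block_table.amplitudes[..., conds == RF0]
    rf4 = block_table.amplitudes[..., conds == RF4]
    if rf0.shape[-1] < 2 or rf4.shape[-1] < 2:
        raise ValueError("need at least 2 blocks per condition")
    t = _two_sample_t(rf0, rf4, method)
    return PreferenceMap(t=t, tag=block_table.tag, method=method, block_table=block_table)
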