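"""Quantification of modular (periodic) map organisation and voxelwise
sensitivity/specificity indices.

A modular preference map laid out in alternating bands produces a sinusoidal
profile when its values are collapsed along the ROI's principal (lead) axis;
deviation from a sinusoid indicates loss of spatial specificity.  Sensitivity
of a voxel is the Euclidean norm of its stimulus-response vector
v = (t_RF0, t_RF4); specificity is the additive inverse of the scaled angle
between the (rectified, normalised) response vector and the winning reference
axis, 1 - arccos(v_hat . w_hat)/theta_max with theta_max = 45 deg for two
conditions: a voxel responding only to its winning condition scores 1, one
responding equally to both scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .laminar import FlatMap

__all__ = [
    "ModularityProfile",
    "SinusoidFit",
    "SensSpecMaps",
    "principal_axis",
    "collapse_profile",
    "fit_sinusoid",
    "sensitivity",
    "specificity",
    "sens_spec_maps",
    "compare_contrasts",
]


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal axis (unit vector) of ROI cell coordinates.

    ``coords`` is (n, 2) in mm.  The sign convention makes the u-component
    positive (v-component positive on ties).  Near-isotropic ROIs (eigenvalue
    ratio < 1.2) trigger a warning: the lead axis is then poorly defined.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 (u, v) coordinate pairs")
    pca = PCA(n_components=2)
    pca.fit(coords - coords.mean(axis=0))
    var = pca.explained_variance_
    if var[1] <= 0 or not np.isfinite(var).all():
        raise ValueError("degenerate (collinear) ROI")
    if var[0] / var[1] < 1.2:
        warnings.warn(
            f"ROI is nearly isotropic (eigenvalue ratio {var[0] / var[1]:.2f}); "
            "the lead axis is poorly defined",
            stacklevel=2,
        )
    axis = pca.components_[0]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass
class ModularityProfile:
    """Map values collapsed along the lead axis."""

    axis: np.ndarray
    bin_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    bin_width: float
    fit: "SinusoidFit | None" = None

    @property
    def extent(self) -> float:
        return float(self.bin_centers[-1] - self.bin_centers[0])


def collapse_profile(
    flatmap: FlatMap, axis: np.ndarray, bin_width_mm: float | None = None
) -> ModularityProfile:
    """Project flat-map cells onto ``axis`` and average per projection bin.

    Cell means are weighted by their voxel counts; empty bins are dropped with
    a warning.
    """
    if bin_width_mm is None:
        bin_width_mm = flatmap.cell_mm
    if bin_width_mm < flatmap.cell_mm:
        raise ValueError("bin width must be at least the flat-map cell size")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    u, v = flatmap.cell_centers
    ok = np.isfinite(flatmap.values)
    s = u[ok] * axis[0] + v[ok] * axis[1]
    w = flatmap.counts[ok].astype(float)
    vals = flatmap.values[ok]
    s0 = s.min()
    idx = np.floor((s - s0) / bin_width_mm + 1e-9).astype(int)
    nbins = idx.max() + 1
    sums = np.bincount(idx, weights=w * vals, minlength=nbins)
    wsum = np.bincount(idx, weights=w, minlength=nbins)
    ssum = np.bincount(idx, weights=w * s, minlength=nbins)
    keep = wsum > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty profile bins")
    # Bin abscissa: count-weighted mean projection of the cells in the bin
    # (the nominal bin midpoint misstates sparse edge bins).
    return ModularityProfile(
        axis=axis,
        bin_centers=ssum[keep] / wsum[keep],
        values=sums[keep] / wsum[keep],
        counts=wsum[keep],
        bin_width=bin_width_mm,
    )


@dataclass
class SinusoidFit:
    period: float
    amplitude: float
    phase: float
    r2: float


def fit_sinusoid(profile: ModularityProfile, n_candidates: int = 240) -> SinusoidFit:
    """Least-squares sinusoid fit to a collapsed profile.

    The period is scanned over [2*bin_width, axis extent] (log-spaced grid
    with a golden-section refinement); amplitude and phase are solved linearly
    per candidate period.  R^2 is relative to the mean-only model.
    """
    s, y = profile.bin_centers, profile.values
    if len(s) < 8:
        raise ValueError("need at least 8 profile bins")
    lo = 2.0 * profile.bin_width
    hi = max(profile.extent, lo * 1.01)

    tss = ((y - y.mean()) ** 2).sum()

    def rss(period: float) -> float:
        w = 2.0 * np.pi / period
        X = np.column_stack([np.ones_like(s), np.cos(w * s), np.sin(w * s)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float((r**2).sum())

    periods = np.geomspace(lo, hi, n_candidates)
    errors = np.array([rss(p) for p in periods])
    best = int(np.argmin(errors))

    # Golden-section refinement within the bracketing interval.
    a = periods[max(best - 1, 0)]
    b = periods[min(best + 1, len(periods) - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    x1, x2 = b - phi * (b - a), a + phi * (b - a)
    f1, f2 = rss(x1), rss(x2)
    for _ in range(40):
        if f1 < f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - phi * (b - a)
            f1 = rss(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + phi * (b - a)
            f2 = rss(x2)
    period = (a + b) / 2.0
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(s), np.cos(w * s), np.sin(w * s)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    final_rss = float(((y - X @ coef) ** 2).sum())
    amplitude = float(np.hypot(coef[1], coef[2]))
    phase = float(np.arctan2(coef[1], coef[2]))
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - final_rss / tss)
    return SinusoidFit(period=float(period), amplitude=amplitude, phase=phase, r2=r2)


def sensitivity(v) -> float:
    """Euclidean norm of the per-voxel response vector (t_RF0, t_RF4)."""
    v = np.asarray(v, dtype=float)
    return float(np.linalg.norm(v))


def specificity(v, theta_max_deg: float = 45.0) -> float:
    """Scaled-angle tuning index in [0, 1].

    Components of ``v`` are rectified at 0 and normalised; the reference
    winning vector is the axis of the larger rectified component (the 45 deg
    diagonal on exact ties, yielding specificity 0: equally tuned = not
    specific).  The zero vector maps to 0.
    """
    if theta_max_deg <= 0:
        raise ValueError("theta_max must be positive")
    v = np.clip(np.asarray(v, dtype=float), 0.0, None)
    norm = np.linalg.norm(v)
    if norm == 0:
        return 0.0
    v_hat = v / norm
    # Winning reference axis; an exact tie sits 45 deg from either axis, so
    # either choice gives the same (zero) specificity.
    w_hat = np.array([1.0, 0.0]) if v[0] >= v[1] else np.array([0.0, 1.0])
    angle = np.degrees(np.arccos(np.clip(v_hat @ w_hat, -1.0, 1.0)))
    # Clip away the -1e-16 residue arccos leaves on an exact 45 deg tie.
    return float(np.clip(1.0 - angle / theta_max_deg, 0.0, 1.0))


@dataclass
class SensSpecMaps:
    """Per-voxel sensitivity and specificity for one contrast mechanism."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    tag: str
    roi: np.ndarray = field(repr=False, default=None)


def sens_spec_maps(
    t_rf0_map: np.ndarray,
    t_rf4_map: np.ndarray,
    tag: str = "",
    roi: np.ndarray | None = None,
    theta_max_deg: float = 45.0,
) -> SensSpecMaps:
    """Voxelwise sensitivity/specificity from the two stimulus t maps."""
    t0 = np.asarray(t_rf0_map, dtype=float)
    t4 = np.asarray(t_rf4_map, dtype=float)
    if t0.shape != t4.shape:
        raise ValueError("t map grids differ")
    if roi is None:
        roi = np.ones(t0.shape, dtype=bool)
    sens = np.zeros(t0.shape)
    spec = np.zeros(t0.shape)
    sens[roi] = np.hypot(t0[roi], t4[roi])

    r0 = np.clip(t0, 0.0, None)[roi]
    r4 = np.clip(t4, 0.0, None)[roi]
    norm = np.hypot(r0, r4)
    with np.errstate(divide="ignore", invalid="ignore"):
        big = np.maximum(r0, r4) / norm
    angle = np.degrees(np.arccos(np.clip(big, -1.0, 1.0)))
    tie = (r0 == r4) & (norm > 0)
    angle[tie] = 45.0
    sp = np.clip(1.0 - angle / theta_max_deg, 0.0, 1.0)
    sp[norm == 0] = 0.0
    spec[roi] = sp
    return SensSpecMaps(sensitivity=sens, specificity=spec, tag=tag, roi=roi)


def compare_contrasts(bold: SensSpecMaps, vaso: SensSpecMaps) -> pd.DataFrame:
    """Summary table (median, quartiles, range) per index per contrast."""
    if bold.roi.shape != vaso.roi.shape or not np.array_equal(bold.roi, vaso.roi):
        raise ValueError("contrasts must share the same ROI")
    if not bold.roi.any():
        raise ValueError("empty ROI")
    rows = []
    for maps, contrast in ((bold, bold.tag or "bold"), (vaso, vaso.tag or "vaso")):
        for index_name, values in (
            ("sensitivity", maps.sensitivity[maps.roi]),
            ("specificity", maps.specificity[maps.roi]),
        ):
            q25, q50, q75 = np.percentile(values, [25, 50, 75])
            rows.append(
                {
                    "contrast": contrast,
                    "index": index_name,
                    "median": q50,
                    "q25": q25,
                    "q75": q75,
                    "iqr": q75 - q25,
                    "min": values.min(),
                    "max": values.max(),
                    "range": values.max() - values.min(),
                    "n": int(values.size),
                }
            )
    return pd.DataFrame(rows)
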