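"""Parametric cortical patch geometry, ground-truth domains and vasculature.

The synthetic cortical sheet is a height field: a slab of white matter, a
gray-matter ribbon of constant thickness, and cerebrospinal fluid above.  The
``folded_sheet`` variant bends the ribbon around a sinusoidal mid-surface
``z = z0 + a*sin(2*pi*x/L)`` whose slope, normal and curvature have closed
forms, so equidistant depths, flat (u, v) coordinates (arc length along the
fold, and y) and the local sheet curvature are all analytic.  Tissue labels
use 0 = WM, 1 = GM, 2 = CSF.

The ground-truth curvature-preference map ``p(u, v)`` in [-1, +1] (+1 = prefers
curved contours / RF0, -1 = prefers straight contours / RF4) is constant along
depth within a column — columnar by construction — and is laid out either as
stripes of period ``lambda_mm`` along u or as thresholded band-pass noise
blobs of the same characteristic scale.

The vascular model assigns every GM voxel a microvascular responsiveness
``m`` (drives the CBV response; zero outside GM) and a venous weight
``w_vein`` that grows toward the pial surface and extends into CSF-adjacent
voxels, emulating draining veins that carry stimulus-evoked BOLD signal beyond
the gray-matter boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "WM",
    "GM",
    "CSF",
    "PatchGeometry",
    "DomainMap",
    "VascularMap",
    "make_patch_geometry",
    "make_domain_map",
    "make_vascular_map",
]

WM, GM, CSF = 0, 1, 2


@dataclass
class PatchGeometry:
    """Voxelised synthetic cortical patch with analytic depth/flat coordinates.

    ``depth`` is the equidistant depth d in [0, 1] (0 = WM boundary, 1 = CSF
    boundary), defined on GM voxels and NaN elsewhere.  ``height`` is the
    signed normal distance (mm) from the ribbon mid-surface for every voxel.
    ``kappa`` is the mid-surface curvature (1/mm) of each voxel's column,
    positive where GM is convex toward CSF.
    """

    labels: np.ndarray
    depth: np.ndarray
    height: np.ndarray
    u: np.ndarray
    v: np.ndarray
    kappa: np.ndarray
    voxel_mm: float
    thickness_mm: float
    kind: str

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels == GM


def make_patch_geometry(
    shape=(40, 20, 10),
    voxel_mm: float = 1.2,
    wm_mm: float = 3.6,
    thickness_mm: float = 3.6,
    kind: str = "flat_slab",
    fold_amp_mm: float = 1.8,
    fold_period_mm: float = 24.0,
) -> PatchGeometry:
    """Construct a flat-slab or sinusoidally folded cortical patch.

    Parameters
    ----------
    shape : tuple of int
        Grid size (nx, ny, nz) in voxels; z is the through-sheet axis.
    wm_mm : float
        Height of the WM compartment below the ribbon (flat slab) /
        mid-surface baseline minus half thickness (folded sheet).
    thickness_mm : float
        GM ribbon thickness T.

    Raises
    ------
    ValueError
        If the ribbon would span fewer than two voxels.
    """
    if thickness_mm <= 0 or voxel_mm <= 0 or any(s <= 0 for s in shape):
        raise ValueError("thickness, grid size and voxel size must be positive")
    if thickness_mm < 2 * voxel_mm:
        raise ValueError(
            f"thickness {thickness_mm} mm < 2 voxels ({2 * voxel_mm} mm): "
            "depth sampling would be degenerate"
        )
    if kind not in ("flat_slab", "folded_sheet"):
        raise ValueError(f"unknown geometry kind {kind!r}")

    nx, ny, nz = shape
    xs = (np.arange(nx) + 0.5) * voxel_mm
    ys = (np.arange(ny) + 0.5) * voxel_mm
    zs = (np.arange(nz) + 0.5) * voxel_mm
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")

    z_mid0 = wm_mm + thickness_mm / 2.0
    if kind == "flat_slab":
        amp = 0.0
    else:
        amp = fold_amp_mm
    k_fold = 2.0 * np.pi / fold_period_mm
    f = z_mid0 + amp * np.sin(k_fold * x)  # mid-surface height
    fp = amp * k_fold * np.cos(k_fold * x)  # slope
    fpp = -amp * k_fold**2 * np.sin(k_fold * x)
    cos_a = 1.0 / np.sqrt(1.0 + fp**2)
    # Signed normal distance from the mid-surface (positive toward CSF).
    height = (z - f) * cos_a
    # Mid-surface curvature, positive where GM is convex toward CSF.
    kappa = -fpp * cos_a**3
    if kind == "flat_slab":
        kappa = np.zeros_like(kappa)

    labels = np.full(shape, CSF, dtype=np.int8)
    labels[height < -thickness_mm / 2.0] = WM
    gm = (height >= -thickness_mm / 2.0) & (height < thickness_mm / 2.0)
    labels[gm] = GM

    depth = np.full(shape, np.nan)
    depth[gm] = height[gm] / thickness_mm + 0.5

    # Flat coordinate u = arc length along the fold; closed under quadrature.
    fine = np.linspace(0.0, nx * voxel_mm, 4096)
    ds = np.sqrt(1.0 + (amp * k_fold * np.cos(k_fold * fine)) ** 2)
    arc = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2.0 * np.diff(fine))])
    u = np.interp(x, fine, arc)
    v = y.copy()

    return PatchGeometry(
        labels=labels,
        depth=depth,
        height=height,
        u=u,
        v=v,
        kappa=kappa,
        voxel_mm=voxel_mm,
        thickness_mm=thickness_mm,
        kind=kind,
    )


@dataclass
class DomainMap:
    """Ground-truth columnar preference map.

    ``p`` holds the per-voxel preference in [-1, +1], constant along depth
    within each column (it is a pure function of (u, v)); defined on the whole
    grid so that CSF voxels above a column inherit that column's preference
    (draining-vein territory).
    """

    p: np.ndarray
    pattern: str
    lambda_mm: float
    seed: int | None = None
    graded: bool = False


def make_domain_map(
    geometry: PatchGeometry,
    pattern: str = "stripes",
    lambda_mm: float = 4.8,
    seed: int | None = None,
    graded: bool = False,
) -> DomainMap:
    """Lay out alternating curvature-preference domains on the patch.

    stripes
        ``p = sign(sin(2*pi*u/lambda))`` (or the graded sine), alternating
        along the flat coordinate u with period ``lambda_mm``.
    blobs
        Band-pass filtered Gaussian noise at scale ``lambda_mm`` on the (u, v)
        chart, thresholded at zero (or amplitude-normalised when graded).

    A warning is emitted when ``lambda_mm < 2 * voxel_mm`` (under-sampled).
    """
    if lambda_mm <= geometry.voxel_mm:
        warnings.warn(
            f"domain period {lambda_mm} mm is not larger than the voxel size "
            f"{geometry.voxel_mm} mm; the pattern cannot be resolved",
            stacklevel=2,
        )
    elif lambda_mm < 2 * geometry.voxel_mm:
        warnings.warn(
            f"domain period {lambda_mm} mm < 2 voxels: under-sampled pattern",
            stacklevel=2,
        )
    if pattern == "stripes":
        wave = np.sin(2.0 * np.pi * geometry.u / lambda_mm)
        p = wave if graded else np.sign(wave)
    elif pattern == "blobs":
        rng = np.random.default_rng(seed)
        # Columnar by construction: noise lives on a 2D (u, v) grid sampled at
        # sub-voxel resolution, band-passed around scale lambda, then looked up
        # per voxel through its (u, v) coordinates.
        cell = geometry.voxel_mm / 3.0
        u_max = float(geometry.u.max()) + cell
        v_max = float(geometry.v.max()) + cell
        gu = np.arange(0.0, u_max + cell, cell)
        gv = np.arange(0.0, v_max + cell, cell)
        noise = rng.standard_normal((len(gu), len(gv)))
        lo = gaussian_filter(noise, sigma=lambda_mm / 4.0 / cell, mode="wrap")
        hi = gaussian_filter(noise, sigma=lambda_mm / 2.0 / cell, mode="wrap")
        band = lo - hi
        band = band / (np.abs(band).max() or 1.0)
        iu = np.clip(np.round(geometry.u / cell).astype(int), 0, len(gu) - 1)
        iv = np.clip(np.round(geometry.v / cell).astype(int), 0, len(gv) - 1)
        p = band[iu, iv] if graded else np.sign(band[iu, iv])
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return DomainMap(p=p, pattern=pattern, lambda_mm=lambda_mm, seed=seed, graded=graded)


@dataclass
class VascularMap:
    """Per-voxel microvascular responsiveness and venous weighting.

    ``m`` (>= 0) scales the CBV response and is nonzero only in GM.
    ``w_vein`` (>= 0) scales the BOLD response, increases toward the pial
    surface inside GM and remains nonzero in CSF voxels within the draining
    territory above the ribbon.  ``pooling_fwhm_mm`` is the in-plane scale over
    which draining veins mix blood from neighbouring columns.
    """

    m: np.ndarray
    w_vein: np.ndarray
    pooling_fwhm_mm: float


def make_vascular_map(
    geometry: PatchGeometry,
    w_deep: float = 0.5,
    w_rise: float = 0.8,
    w_surface: float = 1.3,
    csf_extent_mm: float = 2.4,
    pooling_fwhm_mm: float = 1.5,
    hotspot_density_per_cm2: float = 1.0,
    hotspot_gain: float = 2.5,
    hotspot_sigma_mm: float = 1.5,
    seed: int | None = None,
) -> VascularMap:
    """Build the vascular model on a patch.

    GM: ``m = 1`` and ``w_vein = w_deep + w_rise * d**2`` (depth-weighted
    toward the surface).  CSF within ``csf_extent_mm`` above the ribbon:
    ``m = 0`` and ``w_vein = w_surface * (1 - h_csf / csf_extent_mm)`` where
    ``h_csf`` is the height above the GM/CSF boundary.  Everywhere else both
    are zero.

    On top of the smooth profile, discrete draining-vein hotspots — a Poisson
    scatter of ``hotspot_density_per_cm2`` sites across the flat chart, each a
    Gaussian bump of width ``hotspot_sigma_mm`` — multiply ``w_vein`` by up to
    ``1 + hotspot_gain``.  Large pial veins are sparse and locally dominant,
    which is what breaks the smooth periodic structure of BOLD maps; set the
    density or gain to 0 for a purely laminar vein model.
    """
    gm = geometry.gm_mask
    m = np.where(gm, 1.0, 0.0)
    w = np.zeros(geometry.shape)
    w[gm] = w_deep + w_rise * geometry.depth[gm] ** 2
    h_csf = geometry.height - geometry.thickness_mm / 2.0
    csf_adj = (geometry.labels == CSF) & (h_csf < csf_extent_mm)
    w[csf_adj] = w_surface * (1.0 - h_csf[csf_adj] / csf_extent_mm)

    if hotspot_density_per_cm2 > 0 and hotspot_gain > 0:
        rng = np.random.default_rng(seed)
        sheet = gm | csf_adj
        u_lo, u_hi = float(geometry.u[sheet].min()), float(geometry.u[sheet].max())
        v_lo, v_hi = float(geometry.v[sheet].min()), float(geometry.v[sheet].max())
        area_cm2 = (u_hi - u_lo) * (v_hi - v_lo) / 100.0
        n_sites = rng.poisson(hotspot_density_per_cm2 * area_cm2)
        if n_sites:
            su = rng.uniform(u_lo, u_hi, n_sites)
            sv = rng.uniform(v_lo, v_hi, n_sites)
            bump = np.zeros(geometry.shape)
            for cu, cv in zip(su, sv):
                d2 = (geometry.u - cu) ** 2 + (geometry.v - cv) ** 2
                bump += np.exp(-d2 / (2.0 * hotspot_sigma_mm**2))
            w = w * (1.0 + hotspot_gain * np.clip(bump, 0.0, 1.0))
    return VascularMap(m=m, w_vein=w, pooling_fwhm_mm=pooling_fwhm_mm)
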