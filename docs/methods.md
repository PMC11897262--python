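# Methods

This document specifies the generative model, the analysis chain, the
numerical choices that make the oracle tests exact, and the limitations of
the simulator.

## 1. Cortical geometry

The patch is a height field on a regular grid (default 40×20×10 voxels at
1.2 mm isotropic): a WM base (default 3.6 mm), a GM ribbon of constant
thickness `T` (default 3.6 mm), and CSF above. Two kinds are available:

- `flat_slab`: the mid-surface is a horizontal plane;
- `folded_sheet`: the mid-surface is `f(x) = z0 + A·sin(2πx/P)`
  (default A = 1.8 mm, P = 24 mm).

Voxel height above the mid-surface is measured along the surface normal,
`h = (z − f(x))·cos α` with `tan α = f′(x)`; labels are assigned by
`h < −T/2` (WM), `−T/2 ≤ h < T/2` (GM), else CSF. The chart coordinate `u`
is arc length along the folded profile (so the flat map unrolls the fold),
`v` is the second in-plane axis, and the signed curvature of the mid-surface
is `κ = −f″ cos³α`. Geometries thinner than two voxels across GM are
rejected: depth sampling would be degenerate.

Default GM thickness 3.6 mm puts exactly three voxel centres across the
ribbon (equidistant depths 1/6, 1/2, 5/6), so the default three laminar bins
are all populated. The 40×20 in-plane extent is deliberately elongated so
the ROI's principal axis is well defined and aligned with the stripe axis.

## 2. Domain, vascular and stimulus models

**Curvature-preference map.** `p(u) = sin(2πu/λ)` for stripes (default
λ = 4.8 mm, graded) or band-pass-filtered noise on the (u, v) chart for
blobs. Graded preference models partial voluming: a 1.2 mm voxel averages
sub-voxel domains, so its tuning is fractional. Binary ±1 stripes
(`graded=False`) are available but saturate VASO specificity at 1. A warning
is issued when λ < 2·voxel (aliasing).

**Vascular maps.** Microvascular density `m = 1` in GM (CBV responses are
laminar-uniform in this model). The macrovascular weight is
`w_vein = 0.5 + 0.8·d²` across GM depth `d` (rising toward the surface),
extended into CSF as `1.3·exp-decay` over 2.4 mm, plus sparse pial-vein
hotspots: a seeded Poisson scatter (default 1 cm⁻²) of Gaussian bumps
(σ = 1.5 mm) multiplying `w_vein` by up to ×2.5. Hotspots matter: smooth
pooling alone attenuates but does not distort a sinusoidal layout, whereas
discrete dominant veins are what break the periodicity of the BOLD profile.

**Stimuli and timeline.** RF stimuli `r(θ) = r0(1 + A·sin(ωθ + Φ))` with
contrast-reversing ring textures; RF0 is the circle control, RF4 the
four-lobed curvature pattern (amplitudes `A ≥ 1` are rejected as
non-simple). The run timeline is 33 rest pair-TRs (86.13 s) then 14
alternating 31.32 s blocks (RF0/RF4 with interleaved rests), 369 pair-TRs of
2.610 s per run, 4 runs by default.

## 3. Acquisition model

Per pair index `k` (time `t_k = k·TR_pair`), with condition drive
`drive_c = (1 ± p)/2` and block response `D(t)`:

```
bold_factor = 1 + ΔBOLD · w_vein · Σ_c drive_pooled_c · D_bold
cbv_ratio   = 1 − ΔCBV  · m      · Σ_c drive_c        · D_cbv
nulled      = S0 · cbv_ratio · bold_factor · trend
not_nulled  = S0 ·             bold_factor · trend
```

`S0` is {WM 80, GM 100, CSF 120}; ΔCBV = 0.02, ΔBOLD = 0.04;
`trend` is a linear drift of 0.1 % per run. The BOLD drive uses the
preference map pooled in-plane with a Gaussian of FWHM 1.5 mm (draining
veins integrate over a territory larger than a column); pooling with an even
kernel preserves the sign of the odd stripe pattern at voxel centres, so
noiseless VASO and BOLD preference maps agree in sign.

**Block response.** Piecewise half-cosines: rise to peak at 6 s after
onset, settle over 4 s to a plateau of 0.8, and fall back over 6 s (BOLD) or
14 s (CBV — delayed vascular compliance). Time to peak is therefore exactly
6 s by construction.

**Common time grid.** Both series are sampled at `t_k`; the two inversion
times are carried as metadata only. The pipeline still applies the full
alignment chain (§4); on these equal-time series the alignment step
introduces a half-pair (1.305 s) offset in the nulled series. Against
31.32 s blocks and a 26.1 s analysis window this shifts block means by
≲ 1 sample in 20 and cancels in the RF0−RF4 difference; it is the price of
exercising the real chain rather than a shortcut.

### Noise calibration

Gaussian noise is added in float64 after the clean signal is formed. Targets
are GM temporal-SNR floors of 25 (corrected VASO) and 40 (BOLD), with a
margin factor 1.25 for "well above":

```
σ_bold   = S0 / (40·1.25)
σ_nulled = S0 · sqrt( 1/(25·1.25)² − 1/(40·1.25)² )
```

The second line accounts for the division: relative noise of the corrected
VASO series is the quadrature sum of the nulled and not-nulled relative
noise, so the nulled noise is set to the residual that makes the *corrected*
series hit its target. Measured single-run GM medians land at ≈ 33 (VASO)
and ≈ 49 (BOLD); they sit below the naive margin·floor because
stimulus-evoked variance also enters the temporal SD.

### Bit-exact BOLD correction

The simulator quantises `cbv_ratio` and the clean `not_nulled` signal to
float32 before forming `nulled = cbv_ratio · not_nulled` in float64. Two
24-bit significands multiply exactly in double precision, and IEEE division
of that exact product by one factor returns the other factor exactly. Hence
at zero noise, dynamic division recovers the stored CBV component
bit-identically (`np.array_equal`), by construction rather than by
test-side tolerance.

## 4. Preprocessing chain

Each series carries an append-only provenance log; every operation validates
the log so the chain can only run in order:

1. `separate_contrasts` — split the interleaved pair series.
2. `replace_nonsteady` — first 4 volumes replaced by volume 4.
3. `temporal_upsample` — ×2 cubic-spline interpolation (natural boundary;
   exact on constants and ramps), 369 → 738 samples, dt 1.305 s.
4. `align_nulled` — duplicate the first nulled volume, drop the last,
   restoring temporal correspondence between the contrasts.
5. `boco_correct` — dynamic division nulled/not-nulled with a guarded
   denominator (voxels whose denominator falls below 25 % of their mean are
   filled with the previous valid value and flagged in QC), output clipped
   to [0, 2].
6. `average_runs` — across-run mean on matched grids/logs.
7. `tsnr_map` — mean/SD (ddof = 1); zero-variance voxels get +inf as the QC
   sentinel.

## 5. Activation and preference mapping

**GLM.** Design matrix with 4 columns: DC, zero-mean linear ramp, and one
unconvolved boxcar per condition. No hemodynamic convolution: CBV and BOLD
responses differ in shape, and boxcars keep the two mechanisms comparable.
Voxelwise OLS with `t(c) = c′β̂ / sqrt(σ̂² c′(X′X)⁻¹c)`; CBV-weighted maps
are sign-flipped so positive t means activation. Contrasts: per-condition
versus baseline, their mean (stimulus versus baseline), and RF0−RF4.

**Block-peak preference.** Per block: mean signal in a peak window 5.22 to
31.32 s after onset (past the rise) minus the mean of the last 10.44 s of
the preceding rest. Windows are cut on *integer sample indices* relative to
the onset sample, not by thresholding a float time axis: boolean masks on a
float grid gain or lose edge samples block-to-block through rounding jitter,
which at zero noise produced spurious ~3 % amplitude differences between
identical blocks. Preference is the two-sample t (Welch by default) of
RF0-block versus RF4-block amplitudes; zero-variance cases give ±inf (or 0
when the means agree), the noiseless limit.

## 6. Laminar sampling and flat maps

**Equi-volume depth.** For a voxel at equidistant depth `d` in a ribbon of
thickness `T` with local curvature `κ`, the wedge closed form with inner
radius `r1 = 1/|κ|` gives the volume fraction

```
f(d) = ((r1 + dT)² − r1²) / ((r1 + T)² − r1²)
```

mirrored for κ < 0, reducing to `f = d` as κ → 0. Layer bins are equal
f-fraction bins.

**Flat maps.** GM voxels in a depth range are binned into square (u, v)
cells (default: one voxel size) anchored on the full-GM chart so different
depth bins share cells; the cell value is the voxel mean. On curved
geometry the cell size controls chart-quantisation blur — ground-truth
recovery on the folded sheet reaches r > 0.99 at 0.2 mm cells.

**Columnarity.** Mean pairwise Pearson correlation between depth-bin flat
maps over shared cells; undefined (NaN, with a warning) when bins are
constant or disjoint.

## 7. Modularity quantification

- **Lead axis**: first PCA axis of the ROI cell coordinates; near-isotropic
  ROIs (eigenvalue ratio < 1.2) warn that the axis is ill-defined.
- **Collapse**: cells are projected onto the axis and averaged in bins of
  the cell width, count-weighted; the bin abscissa is the count-weighted
  mean projection of its cells (the nominal midpoint misstates sparse edge
  bins). Bin assignment uses `floor((s − s0)/w + 1e-9)` so bins tile the
  axis without the half-bin overlap a rounding rule produces.
- **Sinusoid fit**: period scanned on a 240-point log grid over
  [2·bin width, extent], refined by golden section; amplitude/phase solved
  linearly per candidate; R² relative to the mean-only model, floored at 0.
- **Sensitivity**: `‖(t_RF0, t_RF4)‖`.
- **Specificity**: components rectified at 0 and normalised;
  `1 − angle(v̂, ŵ)/45°` where `ŵ` is the axis of the larger component. An
  exact tie sits 45° from either axis → 0 (equally tuned = not specific);
  the zero vector → 0. Output clipped to [0, 1] (arccos leaves a −1e-16
  residue on exact ties).

## 8. Problem sizes and runtime

| configuration | grid | runs | wall time |
|---|---|---|---|
| `tiny` (tests, fixtures) | 16×16×8 | 2 | ~1 s end to end |
| default | 40×20×10 | 4 | ~16 s end to end |

The full test suite runs in ~35 s; `scripts/acceptance.py` in ~10 s.

## 9. What the generator does and does not emulate

Emulated: interleaved two-contrast acquisition on a shared grid;
multiplicative BOLD contamination of the nulled series and its removal by
division; distinct CBV/BOLD response shapes; depth-dependent macrovascular
weighting with pial pooling and discrete vein hotspots; partial-volume
graded tuning; thermal noise and linear drift; non-steady-state initial
volumes (replaced, as in the pipeline).

Not emulated: head motion and distortion (no realignment is needed or
implemented); physiological (cardiac/respiratory) noise structure; T1-decay
dynamics across the inversion cycle (inversion times are metadata only);
inflow effects; spatial noise correlations; multi-subject variability;
laminar variation of the CBV response itself (`m` is uniform — laminar
*profiles* here reflect vascular weighting, not neuronal laminar
differences); BOLD nonlinearity (the contamination is purely
multiplicative, which is what makes exact correction possible).

These omissions are deliberate: each one either does not interact with the
quantities under test or would destroy the exactness that makes the oracle
tests sharp.
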