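# Methods

This note documents the models, conventions and numerical choices behind
`domescope`, what the synthetic phantoms do and do not emulate, and the
limitations a user should know before pointing the pipeline at real data.

## Coordinate and calibration conventions

A z-stack is a float volume indexed `(section, y, x, channel)`. Sections
are 0-based and ordered from the Transwell membrane upward; section `i`
lies at height `i · z_step` µm. The nominal axial spacing is 2 µm, so a
28-section stack spans heights 0–54 µm. Intensities are converted to
floating point at load regardless of on-disk bit depth, because the whole
chain operates on a normalized 0–1 scale. When file metadata and
user-supplied calibration disagree, the user value wins with a logged
warning: microscope exports are inconsistent, and explicit intent should be
authoritative.

## Synthetic phantoms and their ground truth

The phantom emulates the geometry the pipeline measures: an epithelial
monolayer occupying a `base_coverage` fraction of the field up to
`monolayer_height_um` (default 14 µm, matching a mature co-culture
monolayer), carrying spherical-cap domes. A cap of base radius `r` px and
height `c` µm contributes, at height `h` above the monolayer top, a disk of
radius `r·sqrt(1 − (h/c)²)`, sampled at `h = 0, z_step, 2·z_step, …` so the
base disk has full radius and the cross-sections shrink monotonically —
this closed form is also the analytic coverage oracle the tests compare
against.

The monolayer mask is smoothed Gaussian noise (σ = 12 px) thresholded at
the exact quantile, so the covered-pixel fraction equals `base_coverage` to
one pixel; dome footprints are forced covered first (domes sit on cells).
The mucus/WGA channel carries a weak signal (0.3) throughout the cell body
— the lectin binds cell-surface glycans everywhere, which is what makes
per-section coverage measurable — plus a bright shell (0.9) where a column
reaches its top surface, mimicking the secreted mucus layer capping the
culture. Nuclei are isotropic Gaussian blobs (σ = 3 px, default 10 per
100×100 px) scattered inside covered regions at random monolayer sections.
Noise is additive Gaussian (default sd 0.02, clipped at 0); Poisson photon
statistics, optical PSF blur, photobleaching and tile-seam artifacts are
deliberately out of scope. Identical specs (including the seed) render
bit-identical stacks.

Because the phantom lacks PSF blur and autofluorescence, a segmentation
result on phantoms bounds what the chain can do on ideal data; it does not
certify performance on real mosaics, where the `SegmentationConfig`
defaults may need tuning (notably `min_intensity` and `block_size`).

## Segmentation chain

Per section: normalize → merge channels → optional gamma → Gaussian smooth
→ adaptive threshold + intensity floor → hygiene.

- **Normalization.** Percentile-clip then affine map to [0, 1]; a constant
  image maps to zeros. By default the clip bounds are computed once over
  the *whole stack* (`normalize_over="stack"`), so sections above the
  tissue, which contain only noise, stay dark instead of being stretched to
  full contrast. Per-section normalization remains available.
- **Channel weights** default to (1, 0): coverage is defined on the
  WGA/mucus channel; nuclei are kept for QC overlays only.
- **Weak-signal enhancement** is a logged gamma transform `x^γ` (γ < 1
  brightens dim regions, γ = 1 identity). It replaces interactive contrast
  editing with a single reproducible, manifest-recorded parameter and
  preserves pixel ordering for any γ > 0.
- **Binarization.** A pixel is foreground if it exceeds the local mean
  over a `block_size` window (default 51 px, reflected borders) by
  `offset` (default 0.02) — robust to the uneven illumination of tiled
  mosaics and exactly invariant to adding a constant to the image — **or**
  if it exceeds an absolute floor `min_intensity` (default 0.15 in
  stack-normalized units). The floor is load-bearing: a large uniform cell
  sheet has no local contrast anywhere in its interior, so a purely
  local criterion detects only its edges. With stack-level normalization
  the floor separates cell-body signal (≈ 0.3) from background noise by
  several standard deviations. Setting `min_intensity=None` recovers the
  purely local rule.
- **Smoothing** (Gaussian, σ = 1.5 px) before thresholding suppresses
  single-pixel noise; it shifts mask boundaries by at most ~1–2 px, which
  is the dominant term in the coverage-error budget (≈ boundary length ×
  2 px / field area per section, about 0.01–0.03 in practice).
- **Hygiene.** Components under `min_object_px` (default 25 px) are
  removed. Hole filling is available but off by default: with the
  intensity floor the mask interior is detected directly, and filling
  would silently annex genuinely uncovered patches enclosed by cells.

Section QC: slide-grid artifacts appear as thin bright image-spanning
lines. A section is excluded when the largest Hough-accumulator peak of
its bright foreground (> 0.5 after per-section normalization) exceeds a
quarter of the image extent *and* accounts for at least `line_occupancy`
(default 0.3) of the foreground area — a thin spanning line concentrates
~half its pixels on one line, while filled blobs concentrate
`2·sqrt(area/π)/area`, well under 0.1. Manual exclusion lists are honored
verbatim. Excluded sections propagate as missing values (never zeros), and
cross-replicate section means are flagged `full` when every replicate
contributes and `partial` otherwise. A line at the same brightness as a
dense confluent sheet it crosses is not separable by this test; the manual
list covers that case.

## Morphometrics

Coverage is the foreground fraction per non-excluded section. Connected
components use 8-connectivity by default (conventional for blob-like
biological objects; 4-connectivity is a config switch). Eccentricity comes
from the ellipse with the same second central moments as the region:
`e = sqrt(1 − (b/a)²)`, identical to the inter-focal-distance over
major-axis definition. The moments-based fit is deterministic and
iteration-free; rasterization keeps it within 0.02 of the closed form for
axis ratios down to 0.25 (verified against rasterized ellipses).
Regions touching the image border are kept — mosaics crop arbitrarily —
but flagged `border=true` for optional filtering. Per-section eccentricity
profiles aggregate object values by mean (default) or median, both
exposed, since the choice of statistic is a user-level decision.

## Height map and dome detection

`height(y, x) = z_step · (1 + highest foreground section index)`, 0 where
no section is foreground; the map depends only on masks, hence is
invariant to intensity rescaling. Resampling to the analysis grid
(default 128×128) uses area-weighted block means — exact block means for
divisible shapes, fractional pixel splitting otherwise — so the global
mean height is conserved exactly. The legacy display z-scale (0.1) is kept
as a plot option and never enters measurements.

Zero-height pixels are *missing surface*, not surface at the membrane.
Before resampling and baseline estimation they are inpainted by iterative
min-propagation: each gap pixel takes the minimum neighboring measured
height, moving inward. Taking the minimum (rather than the nearest value)
matters at dome rims: a gap bordered by both monolayer and dome adopts the
monolayer level, so dome footprints do not smear into adjacent uncovered
patches. Without any inpainting, gaps drag the baseline erosion to the
membrane and the entire monolayer registers as one giant dome.

The local baseline is a grayscale opening with a rolling disk whose radius
(default `min(grid)/4`) must exceed the largest expected dome radius, so
domes are removed from the baseline while broad topography is preserved.
Domes are connected regions where `height − baseline ≥ min_prominence_um`
(default 4 µm = two z-steps) with footprint `≥ min_area_px` (default 25 px
at grid 128); each yields footprint area, maximum prominence (apex height
above the local monolayer), and footprint eccentricity. Two caps whose
elevated regions merge are reported as one dome with the combined
footprint — the intended semantics, since neighboring domes fuse into
larger formations as differentiation progresses. Apex prominences are
quantized upward by the section spacing, so recovered heights sit within
one z-step of truth when the baseline is clean.

Per-angle-view scoring replaces visual counting on rendered 3D surface
plots from four angles with an explicit geometric criterion: for each
azimuth (0°, 90°, 180°, 270°), a dome is visible when some footprint pixel
rises at least `min_prominence_um` above the running maximum of all
*other* structure between it and the viewer (the dome's own pixels are
excised from the sweep — a dome cannot hide behind itself). The headline
statistic is the mean visible count over the four views; it equals the
total count exactly when nothing occludes, and is preserved under 90°
rotations of the surface.

## Condition comparisons

Replicates, not sections, are the independent units. Per section, the
replicate coverage values of two conditions are compared by Mann–Whitney
U; the *overall* test collapses each replicate's profile to its trapezoidal
area under coverage-vs-height (missing sections dropped) and runs one
Mann–Whitney on those scalars — pooling sections across replicates would
pseudo-replicate. Holm-adjusted p-values are reported alongside raw ones
across the per-section family; Holm is conservative and assumption-free,
and both values are always emitted so users can apply their own criterion.

The U statistic counts pairs with `x_i > y_j` plus half the ties, so U = 0
when every x lies below every y. For `n1 + n2 ≤ 12` the two-sided p-value
is exact by full enumeration of the `C(n1+n2, n1)` group labelings of the
pooled data (ties handled naturally, since enumeration permutes observed
values); beyond that, the tie-corrected normal approximation with
continuity correction is used. With three replicates per group the exact
null distribution is discrete with minimum two-sided p = 0.1, so the
overall test cannot produce false positives at α = 0.05 at that size —
small-sample conservatism users should be aware of when powering
experiments.

## Barrier physiology

- **Orbital shear**: `τ_max = a · sqrt(ρ·η·(2πf)³)` — the classic estimate
  of the maximal bottom shear in an orbitally swirled well, with `a` the
  orbital radius (half the orbital diameter). Defaults ρ = 1000 kg/m³ and
  η = 9.5×10⁻⁴ Pa·s describe culture medium at 37 °C; a 25 mm orbit at
  55 rpm gives 0.168 Pa ≈ 0.17 Pa (1.7 dynes/cm²). The estimate scales as
  `f^1.5` and `sqrt(ρη)` and ignores shear attenuation by the microvilli
  brush border.
- **TEER**: `(R_measured − R_blank) · A` in Ω·cm² (blank = cell-free
  insert, default A = 1.12 cm²). Negative corrected values are returned
  with a warning rather than raised — they occur with drifting blanks and
  should be visible, not fatal.
- **P_app** = `K · Vr / A` (cm/s; Vr in mL = cm³, default 1.5 mL and
  1.12 cm²). K is the least-squares slope of the receiver concentration
  (as a fraction of donor concentration) over the steady-state window,
  defaulting to the final two-thirds of time points. When the receiver is
  periodically sampled with volume replacement (e.g. 100 µL every 20 min
  over 3 h), measured concentrations are first corrected by cumulative
  mass accounting, `C'ₙ = Cₙ + (s/Vr)·Σ_{k<n} Cₖ`; omitting this biases K
  low by a deterministic amount (about 3% per sampled fraction here, and
  verified by forward simulation: the corrected fit recovers K to machine
  precision on noiseless simulated series, and to well under 2% median
  error with 1% measurement noise). The fit assumes sink conditions
  (constant donor concentration) over the assay window.
- **Flux AUC** is a plain trapezoid over strictly increasing times, and
  `dilution_nominal` is the nominal concentration after an n-fold
  dilution (`c / factor`) used for digesta dilution bookkeeping.

## Problem sizes used in the bundled checks

The test suite and `scripts/acceptance.py` run entirely on generated
phantoms at desk scale, chosen to exercise every code path with tight
oracles: 256×256 px / 16-section stacks (two 40 px domes) for segmentation
and coverage fidelity; 512×512 px stacks with five randomized
well-separated caps (radius 30–50 px, cap 8–12 µm), 50 replicates, for
dome recovery; 128×128 px / 12-section stacks, four replicates per
condition at coverage 0.8 vs 0.5, for the power check of the overall test;
100 random datasets (n₁+n₂ ≤ 10) against a full permutation oracle for
Mann–Whitney exactness; and 100 random parameter draws for permeability
recovery. One acceptance run completes in about a minute on a single CPU.

## Known limitations

- The segmentation defaults are tuned for two-channel WGA + nuclei stacks
  with dark extracellular background; densely autofluorescent samples will
  need a higher `min_intensity` or `normalize_over="section"`.
- Dome detection assumes domes are *elevations on a monolayer*; it has no
  notion of multi-layered tissue or overhangs (a height map is single-
  valued per column).
- The per-view visibility criterion models occlusion along axis-aligned
  rays on the resampled grid; oblique camera elevation and perspective are
  not modeled.
- Nucleus-level analysis (counts, instance segmentation) is out of scope;
  the nuclei channel is carried through I/O and phantoms for QC only.
- The exact Mann–Whitney enumerator is O(C(n, n1)) and capped at
  n1 + n2 = 12 by default; larger samples switch to the normal
  approximation automatically.
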