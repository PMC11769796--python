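# domescope

Quantitative analysis of **dome formation** and three-dimensional epithelial
organization in confocal z-stacks of intestinal co-culture models
(Caco-2/HT29-MTX-E12 on Transwell inserts), plus the closed-form
barrier-physiology calculators that accompany such experiments.

Domes are fluid-filled, blister-like elevations of a polarized epithelial
monolayer driven by active basolateral fluid transport — a hallmark of
advanced differentiation. `domescope` turns two-channel confocal z-stacks
(a WGA/mucus channel marking cellular presence and the secreted mucus
shell, and a nuclei channel) into per-section morphometrics and explicit
3D dome records:

- **coverage profiles** — fraction of cell-covered pixels per optical
  section, as a function of height above the Transwell membrane;
- **contiguous-object counts and eccentricity** — connected components of
  the per-section masks, scored by area (px) and ellipse eccentricity
  `e = sqrt(1 − (b/a)²)` (0 = circle, → 1 = line);
- **height-map surface reconstruction** — per-pixel top height
  `z_step · (1 + highest foreground section)`, block-averaged to a 128×128
  grid, with domes detected as connected regions rising at least a minimum
  prominence above a rolling-disk (morphological opening) baseline;
- **per-angle-view dome visibility** — each dome is scored against four
  azimuthal viewing directions with an explicit occlusion test, yielding
  the "average number of domes per angle view" statistic;
- **condition comparisons** — exact-enumeration Mann–Whitney U per section
  plus one overall test on per-replicate profile AUCs, with Holm
  adjustment;
- **barrier physiology** — orbital-shaker shear stress
  `τ = a·sqrt(ρ·η·(2πf)³)`, blank-corrected area-normalized TEER,
  apparent permeability `P_app = K·Vr/A` with sampling-dilution
  correction, and trapezoidal flux AUC.

A **synthetic phantom generator** (`domescope.phantom`) renders two-channel
stacks of a monolayer carrying spherical-cap domes with exact ground truth
(per-section masks, analytic coverage, per-dome geometry), so every stage
of the pipeline is testable without microscope data.

## Worked example

```python
import numpy as np
from domescope import phantom, segment, morpho, dome3d, physio

# a 512x512 px, 28-section stack (2 um steps): 80%-covered monolayer up to
# 14 um, carrying two spherical-cap domes
spec = phantom.PhantomSpec(
    width=512, height=512, n_sections=28, z_step=2.0, base_coverage=0.8,
    domes=[phantom.Dome(cx=150, cy=150, radius=50, cap_height_um=10),
           phantom.Dome(cx=360, cy=330, radius=45, cap_height_um=8)],
    noise_sd=0.02, seed=1)
stack, truth = phantom.generate_phantom(spec)

masks = segment.segment_stack(stack)                    # per-section binarization
profile = morpho.coverage_profile(masks, z_step=spec.z_step)
print("coverage at 0/6/12/16/20 um:",
      [round(profile.coverage[i], 3) for i in (0, 3, 6, 8, 10)])

hm = dome3d.resample_grid(dome3d.height_map(masks, spec.z_step), 128)
records, fp = dome3d.detect_domes_with_footprints(hm, min_prominence_um=4.0,
                                                  min_area_px=25)
avg, records = dome3d.count_per_angle_view(hm, records, 4.0, fp)
for r in records:
    print(f"dome {r.dome_id}: height {r.max_height_um:.1f} um, "
          f"eccentricity {r.eccentricity:.2f}, views {r.views_detected}/4")
print(f"average domes per angle view: {avg}")

tau = physio.orbital_shear_stress(physio.ShearParams.from_rpm(25, 55))
print(f"orbital shear stress: {tau:.3f} Pa")
```

prints

```
coverage at 0/6/12/16/20 um: [0.801, 0.801, 0.828, 0.055, 0.032]
dome 1: height 10.0 um, eccentricity 0.12, views 4/4
dome 2: height 8.0 um, eccentricity 0.18, views 4/4
average domes per angle view: 2.0
orbital shear stress: 0.168 Pa
```

Coverage stays at the 80% monolayer level through the first 14 µm and
drops to the dome cross-sections above it; both cap heights are recovered
exactly (quantized to the 2 µm section spacing), the footprints are nearly
circular, neither dome occludes the other from any viewing direction, and
the shear estimate for a 25 mm orbit at 55 rpm in culture medium at 37 °C
rounds to 0.17 Pa (1.7 dynes/cm²).

## Command line

```bash
domescope phantom --out stack.tif --truth truth.json --seed 3
domescope analyze --config run.json --out results/ --seed 3
domescope analyze --self-test --out selftest/          # built-in phantom
domescope compare --group-a a1/coverage.csv --group-a a2/coverage.csv \
                  --group-b b1/coverage.csv --group-b b2/coverage.csv \
                  --out stats.csv
domescope physio shear --params shear.json
```

`analyze` writes `coverage.csv`, `objects.csv`, `domes.csv` and a
`manifest.json` recording the config hash, seed, package version and QC
exclusions; a rerun with the same config and seed is byte-identical.
Sections crossed by slide-grid line artifacts are auto-flagged (Hough
line-concentration test) or can be excluded manually, and propagate as
missing values, never as zero coverage.

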