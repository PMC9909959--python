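# ctoam — CT osteoabsorptiometry of the knee

`ctoam` maps and quantifies the density of the **subchondral bone** of the
knee (distal femur and tibial plateau) from clinical CT, implementing the
CT-osteoabsorptiometry (CTOAM) workflow used in sports-medicine and
orthopaedic imaging to read long-term joint stress distribution out of bone
mineralisation patterns (Wolff's law: bone remodels toward habitual load).

It is aimed at researchers comparing athlete and control cohorts — the kind
of study that asks *where* an athlete's knee carries load (high-density zones
on the articular surface) and *how much* bone has remodelled into each
density class.

## The method

1. **Density scheme.** Hounsfield units ≥ 100 are partitioned into 12 closed
   integer intervals: 100–200, 201–300, …, 1101–1200, 1201–maximum.
   Bins 1–4 form the *low*, 5–8 the *medium*, 9–12 the *high* density class.
2. **Bone tissue of interest (BTOI).** The subchondral bone between the
   articular surface and the epiphyseal line, extracted by HU thresholding,
   26-connected region growing and clipping at the epiphyseal plane.
3. **%BTV.** Per knee and bone, the volume fraction of each density interval:

   %BTV_i = 100 · V_i / Σ_{j=1..12} V_j ,  i = 1…12,

   where V_i is the BTOI volume (mm³) inside interval i.  The 12 percentages
   sum to 100 by construction.
4. **Surface density map.** A maximum-intensity projection of the BTOI along
   the inferior–superior axis gives a pseudo-colour densitogram of the
   articular surface.
5. **Nine anatomical regions.** The map footprint is split into a 3×3
   equal-thirds grid (rows anterior→posterior, columns medial→lateral,
   mirrored between left and right knees); 8-connected high-density areas
   (≥ 901 HU, ≥ 25 mm²) are counted per region across a cohort.
6. **Pattern taxonomy.** Each knee is labelled Blank / Anterior-Lateral /
   Dual Center / Center Connections (femur) or Blank / Scatter /
   Multi-Center / Multi-Center Connections (tibia) by deterministic
   geometric rules.
7. **Statistics.** Per-bin two-group comparison gated by a one-sample
   Kolmogorov–Smirnov normality screen: pooled-variance Student t when both
   samples pass at α = 0.05, two-sided Mann–Whitney U otherwise; results as
   mean ± SD with per-bin P values.

Because athlete CT cohorts cannot be redistributed, the package ships a
**phantom generator** (`ctoam.phantom`): stylized distal-femur / tibial-
plateau volumes at 0.625 mm voxels with a laminar, depth-decaying density
field (control-like) or the same field plus concentric high-density foci at
chosen articular regions (judo-like), additive CT noise, and exact ground
truth (BTOI mask, per-bin voxel counts, epiphyseal plane) for every phantom.

## Worked example

```python
import numpy as np
from ctoam import (PhantomSpec, make_phantom, extract_roi, bin_voxels,
                   btv_profile, class_summary, project_density,
                   nine_regions, detect_high_density, classify)

spec = PhantomSpec(profile="judo_like", seed=7)       # athlete-like right distal femur
vol, truth = make_phantom(spec)
roi = extract_roi(vol, spec.bone, spec.side, plane_z=truth.epiphyseal_plane_z)
profile = btv_profile(bin_voxels(vol, roi), vol.spacing_mm,
                      bone=spec.bone, side=spec.side)
print(f"BTOI volume: {profile.total_btoi_mm3:.1f} mm^3 ({roi.voxel_count} voxels)")
s = class_summary(profile)
print(f"low {s['low']:.2f}%  medium {s['medium']:.2f}%  high {s['high']:.2f}%")
print("pct per bin:", np.round(profile.pct, 2))

dmap = project_density(vol, roi)
grid = nine_regions(dmap)
areas = detect_high_density(dmap, regions=grid)
print("high-density areas:", len(areas.components),
      "| regions touched:", sorted(areas.regions_touched))
print("pattern:", classify(areas, grid, spec.bone).label)
```

prints

```
BTOI volume: 3132.8 mm^3 (12832 voxels)
low 52.01%  medium 42.57%  high 5.42%
pct per bin: [ 0.62 14.25 19.53 17.62 14.09 10.9   9.38  8.2   4.11  1.18  0.12  0.  ]
high-density areas: 1 | regions touched: [2, 4, 5, 6, 8, 9]
pattern: Center Connections
```

i.e. this athlete-like knee keeps about half of its subchondral volume in
the low-density class but has remodelled 43% into medium and 5% into high
density, and one connected high-density area bridges the central row of the
articular surface (regions 4–6, the ligament-insertion / joint-contact
zone) — the *Center Connections* pattern.  A control-like phantom of the
same geometry shows a laminar profile concentrated in bins 1–4, no area
above the 901 HU cutoff, and the *Blank* pattern.

## Command line

```bash
ctoam run --config run.yaml        # simulate -> ROI -> %BTV/maps -> tables
ctoam simulate --out DIR --n-per-group 15 --seed 1
ctoam roi --volume v.nii.gz --bone distal_femur --plane-z 18 --out roi.nii.gz
ctoam btv --volume v.nii.gz --roi roi.nii.gz --out profile.csv
ctoam map --volume v.nii.gz --roi roi.nii.gz --out map.png --csv map.csv
ctoam classify --map map.csv --bone tibial_plateau --out label.json
ctoam frequency --cohort-dir maps/ --bone distal_femur --out table.csv
ctoam compare --group-a judo/ --group-b control/ --bone distal_femur --out cmp.csv
```

A run writes per-knee %BTV profiles, cohort frequency/pattern tables,
per-bin comparison reports, a `manifest.json` with a content hash per file
(reruns with the same config and seed are byte-identical), and `run.log`.
Exit codes: 0 ok, 2 configuration error, 3 stage failure.

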