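# nanosip

**NanoSIMS stable-isotope-probing quantification for pulse-chase tracer
experiments.**

Nanoscale secondary ion mass spectrometry (NanoSIMS) images the fate of
¹³C/¹⁵N-labelled food in tissue at subcellular resolution: a Cs⁺ beam sputters
a section and the instrument counts the secondary ions ¹²C¹²C⁻, ¹³C¹²C⁻,
¹²C¹⁴N⁻, ¹²C¹⁵N⁻ and ³¹P⁻ per pixel, plane by plane. `nanosip` turns those
count stacks into calibrated per-cell isotope enrichment and population-level
statistics. It was built for host–microbiome nutrient-translocation studies in
sponges (choanocytes, mesohyl cells, microbial symbionts), but nothing in the
pipeline is sponge-specific.

The pipeline:

1. **Ion imaging** — per-plane stage-drift estimation by cross-correlation on
   the high-count ¹²C¹⁴N⁻ channel, integer-pixel alignment, plane
   accumulation, per-pixel isotope-ratio maps with Poisson counting errors,
   and hue-saturation-intensity (HSI) renders (hue = ratio from blue at
   natural abundance to red, intensity = ion counts).
2. **Calibration** — a session correction factor from repeated scans of a
   standard of known bulk composition, CF = R<sub>IRMS</sub> /
   mean(R<sub>NanoSIMS</sub>), and conversion of count ratios to heavy-isotope
   atom fractions, F = (R/(R+1))·CF, Atom% = 100·F. Carbon is measured on the
   diatomic C₂⁻ species whose minor/major count ratio is 2f/(1−f); the factor
   of two is absorbed by CF, and the exact algebraic inversion f = r/(2+r) is
   provided as an internal oracle.
3. **ROI quantification** — ratio-of-sums per region of interest, calibrated
   Atom%, and the enrichment call: an ROI is enriched when its Atom% strictly
   exceeds the unlabelled-control mean + 3 SD for its category and isotope.
4. **Statistics** — pulse-phase linear regressions of bulk Δδ on time, slope
   comparison between groups via the time×group interaction F test, rank-sum
   comparisons of single-cell Atom% across time points with
   Benjamini–Hochberg adjustment, and a host→symbiont "translocation
   signature" flag.
5. **Simulation** — a synthetic-scene generator (choanocyte chambers, mesohyl
   cells, ~1 μm microbes, 1–2 μm intracellular hotspots) with a Poisson
   isotopologue measurement model, per-plane drift and instrument
   mass-fractionation bias, plus synthetic bulk pulse-chase tables. Every
   stage of the pipeline is validated against this ground truth.

## Worked example

Simulate a labelled tissue field, recover the stage drift, calibrate, and
classify enrichment against an unlabelled control twin:

```python
from nanosip import (
    AcquisitionSpec, SceneSpec, HotspotSpec, R_AIR_N, R_VPDB_C,
    align_and_accumulate, build_scene, classify_all, control_scene_spec,
    control_stats, estimate_drift, fraction_enriched, measure_rois,
    rois_from_scene, session_cf, simulate_acquisition, summarize_by_category,
)

spec = SceneSpec(
    image_size_px=(128, 128), pixel_size_um=0.2,
    n_choanocyte_chambers=1, choanocytes_per_chamber=8,
    n_mesohyl_cells=3, microbe_density_per_um2=0.03,
    hotspot_spec=HotspotSpec(count_per_cell=1, multiplier=3.0),
    category_atom_fractions={"choanocyte": (0.020, 0.025),
                             "microbe": (0.012, 0.015)},
    seed=7,
)
scene = build_scene(spec)
acq = AcquisitionSpec(n_planes=4,
                      drift_per_plane_px=[(0, 0), (2, -1), (-1, 3), (1, 1)],
                      seed=11)
stack = simulate_acquisition(scene, acq)

shifts = estimate_drift(stack)
print("estimated drift:", shifts)
acc = align_and_accumulate(stack, shifts)

cal_c = session_cf(R_VPDB_C, [2 * R_VPDB_C], isotope="13C")
cal_n = session_cf(R_AIR_N, [R_AIR_N], isotope="15N")
ms = measure_rois(acc, rois_from_scene(scene, timepoint_h=3.0), cal_c, cal_n)

ctrl_scene = build_scene(control_scene_spec(spec))
ctrl_stack = simulate_acquisition(ctrl_scene, AcquisitionSpec(n_planes=4, seed=12))
controls = measure_rois(align_and_accumulate(ctrl_stack, [(0, 0)] * 4),
                        rois_from_scene(ctrl_scene), cal_c, cal_n)
stats = {(cat, iso): control_stats(controls, cat, iso)
         for cat in ("choanocyte", "mesohyl_cell", "microbe")
         for iso in ("13C", "15N")}
classify_all(ms, stats)

print(summarize_by_category(ms).query("isotope == '15N'").to_string(index=False))
print(fraction_enriched(ms).query("isotope == '15N'").to_string(index=False))
```

Output:

```
estimated drift: [(0, 0), (2, -1), (-1, 3), (1, 1)]
    category  timepoint_h isotope  n  mean_atom_pct  median_atom_pct  q25_atom_pct  q75_atom_pct
  choanocyte          3.0     15N  8       3.170708         3.161254      3.061730      3.353446
mesohyl_cell          3.0     15N  3       0.369846         0.370858      0.365473      0.374724
     microbe          3.0     15N 20       1.503860         1.514146      1.466196      1.547029
    category  timepoint_h isotope  n_enriched  n_total  proportion_enriched
  choanocyte          3.0     15N           8        8                  1.0
mesohyl_cell          3.0     15N           0        3                  0.0
     microbe          3.0     15N          20       20                  1.0
```

The applied stage drift is recovered exactly. Choanocytes were configured at
2.5 Atom% ¹⁵N with intracellular hotspots (pulling their mean to 3.17) and
microbes at 1.5; both read back within counting error and all are called
enriched, while unlabelled mesohyl cells sit at the natural-abundance floor
(0.37 Atom%) with none flagged.

## Command line

The same stages are available as a CLI over TIFF-stack + JSON-sidecar,
label-image/ImageJ-archive ROI, and CSV inputs; every command writes a JSON
run manifest for reproducibility:

```sh
nanosip simulate --config scene.yaml --seed 42 --out run/
nanosip align    --stack run/stack.tif --out run/
nanosip quantify --acc run/accumulated.tif --rois run/truth_labels.tif \
                 --mapping run/roi_mapping.csv --calibration cal.csv --out run/
nanosip classify --measurements run/measurements.csv --out run/
nanosip bulk     --table run/bulk.csv --out run/
nanosip compare  --measurements run/measurements.csv --t-a 3 --t-b 48 --out run/
nanosip report   --acc run/accumulated.tif --measurements run/measurements.csv \
                 --out run/report/
```

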