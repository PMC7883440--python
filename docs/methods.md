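# Methods

## Measurement model

NanoSIMS records five negative secondary-ion species per pixel per plane:
¹²C¹²C⁻, ¹³C¹²C⁻, ¹²C¹⁴N⁻, ¹²C¹⁵N⁻ and ³¹P⁻. The simulator treats counts as
independent Poisson draws with means

| species  | expected counts per pixel per plane |
|----------|-------------------------------------|
| ¹²C¹²C⁻  | y_C2 · D_C · (1−f_C)²               |
| ¹³C¹²C⁻  | y_C2 · D_C · 2 f_C (1−f_C) · b_C    |
| ¹²C¹⁴N⁻  | y_CN · D_N · (1−f_N)                |
| ¹²C¹⁵N⁻  | y_CN · D_N · f_N · b_N              |
| ³¹P⁻     | y_P · D_P                           |

where f is the true heavy-isotope atom fraction, D the relative elemental
surface density, y the ion yield per unit density (defaults C2 = 120,
CN = 250, P = 40 counts/pixel/plane — CN⁻ is the dominant channel in organic
tissue), and b a multiplicative instrument mass-fractionation bias on the
minor/major ratio. The diatomic carbon species give a count ratio
2f/(1−f), twice the atomic ratio at trace abundance; ¹³C¹³C⁻ is not recorded
and no mass-interference, dead-time or quasi-simultaneous-arrival effects are
modelled. Per-plane stage drift is an integer-pixel shift of the scene before
sampling; pixels drifting in from outside the field carry natural-abundance
matrix composition.

Natural abundances are fixed by the international standards: R(VPDB) =
0.0111802 for ¹³C/¹²C and R(air N₂) = 0.0036765 for ¹⁵N/¹⁴N, giving atom
fractions f = R/(1+R). Displayed ratio floors of 2×0.011 (C₂) and 0.0037
(CN) are the rounded versions of these values.

## Synthetic scenes

A ground-truth scene is a label image plus per-pixel true f_C, f_N and
relative C/N/P density maps. Geometry emulates encrusting-sponge tissue:

* choanocyte chambers as rings of 3.5 μm cells (cells touch but do not
  overlap; ring radius set by the cell count),
* 4.5 μm mesohyl cells and optional 5.5 μm spherulous cells scattered
  without overlap,
* 1 μm microbes placed in the remaining matrix at a surface density with
  high-microbial-abundance (0.25/μm²) and low-abundance (0.02/μm²) presets,
* 1–2 μm intracellular hotspots inside choanocytes whose pixels multiply the
  cell's excess atom fraction over natural abundance by a configurable
  factor (capped at f = 1).

Placement uses rejection sampling with a distance-transform fallback that
enumerates all feasible centres, so crowded fields fail only when no room
exists, with an informative error. The default field is 512×512 px at
0.05 μm/pixel (≈25 μm across); tests and the acceptance script use coarser
0.2 μm pixels on 96–128 px fields to keep run times in seconds. All
randomness flows from explicit integer seeds; identical spec + seed gives
bit-identical output.

What the simulator does **not** reproduce: sputtering physics and matrix
effects, charge compensation, topography, section-thickness variation,
irregular cell shapes, and spatially correlated biological heterogeneity
within a category. Passing recovery tests therefore demonstrates the
correctness of the processing chain under Poisson counting statistics — not
robustness to every instrumental artefact of real acquisitions.

## Processing chain

**Drift.** Plane k's shift against plane 0 maximises circular FFT
cross-correlation on the reference species (¹²C¹⁴N⁻, the highest-count
organic channel, also the channel cell outlines are drawn on). Ties within
float precision resolve toward smaller |dx|+|dy|, then lexicographically.
Only integer-pixel shifts are estimated and applied: interpolation would
destroy the integer Poisson nature of the counts. Alignment translates each
plane by the negative of its shift and sums; a validity mask marks pixels
covered by every plane. With expected reference counts ≥ 100/pixel, recovery
of applied drifts is exact in practice (verified over 50 seeded trials).

**Ratio maps.** Per pixel, ratio = N_num/N_den with counting standard error
ratio·√(1/N_num + 1/N_den); a zero numerator uses the one-count bound
1/N_den. Pixels with accumulated denominator counts below 20 (default) are
masked — the value caps the relative counting error at ~22% and is a display
threshold, not a quantification filter. HSI renders map ratio linearly from
hue 240° (blue) at the scale floor to 0° (red) at the ceiling, with
intensity proportional to denominator counts (zero counts → black).

**Calibration.** One correction factor per isotope per user-declared
session: CF = R_IRMS(standard) / mean(R_NanoSIMS(standard)) over that
session's standard scans (coefficient of variation above 10% raises a
warning). Atom fractions follow the printed convention
F = (R/(R+1))·CF with CF applied *after* the ratio→fraction transform. For
the CN⁻ species on an unbiased instrument this recovers f_N exactly. For the
C₂⁻ species, CF absorbs the isotopologue factor of two and the conversion is
a small-enrichment approximation: with b = 1, F = f/(1+f), a relative
deviation below f itself for f ≤ 0.05. Under a shared instrument bias b the
exact recoveries are F_N = f/(1−f+fb) and F_C = f/(1−f+2fb) — second-order
deviations in R that the test suite pins down explicitly (carbon at b = 2
deviates by 3f/(1+3f)). Correcting the ratio *before* the transform would
remove these residuals entirely; the printed order is kept deliberately for
fidelity to the established workflow, and the exact C₂ inversion
f = (r/b)/(2 + r/b) is shipped as an independent oracle.

**ROI quantification.** Per ROI the estimator is the ratio of summed counts
over all ROI pixels, not the mean of per-pixel ratios: ratio-of-sums is the
minimum-variance estimator for Poisson counts, is robust when individual
pixels have few counts, and is exactly invariant to splitting an ROI and
pooling. An ROI with zero denominator counts is flagged invalid and
propagated, never dropped silently. Enrichment calls use pooled
unlabelled-control statistics per category × isotope: enriched ⇔ Atom% >
control mean + 3·SD (sample SD, n−1; strict inequality — the one-sided
outlier reading of a "3×SD" rule, with a nominal Gaussian false-positive
rate of ~0.135%). Spherulous cells and bare matrix are measured and reported
but excluded from headline category summaries. Summary quartiles use linear
interpolation (box-plot hinge convention).

## Bulk tracer statistics

δ values are per-mil deviations from VPDB (C) and air-N₂ (N); Δδ is the
excess over the pooled unlabelled-control mean. Atom fractions from δ follow
r = R_std(1+δ/1000), F = r/(1+r). The tracer incorporation rate is
(F_sample − F_control)·1000/Δt, i.e. μmol tracer element per mmol tissue
element per hour. Pulse-phase kinetics are fit by OLS of Δδ (or tracer
amount) on time within the pulse window, default [0, 3] h; the chase decline
is summarised descriptively, not modelled. Two groups' incorporation rates
are compared with the time×group interaction F test (df₁ = 1) in a combined
linear model — the standard ANOVA realisation of a slope contrast. The
synthetic bulk generator uses the study design as defaults: time points
0.25, 0.5, 1, 3, 24, 48 h, three individuals per time point with matched
controls, linear pulse enrichment, geometric chase decay, and Gaussian ‰
noise.

## Single-cell time-series inference

Atom% distributions per category are compared between time points with the
two-sided Wilcoxon rank-sum test: single-cell enrichment is right-skewed
(hotspots) and variances differ across time, so a rank test is safer than a
t test and invariant under monotone rescaling. Direction is the sign of the
median difference. All comparisons in a run are Benjamini–Hochberg adjusted
jointly across category × isotope × time-point pair. The translocation
signature for an isotope is flagged when the microbe category increases
significantly from pulse end to chase end while no host category (choanocyte,
mesohyl cell) also increases significantly — a concurrent host increase makes
the symbiont gain attributable to continued direct uptake and therefore
ambiguous.

## Numerical conventions and edge cases

* Coordinates are 0-based (row, col) = (y, x); shifts are (dx, dy) with x
  along columns. Label images are the mask authority; ImageJ ROI archives
  are rasterised on load (rectangle, oval, polygon, freehand, traced).
* Drift estimation on an all-zero reference plane raises naming the plane;
  shifts larger than the image are rejected.
* Degenerate regressions (< 3 points, zero time variance) and control sets
  with < 2 valid ROIs raise rather than return unstable numbers.
* Seeds are plain integers; simulators use independent `numpy` Generators so
  that scene geometry, acquisition noise and bulk noise can be varied
  independently.

## Validation problem sizes

The acceptance script and test suite validate on: 96–128 px fields
(~19–26 μm at 0.2 μm/pixel) with 30–110 ROIs per field; 4–8 planes per
acquisition; 50 seeded acquisitions for drift recovery; 10,000 single-pixel
ROIs at ~30,000 accumulated CN counts each for the enrichment rule's
operating characteristics; and 1000 simulated bulk series for regression
coverage and test size. These sizes give binomial/Monte-Carlo standard
errors comfortably inside the asserted bands while the whole validation runs
in seconds.

## Known limitations

* No dead-time/QSA correction, subpixel registration, or plane rejection —
  upstream instrument concerns outside this pipeline's scope.
* The printed atom-fraction convention leaves second-order calibration
  residuals under instrument bias (quantified above and in the tests).
* No reader for proprietary raw instrument files; stacks arrive as TIFF +
  sidecar after vendor-tool export.
* Enrichment thresholds use pooled controls per category; per-sample control
  matching is not implemented.
* The translocation signature is a directional screen, not a flux model; it
  cannot distinguish transfer routes or rates.
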