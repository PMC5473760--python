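# Methods

## The measurement

`wormscatter` quantifies relative fat content in *C. elegans* from
dark-field micrographs. Under dark-field illumination only light scattered
by the specimen reaches the objective, and lipid-rich structures
(intestine, eggs, lipid droplets) scatter strongly. The core statistic is
the **scattering density** of a worm:

    density = (sum of pixel intensities inside the worm contour) / (contour area in pixels)

in arbitrary units (a.u.) per pixel. It is a relative measure: values are
comparable only between images corrected onto a common calibration
reference (below). The same statistic applied to inverted 510 nm
bright-field images of Oil Red O (ORO)–stained worms gives an absorption
("staining") density used to validate the scattering proxy; inversion maps
heavily stained (dark) regions to high values, so both statistics increase
with lipid content.

### Pipeline order

Operations are ordered **invert → correct → measure** and the order is
enforced through modality and `corrected` metadata flags. Inversion
(`p → 2^bit_depth − 1 − p`) is defined on the native integer scale and does
not commute with multiplicative scaling, so inverting an already-corrected
frame is rejected with an explanatory error.

## Illumination regulation and correction

A stable scattering phantom (modeled on BaSO₄ in PDMS, with a surface
scratch as a landmark) is imaged once per session. The mean intensity in an
annulus around the mark — default radii 5–25 px, excluding the scratch
itself, both configurable — serves two roles:

1. **Regulation check**: the session mean should lie within 10% (inclusive)
   of a fixed target. The check is advisory, not blocking, because residual
   drift is removed in software anyway.
2. **Correction**: every experimental frame is multiplied by
   `reference_mean / session_mean`, putting all sessions on the scale of one
   common reference phantom. No clipping is applied; corrected values may
   exceed the native full scale.

Because both the correction and the density are ratios, a session-wide
multiplicative lighting change cancels exactly: scaling a scene and its
phantom by any k > 0 leaves corrected densities unchanged to floating-point
precision. This invariance is tested end to end, including through the CLI.
A single scalar per session is used — no per-pixel flat-fielding — because
the drift being corrected is a global lamp/exposure change.

## Segmentation and worm length

Worm bodies are found by a per-condition grayscale threshold (strictly
greater-than; pixels equal to the threshold are background). The threshold
is user-supplied because worm brightness varies between strains; an Otsu
suggestion is available but never applied silently. Components are taken
under 8-connectivity, hole-filled (worm interiors contain dim pixels and
the density must integrate the whole body), filtered by minimum area, and
labeled deterministically (area rank, ties by first row-major pixel).
Raising the threshold can only shrink the segmented area (monotonicity),
which the suite verifies as a property.

High-magnification frames use manually drawn polygon outlines with
optional exclusion polygons (head, cuticle). A pixel belongs to the mask
iff its center lies inside or on the outline; self-intersecting outlines
are rejected, making the even-odd and nonzero-winding fill rules
equivalent.

**Worm length** (for larval staging) is the longest geodesic path through
the morphological skeleton of the body mask, times the pixel size. Two
numerical choices matter:

* the mask indicator is Gaussian-smoothed (σ = 1.5 px, re-thresholded at
  0.5) before skeletonization — ragged boundaries of noisy threshold masks
  otherwise sprout skeleton spurs and zigzags that inflate the measured
  length by up to ~13% at low SNR;
* the selected path (found by Dijkstra with 1/√2 step weights) is measured
  on a moving-average-smoothed polyline (window 9 px, endpoints kept),
  because summing raw 8-connected chain steps overestimates smooth curves
  by up to ~8% (staircase effect).

With both, lengths on synthetic bodies are accurate to ~2% and stage
transitions are recovered to a fraction of an hour. Skeleton end erosion
still loses a few pixels at each body tip. Even-width straight shapes have
a half-pixel centerline ambiguity in skeletonization that produces a ~1%
orientation dependence; odd widths do not.

## Colocalization (dark field vs Nile Red)

In young L1 larvae the bright scatterers are lysosome-related organelles
(gut granules), which Nile Red stains in vivo; in older worms scattering is
dominated by lipid droplets that Nile Red does not mark. To quantify the
overlap each channel is:

1. high-pass filtered (unsharp mask: image minus Gaussian blur, default
   σ = 2 px) with **mask-aware renormalization** — the blur weights are
   renormalized over in-mask pixels so the dark background outside the worm
   does not bleed across the boundary;
2. reduced to its brightest in-worm pixels: those strictly above the 80th
   percentile (linear interpolation) of in-mask filtered values — with
   continuous data this selects 20% of the worm;
3. compared by the Sørensen–Dice coefficient QS = 2|A∩B| / (|A|+|B|).

QS(∅, ∅) is defined as 1 (vacuous agreement) and QS(∅, nonempty) as 0;
unstained controls can produce near-empty selections. Selection is
rank-based, so QS is invariant to monotone intensity transforms of either
channel. Two independent selections at fraction f overlap at QS ≈ f in
expectation, so **0.2 is the no-colocalization baseline** at the default
percentile; the generator's independent-placement mode reproduces it to
within ~0.01. QS magnitudes depend on the filter and percentile, so values
are comparable only at matched parameters.

## Statistics

* Cohort summaries: mean, SEM (sample SD/√n), symmetric 95% t-interval.
* Group comparisons: one-way ANOVA, then pairwise Welch (unpooled) t-tests
  of each condition against the reference, Bonferroni-multiplied by the
  number of comparisons (capped at 1). Reference-only comparisons are the
  default; an all-pairs mode exists. With two groups the ANOVA F equals the
  pooled t², and the family-wise type-I rate on null simulations stays at
  or below the nominal 5%.
* Validation fit: unweighted OLS of cohort-mean staining density on
  cohort-mean scattering density, with r² and a slope-zero t-test. The fit
  is on cohort means because scattering and staining are measured on
  **disjoint worm sets** from each cohort (staining requires fixation), so
  no per-worm pairing exists. Per-cohort SEMs are reported alongside the
  points but do not weight the fit; errors-in-variables modeling is out of
  scope.
* Paired fasting changes: delta = after − before per worm; only delta < 0
  counts as a decrease. Fat-loss vs activity association uses Pearson
  correlation with a degenerate-variance flag.

## Time-course assembly

Different synchronized cohorts are culled and imaged at each timepoint (no
per-worm tracking). Early timepoints are imaged at high magnification
(40×), later ones at 20×, with one timepoint imaged through both. The 20×
series is rescaled onto the 40× series by the ratio of the shared-timepoint
cohort means (direction configurable), the merged trajectory is normalized
to the mean density at a baseline timepoint, and stage transitions are
annotated where the 3-point-median-smoothed mean-length curve first crosses
each length cutoff (linear interpolation). Cutoffs are user-supplied; the
bundled defaults (L1–L2 370 µm, L2–L3 520 µm) are placeholders chosen to
match the synthetic growth profile and are **not** authoritative staging
values.

## Synthetic data: what it emulates and what it does not

Every pipeline stage is validated on generated scenes with exact ground
truth. A scene is a sinusoidal capsule body (uniform base intensity)
on a dark background with optional: rim-bright circular droplets (rim =
1.6 × interior by default, emulating the bright droplet edges seen at high
magnification), small bright puncta (gut granules), multiplicative radial
vignetting, and Poisson–Gaussian camera noise (additive read noise plus
signal-proportional variance — the minimal model that makes SNR a
controllable parameter). Defaults give body/background ≈ 7.5, a clean
dark-field frame. Phantom frames are flat fields with a dark scratch placed
inside the annulus' inner radius.

Key couplings:

* **Latent fat** is defined at the density level: for time courses the
  profile specifies the target mean in-body scattering density (a.u./px),
  and the generator solves for the droplet count whose expected added
  intensity meets that budget. Programmed fold-changes are therefore
  directly comparable to measured density fold-changes. Droplet-count
  rounding quantizes the realized level by a few percent at low fat.
* The two simulated objectives differ in pixel size (1.6 vs 3.2 µm/px) and
  light-collection gain (1.0 vs 0.45), so stitching is exercised against a
  genuine scale mismatch.
* Validation studies draw scattering and staining worms independently
  (split-cohort design): per condition a latent level μ is drawn, each
  worm measures gain·μ·(1+ε), ε ~ N(0, CV). Defaults (23 conditions × 15
  worms, 3× latent range, CV 0.10) give r² ≈ 0.98.
* Colocalization scenes place 60 puncta (radius 2 px) so that punctate
  structure dominates the top-quintile selection, as in L1 worms where
  granules dominate scattering; the "independent" mode places the two
  channels' puncta without any coupling.
* Fasting cohorts apply a per-worm uniform 10–40% density loss with 2%
  measurement noise; a zero-loss variant provides the symmetric null.

All randomness flows from explicit integer seeds; the same seed gives a
bit-identical scene, and there is no hidden global RNG state.

**What passing these tests does and does not show.** The generator
reproduces the geometric and photometric structure of the assay (bodies,
droplets, puncta, illumination drift, camera noise), so the tests establish
that the *computational* pipeline is correct and calibrated: densities are
exact, corrections cancel lighting, QS has the right null, trajectories and
transitions are recovered from known truth. The generator does not simulate
real optics (no Mie scattering, defocus, or depth effects), anatomy
(pharynx, eggs, cuticle texture), staining variability, or touching/moving
worms — so the tests say nothing about segmentation thresholds, filter
scales, or QS magnitudes on any particular real dataset; those remain
per-study choices.

## Problem sizes used in the benchmark script

`scripts/acceptance.py` uses 100 replicate validation studies, 50
segmentation scenes, 100 + 100 colocalization scene pairs, one 60-scene
time-course plus one 48-scene step study, 55-worm fasting cohorts, and 1000
null ANOVA simulations — sizes at which every reported quantity's
simulation error is well below the effect being checked.

## Known limitations

* Densities are only comparable within a common phantom reference;
  cross-project comparison is unsupported by design.
* No absolute triglyceride calibration — relative measurements only.
* No touching-worm separation, learned segmentation, or channel
  registration; frames are assumed pre-aligned.
* The Bonferroni multiplier counts reference comparisons only (default),
  which is anti-conservative if an all-pairs reading was intended; the
  all-pairs flag covers that case.
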