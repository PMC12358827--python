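# Methods

## The assay being modeled

A nanowell chip (6,400 wells, modeled as an 80 × 80 square lattice at
100 µm pitch spanning an 8 × 8 mm field) is seeded with viable,
EpCAM-enriched, FACS-sorted cells — at most one cell per well in the
intended regime. The chip is scanned in three fluorescence channels:
calcein (viability), PSMA-PE (prostate tumor marker) and CD45-APC
(leukocyte marker). A PSA-capture membrane is clamped under the chip for a
24 h secretion window; anti-IgG printed through the well pores leaves an
imprint of the lattice on the membrane (PE channel), and captured PSA is
immunostained (FITC channel). Quantification chains five steps, each a
library module:

1. **Well readout** (`chip.py`) — per-well mean intensity over a disc
   aperture, minus a robust background; threshold gating into
   empty / leukocyte / PSMA± CTC candidate.
2. **Registration** (`registration.py`) — detect imprint spots, fit the
   chip→membrane similarity transform, map membrane coordinates to well
   numbers.
3. **Spot quantification** (`spots.py`) — particle-analysis segmentation
   of PSA spots (area window, roundness 0.64–1.0 with
   roundness = 4·area/(π·major_axis²)), fold-over-background
   normalization, linear standard curve from spotted dilutions, and
   pg/cell = density (pg/µm²) × spot area (µm²).
4. **Cell assembly** (`cohort.py`) — join chip phenotype with secretion
   into the four groups PSMA±PSA±; per-patient secreting fraction,
   mean/median pg/cell; serum-PSA correlation across patients.
5. **Enumeration** (`enumeration.py`) — independent of the chip: gating of
   instrument event tables (CK ≥ 50, PSMA ≥ 200, DAPI+, CD45−) and the
   CK-vs-PSMA concordance statistics (log–log OLS, Spearman).

## Synthetic assay generator

No public imaging data accompany this assay, so `synth.py` generates the
full input set with exact ground truth: chip scans, the membrane pair, the
calibration-standard table and enumeration event tables. What it emulates,
and the defaults chosen where the assay description leaves them open:

- **Lattice and optics.** 80 × 80 wells at 100 µm pitch; rasters at
  2 µm/px (desk-sized 4,000-px fields rather than the sub-µm pixels of a
  20×/0.45 NA scan). Both configurable; nothing downstream assumes these
  values.
- **Phenotype mix.** Defaults reflect the reported cohort structure:
  ~23% PSMA+ and ~8% PSMA− secretors among CTCs, ~69% of CTCs
  non-secreting, plus 10% leukocyte carryover. Exact class counts by
  largest-remainder apportionment so small chips hit the mix exactly.
- **Secretion.** Uniform 2–15 pg/cell per secretor over the 24 h window
  (the reported per-patient averages span 4–11.68 pg/cell). Spot radius
  (12–16 µm) is drawn independently of the amount, so surface density and
  area vary separately — the two factors the quantification multiplies.
- **Intensities.** Discs of constant per-cell intensity plus additive
  Gaussian noise; cell-to-cell brightness varies with a 10% CV. Membrane
  spots encode density through the linear calibration
  NI = intercept + slope·(pg/area), rendered as
  pixel = membrane_background · NI so that fold-over-background recovery
  is exact. The default intercept is 1 (a zero-density spot is
  indistinguishable from bare membrane) and the slope (200 NI per pg/µm²)
  keeps the brightest standards inside the 16-bit range.
- **Chip→membrane transform.** A similarity transform with rotation and
  scale acting about the lattice center (a clamped chip pivots about its
  middle); supported range |rotation| ≤ 10°, |translation| ≤ one pitch.
  Rendering validates that the transformed lattice stays inside the field
  (3-pitch margins) and refuses configurations that clip spots at the
  border.
- **Event tables.** Lognormal marker intensities per population, with
  DAPI/CD45 as categorical flags the way enumeration instruments report
  them.

What it does **not** emulate: optical PSF and diffraction, debris
morphology, well-to-well diffusion or bleed of secreted protein,
multi-cell wells, non-rigid membrane warp, illumination gradients
(only *global* illumination scaling is modeled), and secretion kinetics
(single 24 h endpoint). Passing tests therefore demonstrate correctness of
the measurement chain under its stated geometric and noise model, not
robustness to every artifact of real membranes.

## Numerical and design choices

- **Well aperture.** The measurement disc radius (16 µm default) matches
  the rendered cell footprint; image background is the median over pixels
  outside every aperture. Apertures must satisfy radius < pitch/2.
- **Normalization by division.** "Normalized to the average of the
  background wells" is implemented as spot mean ÷ background mean
  (n = 50 leukocyte/no-cell wells, lowest well ids for reproducibility;
  fewer available ⇒ use all, with a warning). Division makes the quantity
  unit-free: scaling every membrane intensity (spots, background wells and
  standards) by k cancels identically, which the suite checks to 1e-9.
  A subtraction mode is deliberately not offered; it would break this
  invariance.
- **Calibration.** Density of a standard = concentration × volume / area
  (µg/mL × µL × 1000 / µm² → pg/µm²); OLS of normalized intensity on
  density. Standards are spotted in triplicate: with only five single
  dilutions the ±3·SE band is a t₃ interval (~94% coverage) rather than
  the intended near-certain one. When standards carry raw membrane counts
  the pipeline divides them by the same background mean as the patient
  spots.
- **Segmentation thresholds.** `segment_psa_spots` defaults to Otsu,
  which is exact on clean two-level images; the assembled pipeline instead
  uses a robust background threshold (median + 5 × 1.4826·MAD), because a
  membrane whose spots span an order of magnitude in brightness is not
  bimodal and Otsu can sit above the faint spots. Both are overridable by
  an absolute value, as in interactive particle analysis.
- **Registration.** Similarity transform only (contact printing preserves
  angles); full affine behind a flag. The fit is seeded in closed form
  from the lattice structure of the detected spots themselves —
  nearest-neighbor vectors give rotation (mod 90°, unambiguous inside the
  printing tolerance) and scale, the difference of point-cloud means gives
  translation with no correspondences — then refined by iterated
  nearest-neighbor matching with outlier rejection at 0.4 × pitch (up to
  20 rounds, stopping when the inlier set stabilizes). A plain
  expanding-inlier loop without the closed-form seed was tried first and
  can stall in a degenerate matching at ~3–5° rotations on large
  lattices. Failure conditions: < 3 inliers, inlier support below half
  the lattice (the imprint prints through every pore, so genuine
  registrations are supported almost fully), or RMS residual >
  0.25 × pitch.
- **Well assignment.** Nearest well center within 0.5 × pitch after
  inverse transform; exact distance ties (unreachable with continuous
  noise) break to the lowest well id.
- **Spot bookkeeping.** Spots mapping to the same well are merged (areas
  summed, intensities area-weighted) — fragmentation is a segmentation
  artifact, not two cells. Unmatched spots are retained for inspection but
  excluded from secretion records. Negative densities clamp to zero with a
  flag; a well is PSA+ iff its clamped pg/cell exceeds a configurable
  threshold (default 0).
- **Gating.** All cutoffs are inclusive (≥). Samples with a zero CK+ or
  PSMA+ count are dropped from the log–log fit with a warning (their log
  is undefined; no pseudocount is applied).
- **Cohort statistics.** Patients without secretors are excluded from the
  serum correlation (their mean pg/cell does not exist). Cohort mean/median
  secretion is computed pooled across cells by default, with a
  per-patient-first mode available, since the two weightings answer
  different questions and either could be meant by a cohort average.

## Problem sizes in the test suite

The accuracy suite runs the full 80 × 80 chip at 2 µm/px with 250 cells
(200 secretors) for the end-to-end check, 100 random transforms on a
30 × 30 lattice for registration, 100 calibration replicates, and 10⁵
events for gating — sizes chosen so the complete suite runs in well under
a minute per criterion on one core while keeping estimator noise far below
the asserted tolerances.

## Known limitations

- Accuracy claims are conditional on the generator's noise model
  (additive Gaussian, flat background); real membranes show structured
  background the robust threshold only partly addresses.
- Registration assumes most of the imprint lattice is detectable; a
  half-torn or cropped membrane will (correctly) fail loudly rather than
  return a guess.
- The phenotype caller has no debris class beyond "empty"; dim
  autofluorescent debris would need a morphology gate the chip scan model
  does not exercise.
- Enumeration works on event feature tables; it does not re-segment
  instrument image stacks.
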