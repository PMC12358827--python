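# nanospot

Single-cell PSA secretion quantification for nanowell-array CTC assays.

Circulating tumor cells (CTCs) from prostate cancer patients can be seeded
one-per-well into a 6,400-well nanowell chip over a PSA-capture membrane.
After a 24 h incubation, each secreting cell leaves a fluorescent spot on
the membrane; an anti-IgG imprint printed through the well pores ties every
spot back to its well number, and a standard curve of spotted PSA dilutions
converts spot intensity into picograms secreted per cell. `nanospot`
implements the complete measurement chain for this kind of assay —
phenotype gating on the chip scan (calcein/PSMA/CD45), imprint
registration, ELISpot-style spot segmentation, calibration, and
per-patient subpopulation statistics — together with a ground-truth
synthetic assay generator used to validate every step, since no imaging
data are publicly available for this assay class.

The core quantities, in the field's notation:

- spot **normalized intensity** NI = mean spot intensity / mean membrane
  background at leukocyte and no-cell wells (n = 50);
- **surface density** ρ = (NI − b)/m in pg/µm², from the linear standard
  curve NI = m·ρ + b fitted on spotted dilutions
  (ρ_standard = concentration × drop volume / spot area);
- **secretion per cell** = ρ × spot area (µm²), clamped at 0;
- per patient: counts of PSMA⁺PSA⁺ / PSMA⁻PSA⁺ / PSMA⁺PSA⁻ / PSMA⁻PSA⁻
  CTCs, percent secreting, mean/median pg/cell over secretors;
- cohort statistics: log₁₀ regression and Spearman ρ between CK- and
  PSMA-defined CTC counts, Spearman ρ between serum PSA and mean CTC
  secretion.

## Worked example

Simulate a default chip (200 cells, 80 × 80 wells at 2 µm/px) and run the
full pipeline against its ground truth:

```bash
python analysis/01_simulate_assay.py --seed 0
python analysis/03_quantify_secretion.py --seed 0
```

which prints

```
registration: rotation 1.000 deg, scale 1.0000, rms 0.11 px (6400 wells)
calibration: slope 200.2, intercept 1.001, R^2 = 1.000
secretors: 56 true, 56 quantified; median |rel err| 0.8%, max 3.0%
groups: PSMA+PSA+ 42, PSMA-PSA+ 14, PSMA+PSA- 62, PSMA-PSA- 62; 31% of CTCs secreting
secretion over secretors: mean 8.54 pg/cell, median 7.74 pg/cell
```

Reading this: the chip→membrane imprint registration recovered the
generating misalignment (1° rotation) with 0.11 px residual over all 6,400
lattice points; the standard curve matches the generating calibration
(slope 200 NI per pg/µm²); all 56 secreting cells were found and
quantified with sub-percent median error; and the four-group breakdown
reproduces the generator's phenotype mix (31% of CTC candidates
secreting). Per-spot and per-cell tables land in `results/`.

`analysis/02_enumerate_ctc.py` runs the event-table gating and
CK-vs-PSMA concordance statistics over a synthetic 18-patient cohort, and
`analysis/04_cohort_summary.py` builds per-patient summaries and the
serum-PSA correlation over a simulated multi-patient cohort.

Library use mirrors the scripts:

```python
import nanospot as ns
cfg = ns.AssayConfig(seed=0)
truth, layout = ns.make_ground_truth(cfg)
chip = ns.render_chip_images(truth, layout, cfg)
imprint, psa, _ = ns.render_membrane_images(truth, layout, cfg)
standards = ns.make_calibration_standards(cfg, n_replicates=3)
result = ns.run_pipeline(chip, imprint, psa, layout, standards,
                         cfg.um_per_px, patient_id="demo")
result.secretion          # per-well pg/cell records
ns.summarize_patient(result.cells)
```

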