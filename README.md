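# renomark

Long-term kidney toxicity is the dose-limiting concern of peptide receptor
radionuclide therapy (PRRT) with ^177^Lu-octreotate: the kidneys retain a
substantial fraction of the injected activity, and damage appears months
after administration. `renomark` packages the analysis chain used to find
transcriptional biomarkers of that damage in the mouse kidney as a reusable,
tested pipeline:

- **MIRD kidney dosimetry** — mean absorbed dose from a time-activity curve,
  `D = Ã · Δ · φ / M`, with Ã the time-integrated activity (MBq·h),
  Δ = Σᵢ EᵢYᵢ the mean electron energy per decay (147 keV for ^177^Lu,
  electrons only), φ = 0.93 the absorbed fraction and M the kidney mass
  (self-dose only, source = target). A saturable one-site uptake model
  u(A) = u₀·k_sat/(k_sat + A) reproduces the declining Gy/MBq of the study
  design when calibrated to printed dose anchors.
- **Differential expression** — quantile normalization, variance filter,
  Welch t per dose×time group against age-matched controls,
  Benjamini–Hochberg FDR, and the dual rule *q < 0.01 and
  |log₂ ratio| > 0.58* (fold change > 1.5).
- **Biomarker analysis** — recurrence of significant calls across the 15
  dose×time groups per tissue, overlap with a packaged catalogue of
  published kidney-injury / radiation markers, Spearman dose–response
  scoring, and a transparent hypergeometric regulator-target enrichment.
- **Renal scintigraphy** — ROI segmentation at 10% of the local maximal
  pixel count, syringe calibration (equal-attenuation assumption),
  ^99m^Tc-DTPA renograms in percent of injected activity with the bladder
  content read at 27.5 min, static ^99m^Tc-DMSA uptake normalized to
  controls, and paired Student t comparisons (p < 0.05).
- **Blood markers** — test/control percentages, reduction factors and fold
  increases for WBC, RBC, urea and creatinine.
- **Synthetic data** — generators for every input: the 5-activity ×
  3-timepoint × 2-tissue × n=3 expression design with planted null,
  monotone-dose, late-responder and marker-like genes under Gaussian log₂
  noise; biexponential biodistribution curves; Poisson-noise 256×256 planar
  gamma-camera frames with two kidneys, a bladder and a calibration syringe;
  and blood panels with table-driven effect sizes.

## Worked example

```python
import numpy as np
from renomark import (DoseParameters, UptakeModel, calibrate_uptake_model,
                      dose_table, MarkerCatalogue, recurrence_from_catalogue,
                      marker_overlap, recurrence_count, dose_response_score)

# dosimetry: calibrate the uptake model to three dose anchors, predict all five
params = DoseParameters(mass_g=0.3)
model = calibrate_uptake_model({30.0: 16.0, 60.0: 29.0, 90.0: 40.0}, params)
table = dose_table([30, 60, 90, 120, 150], model, params)
print({a: round(d.dose_Gy, 1) for a, d in table.items()})
# {30.0: 16.0, 60.0: 29.0, 90.0: 40.0, 120.0: 49.2, 150.0: 57.2}

# biomarkers from the packaged marker panel
cat = MarkerCatalogue.load()
m = recurrence_from_catalogue(cat, "cortex")
print(marker_overlap(m, cat)[1], recurrence_count(m, "Cdkn1a"))
# 34 12

# dose-response of Cdkn1a at 12 months in cortex
print(dose_response_score([1.3, 1.0, 1.6, 1.4, 2.0]).rho)
# 0.7999999999999999
```

The dose table says the calibrated model recovers the three anchor doses
exactly and extrapolates 120 and 150 MBq to within a few percent of 48 and
54 Gy — receptor saturation makes dose grow sublinearly in injected
activity. The marker panel contains 34 distinct catalogued genes in cortex,
and Cdkn1a is significantly regulated in 12 of the 15 cortex dose×time
groups; its 12-month log₂ ratios rank-correlate with absorbed dose at
ρ = 0.8.

A command-line entry point mirrors the library:

```sh
renomark all --seed 1 --out out/          # full pipeline + report
renomark dose --tac curve.csv --mass-g 0.3
renomark dose-table --activities 30,60,90,120,150
renomark scinti renogram --frames dtpa.tif --meta dtpa.json
```

## Layout

- `src/renomark/synthetic.py` — study designs and all data generators
- `src/renomark/dosimetry.py` — MIRD self-dose chain and model calibration
- `src/renomark/diffexpr.py` — normalization, Welch t, BH, significance calls
- `src/renomark/biomarker.py` — recurrence, catalogue overlap, dose response,
  regulator enrichment (packaged fixtures under `src/renomark/data/`)
- `src/renomark/scintigraphy.py` — ROI, calibration, renograms, DMSA, paired t
- `src/renomark/blood.py` — blood-marker ratio derivation
- `src/renomark/pipeline.py`, `src/renomark/cli.py` — orchestration and CLI
- `docs/methods.md` — models, parameters, numerical conventions, limitations
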