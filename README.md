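# osteoquant

Multi-modal bone-quality analysis for a two-genotype (diabetic vs control)
mouse study, with synthetic forward models for every measurement modality so
the entire chain is testable without instrument data.

The pipeline covers:

- **geometry** — cortical/trabecular μCT morphometry from voxel grids:
  segmentation, compartment labeling (bone / marrow / pore), cross-sectional
  areas, principal second moments of area (I_min, I_max), extreme-fiber
  distance c, cortical porosity, maximal-inscribed-sphere thickness, BV/TV,
  Tb.Th/Tb.Sp/Tb.N, connectivity density, tissue mineral density.
- **flexural** — three-point-bending property extraction: preload zeroing,
  sliding-window stiffness, 10 % secant-stiffness yield, force-drop failure,
  post-yield displacement, work to fracture, beam-theory tissue modulus
  E = K·L³/(48·I_min), and strain-specific body-mass adjustment.
- **indentation** — Oliver–Pharr nanoindentation: load/hold/unload
  segmentation, power-law unloading fit, contact stiffness and depth,
  reduced/sample modulus and hardness, fused-silica tip-area calibration.
- **raman** — compositional spectroscopy: accumulation averaging,
  truncation, rolling-circle baseline correction, band areas, FWHM
  crystallinity, mineral:matrix, carbonate:phosphate, collagen maturity,
  and the exploratory PEN ratio with an SNR flag.
- **stats** — exact (enumeration) Wilcoxon–Mann–Whitney tests, percent
  differences, REML linear mixed models with nested random effects and
  containment-df intervals, Tukey HSD, Levene, ANCOVA slope tests, backward
  stepwise selection by AICc, lifetime-average glucose, and the diabetic
  glucose inclusion filter.
- **synthetic** — deterministic forward models (elliptical-annulus voxel
  grids with spherical pores, piecewise bending curves, three-segment
  indentation curves, band-sum spectra with polynomial baselines, and a
  nested two-genotype cohort) that return closed-form ground truth alongside
  every dataset.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes closed-form oracles, generator round trips, enumeration
oracles for the rank tests, simulation-based coverage checks, and
`tests/test_acceptance.py`, which implements the acceptance criteria.

## CLI

```bash
# simulate a full synthetic study and run every stage
osteoquant all --outdir runs/demo --seed 1

# or stage by stage
osteoquant simulate --outdir runs/demo --seed 1
osteoquant geometry --outdir runs/demo
osteoquant bending  --outdir runs/demo
osteoquant indent   --outdir runs/demo
osteoquant raman    --outdir runs/demo
osteoquant stats    --outdir runs/demo
osteoquant report   --outdir runs/demo
```

Configuration is a schema-validated YAML file (`--config study.yaml`);
unknown keys are rejected. Every run writes `config_used.yaml` and the
report carries the config hash, seed and package version in its provenance
block. Raw files travel as TIFF/CSV/two-column text with `.truth.json`
sidecars carrying generator ground truth.

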