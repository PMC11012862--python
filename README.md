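# gslsrm

A toolkit for wide-targeted selected reaction monitoring (SRM) of acidic
glycosphingolipids (GSLs), plus the downstream semi-quantitative analysis:

- **`gslsrm.chem`** — elemental-composition arithmetic and monoisotopic
  mass / m/z computation for GSLs assembled from glycan residue blocks
  (Hex, HexNAc, NeuAc, dHex) and a ceramide (sphingoid base + fatty acyl).
- **`gslsrm.transitions`** — combinatorial enumeration of the glycan x
  fatty-acyl species grid and emission of the SRM transition list
  (Q1 = [M−zH]^z− precursor, Q3 = the m/z 290 sialic-acid fragment, charge
  from the NeuAc count, CE keyed by NeuAc count). The packaged default
  method (10 acidic glycans x 24 acyl chains on d18:1) yields 240
  transitions; everything is overridable via YAML config.
- **`gslsrm.quant`** — chromatographic peak integration (trapezoid above an
  edge-minimum linear baseline, 3xMAD detection floor), area-ratio tables,
  matrix factor, recovery, and calibration linearity.
- **`gslsrm.biomarker`** — urinary biomarker evaluation: creatinine
  correction, Mann–Whitney group comparison, ROC/AUC (pair counting, with
  stratified-bootstrap CI) and Youden cutoff.
- **`gslsrm.simulate`** — seed-deterministic synthetic fixtures: Gaussian
  SRM peaks on noisy baselines and two-group lognormal cohorts with a known
  fold change and closed-form theoretical AUC.
- **`gslsrm.io_mzml`** — minimal mzML chromatogram reader/writer
  (long-format CSV is supported everywhere as well).

## CLI

```sh
# build / check the transition list (default method: 10 x 24 = 240)
gslsrm transitions build --out transitions.csv
gslsrm transitions validate --config my_method.yaml

# simulate fixtures
gslsrm simulate chromatograms --spec peaks.yaml --out run.mzML
gslsrm simulate cohort --n 50 --fold-change 5 --seed 1 --out cohort.csv

# integrate and compare
gslsrm quant integrate --chromatograms run.mzML --transitions transitions.csv --out areas.csv
gslsrm quant ratios --num achn.csv --den hk2.csv --out ratios.csv
gslsrm quant mf --std 1000 --matrix 500 --spiked 1560
gslsrm quant linearity --points calibration.csv

# cohort evaluation (creatinine-corrected ROC report)
gslsrm biomarker roc --cohort cohort.csv --seed 1 --out report.json --plot roc.png
```

## Notes

- The default glycan catalog stores residue counts only (Glc/Gal and
  GlcNAc/GalNAc are mass-degenerate); isomeric glycans (e.g. GD1a/DSLc4)
  are kept as distinct analytes sharing an `isomer_group` label.
- The default 24-chain acyl list and the CE/DP/CXP values are documented
  reconstructions/placeholders in `src/gslsrm/data/default_method.yaml`;
  override them with `--config` for real acquisitions.
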