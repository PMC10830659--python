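# fickco

Indirect-Fick cardiac output estimation and method-comparison analysis
against a thermodilution-style reference, plus a ground-truth synthetic
cohort generator.

The package computes, per patient: body surface area (Dubois), estimated
oxygen consumption under four approximation formulas (Krakau, LaFarge,
Dehmer, Bergstra), arteriovenous oxygen content difference, indirect-Fick
cardiac output / cardiac index, and pulmonary vascular resistance. It then
compares each Fick CO series with the reference CO using Bland–Altman
limits of agreement, the Critchley percentage error (< 30% acceptable),
Pearson correlation with a Fisher-z CI, a three-way ratio classification
(< 0.8 / 0.8–1.2 / > 1.2), and Cohen's kappa between classifications.

## CLI

Generate a synthetic cohort (writes `cohort.csv`, `truth.csv`,
`config.yaml`):

```bash
fickco generate --out outdir --n 200 --seed 1 --noise-sd 0.15
fickco generate --config synth.yaml --out outdir   # full parameter control
```

Analyze a cohort CSV (writes `derived.csv`, `method_summary.csv`,
`deviation_table.csv`, per-pair `bland_altman_*.csv` coordinates,
`summary.json`, `run.log`):

```bash
fickco analyze --input outdir/cohort.csv --out results \
    [--saturation-mode percent] [--pe-multiplier 1.96] \
    [--formulas krakau,dehmer]
```

Exit codes: 0 success, 1 data error (schema/physiology violations, empty
cohort), 2 configuration error.

Cohort CSV schema (one row per patient, empty cell = missing, sex coded
m/f): `patient_id, age, sex, height_cm, weight_kg, heart_rate,
hemoglobin_g_dl, sao2, svo2, td_co_l_min, mpap_mmhg, mpawp_mmhg`.
Patients missing optional fields stay in every comparison their fields
support (e.g. no heart rate drops only the LaFarge comparisons).

## Python API

```python
from fickco import SynthConfig, generate, derive_cohort, compare_all, Formula

cohort = generate(SynthConfig(n=500, seed=7, noise_sd=0.15))
derived = derive_cohort(cohort.records)
report = compare_all(derived)
report.vs_reference[Formula.KRAKAU].percentage_error
```

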