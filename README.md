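# theradose

Preclinical radiopharmaceutical dosimetry and theranostic-efficacy analytics
for ⁶⁴Cu-labelled antibodies in mouse models.

A therapy study with a β-emitting radioimmunoconjugate produces four strands
of quantitative data: ex vivo biodistribution (organ uptake over time),
binding/QC assays of the labelled antibody, absorbed-dose estimates per
organ, and tumour-growth / survival outcomes. `theradose` implements the
full analysis chain for these strands as an importable library, with seeded
synthetic cohort generators standing in for animal data, and a thin CLI for
running the pipeline end to end.

## What it computes

- **Isotope physics** — bundled ⁶⁴Cu decay data (T½ = 12.7004 h, branch
  fractions, branch-averaged emission energies); decay factors and decay
  correction.
- **Biodistribution** — counter cpm → activity → decay/tail-corrected
  %ID/g; group means ± SD; tumour-to-organ ratios; Welch t-tests.
- **Kinetics** — mono-/bi-exponential and plateau-uptake time–activity
  fits with AICc model selection; closed-form cumulated activity
  (time-integrated activity to infinity under physical decay), with an
  optional conservative no-extrapolation mode.
- **MIRD dosimetry** — D = Ã × S with local-deposition sphere self-dose
  S-values; a straight-path CSDA Monte-Carlo absorbed-fraction oracle;
  blood local-deposition dose; publication-style rounded dose tables.
- **Assays** — immunoreactive fraction (bead assay), radiochemical purity,
  one-site saturation Kd fit, cellular uptake and blocking metrics.
- **Efficacy & survival** — calliper volumes (L×W×h×3.14/6), log-linear
  doubling times, humane-endpoint sacrifice rules, Kaplan–Meier and
  log-rank statistics (via `lifelines`).
- **Synthetic data** — deterministic seeded generators for every data
  strand, with whole-body %ID conservation enforced per mouse.

## Worked example

Fit the plateau-uptake model to three tumour %ID/g group means, integrate
under physical decay, and convert to absorbed dose for a 0.306 g tumour:

```python
from theradose import (cu64, cumulated_activity, fit_tac, organ_dose,
                       sphere_self_svalue)

nuclide = cu64()
tac = fit_tac(([5/60, 2.0, 48.0], [9.2, 45.6, 62.5]), "plateau_uptake")
a_tilde = cumulated_activity(tac, nuclide)
sv = sphere_self_svalue(0.306, nuclide, "local_np")
print(f"{organ_dose(a_tilde, sv):.2f} Gy/MBq")
```

Output:

```
0.77 Gy/MBq
```

The `examples/` directory contains five narrative scripts covering the dose
table, synthetic biodistribution, the assay chain, efficacy/survival, and
the full pipeline. Each runs in seconds and prints interpreted numbers.

## Command line

```sh
theradose all --seed 0 --out run_out        # every stage
theradose dosimetry --seed 0 --out run_out  # just the dose table
```

Outputs: `biodistribution_records.csv`, `biodistribution_summary.csv`,
`tac_fits.json`, `dose_table.tsv`/`.json`, `efficacy_report.json`, and a
`manifest.json` with full provenance. Runs are byte-reproducible for a
fixed seed and configuration.

## Scope and assumptions

Dosimetry is **self-dose only** (no cross-organ photon term) with the
local-deposition electron model; the Monte-Carlo sphere transport is a QA
oracle for that model, not a voxel-phantom calculation. Survival event
times are log-logistic with a configurable cure fraction. All modelling
choices, parameter provenance, and numerical conventions are documented in
[`docs/methods.md`](docs/methods.md).
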