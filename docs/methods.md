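# Methods and design notes

This document records the models, parameter choices, numerical conventions
and deliberate simplifications in `theradose`. Everything here is a package
design decision; where a convention is unusual (e.g. the volume constant
3.14), it is the study-field convention the package reproduces.

## 1. Nuclide physics

The bundled ⁶⁴Cu record (`theradose/data/cu64.json`) carries:

| field | value | note |
|---|---|---|
| half-life | 12.7004 h | ICRP-107 evaluation |
| β⁺ branch | 0.174 | positron, mean energy 0.2782 MeV |
| β⁻ branch | 0.390 | mean energy 0.1902 MeV |
| EC branch | 0.440 | electron capture |
| Δnp | 0.126585 MeV/decay | branch-weighted electron energy incl. Auger/conversion |
| photon energy | 0.18418 MeV/decay | annihilation (0.174 × 1.022) + 1.3458 MeV γ (0.475%) |

The branch fractions are stored as evaluated (sum 1.004) and validated to a
[0.99, 1.01] band rather than renormalised: renormalising would silently
alter the emission energies per decay. Decay arithmetic is exact base-2:
`decay_factor(t) = 2^(−t/T½)`; negative times are rejected.

`mean_energy_per_decay(mode)` returns Δnp (`"nonpenetrating"`) or
Δnp + photon (`"all"`).

## 2. Biodistribution

Measured counts convert as

```
activity[MBq]    = cpm / (efficiency × 6e7 cpm/MBq)
%ID/g            = 100 × decay_correct(activity, t_sacrifice)
                   / (injected − tail_remainder) / organ_mass
```

The injected activity is corrected for the residue left in the tail vein
(`corrected_injected_activity`); decay correction refers everything back to
injection time so %ID/g is a purely biological quantity. Group summaries use
the sample SD (n−1); a single animal gives NaN SD rather than 0. The Welch
t-test (unequal variances, Welch–Satterthwaite df) is the default
two-group comparison; a pooled-variance variant sits behind a flag. Both
delegate to `scipy.stats`.

## 3. Kinetics

Time–activity curves are fitted on decay-corrected %ID/g, and physical decay
is re-applied analytically inside the integral. This ordering keeps the
biological model identifiable (uptake/clearance rates are not confounded
with the known physical decay) and makes the dosimetry integral exact.

Models (t in hours):

- `mono`: A₁·e^(−λ₁t)
- `bi`: A₁·e^(−λ₁t) + A₂·e^(−λ₂t), components sorted so λ₁ is the slow one
- `plateau_uptake`: P·(1 − e^(−λᵤt)) — rising-to-plateau tumour uptake

λ = 0 is allowed and encodes permanent biological retention (the physical
decay term keeps every integral finite). Fitting is multi-start
`scipy.optimize.least_squares` with bounded parameters; model selection uses
AICc, returning infinity when n ≤ k + 1 so under-determined models can never
win, with ties broken toward fewer parameters.

Cumulated activity per injected MBq (concentration form, MBq·s/g):

```
Ã = (3600/100) × Σᵢ Aᵢ / (λᵢ + λ_phys)          (mono/bi)
Ã = (3600/100) × P × (1/λ_phys − 1/(λ_phys+λᵤ))  (plateau)
```

An optional conservative mode (`extrapolation="physical_after_t_last"`)
freezes biology at the last measured time and lets only physical decay act
afterwards; for a rising organ this is a strict lower bound on the
model-extrapolated integral.

## 4. Dosimetry

The MIRD scheme `D = Ã × S` with two sphere self-dose S-value methods:

- **local_np** (default): all non-penetrating energy absorbed where it is
  emitted, `S = Δnp/m`, converted as
  `S[Gy/(MBq·s)] = Δnp[MeV] × 1.602e-13[J/MeV] × 1e6 / (m[g] × 1e-3)`.
  For a 1 g sphere and the β-only Δnp of 0.1226 MeV this is 1.964e-5.
- **monte_carlo**: QA oracle. Uniform emission points in the sphere,
  isotropic directions, straight-path transport with constant dE/dx = E/R
  using a bundled ESTAR-style CSDA water range table (log-log
  interpolated). `S = φ·Δnp/m` with sampled absorbed fraction φ ≤ 1.

For this transport model the escaped energy fraction of a sphere with
radius a ≫ range R is analytically 3R/(8a). The MC estimate therefore
approaches the local model only in the a → ∞ limit; tests compare φ against
`1 − 3R/(8a)` within Monte-Carlo error rather than against exactly 1.

Blood uses the local-deposition convention with **all** emitted energy
(electrons + photons) by default, configurable to electrons only.

**Self-dose only**: cross-organ photon dose is omitted. For ⁶⁴Cu in a mouse
the photon component is a small fraction of the electron dose; omitting it
biases organ doses slightly low, uniformly. The dose-table JSON and manifest
carry a `self_dose_only: true` flag.

Tables round half away from zero to 1 decimal (`decimal.Decimal`,
publication convention). The per-administration column is the *unrounded*
per-MBq dose times administered MBq, then rounded, so the two printed
columns stay mutually consistent under division. Unrounded values are kept
alongside in every row.

## 5. Assays

- Immunoreactive fraction: 100 × beads/(beads + supernatant).
- Radiochemical purity: percent of lane signal in the bound species,
  pass at ≥ 98%.
- Saturation binding: `B(c) = Bmax·c/(Kd + c)` fitted with
  `scipy.optimize.curve_fit` (bounded, p0 = (max signal, median
  concentration)); specific binding only — no nonspecific linear term.
- Concentration conversions assume a 150 kDa IgG.

## 6. Efficacy and survival

- Calliper volume `V = L × W × h × 3.14/6` — the constant is 3.14 exactly,
  not π (field convention; a 0.05% difference that matters for value-level
  reproduction).
- Doubling time: ln 2 / slope of the log-linear fit of ln V on day, over a
  half-open day window [start, stop); non-positive volumes are excluded and
  slopes at round-off scale (≤ 1e-12/day) yield NaN ("no growth").
- Maximum volume reduction: relative to the measurement on a reference day
  (the second-injection day in the pipeline), floored at 0%.
- Sacrifice rules, checked in day order with within-day priority
  paralysis → ≥20% weight loss → volume ≥ 2000 mm³; survivors censored at
  the 100-day horizon.
- Kaplan–Meier and log-rank delegate to `lifelines`; the KM median is the
  smallest event time with S(t) ≤ 0.5 and is NaN when the curve never
  reaches 0.5. The log-rank p-value uses the asymptotic χ²(1) reference,
  which is anti-conservative in small groups: under an exponential null
  with n = 10 + 10 the empirical type-I error at α = 0.05 is ≈ 0.065
  (verified against independent implementations). Calibration tests
  therefore pin 0.05 ± 0.01 at n = 50 + 50 and a wider documented band at
  n = 10 + 10.

## 7. Synthetic generators

All generators are pure functions of (config, seed). Substreams come from
`np.random.SeedSequence([seed, tag])` with fixed per-generator tags, so
regenerating one data strand never perturbs another.

- **Biodistribution**: per-mouse %ID/g drawn truncated-normal (no negative
  uptake) from a per-(group, organ, timepoint) mean ± SD table; if the
  whole-body budget Σ(%ID/g × organ mass) exceeds 100%, the mouse's values
  are rescaled proportionally; cpm are then back-computed through decay,
  efficiency, and the tail-residue model, so the analysis chain is
  exercised end to end. Group sizes are 4, 4, 4, 4, 5 across the five
  timepoints (5 min, 2 h, 24 h, 48 h, 72 h). Cells without a printed
  anchor in the default table are interpolations and carry
  `interpolated: true`.
- **Tumour growth**: lognormal per-mouse doubling time; exponential growth
  from the first-dose day, then (for regressing groups) exponential
  shrinkage by `regression_fraction` over `regression_duration_days`
  followed by regrowth; multiplicative lognormal measurement noise
  (CV 10%). Calliper dimensions are back-solved as equal cube roots so the
  volume formula round-trips exactly. Measurements every 3.5 days
  (twice weekly).
- **Survival**: log-logistic event times (scale = group median,
  shape = 10), plus a cure fraction censored at 100 days. Shape 10 gives
  the tight event clustering seen in control cohorts (IQR a few days
  around the median); the median is preserved exactly by the scale
  parameter. A `gen_survival_from_growth` mode derives events from growth
  curves via the sacrifice rules instead.
- **Assays**: binomial count partitioning for the bead assay; lognormal
  multiplicative noise for saturation binding.

Default parameters (group medians, doubling times, uptake tables, n's) live
in `theradose/config.py` as pydantic models and round-trip through JSON.
V₀ values are calibrated so group-mean volumes at day 18 match the target
means; the `treated` regression fraction 0.707 reproduces the observed mean
maximal regression.

Limits: generators reproduce first and second moments and qualitative
trajectory shapes, not animal-level correlation structure (e.g. no shared
frailty between a mouse's organs beyond the conservation rescale, no
longitudinal autocorrelation in calliper noise).

## 8. Pipeline and reproducibility

`run_pipeline(RunConfig)` chains simulate → biodist summary → TAC fits →
dose table → efficacy report → manifest; each stage writes its own files
and failures re-raise tagged with the stage name. Outputs contain no
timestamps, so a fixed (config, seed) reproduces every file byte for byte.
The CLI is a thin wrapper exposing the same stages.

`scripts/acceptance.py` recomputes the headline numbers from the public API
only, deriving per-target sub-seeds (< 2³¹) from one root seed.
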