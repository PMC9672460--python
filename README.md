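# pbpktrial

Whole-body physiologically based pharmacokinetic (PBPK) simulation,
non-compartmental analysis (NCA), power-model dose-proportionality
assessment and Monte-Carlo virtual-trial generation for intravenous
first-in-human studies, exercised end-to-end on synthetic trial data.

The modeled compound is salvianolic acid A (SAA), an ECCS class 3B acid
dosed by IV infusion, whose hepatic disposition is carried by saturable
OATP1B1 uptake (blood → hepatocyte) chained to saturable P-gp efflux
(hepatocyte → bile, irreversible). Saturation of these transporters above
the Michaelis constant produces the supra-proportional exposure increase
that the dose-proportionality stage detects.

## What is in the box

| Module | Purpose |
| --- | --- |
| `pbpktrial.params` | Validated parameter types (compound, tissues, transporters, regimens) and the packaged 70-kg default parameter set |
| `pbpktrial.pbpk` | Stiff-ODE simulator: 14 permeability-limited tissues (vascular + extravascular sub-compartments), lung in series, venous/arterial pools, zero-order infusion input, Michaelis–Menten hepatic uptake/efflux, transporter-parameter fitting, µM→ng/ml conversion |
| `pbpktrial.partition` | Tissue:plasma partition coefficients from tissue composition (monoprotic-acid form) or from measured tissue/plasma exposure ratios |
| `pbpktrial.nca` | NCA: linear and linear-up/log-down AUC, best-adjusted-R² terminal slope, single-dose and steady-state (AUCτ, Cavg, fluctuation, accumulation index) panels |
| `pbpktrial.doseprop` | Power model ln(Y) = α + β·ln(dose), t-based slope CI, acceptance range (1 + ln θL/ln R, 1 + ln θH/ln R), verdict + deviation direction |
| `pbpktrial.population` | Virtual populations: lognormal (median-preserving) parameter variability, per-subject seed substreams, concentration percentile bands |
| `pbpktrial.synth` | Synthetic trial generator: 9 single-dose cohorts (10–300 mg) + 3 q12h multiple-dose cohorts with the study sampling schedules, LLOQ censoring tiers, residual error; calibration of generator settings to packaged cohort summaries |
| `pbpktrial.io`, `pbpktrial.pipeline`, `pbpktrial.cli` | Tidy CSV interchange, atomic writes, run manifests, the synth → nca → doseprop pipeline and the umbrella CLI |

Units everywhere: hours, litres, L/h, mg doses, ng/ml concentrations.
Doses are interpreted as free-form-equivalent milligrams.

## CLI

```bash
# deterministic simulation of a 80 mg / 60 min infusion
pbpktrial simulate --dose 80 --infusion-min 60 --t-end 13 --out sim.csv

# partition coefficients (composition method, or ratios from --in records)
pbpktrial kp --method rlr --out kp.csv

# generate a full synthetic trial, then analyze it
pbpktrial synth --design default --seed 7 --out conc.csv
pbpktrial nca --in conc.csv --out nca.csv
pbpktrial doseprop --in exposures.csv --theta-low 0.8 --theta-high 1.25 --ci 0.90 --out dp.csv

# Monte-Carlo virtual population (200 subjects, day-6 q12h regimen)
pbpktrial popsim --dose 120 --tau-h 12 --n-doses 11 --n 200 --seed 42 --out pop

# the whole pipeline in one go (writes a manifest next to the outputs)
pbpktrial run --seed 1 --out-dir pipeline_out
```

## Notes on provenance

* The packaged default PBPK parameter set (`data/default_params.json`)
  uses standard reference-human volumes and perfusion fractions; partition
  coefficients, permeability products and transporter kinetics are
  **repository calibrations** against the packaged single-dose exposure
  summaries, not vendor or literature values.
* `data/tissue_composition.csv` carries surrogate tissue-composition
  constants assembled from published mammalian compilations (see file
  header).
* Published population-simulation percentile bands depend on proprietary,
  unreported parameters; the test suite covers that functionality with
  property-based checks (mass balance, closed-form equivalence, linear
  limits, superposition, parameter recovery) instead of value matching.
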