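# capnovent

An in-silico reimplementation of the computational core of a crossover animal
study comparing **variable ventilation (VV)** with conventional
**pressure-controlled ventilation (PCV)** during and after capnoperitoneum:

- **`capnovent.ventilation`** — PCV/VV breath-plan generation (truncated-Gaussian
  breath-to-breath variability with exact 30-breath window-mean rescaling),
  PIP calibration by bisection, and exact-exponential delivery of square-wave
  pressure breaths on a linear single-compartment lung.
- **`capnovent.oscillometry`** — pseudorandom multifrequency forcing signal
  (23 pairwise non-integer-multiple components, 0.5–20.75 Hz, 8-s windows),
  spectral input-impedance estimation (Zrs = Pao/V′), tube-impedance
  subtraction, ensemble averaging, and multi-start constant-phase model
  fitting (Raw, Iaw, G, H; η = G/H; α = (2/π)·atan(H/G)).
- **`capnovent.gas_exchange`** — alveolar gas equation, oxygen contents, the
  oxygen-content (Berggren-type) shunt fraction, and the Pao2/FiO2 index.
- **`capnovent.cohort`** — synthetic 11-subject, 2-mode × 3-stage crossover
  cohort generator with subject random intercepts; shunt fractions are derived
  through the gas-exchange equations from generated blood-gas panels, and raw
  oscillometry recordings can be synthesized per record for end-to-end
  parameter-recovery studies.
- **`capnovent.stats`** — two-way fully-within-subject ANOVA with Mauchly's
  test and Greenhouse–Geisser/Huynh–Feldt corrections, Holm–Šidák step-down
  adjustment, per-subject relative stage changes with t-based 95% CIs, and
  Pearson correlation.
- **`capnovent.study` / CLI** — the full deterministic pipeline:
  simulate → fit oscillometry per record → gas exchange → statistics.

## CLI

```bash
capnovent plan --mode vv --n 300 --seed 1 --out plan.csv
capnovent simulate --n 11 --seed 1 --out cohort.csv
capnovent gases panels.csv --out panels_computed.csv
capnovent fit-impedance spectra.csv --weights uniform --out fit.json
capnovent analyze cohort.csv --out results.json --report report.md
capnovent run-study --seed 1 --out study_out/
```

`run-study` writes `cohort.csv`, `fits.json`, `results.json` and `report.md`
into the output directory; outputs are byte-identical for identical
configurations and seeds.

## Library example

```python
import capnovent as cv

spec = cv.ForcingSpec()
mech = cv.MechanicalState(raw=25, iaw=0.1, g=300, h=1500)
z = cv.cpm_impedance(mech, spec.frequency_array())
fit = cv.fit_constant_phase(z)
print(fit.state.eta, fit.state.alpha)

results = cv.run_study(cv.StudyConfig(seed=1, outdir="study_out"))
print(results.analysis["anova"]["paco2"]["stage"]["p_gg"])
```
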