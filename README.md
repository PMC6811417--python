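# bdqsim

Population-pharmacokinetic simulation of bedaquiline dosing regimens.

Bedaquiline's label for multidrug-resistant tuberculosis (MDR-TB) uses a
loading phase of 400 mg once daily (QD) for two weeks followed by 200 mg
thrice weekly (TIW) for 22 weeks — an awkward schedule next to the QD
companion drugs it is given with. `bdqsim` is for pharmacometricians and
trial designers who want to ask, by simulation from a published population
PK model: *which uniform QD regimen gives exposures comparable to the
labeled regimen?*

The package provides:

* **a population PK model** — dual-path first-order oral absorption feeding a
  4-compartment mammillary disposition system with first-order elimination,
  ``dy/dt = A y`` with doses depositing ``F·D`` split between the two
  absorption depots. Covariate effects are multiplicative on the typical
  values (CL ×1.375 for healthy/DS-TB vs MDR-TB, CL ×1.52 for black vs
  nonblack race, V_c ×0.843 for female vs male, F ×1.51 for healthy/DS-TB);
  between-subject variability is log-normal on CL, V_c and F
  (``P_i = P_typ · e^{η}``, ``η ~ N(0, ω²)``) and logit-normal on the
  fast-pathway dose fraction;
* **an exact simulator** — the linear system is diagonalised once per subject
  and propagated analytically between dose events, vectorised over whole
  virtual populations; AUCs are exact segment integrals, and a matrix-
  exponential/adaptive-ODE back-end pair cross-validates every result;
* **regimen construction and exposure metrics** — the four 24-week regimens
  compared in the source study (labeled; 100 mg QD; 200 mg QD; 200 mg QD ×
  56 days then 100 mg QD), with C_max, cumulative AUC (to 24 h post final
  dose) and end-of-treatment daily AUC (final week / 7), summarised as
  medians with 5th/95th percentiles and percent-of-reference ratios on
  common random numbers;
* **a visual predictive check (VPC)** — an NC-005-like three-arm virtual
  trial (n = 59/59/60, 83 % black), synthetic observed troughs and 24-h
  profiles, 500-replicate simulation of the design, and percentile bands
  with 90 % confidence intervals.

Model parameter values are read from a plain-text file
(`src/bdqsim/data/bedaquiline_popkk.txt`). The shipped file is a documented
reconstruction calibrated to well-established bedaquiline kinetics (CL/F
≈ 2.6 L/h in MDR-TB, t_max ≈ 4–6 h, terminal half-life ≈ 5.5 months); swap
in your own file to run a different parameterisation.

## Worked example

```bash
python examples/01_single_subject_profile.py
```

```
regimen: labeled  (80 doses, 18800 mg over 168 days)
Cmax            =    3.008 ug/mL  at day 13.2
cumulative AUC  =   3929.7 ug.h/mL (to 24 h post final dose)
daily AUC (EOT) =    21.71 ug.h/mL (final week / 7)
```

The typical black male DS-TB patient under the labeled regimen peaks at
3.0 µg/mL inside the 14th dosing day (after the last 400 mg loading dose —
no later TIW dose exceeds it), accumulates ~3,930 µg·h/mL by 24 h after the
final dose, and averages ~22 µg·h/mL of exposure per day over the final
treatment week. `examples/02_regimen_comparison.py` repeats this across a
sampled population and all four regimens: the switch regimen (200 mg QD ×
56 d, then 100 mg QD) lands at ~119 % of the labeled regimen's cumulative
AUC and ~118 % of its end-of-treatment daily AUC — within the 20 % band
usually taken as comparable — while its peak stays ~35 % lower.
`examples/03_visual_predictive_check.py` runs the VPC on model-generated
data (92.6 % of percentile points inside their 90 % CI with 200 replicates).

A thin CLI wraps the same functions:

```bash
bdqsim simulate-regimens --seed 1 --n-subjects 2000 --out results/
bdqsim vpc --seed 1 --n-rep 500 --out results/
bdqsim make-population --seed 1 --out results/
```

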