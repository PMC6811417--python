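# Methods

## Structural model

Bedaquiline kinetics are represented as a linear, time-invariant compartment
system: two parallel first-order oral absorption depots feeding a central
compartment, three peripheral compartments exchanging with the central one
(a mammillary topology), and first-order elimination from the central
compartment. Each oral dose deposits `amount × F` of drug, split between
the depots by the fast-pathway fraction `FR`; each depot empties into the
central compartment at its own rate constant after its own lag time. With
compartment order (depot 1, depot 2, central, peripheral 1–3) the rate
matrix has off-diagonal transfer rates `ka1, ka2, Q_i/V_c, Q_i/V_pi` and
every column sums to zero except the central column, which loses `CL/V_c`
to elimination. All clearances and volumes are apparent (scaled by the
reference bioavailability); `F` is a relative bioavailability with
reference value 1.

Absorption delay is modelled as a per-pathway lag time rather than a
transit-compartment chain. Lags preserve the piecewise-linear-system
structure exactly (a lagged dose is just a shifted deposit event), carry no
extra state, and with two parallel pathways already reproduce the flat-then-
rise shape that transit chains are usually introduced for. The slow pathway
gets a small lag (1.5 h), the fast pathway none.

## Covariate model and variability

Covariate effects multiply the typical values and therefore commute:

| effect | parameter | multiplier |
|---|---|---|
| healthy or DS-TB vs MDR-TB | CL | 1.375 |
| black vs nonblack race | CL | 1.52 |
| female vs male | V_c | 0.843 |
| healthy or DS-TB vs MDR-TB | F | 1.51 |

The patient-type effects on CL and F are applied jointly, never one
without the other: they largely offset in CL/F, and using either alone
would misstate exposure.

Between-subject variability is log-normal on CL, V_c and F
(`P_i = P_typ · exp(η)`, `η ~ N(0, ω²)`) and logit-normal on `FR`, which
keeps the realised fraction inside [0, 1] for any variance. Residual
unexplained variability, used only when synthesising "observed" data for
the VPC, is proportional with 30 % CV (plus an optional additive term),
truncated at zero. Exposure metrics are always computed on the noise-free
model prediction.

## Parameter values

Parameters ship in a flat key-value text file
(`src/bdqsim/data/bedaquiline_popkk.txt`) so the math core stays
data-driven and auditable. The shipped values are a reconstruction, not a
verbatim transcription of the source model's estimates: magnitudes were
fixed once against well-established bedaquiline pharmacokinetic
characteristics — apparent clearance ≈ 2.6 L/h in MDR-TB patients, t_max
≈ 4–6 h, terminal half-life ≈ 5.5 months (the deep third peripheral
compartment), and ≈ 2.4× peak accumulation across the 14-day 400 mg QD
loading phase — and are labelled as such in the file header. Variances
(ω²_CL = 0.15, ω²_Vc = ω²_F = 0.10, logit-scale ω²_FR = 0.5) give a
90 %-interval spread of individual AUCs of ≈ 5×, typical of this drug's
reported between-subject variability. Consequences of this reconstruction
for quantitative agreement with published exposure tables are discussed
under Limitations.

## Simulation engine

Because the system is linear and time-invariant, the solution between dose
events is an exact matrix exponential. The production path diagonalises
each subject's rate matrix once (`A = VΛV⁻¹`, batched over whole
populations) and evaluates concentrations as `Σ_k c_k e^{λ_k s}` at
arbitrary times, AUCs as the exact elementwise integral
`Σ_k c_k (e^{λ_k s} − 1)/λ_k` (with the `λ → 0` limit handled explicitly),
and C_max by scanning every inter-dose segment at 0.25 h resolution (the
peak of the multi-exponential profile is stable to well under 0.5 % at this
spacing; the resolution is configurable). Dose events superpose additively;
common event times across a population let one pass serve thousands of
subjects.

Two independent back-ends guard the eigendecomposition path:
`scipy.linalg.expm` step propagation and adaptive LSODA integration at
rtol ≤ 1e-10; the test suite holds all three to mutual agreement (1e-6
relative or better) and to the closed-form one-compartment solution in the
structural-reduction limit. If a contrived parameter set makes the system
defective (e.g. an absorption rate exactly equal to a disposition
eigenvalue, where the eigenbasis degenerates), the engine detects the
ill-conditioned eigenvector matrix and falls back to `expm` stepping with
an augmented quadrature row, so AUCs remain exact there too. Mass balance —
remaining drug plus `CL·AUC` equals the bioavailable amount deposited — is
verified to 1e-8 relative.

## Regimens and exposure metrics

All compared regimens span 24 weeks. TIW is realised as dosing on days 1,
3, 5 of each week (48/48/72 h gaps, the Mon/Wed/Fri clinic convention; the
weekly pattern is configurable), with the first TIW dose 24 h after the
last loading dose. QD means exactly every 24.0 h; no adherence or
dose-time jitter is modelled.

Per subject: `cmax` is the maximum over the whole horizon (equivalently the
highest-exposure day: day 14 for the labeled regimen, the final day for
constant QD, the end of week 8 for the switch regimen — asserted in tests);
`cumulative_auc` integrates from first dose to 24 h after the final dose;
`eot_daily_auc` is the final week's AUC divided by 7. Population summaries
are medians with 5th/95th percentiles using NumPy's default linear
(type-7) interpolated quantiles. Percent-of-reference columns are ratios
of medians (not medians of ratios), computed on the *same* sampled
individuals across regimens: common random numbers make the ratio columns
free of between-regimen Monte-Carlo noise and make the
200-vs-100 mg QD dose-proportionality identity exact. Comparison cohorts
default to 2,000 male DS-TB subjects per race (black, nonblack); female
subjects are not simulated in comparisons since the small central-volume
sex effect cancels in between-regimen ratios.

## Virtual population and synthetic observed data

The qualification population mirrors the NC-005 design: three arms
(labeled regimen in DS-TB; 200 mg QD × 56 days in DS-TB and in MDR-TB;
n = 59/59/60) with per-arm black fractions 78/81/88 % (83 % overall). The
male fraction, not reported in the source table, is set to 0.65 — typical
of TB trial populations. Body weight, age and albumin are generated as
log-normal descriptors around the reported medians for dataset realism
only; they are not covariates of this model. The sampling schedule is a
documented stand-in, not a reconstruction of the trial's records: troughs
at days 7, 14, 28, 42, 56 and a day-70 follow-up; 24-h profiles after
dosing on days 14 and 56 in the first 15 subjects of each arm. Synthetic
observations are model predictions with residual error; regenerating with
the same seed reproduces the dataset byte-identically.

## Visual predictive check

The observed design is re-simulated (default 500 replicates) with fresh
between-subject effects per subject and residual error, keeping
covariates, dosing and nominal times fixed. Records are binned by arm,
record type and nominal time. Troughs are summarised at the 5th/50th/95th
percentiles; the n = 15 profile substudy at the 10th/50th/90th (an 80 %
prediction interval, appropriate at that sample size). Each observed
percentile is flagged inside/below/above the 90 % confidence interval of
the same percentile across replicates. Calibration is verified in both
directions: model-generated data land inside the bands ~90 % of the time,
while data generated with clearance inflated 3× push trough medians
systematically below the bands.

One naive expectation deserves correction: the across-replicate percentile
CI does **not** narrow toward zero as replicates grow — it converges to the
finite-population sampling spread of the percentile (few replicates
typically *under*-estimate it). The tested property is therefore
convergence of the width estimate to a large-replicate reference, not
monotone shrinkage.

## Numerical and design choices

* Quantiles: type-7 (linear interpolation) throughout; documented and fixed.
* Peak search: 0.25 h segment scan; trough trajectories on a 24 h grid.
* Deposits with equal effective times are merged; a deposit at an
  observation time does not create ambiguity because doses enter depots and
  the central concentration is continuous at dose times.
* Trapezoidal AUC on the 0.25 h grid agrees with the exact integral to
  <0.1 %; the exact integral is used for population runs.
* Seeds: every stochastic entry point takes a seed or NumPy `Generator`;
  CLI runs log the seed and the SHA-256 of the parameter file into output
  headers.
* Problem sizes: comparison runs use 2,000 subjects per race (a full
  4-regimen × 2-race comparison takes ~15 s); the VPC default is 500
  replicates of the 178-subject design, with smaller sizes used in unit
  tests.

## Limitations

* The parameter file is a calibrated reconstruction of the published
  bedaquiline model, not its estimates. Structure, covariate multipliers
  and variability terms follow the published description exactly, and all
  structural properties (linearity, superposition, mass balance, back-end
  agreement, covariate ratios) are parameter-independent; but absolute
  exposure levels and peak-sensitive ratios inherit the reconstruction's
  imprecision. Against the published exposure table, AUC percent-of-
  reference columns agree to within a few points, the <20 % comparability
  bound for the switch regimen reproduces for both races, and the
  dose-proportionality identity is exact — while C_max ratio columns run
  ~3–11 points high and absolute medians deviate by up to ~25 %. The two
  strict reproduction tests in `tests/test_acceptance.py` are left failing
  by design to document this gap; supplying a verbatim parameter file would
  close it without code changes.
* The synthetic population reproduces marginal covariate frequencies, not
  joint real-world correlations, and its sampling schedule is a stand-in;
  passing VPC calibration shows internal consistency of model + engine +
  check, not fidelity to real NC-005 data.
* No metabolite (M2) kinetics, no nonlinearities, no drug–drug
  interactions, no adherence modelling, and no parameter estimation — the
  pipeline only simulates.
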