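# Methods

## Scope and model chain

`resrisk` implements the computational chain of a supervised pesticide
residue study on a single commodity (grapes in the packaged example):
analytical method validation, dissipation kinetics, and dietary risk
assessment in deterministic and probabilistic form. The package covers
two fungicides, pyraclostrobin and cyazofamid, the latter monitored
together with its metabolite CCIM as a total residue; nothing in the
code is specific to these compounds.

## Method validation

Calibration is ordinary least squares of instrument response on
standard concentration (at least three distinct levels; constant
responses are rejected as a degenerate zero-slope curve). The matrix
effect is ME% = (K1/K2 − 1)·100 with K1 the matrix-matched slope and K2
the solvent slope. The signed value is primary; the magnitude is
reported alongside because residue studies conventionally print |ME|,
and |ME| ≥ 20% is flagged significant (an exact 20% sits on the flagged
side; a 1e-9 tolerance absorbs float rounding at the boundary).

Recovery at a spike level is 100·mean(measured)/spike; RSD is
100·SD/mean using the sample (n−1) standard deviation — the usual choice
for small replicate sets, and the literature rarely states which
denominator was used. LOQ screening returns the lowest spike level with
mean recovery in 70–120% and RSD ≤ 20% (the standard supervised-trial
acceptability rule); when no level passes, the result object says so
explicitly rather than raising, because "no LOQ establishable" is a
legitimate experimental outcome.

## Dissipation kinetics

First-order decay C(t) = C0·e^(−kt) is fitted by log-linear OLS on
ln C vs t. Log-linear fitting is the dominant convention in residue
work, is exactly invertible on noiseless data, and is what the reported
rate constants in this literature almost always come from; a nonlinear
least-squares refinement on the original scale (seeded by the log-linear
estimates) is available via `nonlinear=True` for users who prefer
absolute-scale residuals. The fit requires at least three usable points
on at least two distinct days. A non-declining series (slope ≥ 0) is
returned with the half-life flagged undefined rather than raising, so
batch summaries over many sites do not abort.

Censored (< LOQ) observations default to LOQ/2 substitution, with
`drop` and `loq` selectable. Half-LOQ is the common compromise in
residue statistics; exposing all three lets users check sensitivity.
Day-0 samples are included in the fit, matching the usual 0/3/7/14/21/28
day sampling schedule.

Half-life is ln 2/k exactly (the identity `half_life(k) * k == ln 2` is
a tested invariant), and DT% = 100·(C0 − Ct)/C0, the only reading of the
dissipation percentage consistent with reported 65–88% values.

## Deterministic risk

Acute: NESTI = LP·HR·v/bw and %ARfD = 100·NESTI/ARfD. Chronic:
EDI = Σ STMRᵢ·Fᵢ/bw and %ADI = 100·EDI/ADI. Risk is unacceptable
strictly above 100%. Total residue for a parent + metabolite pair is
parent + f·metabolite with f defaulting to 1 (plain concentration sum,
consistent with published total-HR values such as 0.78 = 0.31 + 0.47); a
molecular-weight conversion factor can be supplied where a regulation
demands molar accounting.

## Probabilistic risk

Consumption and residue observations are fitted to lognormals by
log-moment maximum likelihood (mean and MLE SD of the logs; censored
values substituted before the transform, with each censored row's stored
value treated as its reporting limit when no explicit LOQ is given).
Exposure yᵢ = Σₖ x_ik·c_ik / bwᵢ is Monte-Carlo sampled with x and c
drawn independently per food (no dependence structure is assumed);
bodyweight is a per-subgroup constant divisor, matching the point
bodyweights used in deterministic practice, though the synthetic
generator can produce bodyweight variability (truncated normal at zero)
for sensitivity work.

The default is 1000 iterations; extreme percentiles with few expected
tail samples (e.g. P99.9 at 1000 draws has one) are noisy, and the CLI
warns when a requested percentile implies fewer than 10. Empirical
quantiles use linear interpolation between order statistics (numpy's
default), chosen once and fixed for reproducibility. For a single food
the exposure is itself lognormal with μ = μₓ + μ_c − ln bw and
σ = √(σₓ² + σ_c²); this closed form is used as an exact oracle in the
tests, never as the production path.

Each compound's random stream derives from `SeedSequence(seed,
spawn_key=(compound_index,))` and is shared across subgroups: identical
subgroups therefore produce identical reports, and dominance
comparisons between subgroups (e.g. children vs adults at equal
log-scale spread) hold exactly rather than only in distribution.

## Synthetic data

The generator emulates the study shape with known ground truth:

- decay series y(t) = C0·e^(−kt)·ε with ε lognormal, median 1 and
  CV = `noise_cv` (median-1 noise keeps the log-linear fit unbiased in
  log space; residue measurement error is positive and right-skewed);
  values below the LOQ are flagged censored with the latent value
  retained so censoring policies can be compared against truth;
- spike-recovery replicates with mean-1 lognormal multiplicative noise
  targeting a set mean recovery and RSD (strictly positive by
  construction);
- per-subgroup consumption samples, lognormal intake and truncated-normal
  bodyweight (CV 0 by default, the point-bodyweight convention).

The packaged example (`resrisk example`) uses the published study
conditions: the six reported calibration lines on the 0.05–5.0 mg/L
standard series; half-life regimes 17.8/28.9 d (pyraclostrobin),
4.3/7.8 d (cyazofamid) and 16.9 d (CCIM) at the reported initial
deposits with 10% measurement CV on the 0–28 day schedule; HR/STMR of
1.88/0.13 mg/kg (pyraclostrobin) and 0.78/0.11 mg/kg (total cyazofamid);
subgroup large portions 0.570/0.366/0.297 kg/day and bodyweights
53.23/16.14/52.6 kg (general/children/women of childbearing age) with
v = 3; ADI 0.03/0.2 and ARfD 0.05/0.2 mg/kg bw. Mean daily grape
intakes per subgroup are not public (they come from a national nutrition
survey); the defaults 0.048/0.030/0.045 kg/day were chosen once as
survey-plausible values that place the chronic deterministic risk inside
the published 0.348–5.122% band. Consequently the probabilistic
percentile totals published for the original survey population are
checked structurally (degenerate equivalence with the deterministic
model, closed-form quantile agreement, monotonicity, subgroup
dominance), not numerically.

What the synthetic data do not emulate: within-day replicate structure
of field samples, between-site covariates (soil, climate), residue-
consumption dependence, and real survey intake tails. Passing tests
therefore demonstrate correctness of the computational chain under the
stated generative model, not field validity of any particular risk
number.

## Numerical choices and problem sizes

- OLS via `scipy.stats.linregress`; quantiles via `numpy.quantile`
  (linear); truncated normals via `scipy.stats.truncnorm`; all RNG is
  `numpy.random.default_rng` seeded explicitly.
- CSVs are written with shortest round-trippable float representation
  and read with round-trip float parsing, so a fixed seed yields
  byte-identical pipeline outputs.
- Test problem sizes: 200 replicate trials for the noisy-kinetics bias
  check, 2000 observations for distribution-recovery checks, and up to
  100,000 Monte-Carlo iterations for the closed-form quantile oracle;
  these sizes keep sampling error well inside the asserted tolerances
  while the full suite runs in seconds.

## Known limitations

- Single-commodity in practice; the EDI and exposure sums accept
  multiple foods but the packaged example exercises one.
- No two-dimensional (uncertainty vs variability) Monte Carlo, no
  copulas between consumption and residue.
- Lognormality of consumption and residue is assumed, not tested; the
  fitting is deliberately plain log-moment MLE rather than an imitation
  of any proprietary distribution-fitting tool.
- The acute probabilistic mode samples daily consumption from the fitted
  distribution (not the fixed large portion), so its P97.5 is close to,
  but not definitionally equal to, the deterministic NESTI.
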