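# resrisk

Residue-to-risk assessment of pesticides in food crops: analytical
method-validation statistics, first-order dissipation kinetics, and
deterministic plus Monte-Carlo probabilistic dietary-risk models, in one
tested Python package. It is aimed at residue chemists and food-safety
risk assessors who need the full computational chain behind a supervised
field trial — from calibration curves to per-subgroup percentile risk —
reproducible from the command line or from Python.

## The models

**Method validation.** Calibration lines are ordinary least squares of
instrument response on concentration; the matrix effect compares the
matrix and solvent slopes, ME% = (K1/K2 − 1) × 100, with |ME| ≥ 20%
flagged significant. Spike recoveries report the mean recovery and the
relative standard deviation (sample SD); the limit of quantification
(LOQ) is the lowest spike level passing the 70–120% recovery band with
RSD ≤ 20%.

**Dissipation kinetics.** Residue decline follows first-order decay
C(t) = C0·e^(−kt); the half-life is T1/2 = ln 2 / k and the dissipation
percentage DT% = 100·(C0 − Ct)/C0. Below-LOQ points are handled by a
selectable censoring policy (drop, LOQ/2 substitution — the default — or
LOQ substitution).

**Deterministic risk.** Acute: NESTI = LP·HR·v/bw, with LP the large
portion (97.5th-percentile daily consumption, kg/day), HR the highest
trial residue (mg/kg), v the unit-to-unit variability factor (3 for
grapes) and bw the subgroup bodyweight; acceptability is
%ARfD = 100·NESTI/ARfD. Chronic: EDI = Σᵢ STMRᵢ·Fᵢ / bw over registered
foods, with STMR the supervised-trials median residue and Fᵢ the mean
daily intake; acceptability is %ADI = 100·EDI/ADI. Either figure above
100% is unacceptable. Where a parent and its metabolite are regulated
together, the total residue defaults to the plain concentration sum.

**Probabilistic risk.** Consumption x and residue c are fitted to
lognormal distributions; per-capita exposure yᵢ = Σₖ x_ik·c_ik / bwᵢ is
Monte-Carlo resampled (1000 iterations by default) and summarised as
empirical percentiles (P50 … P99.9) expressed as percent of the ADI or
ARfD per population subgroup.

A synthetic-data module generates all study-shaped inputs (decay series
with multiplicative lognormal noise and LOQ censoring, spike-recovery
replicates, per-subgroup lognormal consumption samples) with known
ground truth, so the whole chain runs and is testable without the
original survey microdata.

## Worked example

```python
import math
import resrisk as rr

# Acute risk for children eating grapes with HR = 1.88 mg/kg
children = rr.PopulationSubgroup(name="children", bw=16.14, lp=0.366, fi=0.030)
short = rr.nesti(children, 1.88)           # 0.12790 mg/kg bw
print(rr.percent_arfd(short, 0.05))        # 255.79  (> 100% -> unacceptable)

# Fit first-order decay to a noisy synthetic trial (true T1/2 = 17.8 d)
cfg = rr.SyntheticTrialConfig(c0_true=0.65, k_true=math.log(2) / 17.8,
                              sample_days=[0, 3, 7, 14, 21, 28],
                              noise_cv=0.1, seed=4)
fit = rr.fit_first_order(rr.generate_decay_series(cfg))
print(fit.k_hat, fit.half_life, fit.r_squared)  # 0.041 /day, 16.9 d, r2 = 0.943

# Matrix effect from matrix vs solvent calibration slopes
print(rr.matrix_effect(79.557, 75.023))
# MatrixEffect(percent=6.04..., magnitude=6.04..., significant=False)
```

The NESTI of 0.1279 mg/kg bw is 255.8% of the 0.05 mg/kg bw acute
reference dose — an unacceptable acute exposure for children — while the
fitted half-life of 16.9 d recovers the generating 17.8 d within the
noise, and the +6% matrix effect is below the 20% significance cutoff
(so solvent-standard quantification is justified).

The full pipeline runs from a YAML config:

```bash
resrisk example --out fixture --seed 3      # synthetic study inputs + config.yaml
resrisk run --config fixture/config.yaml    # validation -> kinetics -> risk CSVs
```

writing one CSV per stage (validation, dissipation, deterministic_risk,
probabilistic_risk) plus a combined summary, each with provenance
headers (version, seed, config hash); a fixed seed gives byte-identical
outputs. Individual stages are available as `resrisk simulate`,
`validate`, `dissipation`, `acute`, `chronic` and `probabilistic`.

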