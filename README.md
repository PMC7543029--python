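# mmisurv

Multi-model inference for population cancer **net survival**: flexible
parametric excess hazard regression, information-criterion model-set
selection, Akaike-weight model averaging with an unconditional variance,
Pohar-Perme cohort/period reference estimation, and RMISD evaluation of
predictions — together with a synthetic registry generator that makes the
whole pipeline reproducible without confidential registry data.

## Who this is for

Cancer-registry analysts and biostatisticians who need to *predict* net
survival for recently diagnosed patients (for whom follow-up is still short)
and to *project* it for patients diagnosed after the data cut-off — and who
want to propagate model-selection uncertainty into those predictions instead
of betting on a single selected model.

## The model

Observed mortality of a cancer cohort is decomposed as

```
λ(t, x) = λ_E(t, x) + λ_P(a + t, y + t, z)
```

where `λ_E` is the excess (cancer-related) hazard and `λ_P` is background
mortality from a population life table matched on attained age `a+t`,
calendar year `y+t`, sex and deprivation stratum `z`.  The log excess hazard
is a restricted cubic spline in log time plus covariate effects,

```
log λ_E(t, x) = s₀(log t) + Σ_k β_k(t) · g_k(x_k)
```

with `g_k` linear, spline, or factor coding, and `β_k(t) = β_k` for a
proportional effect or `β_k · log t` for a time-dependent one.  Models are
fitted by maximising the full relative-survival likelihood

```
L = Σ_i [ δ_i · log(λ_P,i(t_i) + λ_E,i(t_i)) − Λ_E,i(t_i) ]
```

with 20-node Gauss-Legendre quadrature for the cumulative excess hazard.

**Selection keeps a set, not a winner.** A stepwise search upgrades one
effect at a time (linear→spline, proportional→time-dependent, then pairwise
interactions) comparing AIC or BIC two models at a time: a model more than
2 criterion units worse is discarded; within 2, *both* are kept and expanded
further.  The rationale is the evidence ratio `exp(Δ/2)`: a model 2 units
from the best is only 2.7 times less likely to be the generating model
(7.4 and 54.6 at Δ = 4 and 8).

**Averaging acts on predictions, not parameters.** Each retained model gets
weight `w_m ∝ exp(−Δ_m/2)`; hazards and cumulative hazards are weight-summed
per patient, individual net survival is `exp(−Λ_MA)`, and cohort net
survival is the mean of the individual curves.  The unconditional variance
`[Σ_m w_m √(var_m + (λ_m − λ_MA)²)]²` adds the between-model spread to the
usual within-model variance.

**Evaluation.** Predictions are compared to a reference (Pohar-Perme
estimates, or the known truth on synthetic data) by the root mean integrated
square difference over groups g (age band × deprivation quintile):

```
RMISD = sqrt( (1/G) Σ_g ∫₀ᴴ (Ŝ_g(u) − S_g(u))² du )
```

## Worked example

```python
import mmisurv as M
from mmisurv import synthetic_registry as synth

table = synth.make_synthetic_life_table()
# moderate-lethality cohort with complete 5-year follow-up
scenario = synth.colon_like(n=3000, seed=12, censor_date=2016.0)
patients, truth = synth.simulate_cohort(scenario, table)

model_set = M.select_models(patients, table, M.default_base_spec(), criterion="bic")
print(model_set.summary()[["spec", "delta", "n_params"]].to_string())

avg = M.average_predictions(model_set, patients, M.monthly_grid(5.0))
print(f"model-averaged 5-year net survival: {avg.cohort_survival[-1]:.3f}")
print(f"true 5-year net survival:           {truth['true_s5'].mean():.3f}")

pp = M.pp_cohort(patients, table, [5.0])
print(f"Pohar-Perme 5-year estimate:        {pp.survival[0]:.3f}")
```

Output:

```
                                         spec  delta  n_params
0  b3 | age:lin:PH + dep:cat:PH + year:lin:PH    0.0        10
model-averaged 5-year net survival: 0.404
true 5-year net survival:           0.397
Pohar-Perme 5-year estimate:        0.400
```

BIC recovers the generating all-linear proportional-hazards form as a
singleton set (so averaging reduces to that one model), and both the
model-based and the non-parametric 5-year estimates agree with the known
truth within sampling error for a cohort of this size.  On data generated
with a time-dependent effect the retained set instead contains the
time-dependent form(s), and averaging propagates that selection uncertainty
into the predictions.

The same pipeline is scriptable from the shell:

```sh
mmisurv simulate --preset colon-like --n 3000 --seed 11 \
        --out-patients patients.csv --out-table lifetable.csv
mmisurv select --data patients.csv --table lifetable.csv \
        --criterion bic --out modelset.json
mmisurv average --model-set modelset.json --data patients.csv --out curve.csv
```

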