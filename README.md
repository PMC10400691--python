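# triagesim

Monte-Carlo microsimulation of ICU bed rationing under surge load, comparing
**ex-ante** triage (prognosis-based assignment of empty beds) and **ex-post**
triage (reallocation in which already-treated patients compete with queued
patients) against purely random allocation — with a focus on how each policy
affects patients *with* and *without* disabilities or pre-existing diseases.

The package is aimed at health-care operations researchers and medical
ethicists who want a reproducible, configurable implementation of this class
of triage experiment: every allocation rule, distributional assumption and
random stream is exposed, seeded and tested.

## Model

An ICU has `B` beds (default 60) and faces demand that exceeds capacity.
Each simulated patient `i` carries

- a comorbidity indicator `x_i` (1 with probability `s = 0.7`),
- a true death probability `p_i ~ Δ(a_k; b_k; c_k)`, a triangular
  distribution depending on the patient's condition `k` — the baseline
  triangle `Δ(0.04; 0.41; 0.045)` with mean `E(X) = 0.165` for patients
  without comorbidities, and condition-specific triangles whose means are
  the baseline mean multiplied by published relative death risks (odds or
  hazard ratios, e.g. hypertension HR 2.12 giving `Δ(0.19; 0.63; 0.23)`,
  `E(X) = 0.35`),
- a pre-drawn death indicator `y_i ~ Bernoulli(p_i)`, fixed for the whole
  stay.

Comorbid patients have a disability with probability 0.1 (trisomy 21, ALS)
and a pre-existing disease with probability 0.9 (cardiovascular disease,
hypertension, type-2 diabetes), with conditions assigned by prevalence
weights within each category.

At `t = 0` the beds are filled from an initial demand of `d = 70` patients;
at each consecutive time point `t = 1..T` (default `T = 3`) a fresh queue of
`w = 10` patients arrives and beds are reallocated. Six policies combine the
initial and consecutive modes:

| id | initial allocation | consecutive reallocation |
|----|--------------------|--------------------------|
| 0  | random             | random replacement (10 % of beds) |
| 1  | random             | ex-post triage |
| 2  | ex-ante triage     | random replacement |
| 3  | ex-ante triage     | ex-post triage |
| 4  | 90 % random / 10 % ex-ante | random replacement |
| 5  | 90 % random / 10 % ex-ante | ex-post triage |

Triage ranks patients by the *perceived* death probability `p'_i = e · p_i`,
where `e ∈ {0.9, 1, 1.1}` models uniform clinician misestimation (a pure
rescaling, so it provably never changes an allocation). The outcome is the
prospective mortality of the treated cohort,

    m_t = (1/B) · Σ_{i treated} y_i,

with group-specific analogues `m_t^n` (no comorbidity) and `m_t^v`
(comorbidity), averaged over `R = 10 000` replications per policy, and
validated by one-way ANOVA with Tukey post-hoc tests.

## Worked example

```python
from triagesim import ExperimentConfig, run_experiment

summary = run_experiment(ExperimentConfig(replications=2000, master_seed=7))
print(summary.mortality_table(1).round(1))
```

```
                     policy_0  policy_1  policy_2  policy_3  policy_4  policy_5
group
all patients             35.8      29.0      29.5      25.5      34.1      27.3
without comorbidity      16.5      16.4      16.4      16.5      15.8      15.9
with comorbidity         44.0      35.6      36.4      31.4      43.1      34.4
```

Mean mortalities at the first reallocation time point, in percent. Reading
it: under fully random allocation (policy 0) the treated cohort mirrors the
population, so 35.8 % of treated patients are destined to die; consecutive
ex-post triage (policies 1, 3, 5) lowers total mortality by 6–10 percentage
points. The reduction comes almost entirely from the comorbid group's
*composition* (fewer high-risk patients keep beds — 44.0 % → 34.4 % under
policy 5), while the mortality of treated patients without comorbidities is
essentially unchanged (~16 %). For the legally inspired policy 5,

```
policy 5: 33.90% (t=0) -> 27.32% (t=1), relative reduction 19.4%
```

The same experiment is available from the shell:

```bash
triagesim run --reps 2000 --seed 7 --out results/
triagesim compare results/replications.csv -t 1
triagesim overlap        # triangle means and overlap with the baseline density
triagesim grid --reps 500 --seed 7 --out grid/   # sensitivity over d, w, e
```

`triagesim overlap` prints, for each condition, its triangle and the
shared-area fraction of its density with the baseline density, e.g.
`hypertension: Δ(0.19; 0.63; 0.23) mean=0.3500 overlap_with_baseline=31.71%`.

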