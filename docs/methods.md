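# Methods

## Model and assumptions

The simulator models an ICU in a sustained high-load situation as a
discrete-time bed-allocation process. Its assumptions are deliberately
stark, chosen to isolate the effect of the allocation *rule* from everything
else:

- **Untreated patients die.** Patients denied a bed or discharged by a
  reallocation leave the system permanently; the only outcome tracked is
  mortality on the ICU itself.
- **No natural patient flow.** There are no recoveries, deaths-in-bed or
  transfers between time points; beds only turn over through the policy's
  reallocation step. The reported quantity is therefore *prospective*
  mortality: the fraction of the currently treated cohort whose pre-drawn
  death indicator is 1, not an observed death count.
- **Static prognosis.** A patient's death probability `p_i` and indicator
  `y_i` are drawn once at generation and never change during the stay.
  Consequences: reallocations cannot react to clinical deterioration or
  improvement, and repeated ex-post triage of the same cohort is
  progressively less consequential as the cohort is already selected.
- **Fresh queues.** The queue at each time point consists of new patients;
  previously denied patients do not re-enter.

These are modelling commitments, not incidental simplifications — the
experiment asks what each rule does *given* a fixed prognosis per patient.

## Death-probability distributions

Death probabilities are triangular, `Δ(min; max; mode)` (note the order:
minimum, maximum, mode), with mean `(min + max + mode)/3`:

- Patients without comorbidities: `Δ(0.04; 0.41; 0.045)`, mean 0.165.
- Comorbid patients: a condition-specific triangle whose mean equals the
  baseline mean times the condition's published relative death risk
  (odds/hazard ratios: trisomy 21 4.52, cardiovascular disease 4.85,
  hypertension 2.12, type-2 diabetes 2.03, ALS 3.0).

Only the hypertension triangle is published explicitly,
`Δ(0.19; 0.63; 0.23)` with mean 0.35. The other four must be reconstructed
from their target means. The package derives them by **mean-preserving
translation plus symmetric widening**: all three vertices are shifted by
`mean·(rr − 1)`, then minimum and maximum are moved outward by
`widen = 0.035`. The widening amount is not free: it is the unique symmetric
widening that maps the translated baseline onto the published hypertension
triangle (translation alone gives `Δ(0.2248; 0.5948; 0.2298)`, which is
*not* the published triple), so it is the best available evidence about the
construction rule actually used. Pure translation (`method: translate`,
`widen: 0`) and fully explicit triangles remain available in the
configuration. When a shifted/widened vertex leaves `[0, 1]` the support is
clamped and the excess is split over the two remaining vertices so that the
target mean is preserved exactly; if no valid triangle can reach the target
mean, an error is raised rather than silently distorting the distribution.

The overlap between two groups' densities is quantified by the **overlap
fraction**: the integral of the pointwise minimum of the two unit-area
densities. It is computed exactly by piecewise-linear segment integration —
the minimum of two piecewise-linear densities is piecewise linear once all
vertices and pairwise segment intersections are breakpoints, so the
trapezoid rule over those breakpoints is exact. For the baseline vs the
hypertension triangle the exact integral is 0.31707 (the published figure is
31.35 %; the 0.36-percentage-point residual is consistent with a coarser
numerical method or rounding in the original computation and is within the
package's own acceptance band of ±0.5 points).

## Population generation

Each patient consumes exactly five uniforms, in fixed order: comorbidity
Bernoulli (`s`), category Bernoulli (disability share), condition
categorical (prevalence weights within category), `p_i` via the closed-form
triangular inverse CDF, and `y_i` via `u < p_i`. The category and condition
uniforms are consumed even for healthy patients, which makes the stream
position after `n` patients independent of the values drawn — generation is
reproducible regardless of batch splitting. Sampling goes through our own
inverse CDF (one uniform per draw) both for this contract and because
degenerate point-mass triangles (useful in tests) must sample cleanly.

**Prevalence weights** are the one input the study design does not publish
numerically. Defaults are approximate German adult population prevalences —
hypertension 0.30, type-2 diabetes 0.092, cardiovascular disease 0.065,
trisomy 21 6·10⁻⁴, ALS 9·10⁻⁵ — normalized within each category. On top of
these, a one-time analytic calibration adjusts the cardiovascular-disease
weight (the highest-mean pre-existing condition, keeping the ratio of the
others fixed) so that the comorbid-group mixture mean equals 0.438 — the
comorbid-group mortality that fully random allocation produces, which pins
down exactly one degree of freedom of the weights. The calibration is a
closed-form solve on mixture means, involves no simulation, and moves the
raw weights only slightly (cardiovascular 0.142 → 0.134 within category).
Uncalibrated or fully custom weights are a config switch away.

## Policies and numerical choices

- Triage ranks by perceived probability `p'_i = e·p_i` with ties broken
  uniformly at random from the step's stream. Ties have probability zero
  for continuous distributions, but the rule must be total (degenerate
  triangles, user-supplied cohorts). Tie-break uniforms are drawn
  identically for every `e`, so misestimation invariance holds exactly.
- Random replacement turns over `⌊0.1·B⌋` beds (6 of 60) per step,
  independent of the queue length.
- Ex-post triage pools the `B` bed-holders with the `w` queued patients and
  keeps the `B` lowest perceived probabilities; up to `w` bed-holders can be
  displaced in one step.
- For pure random initialization exactly `B` patients are generated (all
  admitted); ex-ante and mixed initialization generate the full demand `d`
  and select. A config flag (`random_init_from_demand`) switches random
  initialization to selecting `B` of `d` instead.
- Group mortality uses the group's treated count as denominator; a
  replication in which a group is absent from the cohort contributes no
  value for that group and is counted in `n_missing_*` (with `B = 60` and
  `s = 0.7` this does not occur in practice; it matters for small toy
  configurations).

## Seed discipline

A master seed spawns named `SeedSequence` substreams keyed by replication
index plus a role tag: demand generation and initial-allocation randomness
are keyed by the *initial mode* (so policies 0/1, 2/3 and 4/5 see
bitwise-identical initial cohorts), queues are keyed by the time point and
shared by all policies (common random numbers), and step randomness is keyed
by time point and *consecutive mode*. Identical master seeds reproduce every
output bitwise; the run manifest records the derivation.

## Statistical evaluation

Replication-level mortalities at a fixed time point are compared across
policies with one-way ANOVA plus Tukey-HSD post-hoc tests (Bonferroni
optional), significance threshold 0.05. Inputs with no variation at all are
reported as `F = 0, p = 1` instead of raising. This module is a convenience
over scipy's standard tests, not methodology of its own.

## Problem sizes

The default experiment (R = 10 000 replications × 6 policies × 4 time
points) runs in about a minute on one core; the test suite runs it once at
full scale and otherwise uses 30–400 replications, which is ample for the
structural properties (bed conservation, invariances, orderings) that hold
per-replication or at any scale. The acceptance script runs policy 5 at the
full R = 10 000.

## Known limitations

- Four of the five comorbidity triangles are reconstructions: only their
  means are pinned by published ratios; their shapes follow the
  translation-plus-fitted-widening rule described above. Quantities that
  depend on distribution *shape* (e.g. how sharply ex-post triage separates
  the pool) carry this reconstruction uncertainty; quantities pinned by
  means (random-allocation mortalities, group compositions) do not.
- Prevalence weights are calibrated to one aggregate anchor and are not a
  validated epidemiological profile of German ICU patients.
- The simulator inherits the model's assumptions above; none of the results
  speak to settings with patient flow, evolving prognoses, or re-presenting
  patients.
- Confidence intervals of the published relative-risk ratios are not
  propagated; point ratios are used throughout.
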