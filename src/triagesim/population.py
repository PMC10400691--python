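"""Simulated ICU patient populations.

Each patient i carries a comorbidity flag x_i (1 with probability s), an
assigned condition k for comorbid patients, a true death probability p_i
drawn from the condition's triangular distribution (the baseline triangle
for healthy patients), and a pre-drawn death indicator y_i ~ Bernoulli(p_i).
y_i is fixed at generation and never re-drawn: a patient's prognosis does
not change during the stay.

Comorbid patients fall into one of two categories — disabilities (probability
``disability_share``, default 10 %) and pre-existing diseases (90 %) — and
within a category a condition is chosen proportionally to prevalence weights.

Draw-order contract: every patient consumes exactly five uniforms, in the
fixed order (comorbidity, category, condition, p via inverse CDF, y), all
from one stream.  The category and condition uniforms are consumed even when
unused (healthy patients), so the stream position after n patients is
independent of the values drawn and of batch splitting.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .distributions import (
    RiskScaling,
    TriangularParams,
    scale_by_relative_risk,
    triangular_ppf_arrays,
)

__all__ = [
    "CATEGORY_DISABILITY",
    "CATEGORY_PRE_EXISTING",
    "BASELINE_TRIANGLE",
    "COMORBID_MORTALITY_ANCHOR",
    "ComorbidityProfile",
    "PopulationMix",
    "Patient",
    "Cohort",
    "ConfigurationError",
    "reference_comorbidities",
    "calibrate_prevalence_weights",
    "default_population_mix",
    "generate_cohort",
    "generate_patients",
    "perceived_probability",
    "draw_death_flag",
]

CATEGORY_DISABILITY = "disability"
CATEGORY_PRE_EXISTING = "pre-existing"

#: Baseline death-probability distribution of patients without comorbidities,
#: Δ(0.04; 0.41; 0.045) with mean 0.165 (normalized national surveillance values).
BASELINE_TRIANGLE = TriangularParams(minimum=0.04, maximum=0.41, mode=0.045)

#: Mean death probability of the comorbid group that the default prevalence
#: weights are calibrated to reproduce (the comorbid-group mortality observed
#: under fully random allocation, 43.8 %).
COMORBID_MORTALITY_ANCHOR = 0.438


class ConfigurationError(ValueError):
    """Raised for an unusable population configuration."""


#: Symmetric min/max widening used when deriving comorbid triangles from the
#: baseline.  Fitted once to the one explicitly published comorbid triangle:
#: translating the baseline by mean*(HR - 1) = 0.165 * 1.12 gives
#: (0.2248, 0.5948, 0.2298), while the published hypertension triangle is
#: (0.19, 0.63, 0.23); the symmetric widening that maps one onto the other
#: (to the published rounding) is ((0.2248 - 0.19) + (0.63 - 0.5948)) / 2.
FITTED_WIDEN = 0.035


@dataclass(frozen=True)
class ComorbidityProfile:
    """A named condition: category, relative death risk, triangle, prevalence weight."""

    name: str
    category: str
    scaling: RiskScaling
    prevalence_weight: float

    def __post_init__(self) -> None:
        if self.category not in (CATEGORY_DISABILITY, CATEGORY_PRE_EXISTING):
            raise ConfigurationError(
                f"{self.name}: category must be {CATEGORY_DISABILITY!r} or "
                f"{CATEGORY_PRE_EXISTING!r}, got {self.category!r}"
            )
        if self.prevalence_weight < 0:
            raise ConfigurationError(f"{self.name}: prevalence_weight must be >= 0")

    def resolve_triangle(self, base: TriangularParams) -> TriangularParams:
        """The condition's death-probability triangle, derived from the baseline."""
        return scale_by_relative_risk(base, self.scaling)


def reference_comorbidities() -> tuple[ComorbidityProfile, ...]:
    """The five conditions of the study with literature relative death risks.

    Two disabilities (trisomy 21, OR 4.52; amyotrophic lateral sclerosis,
    OR 3.0) and three pre-existing diseases (cardiovascular disease, OR 4.85;
    hypertension, HR 2.12; type-2 diabetes, OR 2.03).  The hypertension
    triangle Δ(0.19; 0.63; 0.23) is fixed explicitly; the others are derived
    from the baseline by mean-preserving translation plus the symmetric
    widening :data:`FITTED_WIDEN` that reconstructs the published
    hypertension triangle from the baseline.

    Prevalence weights are German adult prevalences (approximate population
    fractions); they are normalized within each category at generation time.
    """
    derived = RiskScaling  # alias for brevity below
    return (
        ComorbidityProfile(
            name="trisomy_21",
            category=CATEGORY_DISABILITY,
            scaling=derived(relative_risk=4.52, method="translate_widen", widen=FITTED_WIDEN),
            prevalence_weight=6.0e-4,
        ),
        ComorbidityProfile(
            name="amyotrophic_lateral_sclerosis",
            category=CATEGORY_DISABILITY,
            scaling=derived(relative_risk=3.0, method="translate_widen", widen=FITTED_WIDEN),
            prevalence_weight=9.0e-5,
        ),
        ComorbidityProfile(
            name="cardiovascular_disease",
            category=CATEGORY_PRE_EXISTING,
            scaling=derived(relative_risk=4.85, method="translate_widen", widen=FITTED_WIDEN),
            prevalence_weight=0.065,
        ),
        ComorbidityProfile(
            name="hypertension",
            category=CATEGORY_PRE_EXISTING,
            scaling=RiskScaling(
                relative_risk=2.12,
                method="explicit",
                explicit=TriangularParams(minimum=0.19, maximum=0.63, mode=0.23),
            ),
            prevalence_weight=0.30,
        ),
        ComorbidityProfile(
            name="type_2_diabetes",
            category=CATEGORY_PRE_EXISTING,
            scaling=derived(relative_risk=2.03, method="translate_widen", widen=FITTED_WIDEN),
            prevalence_weight=0.092,
        ),
    )


def calibrate_prevalence_weights(
    profiles: Sequence[ComorbidityProfile],
    base: TriangularParams = BASELINE_TRIANGLE,
    target_comorbid_mean: float = COMORBID_MORTALITY_ANCHOR,
    disability_share: float = 0.1,
) -> tuple[ComorbidityProfile, ...]:
    """Adjust pre-existing-disease weights so the comorbid mixture mean hits a target.

    Under fully random allocation the comorbid-group mortality converges to
    the prevalence-weighted mean of the comorbid triangles, so that observed
    mortality pins down one degree of freedom of the (otherwise unpublished)
    weights.  The weight of the highest-mean pre-existing condition is solved
    in closed form, keeping the ratio of the remaining pre-existing weights
    and all disability weights fixed.  Analytic: no simulation involved.
    """
    disabilities = [p for p in profiles if p.category == CATEGORY_DISABILITY]
    diseases = [p for p in profiles if p.category == CATEGORY_PRE_EXISTING]
    if not disabilities or not diseases:
        raise ConfigurationError("calibration needs both categories populated")

    def mixture_mean(group: Sequence[ComorbidityProfile]) -> float:
        w = np.array([p.prevalence_weight for p in group])
        m = np.array([p.resolve_triangle(base).mean for p in group])
        return float(np.dot(w, m) / w.sum())

    mu_dis = mixture_mean(disabilities)
    target_pre = (target_comorbid_mean - disability_share * mu_dis) / (
        1.0 - disability_share
    )

    pivot = max(diseases, key=lambda p: p.resolve_triangle(base).mean)
    rest = [p for p in diseases if p is not pivot]
    mu_pivot = pivot.resolve_triangle(base).mean
    mu_rest = mixture_mean(rest) if rest else mu_pivot
    if abs(mu_pivot - mu_rest) < 1e-12:
        raise ConfigurationError("pre-existing triangle means too close to calibrate")
    w_pivot = (target_pre - mu_rest) / (mu_pivot - mu_rest)
    if not 0.0 <= w_pivot <= 1.0:
        raise ConfigurationError(
            f"target comorbid mean {target_comorbid_mean} unreachable by reweighting "
            f"(pivot weight {w_pivot:.3f} outside [0, 1])"
        )

    rest_total = sum(p.prevalence_weight for p in rest)
    out = []
    for p in profiles:
        if p.category != CATEGORY_PRE_EXISTING:
            out.append(p)
        elif p is pivot:
            out.append(replace(p, prevalence_weight=w_pivot))
        else:
            out.append(
                replace(p, prevalence_weight=(1.0 - w_pivot) * p.prevalence_weight / rest_total)
            )
    return tuple(out)


@dataclass(frozen=True)
class PopulationMix:
    """Composition of the simulated patient population.

    ``share_comorbid`` is s, the probability that a patient has any
    comorbidity (default 0.7); ``disability_share`` splits comorbid patients
    into disabilities vs pre-existing diseases (default 0.1).  When
    ``single_condition`` names a profile, every comorbid patient receives
    that condition (the single-comorbidity scenarios); otherwise conditions
    are assigned by prevalence (the realistic mixed scenario).
    """

    share_comorbid: float = 0.7
    disability_share: float = 0.1
    profiles: tuple[ComorbidityProfile, ...] = field(
        default_factory=reference_comorbidities
    )
    baseline: TriangularParams = BASELINE_TRIANGLE
    single_condition: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.share_comorbid <= 1.0:
            raise ConfigurationError("share_comorbid must be in [0, 1]")
        if not 0.0 <= self.disability_share <= 1.0:
            raise ConfigurationError("disability_share must be in [0, 1]")
        if self.share_comorbid > 0 and not self.profiles:
            raise ConfigurationError("share_comorbid > 0 requires comorbidity profiles")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate profile names")
        if self.single_condition is not None and self.single_condition not in names:
            raise ConfigurationError(
                f"single_condition {self.single_condition!r} not among {names}"
            )

    @functools.cached_property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.profiles)

    @functools.cached_property
    def triangles(self) -> tuple[TriangularParams, ...]:
        return tuple(p.resolve_triangle(self.baseline) for p in self.profiles)

    @functools.cached_property
    def comorbid_mixture_mean(self) -> float:
        """Expected p_i of a comorbid patient under this mix."""
        if self.single_condition is not None:
            idx = self.condition_names.index(self.single_condition)
            return self.triangles[idx].mean
        total = 0.0
        for category, share in (
            (CATEGORY_DISABILITY, self.disability_share),
            (CATEGORY_PRE_EXISTING, 1.0 - self.disability_share),
        ):
            idx = [i for i, p in enumerate(self.profiles) if p.category == category]
            if not idx:
                continue
            w = np.array([self.profiles[i].prevalence_weight for i in idx])
            m = np.array([self.triangles[i].mean for i in idx])
            total += share * float(np.dot(w, m) / w.sum())
        return total

    @functools.cached_property
    def population_mean(self) -> float:
        """Expected p_i of a randomly drawn patient."""
        s = self.share_comorbid
        return (1.0 - s) * self.baseline.mean + s * self.comorbid_mixture_mean

    @functools.cached_property
    def _sampler_tables(self):
        """Per-category cumulative weights + per-condition triangle arrays."""
        n = len(self.profiles)
        a = np.array([t.minimum for t in self.triangles])
        b = np.array([t.maximum for t in self.triangles])
        c = np.array([t.mode for t in self.triangles])
        tables = {}
        for code, category in ((0, CATEGORY_DISABILITY), (1, CATEGORY_PRE_EXISTING)):
            idx = np.array(
                [i for i in range(n) if self.profiles[i].category == category],
                dtype=np.int64,
            )
            if idx.size:
                w = np.array([self.profiles[i].prevalence_weight for i in idx])
                if w.sum() <= 0:
                    raise ConfigurationError(
                        f"prevalence weights in category {category!r} sum to 0"
                    )
                cum = np.cumsum(w / w.sum())
            else:
                cum = np.array([])
            tables[code] = (idx, cum)
        return a, b, c, tables


def default_population_mix(calibrated: bool = True, **overrides) -> PopulationMix:
    """The study's default mix: s = 0.7, 10 %/90 % category split, five conditions.

    With ``calibrated`` (default) the pre-existing prevalence weights are
    re-solved once so the comorbid mixture mean equals the 0.438 anchor.
    """
    profiles = reference_comorbidities()
    baseline = overrides.pop("baseline", BASELINE_TRIANGLE)
    disability_share = overrides.get("disability_share", 0.1)
    if calibrated:
        profiles = calibrate_prevalence_weights(
            profiles, base=baseline, disability_share=disability_share
        )
    return PopulationMix(profiles=profiles, baseline=baseline, **overrides)


@dataclass(frozen=True)
class Patient:
    """One simulated person."""

    id: int
    has_comorbidity: bool
    condition: Optional[str]
    true_death_prob: float
    death_flag: int

    def __post_init__(self) -> None:
        if self.has_comorbidity != (self.condition is not None):
            raise ConfigurationError("condition must be set iff has_comorbidity")
        if not 0.0 <= self.true_death_prob <= 1.0:
            raise ConfigurationError("true_death_prob must be in [0, 1]")
        if self.death_flag not in (0, 1):
            raise ConfigurationError("death_flag must be 0 or 1")


@dataclass(frozen=True)
class Cohort:
    """A batch of patients as parallel arrays (fast path used by the engine).

    ``condition`` holds the index into the mix's profile tuple, -1 for none.
    """

    ids: np.ndarray
    comorbid: np.ndarray
    condition: np.ndarray
    p: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return self.ids.size

    def take(self, indices: np.ndarray) -> "Cohort":
        return Cohort(
            ids=self.ids[indices],
            comorbid=self.comorbid[indices],
            condition=self.condition[indices],
            p=self.p[indices],
            y=self.y[indices],
        )

    @staticmethod
    def concat(first: "Cohort", second: "Cohort") -> "Cohort":
        return Cohort(
            ids=np.concatenate([first.ids, second.ids]),
            comorbid=np.concatenate([first.comorbid, second.comorbid]),
            condition=np.concatenate([first.condition, second.condition]),
            p=np.concatenate([first.p, second.p]),
            y=np.concatenate([first.y, second.y]),
        )

    def to_patients(self, mix: PopulationMix) -> list[Patient]:
        names = mix.condition_names
        return [
            Patient(
                id=int(self.ids[i]),
                has_comorbidity=bool(self.comorbid[i]),
                condition=names[self.condition[i]] if self.comorbid[i] else None,
                true_death_prob=float(self.p[i]),
                death_flag=int(self.y[i]),
            )
            for i in range(len(self))
        ]


def generate_cohort(
    count: int,
    mix: PopulationMix,
    rng: np.random.Generator,
    id_start: int = 0,
) -> Cohort:
    """Generate ``count`` patients as a :class:`Cohort`.

    Implements the five-uniform-per-patient draw-order contract; see module
    docstring.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    u = rng.random((count, 5))
    comorbid = u[:, 0] < mix.share_comorbid

    condition = np.full(count, -1, dtype=np.int64)
    a = np.full(count, mix.baseline.minimum)
    b = np.full(count, mix.baseline.maximum)
    c = np.full(count, mix.baseline.mode)

    if comorbid.any():
        ta, tb, tc, tables = mix._sampler_tables
        if mix.single_condition is not None:
            condition[comorbid] = mix.condition_names.index(mix.single_condition)
        else:
            is_disability = u[:, 1] < mix.disability_share
            for code in (0, 1):
                idx, cum = tables[code]
                mask = comorbid & (is_disability == (code == 0))
                if not mask.any():
                    continue
                if idx.size == 0:
                    raise ConfigurationError(
                        "a category was drawn that has no profiles configured"
                    )
                # clip guards the u == cum[-1] float edge
                pos = np.searchsorted(cum, u[mask, 2], side="right")
                condition[mask] = idx[np.minimum(pos, idx.size - 1)]
        cm = comorbid
        a[cm], b[cm], c[cm] = ta[condition[cm]], tb[condition[cm]], tc[condition[cm]]

    p = triangular_ppf_arrays(u[:, 3], a, b, c)
    y = (u[:, 4] < p).astype(np.int8)
    ids = np.arange(id_start, id_start + count, dtype=np.int64)
    return Cohort(ids=ids, comorbid=comorbid, condition=condition, p=p, y=y)


def generate_patients(
    count: int,
    mix: PopulationMix,
    rng: np.random.Generator,
    id_start: int = 0,
) -> list[Patient]:
    """Generate ``count`` patients as :class:`Patient` records."""
    return generate_cohort(count, mix, rng, id_start=id_start).to_patients(mix)


def perceived_probability(p, e: float):
    """Clinician-perceived death probability p' = e * p.

    Used exclusively to rank patients in triage decisions; the death
    indicator y_i is always drawn from the true probability.  A uniform
    factor e rescales all probabilities alike, so rankings are unchanged.
    """
    if e <= 0:
        raise ValueError(f"misestimation factor e must be > 0, got {e}")
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("death probabilities must be in [0, 1]")
    out = e * arr
    return float(out) if np.isscalar(p) else out


def draw_death_flag(p: float, rng: np.random.Generator) -> int:
    """Death indicator: 1 iff a uniform draw on [0, 1) falls below p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"death probability must be in [0, 1], got {p}")
    return int(rng.random() < p)
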