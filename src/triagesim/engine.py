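"""Replication loop, time stepping, mortality metrics and sensitivity grid.

One replication of one policy: generate the initial demand, fill the B beds
(t = 0), then for each consecutive time point t = 1..T generate a fresh
queue of w patients and apply the policy's reallocation step.  At every time
point the prospective mortality of the currently treated cohort is recorded:

    m_t = (1 / B) * sum of y_i over treated patients

together with the group mortalities m_t^n (patients without comorbidities)
and m_t^v (patients with comorbidities) and per-group treated / admitted /
discharged counts.  Group mortalities use the group's own treated count as
denominator; a replication in which a group is absent from the cohort
contributes no value for that group (excluded and counted).

Patients' p_i and y_i are immutable once drawn.  Denied and discharged
patients leave the system permanently (the model's high-load assumption:
untreated patients die, and there is no natural patient flow).

Seed discipline: the master seed spawns named substreams per replication —
demand generation and initial allocation are keyed by the *initial mode*, so
policy pairs (0,1), (2,3) and (4,5) see identical initial draws; queues are
keyed by the time point and shared by all policies; per-step policy
randomness is keyed by time point and *consecutive mode*.  Misestimation
variants (different e) consume identical streams, so their allocations are
identical — uniform scaling cannot change a ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .policies import (
    AllocationResult,
    PolicySpec,
    initial_allocation,
    step_expost_triage,
    step_random_replacement,
)
from .population import Cohort, PopulationMix, default_population_mix, generate_cohort

__all__ = [
    "ExperimentConfig",
    "TimePointMetrics",
    "ExperimentSummary",
    "run_replication",
    "run_experiment",
    "sensitivity_grid",
    "METRIC_FIELDS",
]

logger = logging.getLogger(__name__)

_INITIAL_MODE_CODE = {"random": 0, "exante": 1, "mixed": 2}
_CONSECUTIVE_MODE_CODE = {"random_replacement": 0, "expost": 1}

# Substream tags (first entropy word after master seed and replication index).
_TAG_DEMAND = 1
_TAG_INIT_ALLOC = 2
_TAG_QUEUE = 3
_TAG_STEP = 4

# Queue patients at time t get ids from t * _QUEUE_ID_BLOCK, keeping ids
# unique within a replication for any realistic demand size.
_QUEUE_ID_BLOCK = 100_000

METRIC_FIELDS = (
    "total_mortality",
    "healthy_mortality",
    "comorbid_mortality",
    "treated_healthy",
    "treated_comorbid",
    "admitted_healthy",
    "admitted_comorbid",
    "discharged_healthy",
    "discharged_comorbid",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one simulation experiment (defaults = study setup)."""

    replications: int = 10_000
    horizon: int = 3
    beds: int = 60
    initial_demand: int = 70
    queue_length: int = 10
    comorbid_share: float = 0.7
    misestimation: float = 1.0
    policies: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    mix: Optional[PopulationMix] = None
    master_seed: int = 0
    random_init_from_demand: bool = False

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.beds < 1:
            raise ValueError("beds must be >= 1")
        if self.misestimation <= 0:
            raise ValueError("misestimation must be > 0")
        if not 0.0 <= self.comorbid_share <= 1.0:
            raise ValueError("comorbid_share must be in [0, 1]")
        if any(p not in range(6) for p in self.policies) or not self.policies:
            raise ValueError("policies must be a non-empty subset of 0-5")
        if len(set(self.policies)) != len(self.policies):
            raise ValueError("duplicate policy ids")
        specs = [PolicySpec.from_id(p) for p in self.policies]
        needs_demand_pool = any(s.initial_mode in ("exante", "mixed") for s in specs)
        if (needs_demand_pool or self.random_init_from_demand) and (
            self.initial_demand < self.beds
        ):
            raise ValueError(
                f"initial_demand {self.initial_demand} must be >= beds {self.beds} "
                "for ex-ante or mixed initial allocation"
            )
        if self.horizon >= 1:
            if any(s.consecutive_mode == "random_replacement" for s in specs) and (
                self.queue_length < self.replace_count
            ):
                raise ValueError(
                    f"queue_length {self.queue_length} must be >= replace count "
                    f"{self.replace_count} for random replacement"
                )
            if self.queue_length < 0:
                raise ValueError("queue_length must be >= 0")
        if self.master_seed < 0:
            raise ValueError("master_seed must be >= 0")

    @property
    def replace_count(self) -> int:
        """Beds turned over per random-replacement step: 10 % of capacity."""
        return self.beds // 10

    @property
    def resolved_mix(self) -> PopulationMix:
        """The population mix with ``comorbid_share`` applied (authoritative)."""
        base = self.mix if self.mix is not None else default_population_mix()
        if base.share_comorbid != self.comorbid_share:
            base = replace(base, share_comorbid=self.comorbid_share)
        return base

    def policy_specs(self) -> list[PolicySpec]:
        return [PolicySpec.from_id(p) for p in self.policies]


@dataclass(frozen=True)
class TimePointMetrics:
    """Prospective-mortality metrics of one time point of one replication."""

    time: int
    total_mortality: float
    healthy_mortality: float
    comorbid_mortality: float
    treated_healthy: int
    treated_comorbid: int
    admitted_healthy: int
    admitted_comorbid: int
    discharged_healthy: int
    discharged_comorbid: int


def _rng(master_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, *keys)))


def demand_size(spec: PolicySpec, config: ExperimentConfig) -> int:
    """Initial demand pool size: exactly B for pure random initialization
    (unless configured to draw from the full demand), d otherwise."""
    if spec.initial_mode == "random" and not config.random_init_from_demand:
        return config.beds
    return config.initial_demand


def generate_demand(
    spec: PolicySpec, config: ExperimentConfig, rep_index: int
) -> Cohort:
    rng = _rng(
        config.master_seed,
        rep_index,
        _TAG_DEMAND,
        _INITIAL_MODE_CODE[spec.initial_mode],
        int(config.random_init_from_demand),
    )
    return generate_cohort(demand_size(spec, config), config.resolved_mix, rng)


def generate_queue(config: ExperimentConfig, rep_index: int, time: int) -> Cohort:
    rng = _rng(config.master_seed, rep_index, _TAG_QUEUE, time)
    return generate_cohort(
        config.queue_length,
        config.resolved_mix,
        rng,
        id_start=time * _QUEUE_ID_BLOCK,
    )


def _metrics(
    time: int,
    beds: int,
    cohort: Cohort,
    admitted_healthy: int,
    admitted_comorbid: int,
    discharged_healthy: int,
    discharged_comorbid: int,
) -> TimePointMetrics:
    comorbid = cohort.comorbid
    healthy = ~comorbid
    n_h = int(healthy.sum())
    n_v = int(comorbid.sum())
    deaths_h = int(cohort.y[healthy].sum())
    deaths_v = int(cohort.y[comorbid].sum())
    return TimePointMetrics(
        time=time,
        total_mortality=(deaths_h + deaths_v) / beds,
        healthy_mortality=deaths_h / n_h if n_h else math.nan,
        comorbid_mortality=deaths_v / n_v if n_v else math.nan,
        treated_healthy=n_h,
        treated_comorbid=n_v,
        admitted_healthy=admitted_healthy,
        admitted_comorbid=admitted_comorbid,
        discharged_healthy=discharged_healthy,
        discharged_comorbid=discharged_comorbid,
    )


def run_replication(
    spec: PolicySpec,
    config: ExperimentConfig,
    rep_index: int = 0,
    *,
    demand: Optional[Cohort] = None,
    queues: Optional[Sequence[Cohort]] = None,
) -> list[TimePointMetrics]:
    """One replication of one policy: T+1 time points of metrics.

    ``demand`` and ``queues`` may be supplied explicitly (shared caches in
    :func:`run_experiment`, or hand-built cohorts in tests); otherwise they
    are generated from the replication's named substreams.
    """
    e = config.misestimation
    if demand is None:
        demand = generate_demand(spec, config, rep_index)
    if queues is not None and len(queues) < config.horizon:
        raise ValueError(f"need {config.horizon} queues, got {len(queues)}")

    init_rng = _rng(
        config.master_seed,
        rep_index,
        _TAG_INIT_ALLOC,
        _INITIAL_MODE_CODE[spec.initial_mode],
    )
    result = initial_allocation(spec, demand, config.beds, e, init_rng)
    cohort = result.treated_cohort
    out = [
        _metrics(
            0,
            config.beds,
            cohort,
            admitted_healthy=int((~cohort.comorbid).sum()),
            admitted_comorbid=int(cohort.comorbid.sum()),
            discharged_healthy=0,
            discharged_comorbid=0,
        )
    ]

    for t in range(1, config.horizon + 1):
        queue = queues[t - 1] if queues is not None else generate_queue(config, rep_index, t)
        step_rng = _rng(
            config.master_seed,
            rep_index,
            _TAG_STEP,
            t,
            _CONSECUTIVE_MODE_CODE[spec.consecutive_mode],
        )
        prev_h = int((~cohort.comorbid).sum())
        prev_v = int(cohort.comorbid.sum())
        if spec.consecutive_mode == "random_replacement":
            result = step_random_replacement(
                cohort, queue, config.replace_count, step_rng
            )
        else:
            result = step_expost_triage(cohort, queue, config.beds, e, step_rng)
        cohort = result.treated_cohort
        # Queue-t ids live in their own block, so admissions are identifiable
        # from the id range; discharge counts follow by conservation.
        admitted_mask = cohort.ids >= t * _QUEUE_ID_BLOCK
        adm_h = int((~cohort.comorbid[admitted_mask]).sum())
        adm_v = int(cohort.comorbid[admitted_mask].sum())
        new_h = int((~cohort.comorbid).sum())
        new_v = int(cohort.comorbid.sum())
        out.append(
            _metrics(
                t,
                config.beds,
                cohort,
                admitted_healthy=adm_h,
                admitted_comorbid=adm_v,
                discharged_healthy=prev_h - (new_h - adm_h),
                discharged_comorbid=prev_v - (new_v - adm_v),
            )
        )
    return out


@dataclass
class ExperimentSummary:
    """Replication-level records plus per-policy × time-point summaries."""

    config: ExperimentConfig
    replications: pd.DataFrame
    summary: pd.DataFrame

    def values(self, policy: int, time: int, metric: str = "total_mortality") -> np.ndarray:
        """Replication values of one metric for one policy at one time point."""
        df = self.replications
        sel = df[(df["policy"] == policy) & (df["time"] == time)]
        return sel[metric].to_numpy()

    def mean(self, policy: int, time: int, metric: str = "total_mortality") -> float:
        return float(self.summary.loc[(policy, time), f"mean_{metric}"])

    def mortality_table(self, time: int) -> pd.DataFrame:
        """Mean mortalities at one time point in percent: group rows, policy columns."""
        rows = {}
        for group, metric in (
            ("all patients", "total_mortality"),
            ("without comorbidity", "healthy_mortality"),
            ("with comorbidity", "comorbid_mortality"),
        ):
            rows[group] = {
                f"policy_{p}": 100.0 * self.mean(p, time, metric)
                for p in self.config.policies
            }
        table = pd.DataFrame(rows).T
        table.index.name = "group"
        return table


def _summarize(replications: pd.DataFrame) -> pd.DataFrame:
    grouped = replications.groupby(["policy", "time"])
    pieces = {}
    for m in METRIC_FIELDS:
        pieces[f"mean_{m}"] = grouped[m].mean()
        pieces[f"sd_{m}"] = grouped[m].std(ddof=1).fillna(0.0)
    pieces["n_replications"] = grouped["replication"].count()
    pieces["n_missing_healthy"] = grouped["healthy_mortality"].apply(
        lambda s: int(s.isna().sum())
    )
    pieces["n_missing_comorbid"] = grouped["comorbid_mortality"].apply(
        lambda s: int(s.isna().sum())
    )
    return pd.DataFrame(pieces)


def run_experiment(config: ExperimentConfig) -> ExperimentSummary:
    """Run R independent replications for every requested policy.

    Demand pools and queues are shared across policies within a replication
    (common random numbers), which realizes the identical-initialization
    property for policy pairs sharing an initial mode.
    """
    specs = config.policy_specs()
    n_pol, R, n_t = len(specs), config.replications, config.horizon + 1
    store = {
        m: np.empty((n_pol, R, n_t), dtype=float) for m in METRIC_FIELDS
    }

    for rep in range(R):
        queues = [
            generate_queue(config, rep, t) for t in range(1, config.horizon + 1)
        ]
        demand_cache: dict[tuple[str, int], Cohort] = {}
        for j, spec in enumerate(specs):
            key = (spec.initial_mode, demand_size(spec, config))
            if key not in demand_cache:
                demand_cache[key] = generate_demand(spec, config, rep)
            metrics = run_replication(
                spec, config, rep, demand=demand_cache[key], queues=queues
            )
            for t, m in enumerate(metrics):
                for name in METRIC_FIELDS:
                    store[name][j, rep, t] = getattr(m, name)

    policy_col = np.repeat([s.policy_id for s in specs], R * n_t)
    rep_col = np.tile(np.repeat(np.arange(R), n_t), n_pol)
    time_col = np.tile(np.arange(n_t), n_pol * R)
    data = {"policy": policy_col, "replication": rep_col, "time": time_col}
    for name in METRIC_FIELDS:
        data[name] = store[name].ravel()
    replications = pd.DataFrame(data)
    count_cols = [m for m in METRIC_FIELDS if m.startswith(("treated", "admitted", "discharged"))]
    replications[count_cols] = replications[count_cols].astype(int)
    return ExperimentSummary(
        config=config, replications=replications, summary=_summarize(replications)
    )


def sensitivity_grid(
    base: ExperimentConfig,
    demands: Iterable[int],
    queues: Iterable[int],
    misestimations: Iterable[float],
) -> dict[tuple[int, int, float], ExperimentSummary]:
    """One experiment per (d, w, e) grid cell; infeasible cells are skipped.

    With a fixed master seed, cells differing only in e yield identical
    summaries: scaling every perceived probability by the same factor leaves
    all rankings, hence all allocations, unchanged.
    """
    out: dict[tuple[int, int, float], ExperimentSummary] = {}
    for d in demands:
        for w in queues:
            for e in misestimations:
                try:
                    config = replace(
                        base, initial_demand=d, queue_length=w, misestimation=e
                    )
                except ValueError as err:
                    logger.warning("skipping infeasible cell (d=%s, w=%s, e=%s): %s", d, w, e, err)
                    continue
                out[(d, w, e)] = run_experiment(config)
    return out
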