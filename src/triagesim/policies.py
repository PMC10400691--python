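"""The six ICU allocation policies.

Each policy combines an initial bed-assignment mode with a consecutive
reallocation mode:

====  =============================  ==========================
id    initial allocation             consecutive reallocation
====  =============================  ==========================
0     random                         random replacement
1     random                         ex-post triage
2     ex-ante triage                 random replacement
3     ex-ante triage                 ex-post triage
4     90 % random / 10 % ex-ante     random replacement
5     90 % random / 10 % ex-ante     ex-post triage
====  =============================  ==========================

Ex-ante triage fills empty beds with the patients of lowest perceived death
probability e*p.  Ex-post triage pools current bed-holders with the queue and
keeps the B lowest; a treated patient can lose the bed.  Random replacement
discharges floor(0.1*B) uniformly chosen bed-holders and admits as many
uniformly chosen queue members.  Ties in perceived probability are broken
uniformly at random from the step's stream (ties have measure zero for
continuous p, but the contract is total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import Cohort

__all__ = [
    "PolicySpec",
    "AllocationResult",
    "InfeasibleDemandError",
    "StepError",
    "POLICY_TABLE",
    "initial_allocation",
    "step_random_replacement",
    "step_expost_triage",
]

INITIAL_MODES = ("random", "exante", "mixed")
CONSECUTIVE_MODES = ("random_replacement", "expost")

#: policy id -> (initial mode, consecutive mode); fixed and exhaustive.
POLICY_TABLE: dict[int, tuple[str, str]] = {
    0: ("random", "random_replacement"),
    1: ("random", "expost"),
    2: ("exante", "random_replacement"),
    3: ("exante", "expost"),
    4: ("mixed", "random_replacement"),
    5: ("mixed", "expost"),
}


class InfeasibleDemandError(ValueError):
    """Raised when demand cannot fill the beds as the policy requires."""


class StepError(ValueError):
    """Raised when a reallocation step's preconditions are violated."""


@dataclass(frozen=True)
class PolicySpec:
    """One allocation policy (see module table)."""

    policy_id: int
    initial_mode: str
    consecutive_mode: str
    mixed_random_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.policy_id not in POLICY_TABLE:
            raise ValueError(f"policy_id must be 0-5, got {self.policy_id}")
        expected = POLICY_TABLE[self.policy_id]
        if (self.initial_mode, self.consecutive_mode) != expected:
            raise ValueError(
                f"policy {self.policy_id} is {expected}, got "
                f"({self.initial_mode!r}, {self.consecutive_mode!r})"
            )
        if not 0.0 <= self.mixed_random_fraction <= 1.0:
            raise ValueError("mixed_random_fraction must be in [0, 1]")

    @classmethod
    def from_id(cls, policy_id: int, mixed_random_fraction: float = 0.9) -> "PolicySpec":
        initial, consecutive = POLICY_TABLE[policy_id]
        return cls(
            policy_id=policy_id,
            initial_mode=initial,
            consecutive_mode=consecutive,
            mixed_random_fraction=mixed_random_fraction,
        )


@dataclass(frozen=True)
class AllocationResult:
    """Outcome of one allocation step.

    ``treated`` always has exactly B members and equals
    (previous treated \\ discharged) ∪ admitted.  ``treated_cohort`` carries
    the post-step bed-holders with their attributes for metric computation.
    """

    treated: frozenset
    discharged: frozenset
    admitted: frozenset
    denied: frozenset
    treated_cohort: Cohort = field(compare=False, repr=False)


def _triage_order(p: np.ndarray, e: float, rng: np.random.Generator) -> np.ndarray:
    """Indices sorted by perceived probability e*p, random uniform tie-break.

    The tie-break uniforms are drawn before scaling and independently of e,
    so identical streams give identical orders for every e > 0.
    """
    if e <= 0:
        raise ValueError(f"misestimation factor e must be > 0, got {e}")
    tiebreak = rng.random(p.size)
    return np.lexsort((tiebreak, e * p))


def _ids(cohort: Cohort, idx: np.ndarray) -> frozenset:
    return frozenset(int(i) for i in cohort.ids[idx])


def initial_allocation(
    spec: PolicySpec,
    demand: Cohort,
    bed_count: int,
    e: float,
    rng: np.random.Generator,
) -> AllocationResult:
    """Fill an empty ICU from the initial demand, per the policy's initial mode.

    random: B patients chosen uniformly (all of them when demand == B).
    exante: the B patients with lowest perceived death probability e*p.
    mixed: floor(f*B) beds filled uniformly at random, the rest by lowest
    e*p among the not-yet-admitted demanders.
    """
    n = len(demand)
    if n < bed_count:
        raise InfeasibleDemandError(
            f"demand {n} cannot fill {bed_count} beds"
        )
    if spec.initial_mode == "random":
        if n == bed_count:
            chosen = np.arange(n)
        else:
            chosen = rng.choice(n, size=bed_count, replace=False)
    elif spec.initial_mode == "exante":
        chosen = _triage_order(demand.p, e, rng)[:bed_count]
    elif spec.initial_mode == "mixed":
        n_random = int(np.floor(spec.mixed_random_fraction * bed_count))
        random_part = rng.choice(n, size=n_random, replace=False)
        remaining = np.setdiff1d(np.arange(n), random_part, assume_unique=False)
        rest = demand.take(remaining)
        order = _triage_order(rest.p, e, rng)
        triage_part = remaining[order[: bed_count - n_random]]
        chosen = np.concatenate([random_part, triage_part])
    else:  # pragma: no cover - PolicySpec validates
        raise ValueError(f"unknown initial mode {spec.initial_mode!r}")

    chosen = np.sort(chosen)
    denied = np.setdiff1d(np.arange(n), chosen, assume_unique=False)
    treated_cohort = demand.take(chosen)
    treated = _ids(demand, chosen)
    return AllocationResult(
        treated=treated,
        discharged=frozenset(),
        admitted=treated,
        denied=_ids(demand, denied),
        treated_cohort=treated_cohort,
    )


def step_random_replacement(
    treated: Cohort,
    queue: Cohort,
    replace_count: int,
    rng: np.random.Generator,
) -> AllocationResult:
    """Discharge ``replace_count`` uniformly chosen bed-holders, admit as many
    uniformly chosen queue members; the rest of the queue is denied."""
    if replace_count < 0:
        raise StepError("replace_count must be >= 0")
    if replace_count > min(len(treated), len(queue)):
        raise StepError(
            f"replace_count {replace_count} exceeds treated ({len(treated)}) "
            f"or queue ({len(queue)})"
        )
    if replace_count == 0:
        return AllocationResult(
            treated=frozenset(int(i) for i in treated.ids),
            discharged=frozenset(),
            admitted=frozenset(),
            denied=frozenset(int(i) for i in queue.ids),
            treated_cohort=treated,
        )
    out_idx = np.sort(rng.choice(len(treated), size=replace_count, replace=False))
    in_idx = np.sort(rng.choice(len(queue), size=replace_count, replace=False))
    keep_idx = np.setdiff1d(np.arange(len(treated)), out_idx, assume_unique=True)
    denied_idx = np.setdiff1d(np.arange(len(queue)), in_idx, assume_unique=True)
    new_cohort = Cohort.concat(treated.take(keep_idx), queue.take(in_idx))
    return AllocationResult(
        treated=frozenset(int(i) for i in new_cohort.ids),
        discharged=_ids(treated, out_idx),
        admitted=_ids(queue, in_idx),
        denied=_ids(queue, denied_idx),
        treated_cohort=new_cohort,
    )


def step_expost_triage(
    treated: Cohort,
    queue: Cohort,
    bed_count: int,
    e: float,
    rng: np.random.Generator,
) -> AllocationResult:
    """Ex-post triage: pool bed-holders and queue, keep the B lowest e*p.

    Displaced bed-holders are discharged; queue members not selected are
    denied.  With an empty queue the cohort is unchanged (the tie-break
    stream is still consumed, keeping stream positions mode-independent).
    """
    if len(treated) != bed_count:
        raise StepError(f"expected {bed_count} bed-holders, got {len(treated)}")
    pool = Cohort.concat(treated, queue)
    order = _triage_order(pool.p, e, rng)
    keep = np.sort(order[:bed_count])
    drop = np.sort(order[bed_count:])
    new_cohort = pool.take(keep)
    discharged_idx = drop[drop < len(treated)]
    denied_idx = drop[drop >= len(treated)]
    admitted_idx = keep[keep >= len(treated)]
    return AllocationResult(
        treated=frozenset(int(i) for i in new_cohort.ids),
        discharged=_ids(pool, discharged_idx),
        admitted=_ids(pool, admitted_idx),
        denied=_ids(pool, denied_idx),
        treated_cohort=new_cohort,
    )
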