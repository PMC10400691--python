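"""Allocation policies: selection rules, bookkeeping algebra, invariances."""

import numpy as np
import pytest

from triagesim.policies import (
    POLICY_TABLE,
    InfeasibleDemandError,
    PolicySpec,
    StepError,
    initial_allocation,
    step_expost_triage,
    step_random_replacement,
)
from triagesim.population import default_population_mix, generate_cohort

from conftest import make_cohort


def random_cohort(n, seed, id_start=0):
    mix = default_population_mix()
    return generate_cohort(n, mix, np.random.default_rng(seed), id_start=id_start)


class TestPolicySpec:
    def test_table_mapping_fixed(self):
        assert POLICY_TABLE == {
            0: ("random", "random_replacement"),
            1: ("random", "expost"),
            2: ("exante", "random_replacement"),
            3: ("exante", "expost"),
            4: ("mixed", "random_replacement"),
            5: ("mixed", "expost"),
        }
        for pid in range(6):
            spec = PolicySpec.from_id(pid)
            assert (spec.initial_mode, spec.consecutive_mode) == POLICY_TABLE[pid]

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            PolicySpec(policy_id=0, initial_mode="exante", consecutive_mode="expost")


class TestInitialAllocation:
    def test_exante_takes_lowest_probabilities(self, rng):
        """Brute-force sort oracle at the study's printed size (70 demand, 60 beds)."""
        demand = random_cohort(70, seed=100)
        spec = PolicySpec.from_id(2)
        result = initial_allocation(spec, demand, 60, 1.0, rng)
        order = np.argsort(demand.p)
        expected = frozenset(int(i) for i in demand.ids[order[:60]])
        assert result.treated == expected
        assert result.treated_cohort.p.max() < demand.p[order[60:]].min()

    def test_demand_equals_beds_all_treated(self, rng):
        demand = random_cohort(60, seed=101)
        for pid in (0, 2):
            result = initial_allocation(PolicySpec.from_id(pid), demand, 60, 1.0, rng)
            assert result.treated == frozenset(int(i) for i in demand.ids)
            assert result.denied == frozenset()

    def test_mixed_fills_54_random_6_triage_slots(self):
        """54 random beds plus 6 triage beds: the 6 lowest-p demanders are
        always treated (randomly admitted, or else among the 16 remaining
        candidates for the 6 triage slots)."""
        demand = random_cohort(70, seed=102)
        six_lowest = frozenset(int(i) for i in demand.ids[np.argsort(demand.p)[:6]])
        for seed in range(10):
            rng = np.random.default_rng(seed)
            result = initial_allocation(PolicySpec.from_id(4), demand, 60, 1.0, rng)
            assert len(result.treated) == 60
            assert len(result.denied) == 10
            assert six_lowest <= result.treated

    def test_infeasible_demand(self, rng):
        demand = random_cohort(50, seed=103)
        with pytest.raises(InfeasibleDemandError):
            initial_allocation(PolicySpec.from_id(2), demand, 60, 1.0, rng)

    def test_bookkeeping_algebra(self, rng):
        demand = random_cohort(70, seed=104)
        for pid in range(6):
            result = initial_allocation(PolicySpec.from_id(pid), demand, 60, 1.0, rng)
            assert len(result.treated) == 60
            assert result.admitted == result.treated
            assert result.discharged == frozenset()
            assert result.treated | result.denied == frozenset(int(i) for i in demand.ids)
            assert not (result.treated & result.denied)


class TestRandomReplacement:
    def test_counts_at_study_size(self, rng):
        treated = random_cohort(60, seed=105)
        queue = random_cohort(10, seed=106, id_start=1000)
        result = step_random_replacement(treated, queue, 6, rng)
        assert len(result.discharged) == 6
        assert len(result.admitted) == 6
        assert len(result.denied) == 4
        assert len(result.treated) == 60

    def test_zero_replacement_keeps_cohort(self, rng):
        treated = random_cohort(60, seed=107)
        queue = random_cohort(10, seed=108, id_start=1000)
        result = step_random_replacement(treated, queue, 0, rng)
        assert result.treated == frozenset(int(i) for i in treated.ids)
        assert result.denied == frozenset(int(i) for i in queue.ids)

    def test_full_queue_admitted(self, rng):
        treated = random_cohort(60, seed=109)
        queue = random_cohort(5, seed=110, id_start=1000)
        result = step_random_replacement(treated, queue, 5, rng)
        assert result.admitted == frozenset(int(i) for i in queue.ids)

    def test_precondition_violation(self, rng):
        treated = random_cohort(60, seed=111)
        queue = random_cohort(4, seed=112, id_start=1000)
        with pytest.raises(StepError):
            step_random_replacement(treated, queue, 6, rng)


class TestExpostTriage:
    def test_keeps_lowest_probabilities(self, rng):
        """Brute-force sort oracle on the 60 + 10 pool."""
        treated = random_cohort(60, seed=113)
        queue = random_cohort(10, seed=114, id_start=1000)
        result = step_expost_triage(treated, queue, 60, 1.0, rng)
        pool_p = np.concatenate([treated.p, queue.p])
        pool_ids = np.concatenate([treated.ids, queue.ids])
        order = np.argsort(pool_p)
        assert result.treated == frozenset(int(i) for i in pool_ids[order[:60]])
        assert result.treated_cohort.p.max() < pool_p[order[60:]].min()

    def test_empty_queue_keeps_cohort(self, rng):
        treated = random_cohort(60, seed=115)
        queue = random_cohort(1, seed=116, id_start=1000).take(np.array([], dtype=int))
        result = step_expost_triage(treated, queue, 60, 1.0, rng)
        assert result.treated == frozenset(int(i) for i in treated.ids)

    def test_better_queue_fully_admitted(self, rng):
        treated = make_cohort(ids=range(5), p=[0.5, 0.6, 0.7, 0.8, 0.9])
        queue = make_cohort(ids=range(100, 103), p=[0.1, 0.2, 0.3])
        result = step_expost_triage(treated, queue, 5, 1.0, rng)
        assert result.admitted == {100, 101, 102}
        assert result.discharged == {2, 3, 4}  # the three highest-p bed-holders

    def test_cohort_update_algebra(self, rng):
        treated = random_cohort(60, seed=117)
        queue = random_cohort(10, seed=118, id_start=1000)
        result = step_expost_triage(treated, queue, 60, 1.0, rng)
        prev = frozenset(int(i) for i in treated.ids)
        assert result.treated == (prev - result.discharged) | result.admitted
        assert result.discharged <= prev
        assert result.admitted <= frozenset(int(i) for i in queue.ids)
        assert not (result.admitted & result.discharged)


class TestInvariances:
    def test_bed_conservation_randomized(self):
        rng = np.random.default_rng(500)
        for trial in range(20):
            b = int(rng.integers(2, 40))
            n = int(rng.integers(b, b + 30))
            w = int(rng.integers(1, 20))
            demand = random_cohort(n, seed=600 + trial)
            queue = random_cohort(w, seed=700 + trial, id_start=10_000)
            for pid in range(6):
                spec = PolicySpec.from_id(pid)
                res = initial_allocation(spec, demand, b, 1.0, rng)
                assert len(res.treated) == b
                if spec.consecutive_mode == "expost":
                    step = step_expost_triage(res.treated_cohort, queue, b, 1.0, rng)
                else:
                    rc = min(b // 10, w)
                    step = step_random_replacement(res.treated_cohort, queue, rc, rng)
                assert len(step.treated) == b
                assert step.treated == (res.treated - step.discharged) | step.admitted

    def test_exact_scale_invariance_in_e(self):
        """Uniform misestimation cannot change any allocation."""
        demand = random_cohort(70, seed=801)
        queue = random_cohort(10, seed=802, id_start=1000)
        for pid in range(6):
            spec = PolicySpec.from_id(pid)
            outcomes = []
            for e in (0.9, 1.0, 1.1):
                rng = np.random.default_rng(99)
                res = initial_allocation(spec, demand, 60, e, rng)
                if spec.consecutive_mode == "expost":
                    step = step_expost_triage(res.treated_cohort, queue, 60, e, rng)
                else:
                    step = step_random_replacement(res.treated_cohort, queue, 6, rng)
                outcomes.append((res.treated, step.treated, step.admitted, step.discharged))
            assert outcomes[0] == outcomes[1] == outcomes[2]

    def test_expost_never_worse_than_random_step(self):
        """On identical inputs the ex-post cohort's summed p is minimal."""
        for trial in range(10):
            treated = random_cohort(60, seed=900 + trial)
            queue = random_cohort(10, seed=950 + trial, id_start=1000)
            rng1 = np.random.default_rng(trial)
            rng2 = np.random.default_rng(trial)
            expost = step_expost_triage(treated, queue, 60, 1.0, rng1)
            random_step = step_random_replacement(treated, queue, 6, rng2)
            assert expost.treated_cohort.p.sum() <= random_step.treated_cohort.p.sum()
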