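"""Validation statistics over replication-level mortalities.

A thin convenience over standard tests: one-way ANOVA across policies on the
per-replication mortality values at a fixed time point, followed by all-pairs
post-hoc comparisons (Tukey HSD by default, Bonferroni-adjusted Welch t-tests
as an option).  Expected pattern at t = 0: policy pairs sharing an initial
allocation mode — (0,1), (2,3), (4,5) — are not significantly different,
everything else is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PolicyComparison", "compare_policies", "mortality_by_policy"]


@dataclass
class PolicyComparison:
    """Omnibus ANOVA plus the all-pairs post-hoc table."""

    time: Optional[int]
    means: dict[int, float]
    sds: dict[int, float]
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame
    method: str
    alpha: float
    degenerate: bool

    def nonsignificant_pairs(self) -> set[tuple[int, int]]:
        mask = ~self.pairwise["significant"]
        return {
            (int(r["policy_a"]), int(r["policy_b"]))
            for _, r in self.pairwise[mask].iterrows()
        }


def mortality_by_policy(
    replications: pd.DataFrame, time: int, metric: str = "total_mortality"
) -> dict[int, np.ndarray]:
    """Per-policy replication values of one metric at one time point."""
    sel = replications[replications["time"] == time]
    return {
        int(p): g[metric].dropna().to_numpy() for p, g in sel.groupby("policy")
    }


def compare_policies(
    per_run_mortality: Mapping[int, Sequence[float]],
    alpha: float = 0.05,
    method: str = "tukey",
    time: Optional[int] = None,
) -> PolicyComparison:
    """One-way ANOVA across policies plus multiplicity-adjusted pairwise tests.

    Degenerate inputs (no variation anywhere) are reported as F = 0, p = 1
    with no significant pairs rather than raising.
    """
    if method not in ("tukey", "bonferroni"):
        raise ValueError(f"method must be 'tukey' or 'bonferroni', got {method!r}")
    policies = sorted(per_run_mortality)
    if len(policies) < 2:
        raise ValueError("need at least two policies")
    groups = [np.asarray(per_run_mortality[p], dtype=float) for p in policies]
    if any(g.size < 2 for g in groups):
        raise ValueError("need at least two replications per policy")

    means = {p: float(g.mean()) for p, g in zip(policies, groups)}
    sds = {p: float(g.std(ddof=1)) for p, g in zip(policies, groups)}
    pairs = list(itertools.combinations(range(len(policies)), 2))

    degenerate = all(np.ptp(g) == 0.0 for g in groups) and (
        len({g[0] for g in groups}) == 1
    )
    if degenerate:
        f_stat, p_val = 0.0, 1.0
        rows = [
            {
                "policy_a": policies[i],
                "policy_b": policies[j],
                "mean_diff": 0.0,
                "p_adj": 1.0,
                "significant": False,
            }
            for i, j in pairs
        ]
        return PolicyComparison(
            time=time,
            means=means,
            sds=sds,
            anova_f=f_stat,
            anova_p=p_val,
            pairwise=pd.DataFrame(rows),
            method=method,
            alpha=alpha,
            degenerate=True,
        )

    f_stat, p_val = stats.f_oneway(*groups)
    rows = []
    if method == "tukey":
        res = stats.tukey_hsd(*groups)
        for i, j in pairs:
            p_adj = float(res.pvalue[i, j])
            rows.append(
                {
                    "policy_a": policies[i],
                    "policy_b": policies[j],
                    "mean_diff": means[policies[j]] - means[policies[i]],
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    else:
        m = len(pairs)
        for i, j in pairs:
            gi, gj = groups[i], groups[j]
            if np.ptp(gi) == 0 and np.ptp(gj) == 0:
                p_adj = 1.0 if gi[0] == gj[0] else 0.0
            else:
                _, p_raw = stats.ttest_ind(gi, gj, equal_var=False)
                p_adj = min(1.0, float(p_raw) * m)
            rows.append(
                {
                    "policy_a": policies[i],
                    "policy_b": policies[j],
                    "mean_diff": means[policies[j]] - means[policies[i]],
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return PolicyComparison(
        time=time,
        means=means,
        sds=sds,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        pairwise=pd.DataFrame(rows),
        method=method,
        alpha=alpha,
        degenerate=False,
    )
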