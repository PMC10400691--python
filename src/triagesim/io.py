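"""Result serialization: replication table, summary tables, run manifest."""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import __version__
from .config import config_to_dict
from .engine import ExperimentConfig, ExperimentSummary
from .policies import POLICY_TABLE

__all__ = ["RunManifest", "write_results", "read_results"]

_FLOAT_FORMAT = "%.17g"  # full double precision for exact round trips


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bitwise: resolved config,
    package version, master seed and the per-policy substream derivation."""

    config: dict[str, Any]
    version: str = __version__
    master_seed: int = 0
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    substreams: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def for_run(cls, config: ExperimentConfig) -> "RunManifest":
        streams = {
            f"policy_{p}": {
                "initial_mode": POLICY_TABLE[p][0],
                "consecutive_mode": POLICY_TABLE[p][1],
                "demand": [config.master_seed, "<replication>", 1, "<initial-mode-code>"],
                "initial_allocation": [config.master_seed, "<replication>", 2, "<initial-mode-code>"],
                "queue": [config.master_seed, "<replication>", 3, "<time>"],
                "step": [config.master_seed, "<replication>", 4, "<time>", "<consecutive-mode-code>"],
            }
            for p in config.policies
        }
        return cls(
            config=config_to_dict(config),
            master_seed=config.master_seed,
            substreams={
                "note": "seed-sequence entropy tuples; mode codes: random=0, "
                "exante=1, mixed=2 / random_replacement=0, expost=1",
                **streams,
            },
        )


def write_results(
    summary: ExperimentSummary, manifest: RunManifest, out_dir: str
) -> dict[str, str]:
    """Write replication-level CSV, summary CSVs and the JSON manifest.

    Returns the mapping of artifact name to path.  Floats are written at full
    precision so a read-back reproduces every value exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "replications": os.path.join(out_dir, "replications.csv"),
        "summary_stats": os.path.join(out_dir, "summary_stats.csv"),
        "mortality_summary": os.path.join(out_dir, "mortality_summary.csv"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    summary.replications.to_csv(paths["replications"], index=False, float_format=_FLOAT_FORMAT)
    summary.summary.to_csv(paths["summary_stats"], float_format=_FLOAT_FORMAT)

    # Mortality overview in percent: one block per time point, group rows,
    # policy columns (the layout results tables are usually read in).
    blocks = []
    for t in range(summary.config.horizon + 1):
        table = summary.mortality_table(t)
        table.insert(0, "time", t)
        blocks.append(table.reset_index())
    pd.concat(blocks, ignore_index=True).to_csv(
        paths["mortality_summary"], index=False, float_format=_FLOAT_FORMAT
    )

    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest.__dict__, fh, indent=2)
        fh.write("\n")
    return paths


def read_results(out_dir: str) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    """Read back (replications, summary_stats, manifest) from ``out_dir``."""
    replications = pd.read_csv(os.path.join(out_dir, "replications.csv"))
    summary_stats = pd.read_csv(
        os.path.join(out_dir, "summary_stats.csv"), index_col=["policy", "time"]
    )
    with open(os.path.join(out_dir, "manifest.json"), "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    return replications, summary_stats, manifest
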