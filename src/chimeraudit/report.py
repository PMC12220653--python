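"""Run summaries written beside primary outputs.

The summary records what was assessed, the resolved configuration
(CLI flag > config file > built-in default), and input checksums, so a
scan is reproducible from its own paper trail. Timestamps live only here,
never in the primary TSVs, keeping those byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from .chimera_detect import ChimeraCall, FilterConfig


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_run_summary(
    calls: list[ChimeraCall],
    cfg: FilterConfig,
    n_skipped_no_hits: int,
    inputs: dict[str, str | Path] | None = None,
) -> dict:
    rejected: dict[str, int] = {}
    n_candidates = 0
    for c in calls:
        if c.verdict == "candidate":
            n_candidates += 1
        else:
            rejected[c.failed_filter] = rejected.get(c.failed_filter, 0) + 1
    summary = {
        "counts": {
            "assessed": len(calls),
            "skipped_no_hits": n_skipped_no_hits,
            "candidates": n_candidates,
            "rejected_per_filter": rejected,
        },
        "config": dataclasses.asdict(cfg),
        "input_checksums": {
            name: sha256_file(p) for name, p in (inputs or {}).items()
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    assert summary["counts"]["assessed"] == n_candidates + sum(rejected.values())
    return summary


def write_run_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
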