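"""Per-run enrichment-efficiency QC on PSM tables.

The headline metric is the percentage of PSMs carrying at least one
methylated lysine; enriched runs should exceed a few percent while
unenriched runs sit below a fraction of a percent, and the dominant methyl
state should match the antibody's target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .kopl_design import MethylState
from .methylome_catalog import METHYL_TYPES, PeptideRecord


@dataclass(frozen=True)
class RunQc:
    run_label: str
    strategy_label: str
    total_psms: int
    methyl_psms: dict  # state value -> PSM count carrying that state
    percent_methyl: float  # NaN when the run has zero PSMs
    dominant_state: MethylState | None


def psm_methyl_fraction(records: Sequence[PeptideRecord]) -> list[RunQc]:
    """Per-run percent of PSM rows with >= 1 methyl mod, with state breakdown.

    A PSM carrying two differently-stated methyl lysines counts once toward
    ``percent_methyl`` and once in each state's breakdown.  Runs with zero
    PSM rows are reported with NaN percent rather than dropped.
    """
    runs: dict[str, dict] = {}
    for rec in records:
        entry = runs.setdefault(rec.run_label, {
            "strategy": rec.strategy_label,
            "total": 0,
            "methyl": 0,
            "states": {s: 0 for s in sorted(METHYL_TYPES)},
        })
        if not rec.is_psm:
            continue
        entry["total"] += 1
        states_here = {m.type for m in rec.methyl_mods()}
        if states_here:
            entry["methyl"] += 1
            for s in states_here:
                entry["states"][s] += 1
    out = []
    for run_label in sorted(runs):
        entry = runs[run_label]
        total = entry["total"]
        pct = 100.0 * entry["methyl"] / total if total else float("nan")
        states = entry["states"]
        if entry["methyl"]:
            dominant = MethylState(max(sorted(states), key=lambda s: states[s]))
        else:
            dominant = None
        out.append(RunQc(
            run_label=run_label,
            strategy_label=entry["strategy"],
            total_psms=total,
            methyl_psms=dict(states),
            percent_methyl=pct,
            dominant_state=dominant,
        ))
    return out


def qc_frame(qcs: Sequence[RunQc]) -> pd.DataFrame:
    rows = [
        (q.run_label, q.strategy_label, q.total_psms,
         q.methyl_psms.get("me1", 0), q.methyl_psms.get("me2", 0),
         q.methyl_psms.get("me3", 0), q.percent_methyl,
         q.dominant_state.value if q.dominant_state else "")
        for q in qcs
    ]
    return pd.DataFrame(rows, columns=[
        "run_label", "strategy_label", "total_psms",
        "me1_psms", "me2_psms", "me3_psms", "percent_methyl", "dominant_state",
    ])
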