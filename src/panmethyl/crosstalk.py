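"""Proximity of methyl sites to other PTMs, and within-peptide co-occurrence.

For each methyl site the reference catalog is searched for acetylation,
sumoylation, ubiquitylation and phosphorylation within a fixed residue
window; offset 0 means the same residue (direct competition).  Offsets are
unsigned by default (a hit at -d or +d counts at offset d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .methylome_catalog import PeptideRecord, ReferenceCatalog

DEFAULT_WINDOW = 9

#: PTM types considered for crosstalk, in reporting order.
CROSSTALK_TYPES = (
    "acetyl", "sumo", "ubiquityl", "phospho-S", "phospho-T", "phospho-Y",
)

PHOSPHO_TYPES = frozenset({"phospho-S", "phospho-T", "phospho-Y"})


@dataclass
class ProximityProfile:
    """Per-type, per-offset percentages of methyl sites with a nearby PTM.

    ``percentages`` rows are PTM types, columns offsets 0..window (unsigned)
    or -window..window (signed).  ``overall_within_window`` is the percentage
    of methyl sites with at least one listed PTM anywhere in the window — a
    site with hits at several offsets or of several types counts once.
    """

    percentages: pd.DataFrame
    window: int
    n_sites: int
    overall_within_window: float
    signed: bool = False

    def frame(self) -> pd.DataFrame:
        rows = [
            (ptm, off, float(self.percentages.at[ptm, off]))
            for ptm in self.percentages.index
            for off in self.percentages.columns
        ]
        return pd.DataFrame(rows, columns=["ptm_type", "offset", "percentage"])


def proximity_profile(me_sites: Sequence, reference: ReferenceCatalog,
                      window: int = DEFAULT_WINDOW,
                      ptm_types: Sequence[str] = CROSSTALK_TYPES,
                      signed: bool = False) -> ProximityProfile:
    """Percentage of methyl sites with each PTM type at each offset.

    ``me_sites`` accepts objects with accession/position attributes or
    (accession, position) tuples.  Matching is within one accession only;
    duplicated reference records collapse (the catalog dedups on
    (accession, position, ptm_type)).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sites = [
        (s.accession, s.position) if hasattr(s, "accession") else (s[0], int(s[1]))
        for s in me_sites
    ]
    n_sites = len(sites)
    offsets = (
        list(range(-window, window + 1)) if signed else list(range(0, window + 1))
    )
    ref = reference.records[reference.records["ptm_type"].isin(set(ptm_types))]
    by_acc: dict[str, dict[int, set[str]]] = {}
    for acc, pos, ptm in zip(ref["accession"], ref["position"].astype(int), ref["ptm_type"]):
        by_acc.setdefault(acc, {}).setdefault(pos, set()).add(ptm)

    hit_counts = pd.DataFrame(0, index=list(ptm_types), columns=offsets)
    n_any = 0
    for acc, pos in sites:
        positions = by_acc.get(acc)
        hit_any = False
        if positions:
            for off in offsets:
                if signed:
                    candidates = [pos + off]
                else:
                    candidates = [pos + off] if off == 0 else [pos - off, pos + off]
                types_here = set()
                for p in candidates:
                    types_here |= positions.get(p, set())
                for ptm in types_here:
                    hit_counts.at[ptm, off] += 1
                    hit_any = True
        if hit_any:
            n_any += 1
    if n_sites:
        percentages = 100.0 * hit_counts / n_sites
        overall = 100.0 * n_any / n_sites
    else:
        percentages = hit_counts.astype(float) * np.nan
        overall = float("nan")
    return ProximityProfile(
        percentages=percentages, window=window, n_sites=n_sites,
        overall_within_window=overall, signed=signed,
    )


def overall_within_window(profile: ProximityProfile) -> float:
    """Percentage of methyl sites with >= 1 listed PTM within the window."""
    return profile.overall_within_window


def peptide_cooccurrence(peptides: Sequence[PeptideRecord]) -> pd.DataFrame:
    """Percent of methylated peptides also carrying phosphorylation, per strategy.

    Peptides are deduplicated on (accession, sequence, protein_start) within
    each strategy so repeated PSMs of one peptide count once.  Strategies
    with zero methyl peptides report NaN (undefined), not 0.
    """
    per_strategy: dict[str, dict[tuple, bool]] = {}
    for rec in peptides:
        if not rec.methyl_mods():
            continue
        key = (rec.accession, rec.sequence, rec.protein_start)
        has_phospho = any(m.type.startswith("phospho") for m in rec.mods)
        bucket = per_strategy.setdefault(rec.strategy_label, {})
        bucket[key] = bucket.get(key, False) or has_phospho
    strategies = sorted({rec.strategy_label for rec in peptides})
    rows = []
    for strategy in strategies:
        bucket = per_strategy.get(strategy, {})
        n_methyl = len(bucket)
        n_both = sum(bucket.values())
        pct = 100.0 * n_both / n_methyl if n_methyl else float("nan")
        rows.append((strategy, n_methyl, n_both, pct))
    return pd.DataFrame(rows, columns=["strategy_label", "n_methyl_peptides",
                                       "n_with_phospho", "percent_cooccurrence"])
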