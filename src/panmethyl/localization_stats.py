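"""Compartment-enrichment comparison via the two-proportion Z-test.

Proteins are assigned to every subcellular compartment scoring at or above a
threshold (default 3).  For each compartment the proportion of methylome
proteins localizing there is compared against the proportion of all proteome
proteins with a pooled-variance two-proportion Z statistic and a two-sided
normal p value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_SCORE = 3.0


def assign_compartments(table: pd.DataFrame,
                        min_score: float = DEFAULT_MIN_SCORE) -> dict[str, set[str]]:
    """Map accession -> set of compartments scoring >= ``min_score``.

    Multi-membership is allowed; proteins present in the table but below
    threshold everywhere map to an empty set (they stay in denominators).
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    required = {"accession", "compartment", "score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"compartment table missing columns: {sorted(missing)}")
    if (table["score"] < 0).any():
        raise ValueError("compartment scores must be >= 0")
    out: dict[str, set[str]] = {acc: set() for acc in table["accession"]}
    passing = table[table["score"] >= min_score]
    for acc, comp in zip(passing["accession"], passing["compartment"]):
        out[acc].add(comp)
    return out


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion Z statistic and two-sided p value.

    Positive z means group 1 has the higher proportion.  Equal proportions
    give z = 0, p = 1 (including the degenerate all-or-none pooled cases).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= k <= n and n > 0 for both groups")
    p1, p2 = k1 / n1, k2 / n2
    if p1 == p2:
        return 0.0, 1.0
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:  # pooled 0 or 1 with unequal proportions cannot occur
        return 0.0, 1.0  # pragma: no cover
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class CompartmentComparison:
    table: pd.DataFrame  # one row per compartment
    skipped: list[str]  # compartments with zero members in both groups
    alpha: float


def compare_proportions(methylome: Iterable[str], proteome: Iterable[str],
                        assignments: Mapping[str, set[str]],
                        alpha: float = 0.05,
                        bonferroni: bool = False) -> CompartmentComparison:
    """Per-compartment two-proportion comparison of methylome vs proteome.

    Denominators are the full accession lists (n1 = |methylome|,
    n2 = |proteome|); proteins without any compartment assignment count in
    denominators only.  Compartments empty in both groups are skipped and
    reported.
    """
    methylome = list(dict.fromkeys(methylome))
    proteome = list(dict.fromkeys(proteome))
    n1, n2 = len(methylome), len(proteome)
    if n1 == 0 or n2 == 0:
        raise ValueError("both accession lists must be non-empty")
    compartments = sorted({c for comps in assignments.values() for c in comps})
    rows = []
    skipped = []
    for comp in compartments:
        k1 = sum(1 for a in methylome if comp in assignments.get(a, set()))
        k2 = sum(1 for a in proteome if comp in assignments.get(a, set()))
        if k1 == 0 and k2 == 0:
            skipped.append(comp)
            continue
        z, p = two_proportion_z(k1, n1, k2, n2)
        rows.append((comp, k1, n1, k2, n2, k1 / n1, k2 / n2, z, p))
    table = pd.DataFrame(rows, columns=[
        "compartment", "k1", "n1", "k2", "n2",
        "proportion_methylome", "proportion_proteome", "z", "p",
    ])
    threshold = alpha / len(table) if (bonferroni and len(table)) else alpha
    table["significant"] = table["p"] < threshold
    return CompartmentComparison(table=table, skipped=skipped, alpha=alpha)
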