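"""Site-level methylome construction and accounting.

PSM/peptide tables (one row per spectral match or peptide) are filtered on
methyl-localization probability, collapsed to unique protein sites, and
compared across enrichment strategies and against a reference PTM catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .kopl_design import MethylState

#: Modification labels treated as lysine methylation.
METHYL_TYPES = frozenset({"me1", "me2", "me3"})

#: Reference-catalog PTM labels treated as methylation for novelty purposes.
REFERENCE_METHYL_TYPES = METHYL_TYPES


@dataclass(frozen=True)
class Mod:
    """One modification on a peptide: 1-based residue index within the peptide."""

    residue_index: int
    type: str
    localization_probability: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.localization_probability <= 1.0):
            raise ValueError("localization_probability must be in [0, 1]")

    @property
    def is_methyl(self) -> bool:
        return self.type in METHYL_TYPES


@dataclass(frozen=True)
class PeptideRecord:
    """One row of a PSM/peptide table."""

    sequence: str
    mods: tuple[Mod, ...]
    accession: str
    protein_start: int  # 1-based position of peptide residue 1 in the protein
    run_label: str
    strategy_label: str
    is_psm: bool = True

    def __post_init__(self) -> None:
        for m in self.mods:
            if not (1 <= m.residue_index <= len(self.sequence)):
                raise ValueError(
                    f"mod index {m.residue_index} outside peptide of length {len(self.sequence)}"
                )

    def methyl_mods(self) -> tuple[Mod, ...]:
        return tuple(m for m in self.mods if m.is_methyl)


@dataclass
class MethylSite:
    """A unique (accession, position, state) methylation site with evidence."""

    accession: str
    position: int  # 1-based protein residue index
    state: MethylState
    evidence: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.accession, self.position, self.state.value)

    @property
    def strategies(self) -> frozenset[str]:
        return frozenset(strategy for (_, strategy) in self.evidence)

    @property
    def psm_count(self) -> int:
        return sum(self.evidence.values())


@dataclass(frozen=True)
class ReferenceCatalog:
    """PTM reference records: unique (accession, position, ptm_type)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"accession", "position", "ptm_type"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"reference missing columns: {sorted(missing)}")
        dedup = self.records.drop_duplicates(
            subset=["accession", "position", "ptm_type"]
        ).reset_index(drop=True)
        object.__setattr__(self, "records", dedup)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceCatalog":
        return cls(pd.read_csv(path, sep="\t", dtype={"accession": str, "ptm_type": str}))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def restrict(self, ptm_types: Iterable[str]) -> "ReferenceCatalog":
        keep = set(ptm_types)
        return ReferenceCatalog(self.records[self.records["ptm_type"].isin(keep)])

    def methyl_keys(self) -> set[tuple[str, int, str]]:
        sub = self.records[self.records["ptm_type"].isin(REFERENCE_METHYL_TYPES)]
        return set(zip(sub["accession"], sub["position"].astype(int), sub["ptm_type"]))


def filter_peptides(records: Sequence[PeptideRecord],
                    min_localization: float = 0.75) -> list[PeptideRecord]:
    """Drop methyl mods below the localization-probability threshold.

    Non-methyl mods are untouched.  Records losing all their methyl mods stay
    in the returned list (they still serve as QC denominators) but will not
    contribute sites.
    """
    if not (0.0 <= min_localization <= 1.0):
        raise ValueError("min_localization must be in [0, 1]")
    out = []
    for rec in records:
        kept = tuple(
            m for m in rec.mods
            if not m.is_methyl or m.localization_probability >= min_localization
        )
        out.append(rec if kept == rec.mods else replace(rec, mods=kept))
    return out


@dataclass
class SiteCallResult:
    sites: list[MethylSite]
    quarantined: pd.DataFrame  # sites whose mapped residue is not K

    def frame(self) -> pd.DataFrame:
        rows = [
            (s.accession, s.position, s.state.value,
             ";".join(sorted(s.strategies)), s.psm_count)
            for s in self.sites
        ]
        return pd.DataFrame(rows, columns=["accession", "position", "state",
                                           "strategies", "psm_count"])


def call_sites(records: Sequence[PeptideRecord],
               proteome: Mapping[str, str] | None = None) -> SiteCallResult:
    """Collapse filtered peptide records to unique methylation sites.

    Site position = protein_start + residue_index - 1.  Evidence (PSM counts)
    is aggregated per (run, strategy).  When a proteome is supplied, sites
    mapping to a non-lysine residue are quarantined into a mapping-error
    report instead of being dropped silently.
    """
    sites: dict[tuple[str, int, str], MethylSite] = {}
    bad_rows = []
    for rec in records:
        for mod in rec.methyl_mods():
            position = rec.protein_start + mod.residue_index - 1
            state = MethylState(mod.type)
            if proteome is not None:
                seq = proteome.get(rec.accession)
                mapped = (
                    seq[position - 1]
                    if seq is not None and 1 <= position <= len(seq)
                    else None
                )
                if mapped != "K":
                    bad_rows.append((rec.accession, position, state.value,
                                     rec.run_label, rec.strategy_label,
                                     mapped if mapped is not None else "out-of-range"))
                    continue
            key = (rec.accession, position, state.value)
            site = sites.get(key)
            if site is None:
                site = MethylSite(accession=rec.accession, position=position, state=state)
                sites[key] = site
            ev_key = (rec.run_label, rec.strategy_label)
            site.evidence[ev_key] = site.evidence.get(ev_key, 0) + 1
    quarantined = pd.DataFrame(
        bad_rows, columns=["accession", "position", "state", "run_label",
                           "strategy_label", "mapped_residue"]
    )
    ordered = sorted(sites.values(), key=lambda s: s.key)
    return SiteCallResult(sites=ordered, quarantined=quarantined)


def sites_from_frame(df: pd.DataFrame) -> list[MethylSite]:
    """Rebuild site objects from a site TSV frame.

    Run-level evidence is not stored in the TSV; each strategy in the
    semicolon-joined ``strategies`` column becomes one evidence entry with an
    empty run label.
    """
    sites = []
    for row in df.itertuples(index=False):
        strategies = str(getattr(row, "strategies", "") or "")
        evidence = {("", st): 1 for st in strategies.split(";") if st}
        sites.append(MethylSite(
            accession=row.accession, position=int(row.position),
            state=MethylState(row.state), evidence=evidence,
        ))
    return sites


def site_keys(sites: Iterable[MethylSite], collapse_state: bool = False) -> set[tuple]:
    """Unique site keys, with or without the methyl state."""
    if collapse_state:
        return {(s.accession, s.position) for s in sites}
    return {s.key for s in sites}


@dataclass
class OverlapTable:
    """Upset-style exact-intersection accounting over enrichment strategies."""

    exact_counts: dict[frozenset[str], int]
    marginals: dict[str, int]
    n_sites: int
    unique_fraction: float  # percent of sites seen by exactly one strategy

    def frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(sorted(combo)), len(combo), count)
            for combo, count in sorted(
                self.exact_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["combination", "degree", "count"])


def strategy_overlap(sites: Sequence[MethylSite]) -> OverlapTable:
    """Count sites detected by exactly each non-empty strategy combination."""
    strategies = sorted({st for s in sites for st in s.strategies})
    if len(strategies) < 2:
        raise InsufficientDataError(
            f"overlap requires >= 2 strategies, got {len(strategies)}"
        )
    exact: dict[frozenset[str], int] = {}
    marginals = {st: 0 for st in strategies}
    n_unique = 0
    for s in sites:
        combo = frozenset(s.strategies)
        exact[combo] = exact.get(combo, 0) + 1
        for st in combo:
            marginals[st] += 1
        if len(combo) == 1:
            n_unique += 1
    n_sites = len(sites)
    return OverlapTable(
        exact_counts=exact,
        marginals=marginals,
        n_sites=n_sites,
        unique_fraction=100.0 * n_unique / n_sites if n_sites else float("nan"),
    )


@dataclass
class NoveltyResult:
    annotated: pd.DataFrame  # per-site novel flag
    per_state: pd.DataFrame  # state, n_sites, n_novel, percent_novel
    percent_novel: float


def annotate_novelty(sites: Sequence[MethylSite], reference: ReferenceCatalog,
                     collapse_state: bool = False) -> NoveltyResult:
    """Tag each site novel/known against the reference methyl catalog.

    Known = (accession, position, state) is in the reference, or
    (accession, position) under the relaxed key (``collapse_state=True``).
    """
    ref_keys = reference.methyl_keys()
    if collapse_state:
        ref_lookup = {(a, p) for (a, p, _) in ref_keys}
    else:
        ref_lookup = ref_keys
    rows = []
    for s in sites:
        key = (s.accession, s.position) if collapse_state else s.key
        rows.append((s.accession, s.position, s.state.value, key not in ref_lookup))
    annotated = pd.DataFrame(rows, columns=["accession", "position", "state", "novel"])
    if annotated.empty:
        per_state = pd.DataFrame(columns=["state", "n_sites", "n_novel", "percent_novel"])
        return NoveltyResult(annotated, per_state, float("nan"))
    grouped = annotated.groupby("state", sort=True)["novel"]
    per_state = pd.DataFrame({
        "state": grouped.size().index,
        "n_sites": grouped.size().to_numpy(),
        "n_novel": grouped.sum().to_numpy(),
    })
    per_state["percent_novel"] = 100.0 * per_state["n_novel"] / per_state["n_sites"]
    overall = 100.0 * annotated["novel"].sum() / len(annotated)
    return NoveltyResult(annotated, per_state.reset_index(drop=True), overall)


@dataclass
class MergedMethylome:
    catalog: pd.DataFrame  # accession, position, state, provenance
    n_sites: int
    n_proteins: int


def merge_methylome(sites: Sequence[MethylSite],
                    reference: ReferenceCatalog) -> MergedMethylome:
    """Union of called sites with the reference methyl catalog.

    Provenance per site: ``this-study``, ``reference``, or ``both``.
    """
    ours = {s.key for s in sites}
    theirs = reference.methyl_keys()
    rows = []
    for key in sorted(ours | theirs):
        if key in ours and key in theirs:
            prov = "both"
        elif key in ours:
            prov = "this-study"
        else:
            prov = "reference"
        rows.append((*key, prov))
    catalog = pd.DataFrame(rows, columns=["accession", "position", "state", "provenance"])
    return MergedMethylome(
        catalog=catalog,
        n_sites=len(catalog),
        n_proteins=catalog["accession"].nunique(),
    )


@dataclass
class PerProteinStats:
    counts: pd.Series  # events per protein
    fraction_1_to_3: float  # percent of methylated proteins with 1-3 events
    r2: float
    n_proteins: int
    insufficient: bool = False


def per_protein_stats(sites: Sequence[MethylSite],
                      peptides: Sequence[PeptideRecord]) -> PerProteinStats:
    """Events-per-protein histogram and the events-vs-lysine-count r^2.

    The lysine count per protein is taken over the unique identified peptide
    sequences mapping to that protein (dedup on sequence + protein_start),
    mirroring "lysines in identified peptides" rather than whole-protein
    length.
    """
    counts = pd.Series(
        [s.accession for s in sites], dtype=object
    ).value_counts().sort_index()
    counts.name = "n_events"
    if counts.empty:
        return PerProteinStats(counts, float("nan"), float("nan"), 0, insufficient=True)
    frac = 100.0 * counts.between(1, 3).sum() / len(counts)

    lys: dict[str, int] = {}
    seen: set[tuple[str, str, int]] = set()
    for rec in peptides:
        key = (rec.accession, rec.sequence, rec.protein_start)
        if key in seen:
            continue
        seen.add(key)
        lys[rec.accession] = lys.get(rec.accession, 0) + rec.sequence.count("K")

    accs = [a for a in counts.index if a in lys]
    if len(accs) < 3:
        return PerProteinStats(counts, frac, float("nan"), len(counts), insufficient=True)
    x = np.array([counts[a] for a in accs], dtype=float)
    y = np.array([lys[a] for a in accs], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return PerProteinStats(counts, frac, float("nan"), len(counts), insufficient=True)
    r = float(np.corrcoef(x, y)[0, 1])
    return PerProteinStats(counts, frac, r * r, len(counts))
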