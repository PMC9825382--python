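"""Sequence-motif statistics around methylated lysines.

For each flank offset the per-amino-acid frequency in the site windows
(f_dataset) is compared to the frequency over all lysine windows of a
background protein set (f_background) as log2(f_dataset / f_background).
Cells never observed in the dataset are an explicit missing marker, not a
number; background zeros with positive dataset counts are flagged as
infinite enrichment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kopl_design import AA20, FLANK_OFFSETS, format_offset
from .selectivity_metrics import PAD_CHAR, extract_window

ROLE_DATASET = "dataset"
ROLE_BACKGROUND = "background"


@dataclass
class FrequencyTable:
    """Per-offset amino-acid counts and frequencies over 7-mer K windows.

    Rows are the 20 standard amino acids, columns the six flank offsets.
    Frequencies are normalized per offset over *observed* residues only:
    window positions lost to protein termini (padding) do not enter the
    denominator.
    """

    counts: pd.DataFrame
    n_windows: int
    role: str = ROLE_DATASET
    frequencies: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(
            index=list(AA20), columns=list(FLANK_OFFSETS)
        ).fillna(0).astype(int)
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.frequencies = self.counts / totals
        per_offset = self.frequencies.sum(axis=0)
        ok = (totals == 0) | np.isclose(per_offset, 1.0)
        if not ok.all():  # pragma: no cover - arithmetic guarantee
            raise ValueError("per-offset frequencies must sum to 1")

    @classmethod
    def from_windows(cls, windows: Iterable[str], role: str = ROLE_DATASET) -> "FrequencyTable":
        counts = pd.DataFrame(0, index=list(AA20), columns=list(FLANK_OFFSETS))
        n = 0
        for w in windows:
            n += 1
            for off in FLANK_OFFSETS:
                aa = w[3 + off]
                if aa == PAD_CHAR:
                    continue  # padding is not a residue
                if aa in counts.index:
                    counts.at[aa, off] += 1
        return cls(counts=counts, n_windows=n, role=role)


def lysine_windows(sequence: str) -> list[str]:
    """All padded lysine-centered 7-mers of one protein sequence."""
    return [
        extract_window(sequence, i + 1, pad=True)
        for i, res in enumerate(sequence)
        if res == "K"
    ]


def background_frequencies(proteins: Mapping[str, str],
                           restrict_to: Iterable[str] | None = None) -> FrequencyTable:
    """Frequency table over every lysine of the (restricted) protein set.

    ``restrict_to`` is typically the accessions identified in unenriched
    runs — the detected-proteome background.
    """
    if restrict_to is not None:
        accessions = [a for a in proteins if a in set(restrict_to)]
    else:
        accessions = list(proteins)
    if not accessions:
        raise ValueError("background restriction matches no proteins")
    windows: list[str] = []
    for acc in accessions:
        windows.extend(lysine_windows(proteins[acc]))
    return FrequencyTable.from_windows(windows, role=ROLE_BACKGROUND)


@dataclass
class DatasetFrequencies:
    table: FrequencyTable
    n_unresolved: int
    unresolved: list[tuple[str, int]]


def dataset_frequencies(sites: Sequence, proteome: Mapping[str, str]) -> DatasetFrequencies:
    """Frequency table over the 7-mer windows of called methyl sites.

    Sites accept either objects with ``accession``/``position`` attributes or
    (accession, position) tuples.  Sites whose accession is absent or whose
    position is out of range are counted, excluded, and reported.
    """
    windows = []
    unresolved = []
    for s in sites:
        acc, pos = (s.accession, s.position) if hasattr(s, "accession") else (s[0], s[1])
        seq = proteome.get(acc)
        if seq is None or not (1 <= pos <= len(seq)) or seq[pos - 1] != "K":
            unresolved.append((acc, pos))
            continue
        windows.append(extract_window(seq, pos, pad=True))
    table = FrequencyTable.from_windows(windows, role=ROLE_DATASET)
    return DatasetFrequencies(table=table, n_unresolved=len(unresolved),
                              unresolved=unresolved)


@dataclass
class MotifMatrix:
    """log2(f_dataset / f_background) per (offset, amino acid).

    NaN marks cells whose amino acid was never observed in the dataset
    (rendered gray on heatmaps).  ``infinite_cells`` lists cells with a
    positive dataset frequency over a zero background frequency; their value
    is +inf and should be reported, not plotted as a number.
    """

    values: pd.DataFrame
    dataset_id: str = ""
    background_id: str = ""
    infinite_cells: list[tuple[str, int]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [format_offset(o) for o in out.columns]
        out.index.name = "aa"
        out.to_csv(path, sep="\t", na_rep="NA")


def log2_enrichment(fd: FrequencyTable, fp: FrequencyTable,
                    dataset_id: str = "", background_id: str = "",
                    pseudocount: float = 0.0) -> MotifMatrix:
    """Cellwise log2 ratio of dataset over background frequencies.

    With the default zero pseudocount, dataset zeros become the missing
    marker and background zeros under positive dataset counts are flagged
    infinite.  A positive pseudocount is added to the *counts* of both tables
    before frequency renormalization, removing both special cases.
    """
    if list(fd.counts.columns) != list(fp.counts.columns) or \
            list(fd.counts.index) != list(fp.counts.index):
        raise ValueError("frequency tables have mismatched offsets/alphabet")
    if pseudocount > 0:
        fdf = _with_pseudocount(fd, pseudocount)
        fpf = _with_pseudocount(fp, pseudocount)
        values = np.log2(fdf / fpf)
        return MotifMatrix(values=values, dataset_id=dataset_id,
                           background_id=background_id)
    values = pd.DataFrame(np.nan, index=fd.counts.index, columns=fd.counts.columns)
    infinite = []
    for off in values.columns:
        for aa in values.index:
            d = fd.frequencies.at[aa, off]
            p = fp.frequencies.at[aa, off]
            if not d > 0 or np.isnan(d):
                continue  # missing marker: not detected in dataset
            if not p > 0 or np.isnan(p):
                values.at[aa, off] = np.inf
                infinite.append((aa, off))
            else:
                values.at[aa, off] = np.log2(d / p)
    return MotifMatrix(values=values, dataset_id=dataset_id,
                       background_id=background_id, infinite_cells=infinite)


def _with_pseudocount(table: FrequencyTable, pseudocount: float) -> pd.DataFrame:
    counts = table.counts + pseudocount
    return counts / counts.sum(axis=0)


@dataclass
class FlankContext:
    """Distribution of flank lengths around modified lysines within peptides."""

    joint: Counter  # (n_nterm, n_cterm) -> count
    n_term: Counter
    c_term: Counter
    n_mods: int
    fraction_ge3_both: float  # fraction with >= 3 residues on both sides

    def frame(self) -> pd.DataFrame:
        rows = [(nt, ct, c) for (nt, ct), c in sorted(self.joint.items())]
        return pd.DataFrame(rows, columns=["n_nterm", "n_cterm", "count"])


def flank_context(peptides: Sequence) -> FlankContext:
    """Flank-length histogram over every methyl mod of every peptide.

    For a mod at 1-based residue index ``i`` of a peptide of length ``L`` the
    flank lengths are (i - 1, L - i).
    """
    joint: Counter = Counter()
    n_term: Counter = Counter()
    c_term: Counter = Counter()
    n_mods = 0
    n_ge3 = 0
    for rec in peptides:
        length = len(rec.sequence)
        for mod in rec.methyl_mods():
            nt = mod.residue_index - 1
            ct = length - mod.residue_index
            joint[(nt, ct)] += 1
            n_term[nt] += 1
            c_term[ct] += 1
            n_mods += 1
            if nt >= 3 and ct >= 3:
                n_ge3 += 1
    frac = n_ge3 / n_mods if n_mods else float("nan")
    return FlankContext(joint=joint, n_term=n_term, c_term=c_term,
                        n_mods=n_mods, fraction_ge3_both=frac)
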