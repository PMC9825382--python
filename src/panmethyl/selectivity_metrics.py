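"""Pan metric scoring and PSSM-based proteome scanning.

The pan metric summarizes how evenly an antibody binds across all 114
on-target library sets (100 x mean normalized signal; higher = less sequence
bias).  The PSSM reuses the normalized selectivity matrix as per-position
frequency scores; a lysine-centered 7-mer scores the sum of its six flank
lookups, and scanning a proteome yields a ranked list of preferred peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_processing import SelectivityProfile
from .errors import (
    IncompleteProfileError,
    InsufficientDataError,
    InvalidWindowError,
)
from .kopl_design import AA20, FLANK_OFFSETS, MethylState, format_offset

#: Placeholder residue for window positions beyond a protein terminus.
PAD_CHAR = "X"

#: 7-mer window geometry: central K at 0-based index 3.
WINDOW_LENGTH = 7
WINDOW_CENTER = 3
WINDOW_FLANK = 3


@dataclass(frozen=True)
class PanScore:
    """Pan metric score for one antibody (0-100; higher = less biased)."""

    antibody_id: str
    state: MethylState
    score: float
    max_signal: float = float("nan")


@dataclass
class Pssm:
    """Per-position per-amino-acid frequency scores.

    ``scores`` has the 20 standard amino acids on the rows and the six flank
    offsets on the columns.  Cysteine — never measured on the library — is
    NaN (explicit missing marker), as is any other unmeasured entry.
    """

    antibody_id: str
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = self.scores.reindex(index=list(AA20), columns=list(FLANK_OFFSETS))
        measured = self.scores.to_numpy(dtype=float)
        measured = measured[~np.isnan(measured)]
        if (measured < 0).any():
            raise ValueError("measured PSSM entries must be >= 0")

    def lookup(self, offset: int, aa: str) -> float:
        """Score contribution of one residue; missing entries and padding -> 0."""
        if aa == PAD_CHAR or aa not in self.scores.index:
            return 0.0
        v = self.scores.at[aa, offset]
        return 0.0 if pd.isna(v) else float(v)

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.columns = [format_offset(o) for o in out.columns]
        out.index.name = "aa"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, antibody_id: str = "") -> "Pssm":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        df.columns = [int(c.replace("P", "")) for c in df.columns]
        df.index.name = None
        return cls(antibody_id=antibody_id, scores=df)


def pan_metric(profile: SelectivityProfile, max_signal: float = float("nan")) -> PanScore:
    """100 x mean of the 114 normalized on-target cells.

    ``max_signal`` carries the unnormalized array maximum through to the
    intensity-vs-pan correlation analysis; it does not affect the score.
    """
    if not profile.is_complete():
        n = int(profile.matrix.isna().sum().sum())
        raise IncompleteProfileError(f"profile has {n} unmeasured cell(s)")
    score = 100.0 * float(profile.matrix.to_numpy(dtype=float).mean())
    return PanScore(
        antibody_id=profile.antibody_id, state=profile.state,
        score=score, max_signal=max_signal,
    )


def build_pssm(profile: SelectivityProfile) -> Pssm:
    """Frequency scores = the normalized selectivity matrix; cysteine is NaN."""
    if not profile.is_complete():
        n = int(profile.matrix.isna().sum().sum())
        raise IncompleteProfileError(f"profile has {n} unmeasured cell(s)")
    scores = profile.matrix.reindex(index=list(AA20))  # adds all-NaN C row
    return Pssm(antibody_id=profile.antibody_id, scores=scores.copy())


def score_7mer(pssm: Pssm, window: str) -> float:
    """Sum the six flank lookups of a lysine-centered 7-mer.

    Window positions holding the padding placeholder or an unmeasured residue
    (cysteine) contribute 0.
    """
    if len(window) != WINDOW_LENGTH:
        raise InvalidWindowError(f"window must be {WINDOW_LENGTH} residues, got {len(window)}")
    if window[WINDOW_CENTER] != "K":
        raise InvalidWindowError(
            f"central residue must be K, got {window[WINDOW_CENTER]!r}"
        )
    return sum(pssm.lookup(off, window[WINDOW_CENTER + off]) for off in FLANK_OFFSETS)


def extract_window(sequence: str, position: int, pad: bool = True) -> str | None:
    """Lysine-centered 7-mer around 1-based ``position``.

    Positions beyond the termini are padded with ``X`` (``pad=True``) or the
    window is refused (``None``) when padding is disabled.
    """
    i = position - 1
    if i < 0 or i >= len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    lo, hi = i - WINDOW_FLANK, i + WINDOW_FLANK + 1
    if not pad and (lo < 0 or hi > len(sequence)):
        return None
    left = PAD_CHAR * max(0, -lo) + sequence[max(0, lo):i]
    right = sequence[i + 1:hi] + PAD_CHAR * max(0, hi - len(sequence))
    return left + sequence[i] + right


def rank_proteome(pssm: Pssm, proteome: Mapping[str, str],
                  pad: bool = True) -> pd.DataFrame:
    """Score every lysine-centered 7-mer in a proteome.

    Returns a DataFrame with columns accession, position (1-based coordinate
    of the central lysine), window, score, contains_c, rank — sorted by score
    descending with deterministic (accession, position) tie-breaking.  With
    ``pad=True`` (default) every lysine yields exactly one record; with
    ``pad=False`` lysines within 3 residues of a terminus are skipped.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rows = []
    for accession in proteome:
        seq = proteome[accession]
        for i, res in enumerate(seq):
            if res != "K":
                continue
            window = extract_window(seq, i + 1, pad=pad)
            if window is None:
                continue
            rows.append((
                accession, i + 1, window,
                score_7mer(pssm, window),
                "C" in window,
            ))
    df = pd.DataFrame(rows, columns=["accession", "position", "window", "score", "contains_c"])
    df = df.sort_values(
        by=["score", "accession", "position"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def mean_pssm_score_by_group(
    site_groups: Mapping[str, Sequence[tuple[str, int]]],
    proteome: Mapping[str, str],
    pssm: Pssm,
    pad: bool = True,
) -> pd.DataFrame:
    """Per-group mean 7-mer score over (accession, position) site windows.

    Lysines too close to a terminus are padded by default; with ``pad=False``
    they are skipped, counted in ``n_edge`` and excluded from the mean.
    Sites whose accession is absent from the proteome are unresolvable and
    counted in ``n_unresolved``.
    """
    rows = []
    for group, sites in site_groups.items():
        scores = []
        n_edge = 0
        n_unresolved = 0
        for accession, position in sites:
            seq = proteome.get(accession)
            if seq is None or not (1 <= position <= len(seq)) or seq[position - 1] != "K":
                n_unresolved += 1
                continue
            window = extract_window(seq, position, pad=pad)
            if window is None:
                n_edge += 1
                continue
            if PAD_CHAR in window:
                n_edge += 1
            scores.append(score_7mer(pssm, window))
        rows.append((
            group, len(scores),
            float(np.mean(scores)) if scores else float("nan"),
            n_edge, n_unresolved,
        ))
    return pd.DataFrame(rows, columns=["group", "n", "mean_score", "n_edge", "n_unresolved"])


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    n: int
    degenerate: bool = False


def pan_vs_intensity(scores: Iterable[PanScore]) -> CorrelationResult:
    """Pearson correlation between array maximum intensity and pan score."""
    pts = [(s.max_signal, s.score) for s in scores]
    if len(pts) < 3:
        raise InsufficientDataError(f"need >= 3 antibodies, got {len(pts)}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(r=float("nan"), r2=float("nan"), n=len(pts), degenerate=True)
    r, _ = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), r2=float(r) ** 2, n=len(pts))
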