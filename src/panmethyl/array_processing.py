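"""Microarray fluorescence processing: replicate averaging and normalization.

Raw scan tables (one row per feature x replicate) become replicate-averaged,
normalized selectivity matrices.  Two normalization conventions are provided:
``global_max`` divides every feature mean by the single highest mean on the
array (the K-OPL convention, which keeps weak off-target binding visible),
and ``per_column_max`` divides each column of a feature x antibody matrix by
its own maximum (the histone-array convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateArrayError,
    IncompleteScanError,
    MissingDataError,
)
from .kopl_design import AA19, FLANK_OFFSETS, KoplLibrary, MethylState, format_offset

SCAN_COLUMNS = ("antibody_id", "feature_id", "replicate", "raw_signal")

NORM_MODES = ("global_max", "per_column_max")


@dataclass
class ArrayScan:
    """One antibody's raw scan: (feature_id, replicate, raw_signal) records.

    Features with replicate counts differing from the modal count are flagged
    in ``uneven_features`` rather than silently dropped.
    """

    antibody_id: str
    records: pd.DataFrame
    n_replicates: int = 0
    uneven_features: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        required = {"feature_id", "replicate", "raw_signal"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"scan records missing columns: {sorted(missing)}")
        if (self.records["raw_signal"] < 0).any():
            bad = self.records.loc[self.records["raw_signal"] < 0, "feature_id"]
            raise ValueError(f"negative raw_signal for feature(s): {sorted(set(bad))[:5]}")
        counts = self.records.groupby("feature_id", sort=False)["replicate"].size()
        if len(counts) == 0:
            raise MissingDataError("scan contains no records")
        modal = int(counts.mode().iloc[0])
        if self.n_replicates == 0:
            self.n_replicates = modal
        self.uneven_features = tuple(counts.index[counts != modal])

    @classmethod
    def from_tsv(cls, path, antibody_id: str | None = None) -> "ArrayScan":
        df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "antibody_id": str})
        if antibody_id is not None:
            df = df[df["antibody_id"] == antibody_id]
            if df.empty:
                raise ValueError(f"no records for antibody {antibody_id!r} in {path}")
        else:
            ids = df["antibody_id"].unique()
            if len(ids) != 1:
                raise ValueError(
                    f"scan file holds {len(ids)} antibodies; pass antibody_id to select one"
                )
            antibody_id = ids[0]
        return cls(antibody_id=antibody_id, records=df.reset_index(drop=True))

    def to_tsv(self, path) -> None:
        out = self.records.copy()
        out.insert(0, "antibody_id", self.antibody_id)
        out[list(SCAN_COLUMNS)].to_csv(path, sep="\t", index=False)


def average_replicates(scan: ArrayScan) -> pd.Series:
    """Arithmetic mean signal per feature, feature order preserved."""
    grouped = scan.records.groupby("feature_id", sort=False)["raw_signal"]
    means = grouped.mean()
    empty = grouped.size() == 0
    if empty.any():  # pragma: no cover - groupby cannot emit empty groups
        raise MissingDataError(f"features with zero replicates: {list(means.index[empty])}")
    means.name = "mean_signal"
    return means


def normalize_global(means: pd.Series) -> pd.Series:
    """Divide every value by the global maximum; the maximum maps to 1.0."""
    if (np.asarray(means) < 0).any():
        raise ValueError("means must be non-negative")
    peak = float(means.max())
    if not peak > 0:
        raise DegenerateArrayError("all-zero array: global normalization undefined")
    return means / peak


def normalize_per_column(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its own maximum (histone-array convention)."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("matrix must be non-negative")
    col_max = matrix.max(axis=0)
    zero_cols = col_max[~(col_max > 0)].index.tolist()
    if zero_cols:
        raise DegenerateArrayError(f"zero column(s): {zero_cols}")
    return matrix / col_max


@dataclass
class SelectivityProfile:
    """A 6 x 19 normalized selectivity matrix for one antibody / methyl state.

    ``matrix`` has amino acids on the rows (19 non-cysteine letters) and
    flank offsets on the columns (-3..-1, +1..+3), matching the heatmap
    convention (rows = fixed residue, columns = position).
    """

    antibody_id: str
    state: MethylState
    matrix: pd.DataFrame
    norm_mode: str = "global_max"

    def __post_init__(self) -> None:
        if self.norm_mode not in NORM_MODES:
            raise ValueError(f"norm_mode must be one of {NORM_MODES}")
        self.matrix = self.matrix.reindex(index=list(AA19), columns=list(FLANK_OFFSETS))
        vals = self.matrix.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if ((finite < -1e-12) | (finite > 1 + 1e-12)).any():
            raise ValueError("profile values must lie in [0, 1]")

    def is_complete(self) -> bool:
        return not self.matrix.isna().any().any()

    def value(self, offset: int, aa: str) -> float:
        return float(self.matrix.at[aa, offset])

    def to_tsv(self, path) -> None:
        out = self.matrix.copy()
        out.columns = [format_offset(o) for o in out.columns]
        out.index.name = "aa"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, antibody_id: str, state: MethylState,
                 norm_mode: str = "global_max") -> "SelectivityProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = [int(c.replace("P", "")) for c in df.columns]
        df.index.name = None
        return cls(antibody_id=antibody_id, state=MethylState(state),
                   matrix=df, norm_mode=norm_mode)


def build_profile(scan: ArrayScan, library: KoplLibrary,
                  norm_mode: str = "global_max") -> SelectivityProfile:
    """Replicate-average and normalize a scan into a selectivity profile.

    The global maximum is taken across *all* features in the scan — including
    any off-target-state library sets or control peptides printed on the same
    slide — not just the on-target sets extracted into the profile.
    """
    if norm_mode not in NORM_MODES:
        raise ValueError(f"norm_mode must be one of {NORM_MODES}")
    means = average_replicates(scan)
    wanted = library.set_ids()
    missing = [sid for sid in wanted if sid not in means.index]
    if missing:
        raise IncompleteScanError(missing)
    if norm_mode == "global_max":
        normed = normalize_global(means)
    else:
        normed = normalize_global(means)  # single-antibody scan: column == array
    matrix = pd.DataFrame(np.nan, index=list(AA19), columns=list(FLANK_OFFSETS))
    for s in library.sets:
        matrix.at[s.fixed_aa, s.fixed_offset] = float(normed[s.set_id])
    return SelectivityProfile(
        antibody_id=scan.antibody_id, state=library.state,
        matrix=matrix, norm_mode=norm_mode,
    )
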