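"""Combinatorial model of the lysine-oriented peptide library (K-OPL).

The library consists of 114 sets of 9-mer peptides oriented around a fixed
central lysine.  Each set fixes one additional amino acid at one of six flank
positions (P-3..P-1, P+1..P+3); the 19 non-cysteine amino acids are used, so
each position group holds 19 sets.  The remaining flank positions are
degenerate over the same 19-letter alphabet.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from .errors import InvalidPeptideError

#: The 20 standard amino acids, alphabetical.
AA20: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Degenerate / fixable alphabet: the 20 standard amino acids minus cysteine.
AA19: tuple[str, ...] = tuple(a for a in AA20 if a != "C")

#: Flank offsets relative to the central lysine (P0).
FLANK_OFFSETS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)

#: Length of a library peptide and 0-based index of its central lysine.
PEPTIDE_LENGTH = 9
CENTRAL_INDEX = 4


class MethylState(str, enum.Enum):
    """Methylation state of the central lysine."""

    me0 = "me0"  # unmodified
    me1 = "me1"  # mono-methyl
    me2 = "me2"  # di-methyl
    me3 = "me3"  # tri-methyl

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three methylated states (me0 belongs to the unmodified library only).
METHYL_STATES: tuple[MethylState, ...] = (
    MethylState.me1,
    MethylState.me2,
    MethylState.me3,
)


def format_offset(offset: int) -> str:
    """Render a flank offset as ``P-1`` / ``P+2``."""
    return f"P{offset:+d}"


@dataclass(frozen=True)
class KoplSet:
    """One library set: a fixed flank residue at a fixed offset.

    Parameters
    ----------
    fixed_offset
        Position of the fixed residue relative to the central lysine; one of
        ``{-3, -2, -1, +1, +2, +3}``.
    fixed_aa
        The fixed amino acid (19-letter alphabet, no cysteine).
    state
        Methylation state of the central lysine.
    """

    fixed_offset: int
    fixed_aa: str
    state: MethylState

    def __post_init__(self) -> None:
        if self.fixed_offset not in FLANK_OFFSETS:
            raise ValueError(f"fixed_offset must be in {FLANK_OFFSETS}, got {self.fixed_offset}")
        if self.fixed_aa not in AA19:
            raise ValueError(f"fixed_aa must be one of the 19 non-cysteine amino acids, got {self.fixed_aa!r}")

    @property
    def set_id(self) -> str:
        """Stable identifier, e.g. ``me2_P-1_F`` — the join key across array files."""
        return f"{self.state.value}_{format_offset(self.fixed_offset)}_{self.fixed_aa}"


@dataclass(frozen=True)
class KoplLibrary:
    """The full 114-set library for one methyl state."""

    state: MethylState
    sets: tuple[KoplSet, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.sets)

    def by_offset(self) -> dict[int, tuple[KoplSet, ...]]:
        """Group sets into the six position groups, offset ascending."""
        groups: dict[int, list[KoplSet]] = {off: [] for off in FLANK_OFFSETS}
        for s in self.sets:
            groups[s.fixed_offset].append(s)
        return {off: tuple(members) for off, members in groups.items()}

    def set_ids(self) -> tuple[str, ...]:
        return tuple(s.set_id for s in self.sets)


def enumerate_library(state: MethylState) -> KoplLibrary:
    """Enumerate all 6 x 19 = 114 sets for one methyl state.

    Order is deterministic: offset ascending, then amino acid alphabetical,
    so set ids are stable across runs.
    """
    state = MethylState(state)
    sets = tuple(
        KoplSet(fixed_offset=off, fixed_aa=aa, state=state)
        for off in FLANK_OFFSETS
        for aa in AA19
    )
    return KoplLibrary(state=state, sets=sets)


def set_membership(s: KoplSet, peptide: str, central_state: MethylState) -> bool:
    """Decide whether a 9-mer peptide belongs to a library set.

    The peptide must be 9 residues with lysine at the central position
    (1-based position 5).  Membership requires the set's methyl state, its
    fixed residue at the fixed offset, and every other flank residue
    (offsets -3..+3, excluding the fixed one) drawn from the 19-letter
    degenerate alphabet.  Residues at offsets +/-4 carry no fixed identity
    and are ignored.
    """
    if len(peptide) != PEPTIDE_LENGTH:
        raise InvalidPeptideError(
            f"peptide must be {PEPTIDE_LENGTH} residues, got {len(peptide)}"
        )
    if peptide[CENTRAL_INDEX] != "K":
        raise InvalidPeptideError(
            f"central residue (position {CENTRAL_INDEX + 1}) must be K, got {peptide[CENTRAL_INDEX]!r}"
        )
    if MethylState(central_state) is not s.state:
        return False
    if peptide[CENTRAL_INDEX + s.fixed_offset] != s.fixed_aa:
        return False
    for off in FLANK_OFFSETS:
        if off == s.fixed_offset:
            continue
        if peptide[CENTRAL_INDEX + off] not in AA19:
            return False
    return True


def membership_sets(library: KoplLibrary, peptide: str, central_state: MethylState) -> list[KoplSet]:
    """All sets of ``library`` that a peptide belongs to."""
    return [s for s in library.sets if set_membership(s, peptide, central_state)]


def write_manifest(library: KoplLibrary, path) -> None:
    """Write the library manifest TSV: set_id, state, fixed_offset, fixed_aa."""
    with open(path, "w") as fh:
        fh.write("set_id\tstate\tfixed_offset\tfixed_aa\n")
        for s in library.sets:
            fh.write(f"{s.set_id}\t{s.state.value}\t{s.fixed_offset:+d}\t{s.fixed_aa}\n")


def read_manifest(path) -> KoplLibrary:
    """Read a manifest written by :func:`write_manifest`."""
    sets: list[KoplSet] = []
    states: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            state = MethylState(row[idx["state"]])
            states.add(state.value)
            sets.append(
                KoplSet(
                    fixed_offset=int(row[idx["fixed_offset"]]),
                    fixed_aa=row[idx["fixed_aa"]],
                    state=state,
                )
            )
    if len(states) != 1:
        raise ValueError(f"manifest mixes methyl states: {sorted(states)}")
    return KoplLibrary(state=sets[0].state, sets=tuple(sets))
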