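"""Readers and writers for the pipeline's plain-text dialects.

All tables are tab-separated with header rows.  Modifications on a peptide
row are semicolon-encoded ``index:type:prob`` triples.  FASTA is read with
Biopython and written with a deterministic plain writer.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .methylome_catalog import Mod, PeptideRecord

PSM_COLUMNS = ("sequence", "mods", "accession", "protein_start",
               "run_label", "strategy_label", "is_psm")


def read_fasta(path) -> dict[str, str]:
    """accession -> sequence, order preserved."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def encode_mods(mods: Sequence[Mod]) -> str:
    return ";".join(
        f"{m.residue_index}:{m.type}:{m.localization_probability:g}" for m in mods
    )


def decode_mods(text: str) -> tuple[Mod, ...]:
    text = "" if pd.isna(text) else str(text).strip()
    if not text:
        return ()
    mods = []
    for chunk in text.split(";"):
        idx, mtype, prob = chunk.split(":")
        mods.append(Mod(residue_index=int(idx), type=mtype,
                        localization_probability=float(prob)))
    return tuple(mods)


def write_psm_tsv(records: Sequence[PeptideRecord], path) -> None:
    rows = [
        (r.sequence, encode_mods(r.mods), r.accession, r.protein_start,
         r.run_label, r.strategy_label, int(r.is_psm))
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_psm_tsv(path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "accession": str},
                     keep_default_na=False, na_values=[""])
    records = []
    for row in df.itertuples(index=False):
        records.append(PeptideRecord(
            sequence=row.sequence,
            mods=decode_mods(row.mods),
            accession=row.accession,
            protein_start=int(row.protein_start),
            run_label=str(row.run_label),
            strategy_label=str(row.strategy_label),
            is_psm=bool(int(row.is_psm)),
        ))
    return records


def write_sites_tsv(sites_frame: pd.DataFrame, path) -> None:
    sites_frame.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"accession": str, "state": str})


def read_compartments_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"accession": str, "compartment": str})


def read_accession_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
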