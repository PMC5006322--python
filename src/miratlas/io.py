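"""File I/O: FASTA/FASTQ reads, precursor sets with annotation tables, TSVs.

Precursors travel as a FASTA of hairpin sequences plus a TSV annotation
table (precursor_id, species, arm, start, end, mature_name) with 1-based
inclusive coordinates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import MatureWindow, PrecursorRecord

ANNOT_COLUMNS = ["precursor_id", "species", "arm", "start", "end", "mature_name"]


def write_precursors(
    precursors: list[PrecursorRecord], fasta_path, annot_path
) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.name, description=p.species)
        for p in precursors
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        (p.name, p.species, w.arm, w.start, w.end, w.name)
        for p in precursors
        for w in p.mature_windows
    ]
    pd.DataFrame(rows, columns=ANNOT_COLUMNS).to_csv(annot_path, sep="\t", index=False)


def read_precursors(fasta_path, annot_path) -> list[PrecursorRecord]:
    annot = pd.read_csv(annot_path, sep="\t")
    missing = set(ANNOT_COLUMNS) - set(annot.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    windows: dict[str, list[MatureWindow]] = {}
    species: dict[str, str] = {}
    for row in annot.itertuples(index=False):
        windows.setdefault(row.precursor_id, []).append(
            MatureWindow(row.mature_name, row.arm, int(row.start), int(row.end))
        )
        species[row.precursor_id] = row.species
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(
            PrecursorRecord(
                name=rec.id,
                species=species.get(rec.id, rec.description.split()[-1] if rec.description else ""),
                sequence=str(rec.seq),
                mature_windows=windows.get(rec.id, []),
            )
        )
    return out


def write_reads_fasta(sequences: list[str], path, prefix: str = "read") -> None:
    records = [
        SeqRecord(Seq(s), id=f"{prefix}_{i + 1}", description="")
        for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_sequences(path) -> list[str]:
    """Read sequences from FASTA or FASTQ (by extension)."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(p), fmt)]
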