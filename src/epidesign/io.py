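"""Readers and writers: peptide tables (TSV/CSV), FASTA, docking-score lists.

All tabular formats are plain text. Peptide tables need a sequence column
and optionally an intensity column plus any number of replicate-intensity
columns; column names are configurable.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DEFAULT_ALPHABET, LabeledPeptideRecord, Peptide, PeptideAlphabet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnSpec:
    """Column names in a peptide table. ``replicate_columns`` lists columns
    carrying per-replicate intensities (e.g. triplicate assays)."""

    sequence: str = "sequence"
    intensity: str = "intensity"
    id: str = "id"
    replicate_columns: tuple[str, ...] = ()


def read_peptide_table(
    path: str | os.PathLike,
    columns: ColumnSpec = ColumnSpec(),
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
) -> list[LabeledPeptideRecord]:
    """Read a tab- or comma-separated peptide table into records, in file
    order. Sequences are validated against the alphabet; the reader never
    assigns binding labels (pool construction does that).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if columns.sequence not in df.columns:
        raise ValueError(
            f"{path}: missing sequence column {columns.sequence!r}; found {list(df.columns)}"
        )
    records: list[LabeledPeptideRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        seq = str(row_d[columns.sequence]).strip()
        try:
            pep = Peptide(
                id=str(row_d.get(columns.id, f"row{row_no}")),
                sequence=seq,
                alphabet=alphabet,
            )
        except ValueError as err:
            raise ValueError(f"{path}: row {row_no}: {err}") from err
        reps = None
        if columns.replicate_columns:
            present = [c for c in columns.replicate_columns if c in df.columns]
            if present:
                reps = tuple(float(row_d[c]) for c in present)
        intensity = float(row_d.get(columns.intensity, 0.0) or 0.0)
        if reps is not None and columns.intensity not in df.columns:
            intensity = float(max(reps))
        records.append(
            LabeledPeptideRecord(peptide=pep, intensity=intensity, replicate_intensities=reps)
        )
    return records


def write_peptide_table(
    records: list[LabeledPeptideRecord], path: str | os.PathLike, columns: ColumnSpec = ColumnSpec()
) -> None:
    df = pd.DataFrame(
        {
            columns.id: [r.peptide.id for r in records],
            columns.sequence: [r.peptide.sequence for r in records],
            columns.intensity: [r.intensity for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(
    path: str | os.PathLike, alphabet: PeptideAlphabet = DEFAULT_ALPHABET
) -> list[Peptide]:
    """Read peptides from FASTA. Duplicate ids are warned about and
    suffix-deduplicated (``id``, ``id.2``, ``id.3``, ...)."""
    peptides: list[Peptide] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            seen[pid] += 1
            new_id = f"{pid}.{seen[pid]}"
            logger.warning("duplicate FASTA id %r renamed to %r", pid, new_id)
            pid = new_id
        else:
            seen[pid] = 1
        peptides.append(Peptide(id=pid, sequence=str(rec.seq).upper(), alphabet=alphabet))
    return peptides


def write_fasta(peptides: list[Peptide], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def read_dock_scores(path: str | os.PathLike) -> list[float]:
    """Read one peptide's docking scores from two-column text
    (pose rank, score); lines starting with '#' are comments."""
    scores: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            scores.append(float(parts[-1]))
    if not scores:
        raise ValueError(f"{path}: no docking scores found")
    return scores


def write_dock_scores(scores: list[float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rank, s in enumerate(scores, start=1):
            fh.write(f"{rank}\t{s:.6g}\n")
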