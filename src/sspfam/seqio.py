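"""Sequence input/output and preprocessing for candidate secretory peptides.

Candidate small secretory peptides (SSPs) are preproproteins: an N-terminal
signal peptide, a variable middle region, and a conserved — usually
C-terminal — bioactive motif. This module reads predicted proteomes,
applies the strict length-<200-aa preselection, and extracts the last 50
residues that downstream all-vs-all comparison operates on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import validate_sequence


class FastaParseError(ValueError):
    """Malformed FASTA input (empty sequence, duplicate ID, bad residue)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein — the pipeline's atom.

    Splice variants are independent records. Sequences are uppercase over
    the 20-letter alphabet plus X; trailing stop characters are stripped
    on input.
    """

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"ProteinRecord {self.id!r}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"ProteinRecord {self.id!r}: sequence must be uppercase")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CTerminalSegment:
    """The C-terminal window of a protein — the unit of motif search."""

    parent_id: str
    sequence: str
    offset: int  # 0-based start of the suffix within the parent

    def is_suffix_of(self, record: ProteinRecord) -> bool:
        return record.sequence[self.offset:] == self.sequence


_SPECIES_RE = re.compile(r"\bspecies=(\S+)")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into ProteinRecords.

    The record ID is the first whitespace-delimited header token; an
    optional ``species=<tag>`` key anywhere in the header sets the species.
    Sequences are uppercased, trailing ``*`` stops stripped, and residues
    validated (ambiguity codes are tolerated and treated as X downstream).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if not rid:
            raise FastaParseError(f"{path}: entry with empty ID")
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate sequence ID {rid!r}")
        seen.add(rid)
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise FastaParseError(f"{path}: entry {rid!r} has an empty sequence")
        try:
            validate_sequence(seq)
        except ValueError as exc:
            raise FastaParseError(f"{path}: entry {rid!r}: {exc}") from exc
        m = _SPECIES_RE.search(entry.description)
        species = m.group(1) if m else ""
        records.append(ProteinRecord(id=rid, sequence=seq, species=species))
    if not records:
        raise FastaParseError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving the species tag in the header."""
    out = []
    for r in records:
        desc = f"species={r.species}" if r.species else ""
        out.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


@dataclass
class LengthFilterResult:
    kept: list[ProteinRecord]
    n_removed: int
    report: pd.DataFrame = field(repr=False, default=None)


def filter_by_length(
    records: Sequence[ProteinRecord], max_len: int = 200
) -> LengthFilterResult:
    """Keep proteins strictly shorter than ``max_len`` residues.

    The 200-aa preselection is deliberately conservative: most known
    secretory peptide precursors are ~100 aa. Order is preserved and the
    result carries a per-species TSV-ready report.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    kept = [r for r in records if r.length < max_len]
    by_species: dict[str, list[int]] = {}
    for r in records:
        row = by_species.setdefault(r.species or "-", [0, 0])
        row[0] += 1
        row[1] += r.length < max_len
    report = pd.DataFrame(
        [
            {"species": sp, "n_input": n_in, "n_short": n_short,
             "n_removed": n_in - n_short}
            for sp, (n_in, n_short) in sorted(by_species.items())
        ],
        columns=["species", "n_input", "n_short", "n_removed"],
    )
    return LengthFilterResult(kept=kept, n_removed=len(records) - len(kept),
                              report=report)


def extract_cterm(record: ProteinRecord, window: int = 50) -> CTerminalSegment:
    """Extract the C-terminal window (last ``window`` residues).

    Proteins shorter than the window contribute their entire sequence:
    genuinely tiny precursors should not be discarded by a fixed window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = min(window, record.length)
    offset = record.length - n
    return CTerminalSegment(parent_id=record.id,
                            sequence=record.sequence[offset:], offset=offset)


def extract_cterm_all(
    records: Sequence[ProteinRecord], window: int = 50
) -> list[CTerminalSegment]:
    return [extract_cterm(r, window) for r in records]
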