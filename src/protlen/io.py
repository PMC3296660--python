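"""Protein/CDS FASTA input-output and dataset curation.

Reading keeps one record per FASTA entry in file order, uppercases the
sequence and strips a single trailing stop symbol (``*``).  Curation builds
the non-redundant (nr) set by removing exact duplicates and sequences that
occur as contiguous substrings of longer sequences, and can drop records
whose annotation line matches configurable keywords (transposon filtering).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "Proteome",
    "read_fasta",
    "write_fasta",
    "deduplicate",
    "filter_by_keywords",
    "write_curation_log",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, annotation line and residue sequence.

    ``length`` is the residue count z used throughout the analysis.  The
    stored sequence carries no terminal stop symbol; records with internal
    stops are rejected at construction.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if "*" in self.sequence:
            raise ValueError(f"record {self.id!r}: sequence contains '*'")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """A species-level collection of protein records with provenance."""

    species_code: str
    records: list[ProteinRecord] = field(default_factory=list)
    taxon_group: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.species_code:
            raise ValueError("species_code must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    def lengths(self) -> np.ndarray:
        """Residue counts of all records as an integer array."""
        return np.array([r.length for r in self.records], dtype=np.int64)


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, kind: str = "protein") -> list[ProteinRecord]:
    """Read a (possibly gzip-compressed) FASTA file into records.

    Sequences are uppercased and a single trailing ``*`` is stripped before
    the length is computed.  Records that are empty after stripping, or that
    contain internal stop symbols, are skipped with a logged warning.

    Parameters
    ----------
    path:
        FASTA file, plain or ``.gz``.
    kind:
        ``"protein"`` or ``"nucleotide"``; recorded for provenance only,
        the parsing is identical.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"unknown sequence kind {kind!r}")
    path = Path(path)
    records: list[ProteinRecord] = []
    n_skipped = 0
    with _open_maybe_gzip(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            seq = str(entry.seq).upper()
            if seq.endswith("*"):
                seq = seq[:-1]
            desc = entry.description
            if desc.startswith(entry.id):
                desc = desc[len(entry.id):].strip()
            if not seq or "*" in seq:
                n_skipped += 1
                reason = "empty sequence" if not seq else "internal stop codon"
                logger.warning("skipping record %r: %s", entry.id, reason)
                continue
            records.append(ProteinRecord(id=entry.id, sequence=seq, description=desc))
    if n_skipped:
        logger.warning("%s: skipped %d invalid record(s)", path.name, n_skipped)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as plain FASTA, wrapping sequence lines at ``width``."""
    path = Path(path)
    with open(path, "wt") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for start in range(0, len(rec.sequence), width):
                out.write(rec.sequence[start:start + width] + "\n")


def deduplicate(records: Sequence[ProteinRecord]) -> tuple[list[ProteinRecord], int]:
    """Build the non-redundant set: drop duplicates and contained sequences.

    A record is removed when its sequence equals, or occurs as a contiguous
    substring of, another kept sequence.  Within a duplicate group the
    longest sequence is kept; on ties the first occurrence in input order
    retains its metadata.  Kept records are returned in input order.
    """
    # Scan candidates longest-first so every kept sequence is at least as
    # long as the next candidate; containment then only needs to be checked
    # against what is already kept.  Kept sequences are accumulated in one
    # newline-separated buffer so each check is a single C-level search.
    order = sorted(range(len(records)), key=lambda i: -records[i].length)
    blob = bytearray()
    kept_idx: list[int] = []
    for i in order:
        needle = records[i].sequence.encode("ascii")
        if blob.find(needle) != -1:
            continue
        kept_idx.append(i)
        blob += needle
        blob += b"\n"
    kept_idx.sort()
    kept = [records[i] for i in kept_idx]
    return kept, len(records) - len(kept)


def filter_by_keywords(
    records: Sequence[ProteinRecord], keywords: Sequence[str]
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split records by annotation keywords (case-insensitive substrings).

    A record lands in ``removed`` iff its lowercased description contains
    any keyword; order is preserved in both outputs.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    lowered = [k.lower() for k in keywords]
    kept: list[ProteinRecord] = []
    removed: list[ProteinRecord] = []
    for rec in records:
        desc = rec.description.lower()
        (removed if any(k in desc for k in lowered) else kept).append(rec)
    return kept, removed


def write_curation_log(rows: Iterable[dict], path: str | Path) -> None:
    """Write a TSV curation log (one row per species).

    Expected keys: species_code, n_raw, n_duplicates_removed,
    n_keyword_removed, n_kept.
    """
    import pandas as pd

    cols = ["species_code", "n_raw", "n_duplicates_removed", "n_keyword_removed", "n_kept"]
    pd.DataFrame(list(rows), columns=cols).to_csv(path, sep="\t", index=False)
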