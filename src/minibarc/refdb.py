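"""Aligned reference databases for mini-barcode design.

A reference database is a multiple sequence alignment of mitochondrial
marker sequences (here typically 12S rRNA) in which each record carries a
species label parsed from its FASTA header.  This module reads and
validates such alignments, summarises their taxonomic composition, and
builds "UNIQUE" databases in which duplicate haplotypes are collapsed and
singleton species (species with a single distinct haplotype, which can
never be matched by a conspecific) are removed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "LabelRule",
    "SequenceRecord",
    "ReferenceAlignment",
    "DatabaseSummary",
    "LabelParseError",
    "RaggedAlignmentError",
    "read_alignment",
    "write_alignment",
    "summarize",
    "build_unique",
]

# Numeric encoding used throughout the package: unambiguous bases map to
# 0..3, everything else (gaps, N, partial IUPAC codes) to INVALID and is
# excluded by pairwise deletion.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
INVALID = 4


class RaggedAlignmentError(ValueError):
    """Raised when input sequences do not all share one alignment length."""


class LabelParseError(ValueError):
    """Raised when a species label cannot be parsed from a FASTA header."""


@dataclass(frozen=True)
class LabelRule:
    """How to extract ``genus`` and ``species`` from a FASTA identifier.

    The default takes the first two delimiter-separated tokens as genus and
    species epithet ("Dasyurus_maculatus_A3395" -> "Dasyurus maculatus").
    Alternatively a regular expression with named groups ``genus`` and
    ``epithet`` may be supplied; it takes precedence over token splitting.

    Parameters
    ----------
    delimiter : str
        Token separator in the identifier.
    genus_token, epithet_token : int
        Indices of the genus and species-epithet tokens.
    regex : str, optional
        Pattern with named groups ``genus`` and ``epithet``.
    fallback_species : str, optional
        Species label to assign when parsing fails; by default parsing
        failure is an error.
    """

    delimiter: str = "_"
    genus_token: int = 0
    epithet_token: int = 1
    regex: str | None = None
    fallback_species: str | None = None

    def parse(self, identifier: str) -> tuple[str, str]:
        """Return ``(species, genus)`` for a record identifier."""
        if self.regex is not None:
            m = re.search(self.regex, identifier)
            if m is not None:
                genus = m.group("genus")
                epithet = m.group("epithet")
                return f"{genus} {epithet}", genus
        else:
            tokens = [t for t in identifier.split(self.delimiter) if t]
            hi = max(self.genus_token, self.epithet_token)
            if len(tokens) > hi:
                genus = tokens[self.genus_token]
                epithet = tokens[self.epithet_token]
                if genus and epithet:
                    return f"{genus} {epithet}", genus
        if self.fallback_species is not None:
            toks = self.fallback_species.split(None, 1)
            return self.fallback_species, toks[0]
        raise LabelParseError(
            f"cannot parse species label from identifier {identifier!r} "
            f"with rule {self!r}"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its parsed taxonomy."""

    id: str
    species: str
    genus: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceAlignment:
    """An ordered collection of equal-length :class:`SequenceRecord`."""

    records: list[SequenceRecord]
    name: str = ""
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.records:
            L = len(self.records[0].sequence)
            for rec in self.records:
                if len(rec.sequence) != L:
                    raise RaggedAlignmentError(
                        f"record {rec.id!r} has length {len(rec.sequence)}, "
                        f"expected alignment length {L}"
                    )
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def length(self) -> int:
        """Alignment length in columns (0 for an empty database)."""
        return len(self.records[0].sequence) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix: A,C,G,T -> 0..3, anything else -> 4.

        Cached; the alignment is treated as immutable once encoded.
        """
        if self._encoded is None:
            n, L = len(self.records), self.length
            arr = np.full((n, L), INVALID, dtype=np.uint8)
            table = np.full(256, INVALID, dtype=np.uint8)
            for base, code in _CODE.items():
                table[ord(base)] = code
            for i, rec in enumerate(self.records):
                arr[i] = table[np.frombuffer(rec.sequence.encode("ascii"), np.uint8)]
            self._encoded = arr
        return self._encoded

    def slice_columns(self, start: int, end_exclusive: int, name: str | None = None
                      ) -> "ReferenceAlignment":
        """New alignment restricted to 0-based columns [start, end_exclusive)."""
        recs = [
            SequenceRecord(r.id, r.species, r.genus, r.sequence[start:end_exclusive])
            for r in self.records
        ]
        return ReferenceAlignment(recs, name=name or self.name)


@dataclass(frozen=True)
class DatabaseSummary:
    """Taxonomic composition of a reference database."""

    n_sequences: int
    n_species: int
    n_genera: int
    species_counts: dict[str, int]
    singleton_species: list[str]


def read_alignment(path: str | Path, label_rule: LabelRule | None = None,
                   name: str | None = None) -> ReferenceAlignment:
    """Read an aligned multi-FASTA file into a :class:`ReferenceAlignment`.

    Sequences are upper-cased on read.  All records must share one length;
    a ragged file raises :class:`RaggedAlignmentError` naming the offending
    record.  Species/genus labels are parsed from headers with *label_rule*
    (default: first two underscore-separated tokens).
    """
    rule = label_rule or LabelRule()
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        species, genus = rule.parse(bio.id)
        records.append(SequenceRecord(bio.id, species, genus, str(bio.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceAlignment(records, name=name or path.stem)


def write_alignment(db: ReferenceAlignment, path: str | Path) -> None:
    """Write the database as multi-FASTA (80-column wrapped)."""
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in db]
    SeqIO.write(bio, str(path), "fasta")


def _haplotypes_by_species(db: ReferenceAlignment) -> dict[str, list[str]]:
    """Distinct aligned sequences per species, in order of first occurrence."""
    out: dict[str, list[str]] = {}
    for rec in db:
        haps = out.setdefault(rec.species, [])
        if rec.sequence not in haps:
            haps.append(rec.sequence)
    return out


def summarize(db: ReferenceAlignment) -> DatabaseSummary:
    """Count sequences, species, genera, and singleton species.

    A singleton species has exactly one distinct haplotype (exact string
    identity of aligned sequences), regardless of how many copies of it
    are present.
    """
    counts: dict[str, int] = {}
    genera: set[str] = set()
    for rec in db:
        counts[rec.species] = counts.get(rec.species, 0) + 1
        genera.add(rec.genus)
    haps = _haplotypes_by_species(db)
    singletons = [sp for sp, h in haps.items() if len(h) == 1]
    return DatabaseSummary(
        n_sequences=len(db),
        n_species=len(counts),
        n_genera=len(genera),
        species_counts=counts,
        singleton_species=singletons,
    )


def build_unique(db: ReferenceAlignment) -> ReferenceAlignment:
    """Collapse duplicate haplotypes and drop singleton species.

    Within each species, identical aligned sequences are collapsed to the
    first occurrence; species left with exactly one distinct haplotype are
    removed entirely.  Output order follows input order.  The operation is
    idempotent.
    """
    if not db.records:
        raise ValueError("cannot build a UNIQUE database from an empty database")
    haps = _haplotypes_by_species(db)
    multi = {sp for sp, h in haps.items() if len(h) >= 2}
    kept: list[SequenceRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in db:
        if rec.species not in multi:
            continue
        key = (rec.species, rec.sequence)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    if not kept:
        warnings.warn(
            "UNIQUE database is empty: every species is a singleton",
            UserWarning,
            stacklevel=2,
        )
    name = f"{db.name}_UNIQUE" if db.name else "UNIQUE"
    return ReferenceAlignment(kept, name=name)


def summary_table(db: ReferenceAlignment):
    """Per-species summary as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    s = summarize(db)
    haps = _haplotypes_by_species(db)
    rows = [
        {
            "species": sp,
            "n_sequences": s.species_counts[sp],
            "n_haplotypes": len(haps[sp]),
            "singleton": sp in s.singleton_species,
        }
        for sp in s.species_counts
    ]
    return pd.DataFrame(rows)
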