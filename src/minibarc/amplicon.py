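"""Primer localisation, in-silico amplicon trimming, and query assignment.

Given a primer pair designed inside conserved windows, the reference
alignment is trimmed to the amplicon *insert* (the product minus the two
primer-binding sites) to produce the databases against which short query
fragments — e.g. sequences amplified from predator scats — are classified.

Primer sites are located by IUPAC-aware matching of the primer against
each sequence's degapped row (alignment columns tracked through the
gaps), taking the modal column span across sequences: individual rows may
carry a few mismatches under the primers, so a majority vote is more
robust than any single row.  Queries are assigned by semi-global pairwise
alignment against each degapped reference — reference overhang is free
(queries are fragments of the barcode region) while the query itself must
align end-to-end — with best-close-match semantics on the distance
1 - identity.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from .refdb import ReferenceAlignment, SequenceRecord

__all__ = [
    "PrimerPair",
    "AmpliconRegion",
    "QueryClassification",
    "PrimerLocalizationError",
    "locate_primer",
    "locate_amplicon",
    "trim_to_amplicon",
    "classify_query",
]

_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PrimerLocalizationError(ValueError):
    """Raised when a primer cannot be placed in a majority of sequences."""


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    name: str
    forward: str
    reverse: str
    expected_product: int | None = None

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{label} primer is empty")
            bad = set(seq.upper()) - set(_IUPAC)
            if bad:
                raise ValueError(f"{label} primer has non-IUPAC characters {bad}")


@dataclass(frozen=True)
class AmpliconRegion:
    """Alignment coordinates (1-based inclusive) of an amplicon."""

    insert_start: int
    insert_end_inclusive: int
    forward_site: tuple[int, int]
    reverse_site: tuple[int, int]

    @property
    def insert_length(self) -> int:
        return self.insert_end_inclusive - self.insert_start + 1


@dataclass(frozen=True)
class QueryClassification:
    query_id: str
    best_species: str | None
    identity: float
    outcome: str
    aligned_length: int
    best_ids: tuple[str, ...] = ()


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def degap(record: SequenceRecord) -> tuple[str, list[int]]:
    """Ungapped sequence plus the 0-based alignment column of each base."""
    bases: list[str] = []
    cols: list[int] = []
    for c, ch in enumerate(record.sequence):
        if ch in _IUPAC:
            bases.append(ch)
            cols.append(c)
    return "".join(bases), cols


def _mismatches(primer: str, target: str) -> int:
    n = 0
    for p, t in zip(primer, target):
        pset = _IUPAC[p]
        tset = _IUPAC.get(t)
        if tset is None or pset.isdisjoint(tset):
            n += 1
    return n


def _best_hit(primer: str, seq: str) -> tuple[int, int]:
    """(offset, mismatches) of the leftmost best placement of primer in seq."""
    k = len(primer)
    best_off, best_mm = -1, k + 1
    for off in range(len(seq) - k + 1):
        mm = _mismatches(primer, seq[off:off + k])
        if mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    return best_off, best_mm


def locate_primer(db: ReferenceAlignment, primer: str,
                  orientation: str = "forward",
                  max_mismatch: int = 4) -> tuple[int, int]:
    """Locate a primer's binding site as a 1-based inclusive column span.

    The primer (reverse-complemented first for ``orientation=
    "reverse_complement"``) is matched IUPAC-aware against every degapped
    row; the modal column span among rows with <= *max_mismatch*
    mismatches is returned.  If fewer than half the rows yield a hit, a
    :class:`PrimerLocalizationError` lists the per-row best mismatch
    counts.
    """
    primer = primer.upper()
    if orientation == "reverse_complement":
        primer = reverse_complement(primer)
    elif orientation != "forward":
        raise ValueError(f"unknown orientation {orientation!r}")
    if len(primer) >= db.length:
        raise ValueError("primer is not shorter than the alignment")
    spans: Counter[tuple[int, int]] = Counter()
    best_by_seq: dict[str, int] = {}
    for rec in db:
        seq, cols = degap(rec)
        if len(seq) < len(primer):
            best_by_seq[rec.id] = len(primer)
            continue
        off, mm = _best_hit(primer, seq)
        best_by_seq[rec.id] = mm
        if mm <= max_mismatch:
            spans[(cols[off] + 1, cols[off + len(primer) - 1] + 1)] += 1
    n_hit = sum(spans.values())
    if n_hit * 2 < len(db):
        worst = sorted(best_by_seq.items(), key=lambda kv: -kv[1])[:10]
        raise PrimerLocalizationError(
            f"primer {primer!r} found in only {n_hit}/{len(db)} sequences "
            f"(max_mismatch={max_mismatch}); worst rows: {worst}"
        )
    return spans.most_common(1)[0][0]


def locate_amplicon(db: ReferenceAlignment, pair: PrimerPair,
                    max_mismatch: int = 4) -> AmpliconRegion:
    """Locate both primer sites and the insert they flank."""
    fwd = locate_primer(db, pair.forward, "forward", max_mismatch)
    rev = locate_primer(db, pair.reverse, "reverse_complement", max_mismatch)
    if not fwd[1] < rev[0]:
        raise PrimerLocalizationError(
            f"forward site {fwd} does not precede reverse site {rev}"
        )
    return AmpliconRegion(
        insert_start=fwd[1] + 1,
        insert_end_inclusive=rev[0] - 1,
        forward_site=fwd,
        reverse_site=rev,
    )


def trim_to_amplicon(db: ReferenceAlignment,
                     region: AmpliconRegion) -> ReferenceAlignment:
    """Slice every record to the insert columns; labels and order kept."""
    if not (1 <= region.insert_start <= region.insert_end_inclusive <= db.length):
        raise ValueError("amplicon region outside alignment")
    name = f"{db.name}_trimmed" if db.name else "trimmed"
    return db.slice_columns(region.insert_start - 1, region.insert_end_inclusive,
                            name=name)


def _make_aligner() -> Align.PairwiseAligner:
    # semi-global: fragments pay nothing for terminal gaps
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free reference (target) overhang only: the query is a fragment that
    # must align end-to-end, otherwise any short perfect overlap between
    # unrelated sequences would score 100% identity.  The attribute was
    # renamed across Biopython releases.
    try:
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.query_end_gap_score = 0
    return aligner


def _identity(aligner: Align.PairwiseAligner, ref: str, query: str
              ) -> tuple[float, int]:
    """Percent identity over non-terminal alignment columns.

    Terminal gap columns are excluded (the query is a fragment of the
    reference); internal gaps count as mismatches.
    """
    alignment = next(iter(aligner.align(ref, query)))
    a, b = str(alignment[0]), str(alignment[1])
    core = [
        k
        for k in range(len(a))
        if a[k] != "-" and b[k] != "-"
    ]
    if not core:
        return 0.0, 0
    lo, hi = core[0], core[-1] + 1
    n_cols = hi - lo
    n_match = sum(1 for k in range(lo, hi) if a[k] == b[k] and a[k] != "-")
    return 100.0 * n_match / n_cols, n_cols


def classify_query(query_id: str, query_seq: str, db: ReferenceAlignment,
                   t: float = 0.01, min_length: int = 50,
                   floor_identity: float = 70.0,
                   true_species: str | None = None) -> QueryClassification:
    """Assign a species to an unaligned query fragment.

    Per-reference distance is ``1 - identity`` from a semi-global
    alignment; best-close-match semantics are applied at threshold *t*
    (references with distance < t, judged at the minimum distance).
    Outcomes are ``assigned`` / ``ambiguous`` / ``no_id``; when
    *true_species* is given, ``assigned`` becomes ``correct`` or
    ``incorrect``.
    """
    query_seq = query_seq.upper().replace("-", "")
    if len(query_seq) < min_length:
        raise ValueError(
            f"query {query_id!r} is {len(query_seq)} bp, below the "
            f"{min_length} bp minimum"
        )
    n_ambig = sum(1 for ch in query_seq if ch not in "ACGT")
    if n_ambig > 0.05 * len(query_seq):
        warnings.warn(
            f"query {query_id!r} contains >5% ambiguity codes; a mixed "
            "template cannot be assigned with confidence",
            UserWarning,
            stacklevel=2,
        )
    aligner = _make_aligner()
    idents = np.empty(len(db))
    for i, rec in enumerate(db):
        ref, _ = degap(rec)
        idents[i], _ = _identity(aligner, ref, query_seq)
    dists = 1.0 - idents / 100.0
    best_i = int(np.argmax(idents))
    best_identity = float(idents[best_i])
    _, aligned_len = _identity(aligner, degap(db.records[best_i])[0], query_seq)
    within = np.nonzero((dists < t) & (idents >= floor_identity))[0]
    sp = np.asarray(db.species, dtype=object)
    if within.size == 0:
        return QueryClassification(query_id, None, best_identity, "no_id",
                                   aligned_len)
    dmin = dists[within].min()
    best = within[dists[within] == dmin]
    best_species = set(sp[best])
    best_ids = tuple(db.ids[j] for j in best)
    if len(best_species) > 1:
        return QueryClassification(query_id, None, best_identity, "ambiguous",
                                   aligned_len, best_ids)
    species = best_species.pop()
    if true_species is None:
        outcome = "assigned"
    else:
        outcome = "correct" if species == true_species else "incorrect"
    return QueryClassification(query_id, species, best_identity, outcome,
                               aligned_len, best_ids)


def classify_queries(queries: Sequence[tuple[str, str]],
                     db: ReferenceAlignment, t: float = 0.01,
                     **kwargs):
    """Classify many ``(id, sequence)`` queries; returns a DataFrame."""
    import pandas as pd

    rows = []
    for qid, seq in queries:
        c = classify_query(qid, seq, db, t=t, **kwargs)
        rows.append(
            {
                "query_id": c.query_id,
                "best_species": c.best_species,
                "identity": c.identity,
                "outcome": c.outcome,
                "aligned_length": c.aligned_length,
            }
        )
    return pd.DataFrame(rows)
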