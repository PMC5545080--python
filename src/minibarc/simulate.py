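"""Synthetic reference alignments with a planted barcode-gap structure.

The generator emulates the statistical shape of a curated mitochondrial
reference database for a predator panel: species form tight clusters (low
intra-specific divergence) separated by much larger inter-specific
divergence, the divergence is concentrated in one variable region
(the mini-barcode target), two short flanks are perfectly conserved
(primer sites), some species are singletons, and some haplotypes are
present in duplicate copies.

Sequences evolve on a star phylogeny: one ancestral sequence, one branch
per species with substitutions confined to the variable region, then one
branch per individual with substitutions anywhere outside the conserved
flanks.  Substitutions favour transitions over transversions by the ratio
``kappa``, so the K2P model is the matched estimator.  Per-branch
substitution probabilities are calibrated analytically so that the
*expected* pairwise raw distance across the whole alignment equals
``inter_div`` (between species) and ``intra_div`` (within species): for a
per-site substitution probability m on w mutable sites out of L,

    E[raw distance] = (w / L) * (2m - (1 + c) m^2),

where c is the chance that two independent substitutions of the same base
coincide, c = (kappa^2 + 2) / (kappa + 2)^2; the quadratic is inverted
for m.  The defaults are a scaled-down predator panel: 8 species (6
multi-haplotype + 2 singletons), a 178-bp variable region with 20-bp
conserved flanks, intra_div 0.005 and inter_div 0.10.

Everything is driven by one integer seed through a single
``numpy.random.default_rng`` stream: the same seed gives byte-identical
output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .refdb import ReferenceAlignment, SequenceRecord

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "Query",
    "simulate_reference",
    "simulate_queries",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner of code 0..3 (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.int64)
# the two transversion partners of each code
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int64)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic reference-set generator.

    ``per_species`` gives the number of individuals per species; entries
    of 1 are singleton species.  ``variable_region`` and each of the two
    ``conserved_flanks`` are 1-based inclusive column spans.
    ``n_duplicate_copies`` appends verbatim copies of the first individual
    of that many multi-haplotype species, emulating identical GenBank
    submissions.  Divergences are expected pairwise raw distances over the
    whole alignment.
    """

    n_species: int = 8
    per_species: tuple[int, ...] = (4, 4, 3, 3, 3, 3, 1, 1)
    length: int = 350
    variable_region: tuple[int, int] = (66, 243)
    conserved_flanks: tuple[tuple[int, int], tuple[int, int]] = (
        (46, 65),
        (244, 263),
    )
    intra_div: float = 0.005
    inter_div: float = 0.10
    kappa: float = 4.0
    n_duplicate_copies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_species) != self.n_species:
            raise ValueError("per_species length must equal n_species")
        if any(k < 1 for k in self.per_species):
            raise ValueError("each species needs at least 1 individual")
        if not 0 <= self.intra_div < self.inter_div:
            raise ValueError("need 0 <= intra_div < inter_div")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        spans = [self.variable_region, *self.conserved_flanks]
        for lo, hi in spans:
            if not 1 <= lo <= hi <= self.length:
                raise ValueError(f"span ({lo}, {hi}) outside [1, {self.length}]")


@dataclass(frozen=True)
class Query:
    """An unaligned query fragment with its true origin."""

    id: str
    sequence: str
    true_species: str
    source_id: str


@dataclass
class SimulatedDataset:
    """A simulated alignment plus the planted truth."""

    alignment: ReferenceAlignment
    spec: SimulationSpec
    species_of: dict[str, str] = field(default_factory=dict)
    singleton_species: list[str] = field(default_factory=list)

    @property
    def variable_region(self) -> tuple[int, int]:
        return self.spec.variable_region

    @property
    def conserved_flanks(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.spec.conserved_flanks


def _coincidence_prob(kappa: float) -> float:
    return (kappa**2 + 2.0) / (kappa + 2.0) ** 2


def _per_site_rate(target_div: float, n_mutable: int, length: int,
                   kappa: float) -> float:
    """Invert the expected-distance formula for the per-branch, per-site
    substitution probability m."""
    if target_div == 0.0:
        return 0.0
    p = target_div * length / n_mutable
    if p > 0.75:
        raise ValueError(
            f"infeasible divergence: expected per-mutable-site distance "
            f"{p:.3f} exceeds 0.75"
        )
    c = _coincidence_prob(kappa)
    disc = 1.0 - (1.0 + c) * p
    if disc < 0.0:
        raise ValueError(
            f"infeasible divergence: {p:.3f} unreachable at kappa={kappa}"
        )
    return (1.0 - np.sqrt(disc)) / (1.0 + c)


def _mutate(codes: np.ndarray, mutable: np.ndarray, m: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """One branch: substitute each mutable site with probability m."""
    out = codes.copy()
    hit = mutable[rng.random(mutable.size) < m]
    if hit.size == 0:
        return out
    is_ts = rng.random(hit.size) < kappa / (kappa + 2.0)
    old = out[hit].astype(np.int64)
    new = np.where(
        is_ts,
        _TS_PARTNER[old],
        _TV_PARTNERS[old, rng.integers(0, 2, hit.size)],
    )
    out[hit] = new.astype(np.uint8)
    return out


def _span_to_index(span: tuple[int, int]) -> np.ndarray:
    return np.arange(span[0] - 1, span[1])


def simulate_reference(spec: SimulationSpec | None = None,
                       seed: int | None = None) -> SimulatedDataset:
    """Generate a reference alignment under *spec* (fully reproducible).

    *seed*, when given, overrides ``spec.seed``.
    """
    spec = spec or SimulationSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    ancestor = rng.integers(0, 4, L).astype(np.uint8)

    var_idx = _span_to_index(spec.variable_region)
    flank_idx = np.concatenate(
        [_span_to_index(f) for f in spec.conserved_flanks]
    )
    # species branches mutate only the variable region; individual branches
    # mutate everything except the conserved primer flanks
    indiv_idx = np.setdiff1d(np.arange(L), flank_idx)
    m_inter = _per_site_rate(spec.inter_div, var_idx.size, L, spec.kappa)
    m_intra = _per_site_rate(spec.intra_div, indiv_idx.size, L, spec.kappa)

    records: list[SequenceRecord] = []
    species_of: dict[str, str] = {}
    singletons: list[str] = []
    dup_budget = spec.n_duplicate_copies
    for k, n_indiv in enumerate(spec.per_species):
        genus = f"Genus{k // 2 + 1:02d}"
        epithet = f"species{k + 1:02d}"
        label = f"{genus} {epithet}"
        sp_ancestor = _mutate(ancestor, var_idx, m_inter, spec.kappa, rng)
        individuals = [
            _mutate(sp_ancestor, indiv_idx, m_intra, spec.kappa, rng)
            for _ in range(n_indiv)
        ]
        if n_indiv > 1 and dup_budget > 0:
            individuals.append(individuals[0].copy())
            dup_budget -= 1
        if n_indiv == 1:
            singletons.append(label)
        for j, codes in enumerate(individuals):
            rid = f"{genus}_{epithet}_{j + 1:02d}"
            seq = _BASES[codes].tobytes().decode("ascii")
            records.append(SequenceRecord(rid, label, genus, seq))
            species_of[rid] = label
    alignment = ReferenceAlignment(records, name=f"SIM_seed{spec.seed}")
    return SimulatedDataset(
        alignment=alignment,
        spec=spec,
        species_of=species_of,
        singleton_species=singletons,
    )


def simulate_queries(ds: SimulatedDataset, n_queries: int = 50,
                     fragment_range: tuple[int, int] = (116, 178),
                     error_rate: float = 0.0,
                     seed: int | None = None) -> list[Query]:
    """Random subfragments of the planted insert with per-base errors.

    Fragments are drawn from the variable region of randomly chosen
    records (mimicking amplicons sequenced from trace samples), with
    independent per-base substitution errors at *error_rate*.  The
    fragment length is uniform over *fragment_range*, capped at the
    insert length.
    """
    spec = ds.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    lo_col, hi_col = spec.variable_region
    insert_len = hi_col - lo_col + 1
    fmin, fmax = fragment_range
    if fmin > insert_len:
        raise ValueError(
            f"minimum fragment length {fmin} exceeds insert length {insert_len}"
        )
    fmax = min(fmax, insert_len)
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    records = ds.alignment.records
    queries: list[Query] = []
    for q in range(n_queries):
        rec = records[int(rng.integers(0, len(records)))]
        frag_len = int(rng.integers(fmin, fmax + 1))
        insert = rec.sequence[lo_col - 1:hi_col]
        start = int(rng.integers(0, insert_len - frag_len + 1))
        frag = insert[start:start + frag_len]
        codes = np.frombuffer(frag.encode("ascii"), np.uint8).copy()
        code_map = np.zeros(256, dtype=np.int64)
        for b, c in zip("ACGT", range(4)):
            code_map[ord(b)] = c
        if error_rate > 0.0:
            err = np.nonzero(rng.random(frag_len) < error_rate)[0]
            if err.size:
                old = code_map[codes[err]]
                shift = rng.integers(1, 4, err.size)
                codes[err] = _BASES[(old + shift) % 4]
        queries.append(
            Query(
                id=f"query{q + 1:04d}_{rec.id}",
                sequence=codes.tobytes().decode("ascii"),
                true_species=rec.species,
                source_id=rec.id,
            )
        )
    return queries
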