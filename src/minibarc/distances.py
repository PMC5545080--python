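"""Pairwise raw (p) and Kimura 2-parameter distances with pairwise deletion.

Distances are computed per sequence pair over the alignment columns where
*both* sequences carry an unambiguous A/C/G/T; columns with a gap, N or any
partial IUPAC code in either member are excluded (pairwise deletion).  The
raw distance is the proportion of differing valid sites.  The K2P distance
corrects for multiple hits while distinguishing transitions (A<->G, C<->T)
from transversions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions.  Pairs with no
valid sites, or saturated pairs where a log argument is non-positive, are
*undefined* and propagate as NaN — they are never silently zeroed.

Because P and Q derive from integer site counts, a distance of exactly 0.0
occurs precisely when a pair is identical on all mutually valid sites;
zero-proportion statistics therefore use exact equality, never a floating
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .refdb import INVALID, ReferenceAlignment

__all__ = [
    "SiteComparison",
    "DistanceMatrix",
    "site_stats",
    "raw_distance",
    "k2p_distance",
    "pair_count_matrices",
    "distance_matrix",
    "zero_cell_proportion",
]

Model = Literal["raw", "k2p"]

# purine/pyrimidine family of each code 0..3 (A,C,G,T); mismatches within a
# family are transitions, across families transversions
_FAMILY = np.array([0, 1, 0, 1], dtype=np.uint8)


@dataclass(frozen=True)
class SiteComparison:
    """Site counts for one sequence pair after pairwise deletion."""

    valid_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        """Transition proportion (NaN when no valid sites)."""
        return self.transitions / self.valid_sites if self.valid_sites else np.nan

    @property
    def Q(self) -> float:
        """Transversion proportion (NaN when no valid sites)."""
        return self.transversions / self.valid_sites if self.valid_sites else np.nan


def _encode_pairwise(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    table = np.full(256, INVALID, dtype=np.uint8)
    for base, code in zip("ACGT", range(4)):
        table[ord(base)] = code
        table[ord(base.lower())] = code
    xa = table[np.frombuffer(a.encode("ascii"), np.uint8)]
    xb = table[np.frombuffer(b.encode("ascii"), np.uint8)]
    return xa, xb


def site_stats(a: str, b: str) -> SiteComparison:
    """Compare two equal-length aligned sequences site by site."""
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    xa, xb = _encode_pairwise(a, b)
    ok = (xa != INVALID) & (xb != INVALID)
    xa, xb = xa[ok], xb[ok]
    diff = xa != xb
    ts = int(np.count_nonzero(diff & (_FAMILY[xa] == _FAMILY[xb])))
    tv = int(np.count_nonzero(diff)) - ts
    return SiteComparison(int(ok.sum()), ts, tv)


def raw_distance(s: SiteComparison) -> float:
    """Proportion of differing valid sites; NaN when no valid sites."""
    if s.valid_sites == 0:
        return np.nan
    return (s.transitions + s.transversions) / s.valid_sites


def k2p_distance(s: SiteComparison) -> float:
    """Kimura 2-parameter distance; NaN when undefined (saturation)."""
    if s.valid_sites == 0:
        return np.nan
    P, Q = s.P, s.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return np.nan
    return -0.5 * np.log(w1 * np.sqrt(w2))


def pair_count_matrices(encoded: np.ndarray, col_start: int = 0,
                        col_end: int | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (valid, transitions, transversions) over a column range.

    *encoded* is the (n, L) uint8 matrix from
    :meth:`~minibarc.refdb.ReferenceAlignment.encoded`.  Counts come from
    one-hot inner products, which BLAS makes fast enough to recompute per
    sliding window; float products are exact for counts far below 2**53.
    """
    sub = encoded[:, col_start:col_end]
    n, w = sub.shape
    valid_mask = sub != INVALID
    # one-hot over the 4 bases; invalid columns are all-zero
    onehot = np.zeros((n, w, 4), dtype=np.float64)
    idx = np.nonzero(valid_mask)
    onehot[idx[0], idx[1], sub[idx]] = 1.0
    flat = onehot.reshape(n, w * 4)
    matches = flat @ flat.T
    vm = valid_mask.astype(np.float64)
    valid = vm @ vm.T
    # same purine/pyrimidine family -> match or transition
    fam = np.zeros((n, w, 2), dtype=np.float64)
    fam[idx[0], idx[1], _FAMILY[sub[idx]]] = 1.0
    famflat = fam.reshape(n, w * 2)
    same_family = famflat @ famflat.T
    ts = np.rint(same_family - matches).astype(np.int64)
    tv = np.rint(valid - same_family).astype(np.int64)
    return np.rint(valid).astype(np.int64), ts, tv


def _distances_from_counts(valid: np.ndarray, ts: np.ndarray, tv: np.ndarray,
                           model: Model) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "raw":
            d = (ts + tv) / valid
        elif model == "k2p":
            P = ts / valid
            Q = tv / valid
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = -0.5 * np.log(w1 * np.sqrt(w2))
            d[(w1 <= 0) | (w2 <= 0)] = np.nan
            # identical pairs: exact zero, no log round-off
            d[(ts + tv == 0) & (valid > 0)] = 0.0
        else:
            raise ValueError(f"unknown model {model!r}")
    d[valid == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with NaN for undefined pairs."""

    ids: list[str]
    model: Model
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def undefined_pairs(self) -> set[tuple[str, str]]:
        """Unordered id pairs whose distance is undefined."""
        nan_mask = np.isnan(self.values)
        out = set()
        for a in range(self.n):
            for b in range(a + 1, self.n):
                if nan_mask[a, b]:
                    out.add((self.ids[a], self.ids[b]))
        return out

    def to_frame(self):
        """Square pandas DataFrame with id index/columns."""
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(db: ReferenceAlignment, model: Model = "raw",
                    columns: tuple[int, int] | None = None) -> DistanceMatrix:
    """All-pairs distance matrix, optionally restricted to a column window.

    *columns* is a 0-based half-open ``(start, end)`` range.  Undefined
    pairs (no shared valid sites, or K2P saturation) are NaN.
    """
    if len(db) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    start, end = columns if columns is not None else (0, db.length)
    valid, ts, tv = pair_count_matrices(db.encoded(), start, end)
    values = _distances_from_counts(valid, ts, tv, model)
    return DistanceMatrix(ids=db.ids, model=model, values=values)


def zero_cell_proportion(m: DistanceMatrix,
                         scope: Literal["all_offdiagonal", "nonconspecific"]
                         = "all_offdiagonal",
                         species: list[str] | None = None) -> float:
    """Fraction of defined unordered pairs in scope with distance exactly 0.

    The non-conspecific scope restricts to pairs with different species
    labels.  Returns NaN when the scope contains no defined pair (e.g. a
    single species under the non-conspecific scope).
    """
    n = m.n
    iu = np.triu_indices(n, 1)
    vals = m.values[iu]
    in_scope = np.ones(len(vals), dtype=bool)
    if scope == "nonconspecific":
        if species is None:
            raise ValueError("species labels required for nonconspecific scope")
        if len(species) != n:
            raise ValueError("species labels do not match matrix size")
        sp = np.asarray(species, dtype=object)
        in_scope = sp[iu[0]] != sp[iu[1]]
    elif scope != "all_offdiagonal":
        raise ValueError(f"unknown scope {scope!r}")
    defined = in_scope & ~np.isnan(vals)
    if not defined.any():
        return np.nan
    return float(np.count_nonzero(vals[defined] == 0.0) / defined.sum())
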