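"""Sliding-window alignment diagnostics for mini-barcode design.

A short diagnostic region ("mini-barcode") must separate species — every
non-conspecific pair should differ within it — while its flanks must be
conserved enough across all taxa to place universal primers.  Both
properties are screened by sliding a fixed-width window along the
alignment and computing, per window: the mean K2P distance, the proportion
of zero cells in the distance matrix, the number of diagnostic nucleotide
positions, and the proportion of zero *non-conspecific* distances.  A
candidate barcode region is a maximal run of window starts where the last
quantity is exactly 0; a candidate primer site is a 20-bp window where it
exceeds 0.8 with at most one diagnostic nucleotide.

Window starts are reported 1-based in all outputs (matching how positions
are read off an alignment viewer); ``diagnostic_positions`` returns
0-based column indices for programmatic use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .distances import pair_count_matrices, _distances_from_counts
from .refdb import INVALID, ReferenceAlignment

__all__ = [
    "WindowMetrics",
    "WindowProfile",
    "BarcodeCandidate",
    "PrimerSiteCandidate",
    "diagnostic_positions",
    "diagnostic_column_counts",
    "window_profile",
    "find_barcode_regions",
    "find_primer_sites",
]

RegionConvention = Literal["start-span", "inclusive", "covered"]


@dataclass(frozen=True)
class WindowMetrics:
    """Diagnostics for one window.

    ``start`` is the 1-based alignment column of the window's first
    nucleotide.  ``n_diagnostic`` counts columns diagnostic for at least
    one species (union convention); ``n_diagnostic_sum`` is the
    per-species sum over the same columns, exposed so either counting
    convention can be compared against published profiles.
    """

    start: int
    width: int
    mean_k2p: float
    prop_zero_cells: float
    n_diagnostic: int
    prop_zero_noncon: float
    n_diagnostic_sum: int


@dataclass
class WindowProfile:
    """Ordered window metrics at a fixed width and stride."""

    metrics: list[WindowMetrics]
    alignment_name: str
    model: str
    width: int
    stride: int

    def __iter__(self):
        return iter(self.metrics)

    def __len__(self) -> int:
        return len(self.metrics)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "start": m.start,
                    "width": m.width,
                    "mean_k2p": m.mean_k2p,
                    "prop_zero_cells": m.prop_zero_cells,
                    "n_diagnostic": m.n_diagnostic,
                    "prop_zero_noncon": m.prop_zero_noncon,
                    "n_diagnostic_sum": m.n_diagnostic_sum,
                }
                for m in self.metrics
            ]
        )


@dataclass(frozen=True)
class BarcodeCandidate:
    """A maximal run of window starts with zero non-conspecific overlap."""

    start: int
    end_exclusive: int
    length: int
    supporting_widths: tuple[int, ...]


@dataclass(frozen=True)
class PrimerSiteCandidate:
    """A maximal run of conserved primer-width windows.

    ``prop_zero_noncon`` is the best (largest) value in the run and
    ``n_diagnostic`` the smallest; ``n_windows`` the run length in starts.
    """

    start: int
    width: int
    n_windows: int
    prop_zero_noncon: float
    n_diagnostic: int


def _state_counts(db: ReferenceAlignment) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-species per-column base counts.

    Returns ``(counts, members, species_order)`` where counts has shape
    (n_species, L, 4) and members the number of records per species.
    """
    enc = db.encoded()
    species_order = list(dict.fromkeys(db.species))
    sp_index = {s: k for k, s in enumerate(species_order)}
    n_sp, L = len(species_order), db.length
    counts = np.zeros((n_sp, L, 4), dtype=np.int64)
    members = np.zeros(n_sp, dtype=np.int64)
    for rec, row in zip(db.records, enc):
        k = sp_index[rec.species]
        members[k] += 1
        ok = row != INVALID
        np.add.at(counts[k], (np.nonzero(ok)[0], row[ok]), 1)
    return counts, members, species_order


def _diagnostic_matrix(db: ReferenceAlignment) -> tuple[np.ndarray, list[str]]:
    """(n_species, L) bool: column diagnostic for that species.

    A column is diagnostic for species *s* iff every member of *s* carries
    the same unambiguous base there and no member of any other species
    carries that base.  Columns where *s* has any gap or ambiguity are not
    diagnostic for *s*.
    """
    counts, members, species_order = _state_counts(db)
    totals = counts.sum(axis=0)  # (L, 4) across all species
    fixed = counts == members[:, None, None]  # all members share this base
    exclusive = counts == totals[None, :, :]  # no other species has it
    return (fixed & exclusive).any(axis=2), species_order


def diagnostic_positions(db: ReferenceAlignment,
                         columns: tuple[int, int] | None = None
                         ) -> dict[str, set[int]]:
    """Per-species sets of diagnostic 0-based column indices."""
    if len(set(db.species)) < 2:
        raise ValueError("diagnostic positions need at least 2 species")
    diag, species_order = _diagnostic_matrix(db)
    start, end = columns if columns is not None else (0, db.length)
    out: dict[str, set[int]] = {}
    for k, sp in enumerate(species_order):
        cols = np.nonzero(diag[k, start:end])[0] + start
        out[sp] = set(int(c) for c in cols)
    return out


def diagnostic_column_counts(db: ReferenceAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column union indicator and per-species sum of diagnosticity."""
    diag, _ = _diagnostic_matrix(db)
    return diag.any(axis=0), diag.sum(axis=0)


def _zero_proportions(values: np.ndarray, noncon_mask: np.ndarray,
                      iu: tuple[np.ndarray, np.ndarray]
                      ) -> tuple[float, float]:
    vals = values[iu]
    defined = ~np.isnan(vals)
    prop_all = (
        float(np.count_nonzero(vals[defined] == 0.0) / defined.sum())
        if defined.any()
        else np.nan
    )
    dn = defined & noncon_mask
    prop_noncon = (
        float(np.count_nonzero(vals[dn] == 0.0) / dn.sum()) if dn.any() else np.nan
    )
    return prop_all, prop_noncon


def window_profile(db: ReferenceAlignment, width: int, stride: int = 1,
                   model: str = "k2p") -> WindowProfile:
    """Compute window diagnostics at every start position at a stride.

    The distance matrix is recomputed inside each window with pairwise
    deletion restricted to the window's columns; windows are only placed
    fully inside the alignment.
    """
    L = db.length
    if not 1 <= width <= L:
        raise ValueError(f"window width {width} not in [1, {L}]")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    enc = db.encoded()
    union, persum = diagnostic_column_counts(db)
    cum_union = np.concatenate([[0], np.cumsum(union)])
    cum_sum = np.concatenate([[0], np.cumsum(persum)])
    sp = np.asarray(db.species, dtype=object)
    iu = np.triu_indices(len(db), 1)
    noncon = sp[iu[0]] != sp[iu[1]]
    metrics: list[WindowMetrics] = []
    for s0 in range(0, L - width + 1, stride):
        valid, ts, tv = pair_count_matrices(enc, s0, s0 + width)
        values = _distances_from_counts(valid, ts, tv, model)
        vals = values[iu]
        mean_d = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else np.nan
        prop_all, prop_noncon = _zero_proportions(values, noncon, iu)
        metrics.append(
            WindowMetrics(
                start=s0 + 1,
                width=width,
                mean_k2p=mean_d,
                prop_zero_cells=prop_all,
                n_diagnostic=int(cum_union[s0 + width] - cum_union[s0]),
                prop_zero_noncon=prop_noncon,
                n_diagnostic_sum=int(cum_sum[s0 + width] - cum_sum[s0]),
            )
        )
    return WindowProfile(
        metrics=metrics,
        alignment_name=db.name,
        model=model,
        width=width,
        stride=stride,
    )


def _run_length(s1: int, s2: int, width: int,
                convention: RegionConvention) -> int:
    if convention == "start-span":
        return s2 - s1
    if convention == "inclusive":
        return s2 - s1 + 1
    if convention == "covered":
        return s2 + width - s1
    raise ValueError(f"unknown region convention {convention!r}")


def find_barcode_regions(profile: WindowProfile, min_len: int = 100,
                         max_len: int | None = None,
                         convention: RegionConvention = "start-span"
                         ) -> list[BarcodeCandidate]:
    """Maximal runs of window starts whose prop_zero_noncon is exactly 0.

    A run of qualifying starts s1..s2 is reported with length s2 - s1 under
    the default start-span convention; ``inclusive`` (s2 - s1 + 1) and
    ``covered`` (s2 + width - s1, the full extent of sequence touched) are
    available.  Runs shorter than *min_len* are dropped; *max_len*, when
    given, drops longer runs.
    """
    out: list[BarcodeCandidate] = []
    run: list[int] = []

    def flush() -> None:
        if not run:
            return
        s1, s2 = run[0], run[-1]
        length = _run_length(s1, s2, profile.width, convention)
        if length >= min_len and (max_len is None or length <= max_len):
            out.append(
                BarcodeCandidate(
                    start=s1,
                    end_exclusive=s1 + length,
                    length=length,
                    supporting_widths=(profile.width,),
                )
            )
        run.clear()

    prev = None
    for m in profile:
        qualifies = m.prop_zero_noncon == 0.0
        contiguous = prev is not None and m.start == prev + profile.stride
        if qualifies:
            if run and not contiguous:
                flush()
            run.append(m.start)
        else:
            flush()
        prev = m.start
    flush()
    return out


def find_primer_sites(profile: WindowProfile,
                      min_prop_zero_noncon: float = 0.8,
                      max_diagnostic: int = 1) -> list[PrimerSiteCandidate]:
    """Conserved windows suitable for primer placement, merged into runs.

    A window qualifies when its proportion of zero non-conspecific
    distances exceeds *min_prop_zero_noncon* and it contains at most
    *max_diagnostic* diagnostic nucleotides.
    """
    out: list[PrimerSiteCandidate] = []
    run: list[WindowMetrics] = []

    def flush() -> None:
        if not run:
            return
        out.append(
            PrimerSiteCandidate(
                start=run[0].start,
                width=profile.width,
                n_windows=len(run),
                prop_zero_noncon=max(m.prop_zero_noncon for m in run),
                n_diagnostic=min(m.n_diagnostic for m in run),
            )
        )
        run.clear()

    prev = None
    for m in profile:
        qualifies = (
            not np.isnan(m.prop_zero_noncon)
            and m.prop_zero_noncon > min_prop_zero_noncon
            and m.n_diagnostic <= max_diagnostic
        )
        contiguous = prev is not None and m.start == prev + profile.stride
        if qualifies:
            if run and not contiguous:
                flush()
            run.append(m)
        else:
            flush()
        prev = m.start
    flush()
    return out


def plot_profile(profile: WindowProfile, path=None):
    """Four-panel window profile plot (mean K2P, zero cells, diagnostic
    nucleotides, zero non-conspecific), one point per window start."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = profile.to_frame()
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 9))
    panels = [
        ("mean_k2p", "mean K2P"),
        ("prop_zero_cells", "prop. zero cells"),
        ("n_diagnostic", "diagnostic nt"),
        ("prop_zero_noncon", "prop. zero non-consp."),
    ]
    for ax, (col, label) in zip(axes, panels):
        ax.plot(frame["start"], frame[col], lw=0.8)
        ax.set_ylabel(label)
    axes[-1].set_xlabel("window start (alignment position)")
    fig.suptitle(f"{profile.alignment_name}: {profile.width}-bp windows")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
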