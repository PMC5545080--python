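"""Distance-threshold species identification and threshold optimisation.

Three self-match tests evaluate how reliably a reference database assigns
species from a short barcode, each treating every database sequence in
turn as a query against all others:

* **nearest neighbour** — is any sequence at the minimum distance a
  conspecific?  Outcomes: true / false.
* **best close match** — among non-self sequences *within* a distance
  threshold t, look only at those at the minimum distance: all conspecific
  -> correct, none -> incorrect, mixed -> ambiguous; nothing within t ->
  no identification.
* **threshold ID** — consider *all* sequences within t: all conspecific ->
  correct, all heterospecific -> incorrect, both -> ambiguous, none ->
  no identification.

The working threshold is chosen by scanning a grid and minimising the
cumulative error, false positives (a query whose in-threshold match set
contains a heterospecific) plus false negatives (a query with conspecifics
in the database but none within t).

Conventions frozen here: "within threshold" means strictly ``d < t``
(``inclusive=True`` switches to ``d <= t``); nearest-neighbour ties use
the optimistic rule (true if *any* tied nearest sequence is conspecific;
``strict_ties=True`` requires all); undefined (NaN) distances never count
as matches at any threshold; the scan's tie-break is the smallest
threshold attaining the minimum error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "IdentificationOutcome",
    "IdentificationReport",
    "ThresholdScan",
    "DEFAULT_GRID",
    "near_neighbour",
    "best_close_match",
    "thresh_id",
    "threshold_scan",
    "summarize_report",
]

Outcome = Literal["correct", "incorrect", "ambiguous", "no_id", "undefined"]

#: 0.1% to 10% in 0.1% steps — covers the 1% and 3.5% working thresholds.
DEFAULT_GRID: np.ndarray = np.round(np.arange(1, 101) * 0.001, 3)


@dataclass(frozen=True)
class IdentificationOutcome:
    sequence_id: str
    species: str
    outcome: Outcome
    nearest_ids: tuple[str, ...]
    nearest_distance: float
    matches_in_threshold: tuple[str, ...] = ()


@dataclass
class IdentificationReport:
    test: Literal["near_neighbour", "best_close_match", "thresh_id"]
    threshold: float | None
    per_sequence: list[IdentificationOutcome]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = summarize_report(self)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": o.sequence_id,
                    "species": o.species,
                    "outcome": o.outcome,
                    "nearest_ids": ";".join(o.nearest_ids),
                    "nearest_distance": o.nearest_distance,
                }
                for o in self.per_sequence
            ]
        )


@dataclass
class ThresholdScan:
    grid: np.ndarray
    true_pos: np.ndarray
    false_pos: np.ndarray
    false_neg: np.ndarray
    true_neg: np.ndarray

    @property
    def cumulative_error(self) -> np.ndarray:
        return self.false_pos + self.false_neg

    @property
    def optimum(self) -> float:
        """Smallest grid threshold attaining the minimum cumulative error."""
        e = self.cumulative_error
        return float(self.grid[int(np.argmin(e))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.grid,
                "true_pos": self.true_pos,
                "false_pos": self.false_pos,
                "false_neg": self.false_neg,
                "true_neg": self.true_neg,
                "cumulative_error": self.cumulative_error,
            }
        )


def _check(m: DistanceMatrix, species: Sequence[str]) -> np.ndarray:
    if len(species) != m.n:
        raise ValueError("species labels do not match matrix size")
    if m.n < 2:
        raise ValueError("identification needs at least 2 records")
    d = m.values.copy()
    np.fill_diagonal(d, np.nan)  # self-comparisons excluded
    return d


def _warn_undefined(m: DistanceMatrix, i: int) -> None:
    warnings.warn(
        f"sequence {m.ids[i]!r} has no defined distance to any other "
        "sequence; excluded from identification counts",
        UserWarning,
        stacklevel=3,
    )


def near_neighbour(m: DistanceMatrix, species: Sequence[str],
                   strict_ties: bool = False) -> IdentificationReport:
    """Nearest-neighbour self-match test (true/false outcomes).

    A sequence is *true* when a conspecific sits at the minimum non-self
    distance (any tied nearest under the default optimistic rule, all of
    them when *strict_ties*).  Singleton species are necessarily false:
    their nearest neighbour is automatically another species.
    """
    d = _check(m, species)
    sp = np.asarray(species, dtype=object)
    outcomes: list[IdentificationOutcome] = []
    for i in range(m.n):
        row = d[i]
        if np.all(np.isnan(row)):
            _warn_undefined(m, i)
            outcomes.append(
                IdentificationOutcome(m.ids[i], sp[i], "undefined", (), np.nan)
            )
            continue
        dmin = np.nanmin(row)
        nearest = np.nonzero(row == dmin)[0]
        consp = sp[nearest] == sp[i]
        ok = bool(consp.all()) if strict_ties else bool(consp.any())
        outcomes.append(
            IdentificationOutcome(
                m.ids[i],
                sp[i],
                "correct" if ok else "incorrect",
                tuple(m.ids[j] for j in nearest),
                float(dmin),
            )
        )
    return IdentificationReport("near_neighbour", None, outcomes)


def _threshold_matches(row: np.ndarray, t: float, inclusive: bool) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        hit = row <= t if inclusive else row < t
    return np.nonzero(hit & ~np.isnan(row))[0]


def best_close_match(m: DistanceMatrix, species: Sequence[str], t: float,
                     inclusive: bool = False) -> IdentificationReport:
    """Best-close-match test at threshold *t* (strict ``d < t`` by default)."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    d = _check(m, species)
    sp = np.asarray(species, dtype=object)
    outcomes: list[IdentificationOutcome] = []
    for i in range(m.n):
        row = d[i]
        if np.all(np.isnan(row)):
            _warn_undefined(m, i)
            outcomes.append(
                IdentificationOutcome(m.ids[i], sp[i], "undefined", (), np.nan)
            )
            continue
        within = _threshold_matches(row, t, inclusive)
        if within.size == 0:
            outcomes.append(
                IdentificationOutcome(
                    m.ids[i], sp[i], "no_id", (), float(np.nanmin(row))
                )
            )
            continue
        dmin = row[within].min()
        best = within[row[within] == dmin]
        consp = sp[best] == sp[i]
        if consp.all():
            out: Outcome = "correct"
        elif not consp.any():
            out = "incorrect"
        else:
            out = "ambiguous"
        outcomes.append(
            IdentificationOutcome(
                m.ids[i],
                sp[i],
                out,
                tuple(m.ids[j] for j in best),
                float(dmin),
                tuple(m.ids[j] for j in within),
            )
        )
    return IdentificationReport("best_close_match", t, outcomes)


def thresh_id(m: DistanceMatrix, species: Sequence[str], t: float,
              inclusive: bool = False) -> IdentificationReport:
    """Threshold-ID test: judge *all* sequences within the threshold."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    d = _check(m, species)
    sp = np.asarray(species, dtype=object)
    outcomes: list[IdentificationOutcome] = []
    for i in range(m.n):
        row = d[i]
        if np.all(np.isnan(row)):
            _warn_undefined(m, i)
            outcomes.append(
                IdentificationOutcome(m.ids[i], sp[i], "undefined", (), np.nan)
            )
            continue
        within = _threshold_matches(row, t, inclusive)
        dmin = float(np.nanmin(row))
        nearest = tuple(m.ids[j] for j in np.nonzero(row == np.nanmin(row))[0])
        if within.size == 0:
            out: Outcome = "no_id"
        else:
            consp = sp[within] == sp[i]
            if consp.all():
                out = "correct"
            elif not consp.any():
                out = "incorrect"
            else:
                out = "ambiguous"
        outcomes.append(
            IdentificationOutcome(
                m.ids[i],
                sp[i],
                out,
                nearest,
                dmin,
                tuple(m.ids[j] for j in within),
            )
        )
    return IdentificationReport("thresh_id", t, outcomes)


def threshold_scan(m: DistanceMatrix, species: Sequence[str],
                   grid: Iterable[float] | None = None,
                   inclusive: bool = False) -> ThresholdScan:
    """Cumulative-error scan over a threshold grid.

    Per threshold, each sequence is a true positive (has in-threshold
    matches, all conspecific), false positive (matches include a
    heterospecific), false negative (no matches though conspecifics exist
    in the database) or true negative (no matches and no conspecifics — a
    singleton).  Sequences with no defined distances are excluded.
    """
    grid_arr = DEFAULT_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if grid_arr.size == 0 or np.any(np.diff(grid_arr) <= 0):
        raise ValueError("grid must be non-empty and strictly ascending")
    d = _check(m, species)
    sp = np.asarray(species, dtype=object)
    has_consp = np.array(
        [np.count_nonzero(sp == sp[i]) > 1 for i in range(m.n)]
    )
    tp = np.zeros(grid_arr.size, dtype=int)
    fp = np.zeros_like(tp)
    fn = np.zeros_like(tp)
    tn = np.zeros_like(tp)
    for i in range(m.n):
        row = d[i]
        if np.all(np.isnan(row)):
            _warn_undefined(m, i)
            continue
        for k, t in enumerate(grid_arr):
            within = _threshold_matches(row, float(t), inclusive)
            if within.size == 0:
                if has_consp[i]:
                    fn[k] += 1
                else:
                    tn[k] += 1
            elif np.all(sp[within] == sp[i]):
                tp[k] += 1
            else:
                fp[k] += 1
    return ThresholdScan(grid_arr, tp, fp, fn, tn)


def summarize_report(report: IdentificationReport) -> dict[str, int]:
    """Outcome counts in summary-table shape (conserving the total)."""
    if report.test == "near_neighbour":
        keys = ["correct", "incorrect"]
    else:
        keys = ["correct", "incorrect", "ambiguous", "no_id"]
    counts = {k: 0 for k in keys}
    for o in report.per_sequence:
        if o.outcome == "undefined":
            counts.setdefault("undefined", 0)
            counts["undefined"] += 1
        else:
            counts[o.outcome] += 1
    return counts
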