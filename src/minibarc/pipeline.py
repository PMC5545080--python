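"""End-to-end design and evaluation pipelines with reproducible outputs.

Two orchestrations mirror the two halves of a mini-barcode study:

* the **design** pipeline scans the alignment at a wide (barcode) width
  and a narrow (primer) width, then reports candidate barcode regions and
  conserved primer sites;
* the **evaluation** pipeline optionally trims the alignment to a primer
  pair's insert, builds the FULL and UNIQUE databases, optimises the
  distance threshold by cumulative error, and runs the three
  identification tests on both databases at their optima.

Every run writes plain TSV tables plus a JSON echo of the configuration
(including input file hashes and package version), so a run can be
reproduced and diffed byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .amplicon import PrimerPair, locate_amplicon, trim_to_amplicon
from .distances import distance_matrix
from .identify import (
    DEFAULT_GRID,
    best_close_match,
    near_neighbour,
    thresh_id,
    threshold_scan,
)
from .refdb import LabelRule, ReferenceAlignment, build_unique, read_alignment, summarize
from .windows import find_barcode_regions, find_primer_sites, window_profile

__all__ = ["RunConfig", "run_design_pipeline", "run_evaluation_pipeline"]


@dataclass
class RunConfig:
    """Configuration shared by the pipelines."""

    input_path: str
    output_dir: str
    label_rule: LabelRule = field(default_factory=LabelRule)
    model: str = "k2p"
    barcode_widths: tuple[int, ...] = (100, 125, 150, 175)
    primer_widths: tuple[int, ...] = (20, 25, 30)
    stride: int = 1
    min_region_len: int = 100
    min_prop_zero_noncon: float = 0.8
    max_diagnostic: int = 1
    eval_model: str = "raw"
    grid: tuple[float, ...] = tuple(float(t) for t in DEFAULT_GRID)
    primer_pair: PrimerPair | None = None
    max_primer_mismatch: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.input_path).is_file():
            raise FileNotFoundError(f"input file not found: {self.input_path}")

    def to_json(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return dataclasses.asdict(v)
            return v

        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _run_echo(config: RunConfig, db: ReferenceAlignment) -> dict:
    s = summarize(db)
    return {
        "config": config.to_json(),
        "input_sha256": _sha256(config.input_path),
        "n_sequences": s.n_sequences,
        "n_species": s.n_species,
        "n_genera": s.n_genera,
        "alignment_length": db.length,
        "minibarc_version": __version__,
    }


def run_design_pipeline(config: RunConfig) -> dict:
    """Scan -> candidate regions -> primer sites; write TSVs and a log."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = read_alignment(config.input_path, config.label_rule)
    echo = _run_echo(config, db)

    results: dict = {"profiles": {}, "regions": {}, "primer_sites": {}}
    for width in (*config.barcode_widths, *config.primer_widths):
        profile = window_profile(db, width, config.stride, config.model)
        frame = profile.to_frame()
        frame.to_csv(out / f"profile_w{width}.tsv", sep="\t", index=False)
        results["profiles"][width] = profile
    for width in config.barcode_widths:
        regions = find_barcode_regions(
            results["profiles"][width], min_len=config.min_region_len
        )
        results["regions"][width] = regions
    for width in config.primer_widths:
        sites = find_primer_sites(
            results["profiles"][width],
            min_prop_zero_noncon=config.min_prop_zero_noncon,
            max_diagnostic=config.max_diagnostic,
        )
        results["primer_sites"][width] = sites

    import pandas as pd

    pd.DataFrame(
        [
            {
                "width": w,
                "start": r.start,
                "end_exclusive": r.end_exclusive,
                "length": r.length,
            }
            for w, rs in results["regions"].items()
            for r in rs
        ]
    ).to_csv(out / "barcode_candidates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "width": w,
                "start": s.start,
                "n_windows": s.n_windows,
                "prop_zero_noncon": s.prop_zero_noncon,
                "n_diagnostic": s.n_diagnostic,
            }
            for w, ss in results["primer_sites"].items()
            for s in ss
        ]
    ).to_csv(out / "primer_sites.tsv", sep="\t", index=False)
    echo["outputs"] = sorted(p.name for p in out.glob("*.tsv"))
    _write_json(echo, out / "design_run.json")
    results["echo"] = echo
    return results


def _evaluate_database(db: ReferenceAlignment, config: RunConfig, out: Path,
                       tag: str) -> dict:
    m = distance_matrix(db, model=config.eval_model)
    scan = threshold_scan(m, db.species, config.grid)
    scan.to_frame().to_csv(out / f"threshold_scan_{tag}.tsv", sep="\t",
                           index=False)
    t = scan.optimum
    reports = {
        "near_neighbour": near_neighbour(m, db.species),
        "best_close_match": best_close_match(m, db.species, t),
        "thresh_id": thresh_id(m, db.species, t),
    }
    for name, rep in reports.items():
        rep.to_frame().to_csv(out / f"{name}_{tag}.tsv", sep="\t", index=False)
    return {"matrix": m, "scan": scan, "optimum": t, "reports": reports}


def run_evaluation_pipeline(config: RunConfig) -> dict:
    """Trim (if primers given) -> FULL/UNIQUE -> scan -> three tests."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = read_alignment(config.input_path, config.label_rule)
    echo = _run_echo(config, db)

    region = None
    if config.primer_pair is not None:
        region = locate_amplicon(db, config.primer_pair,
                                 config.max_primer_mismatch)
        db = trim_to_amplicon(db, region)
        echo["amplicon"] = {
            "insert_start": region.insert_start,
            "insert_end_inclusive": region.insert_end_inclusive,
            "insert_length": region.insert_length,
        }
    full = ReferenceAlignment(list(db.records), name="FULL")
    unique = build_unique(full)
    unique.name = "UNIQUE"

    results: dict = {"region": region, "databases": {"FULL": full,
                                                     "UNIQUE": unique}}
    summary_rows = []
    for tag, database in (("FULL", full), ("UNIQUE", unique)):
        if len(database) < 2:
            continue
        res = _evaluate_database(database, config, out, tag)
        results[tag] = res
        for name, rep in res["reports"].items():
            summary_rows.append(
                {"database": tag, "test": name, "threshold": res["optimum"],
                 **rep.counts}
            )
    import pandas as pd

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "identification_summary.tsv", sep="\t", index=False)
    results["summary"] = summary
    echo["outputs"] = sorted(p.name for p in out.glob("*.tsv"))
    echo["optima"] = {tag: results[tag]["optimum"]
                      for tag in ("FULL", "UNIQUE") if tag in results}
    _write_json(echo, out / "evaluation_run.json")
    results["echo"] = echo
    return results
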