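import math

import numpy as np
import pytest

from minibarc.distances import distance_matrix, zero_cell_proportion
from minibarc.simulate import SimulationSpec, simulate_reference
from minibarc.windows import (
    diagnostic_column_counts,
    diagnostic_positions,
    find_barcode_regions,
    find_primer_sites,
    window_profile,
)

from _bruteforce import brute_diagnostic_columns, brute_window_metrics


class TestDiagnosticPositions:
    def test_hand_example(self, db_factory):
        db = db_factory(
            [
                ("a1", "A a", "ACGT"),
                ("a2", "A a", "ACGT"),
                ("b1", "B b", "ACGA"),
                ("b2", "B b", "ACTA"),
            ]
        )
        pos = diagnostic_positions(db)
        assert pos["A a"] == {3}  # fixed T, absent from B
        assert pos["B b"] == {3}  # fixed A, absent from A
        union, _ = diagnostic_column_counts(db)
        assert union.sum() == 1

    def test_all_identical_none(self, db_factory):
        db = db_factory(
            [("a1", "A a", "ACGT"), ("b1", "B b", "ACGT")]
        )
        pos = diagnostic_positions(db)
        assert pos["A a"] == set() and pos["B b"] == set()

    def test_ambiguity_blocks_diagnosticity(self, db_factory):
        # species A fixed T at col 4, but one member has N there
        db = db_factory(
            [
                ("a1", "A a", "ACGT"),
                ("a2", "A a", "ACGN"),
                ("b1", "B b", "ACGA"),
            ]
        )
        assert diagnostic_positions(db)["A a"] == set()

    def test_matches_bruteforce_on_random_alignments(self, db_factory):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(3, 7))
            seqs = ["".join(rng.choice(list("ACGTN-"), 12)) for _ in range(n)]
            species = [f"S p{int(rng.integers(0, 3))}" for _ in range(n)]
            db = db_factory(
                [(f"s{i}", species[i], seqs[i]) for i in range(n)],
                name=f"t{trial}",
            )
            union, _ = diagnostic_column_counts(db)
            assert set(np.nonzero(union)[0]) == brute_diagnostic_columns(
                [s.upper() for s in seqs], species
            )


class TestWindowProfile:
    def test_degenerate_full_width_window(self, db_factory):
        db = db_factory(
            [("a1", "A a", "ACGTACGT"), ("a2", "A a", "ACGTACGA"),
             ("b1", "B b", "TCGAACGT")]
        )
        profile = window_profile(db, width=db.length)
        assert len(profile) == 1
        m = distance_matrix(db, "k2p")
        iu = np.triu_indices(3, 1)
        assert profile.metrics[0].mean_k2p == pytest.approx(
            np.nanmean(m.values[iu])
        )
        assert profile.metrics[0].start == 1

    def test_metrics_equal_bruteforce_per_window(self, db_factory):
        rng = np.random.default_rng(17)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(4)]
        species = ["A a", "A a", "B b", "C c"]
        db = db_factory([(f"s{i}", species[i], seqs[i]) for i in range(4)])
        profile = window_profile(db, width=4, stride=1)
        assert [m.start for m in profile] == list(range(1, 8))

        def close(got, expect):
            if expect is None:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)

        for m in profile:
            s0 = m.start - 1
            mean_d, prop_zero, prop_zero_noncon = brute_window_metrics(
                seqs, species, s0, 4, "k2p"
            )
            close(m.mean_k2p, mean_d)
            close(m.prop_zero_cells, prop_zero)
            close(m.prop_zero_noncon, prop_zero_noncon)
            window_cols = brute_diagnostic_columns(seqs, species)
            assert m.n_diagnostic == len(
                {c for c in window_cols if s0 <= c < s0 + 4}
            )

    def test_windowed_matrix_agrees_with_distances_module(self, db_factory):
        rng = np.random.default_rng(23)
        seqs = ["".join(rng.choice(list("ACGT-"), 20)) for _ in range(5)]
        species = ["A a", "A a", "B b", "B b", "C c"]
        db = db_factory([(f"s{i}", species[i], seqs[i]) for i in range(5)])
        profile = window_profile(db, width=6, stride=2, model="raw")
        for m in profile:
            s0 = m.start - 1
            sub = distance_matrix(db, "raw", columns=(s0, s0 + 6))
            assert m.prop_zero_noncon == pytest.approx(
                zero_cell_proportion(sub, "nonconspecific", species), nan_ok=True
            )

    def test_invariant_columns_window(self, db_factory):
        # cols 1-4 invariant; at col 5 the three species carry three states
        db = db_factory(
            [("a1", "A a", "AAAAGAAA"), ("b1", "B b", "AAAACAAA"),
             ("c1", "C c", "AAAATAAA")]
        )
        profile = window_profile(db, width=4)
        assert profile.metrics[0].prop_zero_noncon == 1.0
        assert profile.metrics[4].prop_zero_noncon == 0.0  # cols 5-8

    def test_diagnostic_count_bounded_by_columns(self, db_factory):
        rng = np.random.default_rng(29)
        seqs = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(6)]
        species = ["A a", "A a", "B b", "B b", "C c", "C c"]
        db = db_factory([(f"s{i}", species[i], seqs[i]) for i in range(6)])
        union, persum = diagnostic_column_counts(db)
        for m in window_profile(db, width=5):
            s0 = m.start - 1
            assert m.n_diagnostic == union[s0:s0 + 5].sum()
            assert m.n_diagnostic <= m.n_diagnostic_sum == persum[s0:s0 + 5].sum()
            assert 0 <= m.n_diagnostic <= 5

    def test_width_and_stride_validation(self, db_factory):
        db = db_factory([("a1", "A a", "ACGT"), ("b1", "B b", "ACGA")])
        with pytest.raises(ValueError):
            window_profile(db, width=5)
        with pytest.raises(ValueError):
            window_profile(db, width=2, stride=0)


class TestRegionFinding:
    def test_no_zero_windows_empty(self, db_factory):
        db = db_factory(
            [("a1", "A a", "ACGTACGT"), ("a2", "A a", "ACGTACGT"),
             ("b1", "B b", "ACGTACGT")]
        )
        profile = window_profile(db, width=4)
        assert find_barcode_regions(profile, min_len=1) == []

    def test_run_length_conventions(self, db_factory):
        # one substitution inside every 4-bp window: all windows qualify
        db = db_factory(
            [("a1", "A a", "AAAAAAAA"), ("b1", "B b", "AAGAAAGA")]
        )
        profile = window_profile(db, width=4)  # starts 1..5
        span = find_barcode_regions(profile, min_len=1)[0]
        assert (span.start, span.length) == (1, 4)  # 5 - 1
        inc = find_barcode_regions(profile, min_len=1, convention="inclusive")[0]
        assert inc.length == 5
        cov = find_barcode_regions(profile, min_len=1, convention="covered")[0]
        assert cov.length == 8

    def test_min_len_filter(self, db_factory):
        db = db_factory(
            [("a1", "A a", "AAAAAAAA"), ("b1", "B b", "AAGAAAGA")]
        )
        profile = window_profile(db, width=4)
        assert find_barcode_regions(profile, min_len=5) == []

    def test_planted_region_recovered(self):
        spec = SimulationSpec(
            n_species=6,
            per_species=(3, 3, 3, 3, 2, 2),
            length=700,
            variable_region=(201, 420),
            conserved_flanks=((181, 200), (421, 440)),
            intra_div=0.002,
            inter_div=0.12,
            n_duplicate_copies=0,
            seed=42,
        )
        ds = simulate_reference(spec)
        profile = window_profile(ds.alignment, width=100)
        regions = find_barcode_regions(profile, min_len=50)
        assert len(regions) == 1
        region = regions[0]
        lo, hi = spec.variable_region
        # qualifying starts can at most span windows overlapping the planted
        # region, and must include every window fully inside it
        assert region.start >= lo - 100 + 1
        assert region.end_exclusive <= hi
        assert region.start <= lo
        assert region.end_exclusive >= hi - 100 + 1


class TestPrimerSites:
    def test_fully_conserved_alignment_every_window_qualifies(self, db_factory):
        db = db_factory(
            [("a1", "A a", "ACGTACGTACGT"), ("b1", "B b", "ACGTACGTACGT")]
        )
        profile = window_profile(db, width=4)
        sites = find_primer_sites(profile)
        assert len(sites) == 1
        site = sites[0]
        assert site.start == 1
        assert site.n_windows == len(profile)
        assert site.prop_zero_noncon == 1.0
        assert site.n_diagnostic == 0

    def test_planted_flanks_recovered(self):
        spec = SimulationSpec(seed=3)
        ds = simulate_reference(spec)
        profile = window_profile(ds.alignment, width=20)
        sites = find_primer_sites(profile)
        for lo, hi in spec.conserved_flanks:
            covered = any(
                s.start <= hi and s.start + s.n_windows - 1 + 20 - 1 >= lo
                for s in sites
            )
            assert covered, f"no primer site overlaps planted flank ({lo},{hi})"
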