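import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minibarc.distances import DistanceMatrix, distance_matrix
from minibarc.identify import (
    best_close_match,
    near_neighbour,
    summarize_report,
    thresh_id,
    threshold_scan,
)

from _bruteforce import (
    brute_best_close_match,
    brute_near_neighbour,
    brute_thresh_id,
)


def outcomes(report):
    return [o.outcome for o in report.per_sequence]


class TestNearNeighbour:
    def test_toy_enumeration(self, toy_three):
        m = distance_matrix(toy_three, "raw")
        rep = near_neighbour(m, toy_three.species)
        assert outcomes(rep) == ["correct", "correct", "incorrect"]
        assert rep.counts == {"correct": 2, "incorrect": 1}

    def test_singleton_species_always_false(self, db_factory):
        db = db_factory(
            [("a1", "A a", "AAAA"), ("a2", "A a", "AAAA"),
             ("c1", "C c", "AATT")]
        )
        rep = near_neighbour(distance_matrix(db, "raw"), db.species)
        assert outcomes(rep)[2] == "incorrect"

    def test_tie_rules(self, db_factory):
        # query a1 ties between conspecific a2 and heterospecific b1
        db = db_factory(
            [("a1", "A a", "AAAA"), ("a2", "A a", "AAAT"),
             ("b1", "B b", "AAAG")]
        )
        m = distance_matrix(db, "raw")
        assert outcomes(near_neighbour(m, db.species))[0] == "correct"
        assert outcomes(near_neighbour(m, db.species, strict_ties=True))[0] \
            == "incorrect"

    def test_scale_invariance(self, db_factory):
        rng = np.random.default_rng(2)
        n = 8
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        ids = [f"s{i}" for i in range(n)]
        species = [f"S p{i % 3}" for i in range(n)]
        m1 = DistanceMatrix(ids, "raw", vals)
        m2 = DistanceMatrix(ids, "raw", vals * 7.3)
        assert outcomes(near_neighbour(m1, species)) == outcomes(
            near_neighbour(m2, species)
        )

    def test_undefined_sequence_warned_and_flagged(self, db_factory):
        db = db_factory(
            [("a1", "A a", "AA--"), ("a2", "A a", "--TT"), ("b1", "B b", "AATT")]
        )
        vals = distance_matrix(db, "raw").values.copy()
        vals[0, 1] = vals[1, 0] = np.nan
        vals[0, 2] = vals[2, 0] = np.nan
        m = DistanceMatrix(db.ids, "raw", vals)
        with pytest.warns(UserWarning, match="no defined distance"):
            rep = near_neighbour(m, db.species)
        assert outcomes(rep)[0] == "undefined"


class TestBestCloseMatch:
    def test_toy_enumeration(self, toy_three):
        m = distance_matrix(toy_three, "raw")
        rep = best_close_match(m, toy_three.species, t=0.3)
        assert outcomes(rep) == ["correct", "correct", "no_id"]

    def test_mixed_tie_is_ambiguous(self, db_factory):
        db = db_factory(
            [("q", "A a", "AAAA"), ("r1", "A a", "AAAT"),
             ("r2", "B b", "AAAG")]
        )
        m = distance_matrix(db, "raw")
        rep = best_close_match(m, db.species, t=0.5)
        assert outcomes(rep)[0] == "ambiguous"

    def test_strict_threshold_boundary(self, db_factory):
        db = db_factory(
            [("a1", "A a", "AAAA"), ("a2", "A a", "AAAT"), ("b1", "B b", "GGGG")]
        )
        m = distance_matrix(db, "raw")  # d(a1,a2) = 0.25
        assert outcomes(best_close_match(m, db.species, t=0.25))[0] == "no_id"
        assert outcomes(
            best_close_match(m, db.species, t=0.25, inclusive=True)
        )[0] == "correct"


class TestThreshId:
    def test_shared_haplotype_ambiguous(self, db_factory):
        db = db_factory(
            [
                ("a1", "A a", "AAAA"),
                ("a2", "A a", "AAAT"),
                ("b1", "B b", "AAAT"),
                ("b2", "B b", "AATT"),
            ]
        )
        m = distance_matrix(db, "raw")
        rep = thresh_id(m, db.species, t=0.5)
        # a2 and b1 share a haplotype: each sees a conspecific and the
        # other-species twin inside the threshold
        assert outcomes(rep)[1] == "ambiguous"
        assert outcomes(rep)[2] == "ambiguous"

    def test_huge_threshold_no_noid(self, db_factory):
        db = db_factory(
            [("a1", "A a", "AAAA"), ("a2", "A a", "AATT"), ("b1", "B b", "GGGG")]
        )
        m = distance_matrix(db, "raw")
        rep = thresh_id(m, db.species, t=2.0)
        assert rep.counts["no_id"] == 0


class TestThresholdScan:
    def test_two_clean_species(self, db_factory):
        db = db_factory(
            [
                ("a1", "A a", "AAAAAAAA"),
                ("a2", "A a", "AAAAAAAA"),
                ("b1", "B b", "AAAATTTT"),
                ("b2", "B b", "AAAATTTT"),
            ]
        )
        m = distance_matrix(db, "raw")  # inter-species distance 0.5
        scan = threshold_scan(m, db.species, grid=[0.1, 0.2, 0.3, 0.4])
        assert np.all(scan.cumulative_error == 0)
        assert np.all(scan.true_pos == 4)
        assert scan.optimum == 0.1

    def test_below_all_distances_everything_false_negative(self, db_factory):
        db = db_factory(
            [
                ("a1", "A a", "AAAT"),
                ("a2", "A a", "AATT"),
                ("b1", "B b", "GGGC"),
                ("b2", "B b", "GGCC"),
            ]
        )
        m = distance_matrix(db, "raw")
        scan = threshold_scan(m, db.species, grid=[0.01])
        assert scan.false_neg[0] == 4
        assert scan.cumulative_error[0] == 4

    def test_counts_sum_to_database_size(self, db_factory):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(7)]
        db = db_factory(
            [(f"s{i}", f"S p{i % 3}", seqs[i]) for i in range(7)]
        )
        m = distance_matrix(db, "raw")
        scan = threshold_scan(m, db.species)
        totals = scan.true_pos + scan.false_pos + scan.false_neg + scan.true_neg
        assert np.all(totals == 7)

    def test_grid_validation(self, toy_three):
        m = distance_matrix(toy_three, "raw")
        with pytest.raises(ValueError):
            threshold_scan(m, toy_three.species, grid=[0.2, 0.1])


# -- oracle equivalence & structural properties --------------------------

species_pool = ["Alpha one", "Beta two", "Gamma three"]

random_db = st.lists(
    st.tuples(
        st.integers(0, 2),
        st.text("ACGT", min_size=6, max_size=6),
    ),
    min_size=2,
    max_size=6,
)


@settings(deadline=None, max_examples=150)
@given(rows=random_db, t=st.sampled_from([0.01, 0.2, 0.4, 0.8]))
def test_all_tests_agree_with_bruteforce(rows, t):
    """The three identification tests match an exhaustive reimplementation
    on every small random database."""
    seqs = [seq for _, seq in rows]
    species = [species_pool[k] for k, _ in rows]
    from conftest import make_db

    db = make_db([(f"s{i}", species[i], seqs[i]) for i in range(len(rows))])
    m = distance_matrix(db, "raw")
    assert outcomes(near_neighbour(m, species)) == brute_near_neighbour(
        seqs, species
    )
    assert outcomes(best_close_match(m, species, t)) == \
        brute_best_close_match(seqs, species, t)
    assert outcomes(thresh_id(m, species, t)) == brute_thresh_id(
        seqs, species, t
    )


@settings(deadline=None, max_examples=40)
@given(rows=random_db)
def test_conservation_and_noid_monotonicity(rows):
    """Outcome counts conserve the total; no_id never increases with t."""
    seqs = [seq for _, seq in rows]
    species = [species_pool[k] for k, _ in rows]
    from conftest import make_db

    db = make_db([(f"s{i}", species[i], seqs[i]) for i in range(len(rows))])
    m = distance_matrix(db, "raw")
    prev_noid = None
    for t in [0.05, 0.1, 0.3, 0.6, 1.1]:
        for rep in (best_close_match(m, species, t), thresh_id(m, species, t)):
            assert sum(rep.counts.values()) == len(seqs)
        noid = thresh_id(m, species, t).counts["no_id"]
        if prev_noid is not None:
            assert noid <= prev_noid
        prev_noid = noid
    nn = near_neighbour(m, species)
    assert sum(nn.counts.values()) == len(seqs)
    assert summarize_report(nn) == nn.counts


def test_best_close_match_large_t_agrees_with_nn_on_clean_nearest(db_factory):
    rng = np.random.default_rng(9)
    seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(8)]
    db = db_factory(
        [(f"s{i}", f"S p{i % 4}", seqs[i]) for i in range(8)]
    )
    m = distance_matrix(db, "raw")
    nn = near_neighbour(m, db.species, strict_ties=True)
    bcm = best_close_match(m, db.species, t=10.0)
    for o_nn, o_bcm in zip(outcomes(nn), outcomes(bcm)):
        if o_bcm in ("correct", "incorrect"):
            assert o_nn == o_bcm
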