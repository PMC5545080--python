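import pytest

from minibarc.refdb import ReferenceAlignment, SequenceRecord


def make_db(rows, name="toy"):
    """Build a ReferenceAlignment from (id, species, sequence) triples.

    The genus is the first whitespace token of the species label.
    """
    records = [
        SequenceRecord(rid, sp, sp.split()[0], seq.upper())
        for rid, sp, seq in rows
    ]
    return ReferenceAlignment(records, name=name)


@pytest.fixture
def toy_three():
    """The minimal two-species database used across identification tests."""
    return make_db(
        [
            ("A1", "Alpha one", "AAAA"),
            ("A2", "Alpha one", "AAAT"),
            ("B1", "Beta two", "TTTT"),
        ]
    )


@pytest.fixture
def db_factory():
    return make_db
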