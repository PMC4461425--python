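import numpy as np
import pytest

from otubench.amplicon_io import Read
from otubench.synthetic_community import fixture_suite

# one concrete realisation of the degenerate forward primer (K->G, Y->C)
PRIMER = "AGGGCAAGCCTGGTGCCAGC"


def random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite(seed=7)


def _read(read_id, seq, quality=40):
    if isinstance(quality, int):
        quals = [quality] * len(seq)
    else:
        quals = list(quality)
    return Read(read_id, seq, quals)


@pytest.fixture(scope="session")
def twelve_read_fixture():
    """Hand-built 12-read dataset with per-rule expected filter outcomes.

    Returns (reads, expected) where expected maps regime ->
    {"kept_ids": [...], "counts": {reason: n}}.
    """
    gen = np.random.default_rng(12)

    def body(n):
        return random_seq(gen, n)

    b450 = body(450)
    reads = [
        _read("r01", PRIMER + b450),                       # kept by both
        _read("r02", "T" + (PRIMER + body(450))[1:]),       # primer mismatch
        _read("r03", PRIMER + body(380)),                   # short for stringent only
        _read("r04", PRIMER + body(240)),                   # short for both
        _read("r05", PRIMER + body(650)),                   # long for relaxed only
        _read("r06", PRIMER + body(100) + "N" + body(349)),  # N inside trim window
        _read("r07", PRIMER + body(420) + "N" + body(29)),  # N beyond trim window
        _read("r08", PRIMER + body(450), quality=15),       # bad quality for both
        _read("r09", PRIMER + body(450), quality=28),       # EE 0.63 > 0.5; mean 28 ok
        _read("r10", body(10)),                             # shorter than primer
        _read("r11", PRIMER[:10] + "A" + PRIMER[11:] + body(450)),  # 1 mismatch
        _read("r12", PRIMER + body(500)),                   # kept by both
    ]
    assert PRIMER[10] != "A"  # r11 really carries a mismatch
    expected = {
        "stringent": {
            "kept_ids": ["r01", "r05", "r07", "r12"],
            "counts": {"primer_mismatch": 2, "too_short_for_primer": 1,
                       "too_short": 2, "too_long": 0, "ambiguous_base": 1,
                       "expected_error": 2, "avg_quality": 0},
        },
        "relaxed": {
            "kept_ids": ["r01", "r03", "r09", "r12"],
            "counts": {"primer_mismatch": 2, "too_short_for_primer": 1,
                       "too_short": 1, "too_long": 1, "ambiguous_base": 2,
                       "expected_error": 0, "avg_quality": 1},
        },
    }
    return reads, expected
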