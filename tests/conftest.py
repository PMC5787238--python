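import numpy as np
import pytest

from smurf.reference_db import (
    PrimerPair,
    ReferenceSet,
    RefRecord,
    build_region_kmer_db,
)
from smurf._seq import revcomp
from smurf.simulation_eval import toy_primer_set, toy_reference


@pytest.fixture(scope="session")
def primers3():
    return toy_primer_set(3, seed=7)


@pytest.fixture(scope="session")
def ref10(primers3):
    """Ten mutually distinguishable taxa, all amplified in 3 regions."""
    return toy_reference(10, primers3, seed=11)


@pytest.fixture(scope="session")
def db10(ref10, primers3):
    return build_region_kmer_db(ref10, primers3, k=20, mode="paired")


def make_record(primer_sites, pad=12, rid="rec0", tax="", seed=0):
    """Handcraft a sequence as pad + sum(fwd + amplicon + rc(rev) + pad).

    ``primer_sites`` is a list of (PrimerPair, amplicon) tuples; the
    amplicon string may contain deliberate primer mismatches already
    applied by the caller to fwd/rev.
    """
    rng = np.random.default_rng(seed)

    def rand(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    parts = [rand(pad)]
    for fwd, amp, rev in primer_sites:
        parts.append(fwd + amp + revcomp(rev) + rand(pad))
    return RefRecord(rid, "".join(parts), tax, rid)


def mutate_positions(seq, positions, rng=None):
    """Substitute the given positions with a different base (deterministic)."""
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)
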