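import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smurf._seq import IUPAC_SETS, revcomp
from smurf.reference_db import (
    PrimerPair,
    RefRecord,
    ReferenceSet,
    build_region_kmer_db,
    compute_theoretical_groups,
    count_primer_mismatches,
    default_primer_set,
    expand_ambiguous_sequence,
    locate_amplicons,
    v4_primer_pair,
    RegionKmerDb,
)
from smurf.simulation_eval import toy_primer_set, toy_reference

from conftest import make_record, mutate_positions


# ---------------------------------------------------------------------------
# ambiguity expansion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGT", ["ACGT"]),
        ("ACRT", ["ACAT", "ACGT"]),
        ("MG", ["AG", "CG"]),
    ],
)
def test_expand_examples(seq, expected):
    assert expand_ambiguous_sequence(seq) == expected


def test_expand_three_fully_degenerate_positions_gives_64():
    seq = "ACGTN" + "ACGT" * 4 + "N" + "ACGT" * 2 + "N"
    out = expand_ambiguous_sequence(seq)
    assert len(out) == 64
    assert len(set(out)) == 64


def test_expand_discards_more_than_three_ambiguous():
    assert expand_ambiguous_sequence("NRYS" + "ACGT" * 5) == []


def test_expand_rejects_non_iupac_with_position():
    with pytest.raises(ValueError, match="position 2"):
        expand_ambiguous_sequence("ACXT")
    with pytest.raises(ValueError):
        expand_ambiguous_sequence("")


@given(
    st.lists(
        st.sampled_from(sorted(IUPAC_SETS)), min_size=1, max_size=12
    ).map("".join)
)
@settings(max_examples=200, deadline=None)
def test_expand_count_is_product_of_set_sizes(seq):
    n_ambiguous = sum(1 for c in seq if len(IUPAC_SETS[c]) > 1)
    out = expand_ambiguous_sequence(seq)
    if n_ambiguous > 3:
        assert out == []
    else:
        expected = int(np.prod([len(IUPAC_SETS[c]) for c in seq]))
        assert len(out) == expected <= 64
        assert all(set(s) <= set("ACGT") for s in out)
        assert out == sorted(out)  # alphabetical at each position


# ---------------------------------------------------------------------------
# primer mismatch counting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "primer,window,expected",
    [
        ("TGGCGGACGGGTGAGTAA", "TGGCGGACGGGTGAGTAA", 0),
        ("ACGT", "AGGT", 1),
        ("M", "A", 0),
        ("M", "C", 0),
        ("M", "G", 1),
        ("NNNN", "ACGT", 0),
    ],
)
def test_count_primer_mismatches(primer, window, expected):
    assert count_primer_mismatches(primer, window) == expected


def test_count_primer_mismatches_rejects_length_mismatch():
    with pytest.raises(ValueError):
        count_primer_mismatches("ACGT", "ACG")


# ---------------------------------------------------------------------------
# amplicon location
# ---------------------------------------------------------------------------

def _toy_pair():
    return PrimerPair(1, "TGGCGGACGGGTGAGTAA", "CTGCTGCCTCCCGTAGGA")


def test_locate_amplicon_exact_sites():
    pair = _toy_pair()
    core = "ACGT" * 50
    rec = make_record([(pair.forward, core, pair.reverse)], pad=15, seed=3)
    ref = ReferenceSet([rec])
    site = locate_amplicons(ref, pair)[0]
    assert site.amplified
    assert rec.sequence[site.start:site.end] == core
    assert site.fwd_mismatches == 0 and site.rev_mismatches == 0


def test_three_mismatches_in_forward_primer_not_amplified():
    pair = _toy_pair()
    damaged_fwd = mutate_positions(pair.forward, [2, 7, 12])
    rec = make_record([(damaged_fwd, "ACGT" * 50, pair.reverse)], seed=4)
    site = locate_amplicons(ReferenceSet([rec]), pair)[0]
    assert not site.amplified


def test_two_mismatches_in_each_primer_is_amplified():
    pair = _toy_pair()
    rec = make_record(
        [(mutate_positions(pair.forward, [2, 7]),
          "ACGT" * 50,
          mutate_positions(pair.reverse, [1, 9]))],
        seed=5,
    )
    site = locate_amplicons(ReferenceSet([rec]), pair)[0]
    assert site.amplified
    assert site.fwd_mismatches == 2 and site.rev_mismatches == 2


def _brute_force_site(seq, pair):
    """Independent pure-Python oracle for the best-site scan."""
    def mism(primer, window):
        return sum(w not in IUPAC_SETS[p] for p, w in zip(primer, window))

    m = len(pair.forward)
    fwd = min(
        ((mism(pair.forward, seq[p:p + m]), p)
         for p in range(len(seq) - m + 1)),
        default=None,
    )
    if fwd is None:
        return None
    fmm, fpos = fwd
    start = fpos + m
    rc = revcomp(pair.reverse)
    n = len(rc)
    rev = min(
        ((mism(rc, seq[p:p + n]), p)
         for p in range(start, len(seq) - n + 1)),
        default=None,
    )
    if rev is None:
        return (False, fmm, None, None)
    rmm, rpos = rev
    amplified = fmm <= 2 and rmm <= 2 and rpos > start
    return (amplified, fmm, rmm, (start, rpos))


def test_locate_agrees_with_brute_force_scan():
    rng = np.random.default_rng(42)
    pair = _toy_pair()
    records = []
    for i in range(15):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        if i % 3 == 0:  # plant a real site in some sequences
            ins = pair.forward + "".join(
                rng.choice(list("ACGT"), size=80)
            ) + revcomp(pair.reverse)
            pos = int(rng.integers(0, 200))
            seq = seq[:pos] + ins + seq[pos + len(ins):]
        records.append(RefRecord(f"r{i}", seq, "", f"r{i}"))
    ref = ReferenceSet(records)
    sites = locate_amplicons(ref, pair)
    for rec, site in zip(records, sites):
        oracle = _brute_force_site(rec.sequence, pair)
        assert site.amplified == oracle[0]
        if site.amplified:
            assert (site.fwd_mismatches, site.rev_mismatches) == oracle[1:3]
            assert (site.start, site.end) == oracle[3]


# ---------------------------------------------------------------------------
# k-mer database construction
# ---------------------------------------------------------------------------

def _partial_amplification_ref(n_regions=3):
    """Taxon 0 amplified in all regions, taxon 1 only in region 1."""
    primers = toy_primer_set(n_regions, seed=19)
    rng = np.random.default_rng(1)
    amp = lambda: "".join(rng.choice(list("ACGT"), size=60))
    rec0 = make_record(
        [(p.forward, amp(), p.reverse) for p in primers], rid="t0", seed=21
    )
    rec1 = make_record([(primers[0].forward, amp(), primers[0].reverse)],
                       rid="t1", seed=22)
    return ReferenceSet([rec0, rec1]), primers


def test_paired_end_rows_and_weights():
    ref, primers = _partial_amplification_ref()
    db = build_region_kmer_db(ref, primers, k=20, mode="paired")
    assert db.R.tolist() == [3, 1]
    col0 = db.M.tocsc()[:, 0]
    assert col0.nnz == 3
    assert np.allclose(col0.data, 1 / 3)
    assert np.allclose(np.asarray(db.M.sum(axis=0)).ravel(), 1.0)
    # every paired k-mer row is forward||reverse pieces of length 2k
    assert all(len(kmer) == 40 for _, kmer in db.row_keys)


def test_single_end_rows_and_weights():
    ref, primers = _partial_amplification_ref()
    db = build_region_kmer_db(ref, primers, k=20, mode="single")
    col0 = db.M.tocsc()[:, 0]
    assert col0.nnz == 6
    assert np.allclose(col0.data, 0.5 / 3)
    assert np.allclose(np.asarray(db.M.sum(axis=0)).ravel(), 1.0)


def test_amplicon_shorter_than_k_treated_as_not_amplified():
    primers = toy_primer_set(1, seed=23)
    rec = make_record([(primers[0].forward, "ACGTACGTAC", primers[0].reverse)],
                      rid="short", seed=24)
    db = build_region_kmer_db(ReferenceSet([rec]), primers, k=20)
    assert db.R.tolist() == [0]
    assert db.H == 0


def test_empty_primer_set_rejected(ref10):
    with pytest.raises(ValueError):
        build_region_kmer_db(ref10, [], k=20)


def test_db_save_load_roundtrip(tmp_path, db10):
    db10.save(tmp_path / "db")
    loaded = RegionKmerDb.load(tmp_path / "db")
    assert loaded.k == db10.k and loaded.mode == db10.mode
    assert loaded.taxon_ids == db10.taxon_ids
    assert loaded.R.tolist() == db10.R.tolist()
    assert loaded.row_keys == db10.row_keys
    assert np.allclose(loaded.M.toarray(), db10.M.toarray())
    for j in range(db10.J):
        assert loaded.footprint(j) == db10.footprint(j)
    assert [p.region_id for p in loaded.primers] == [1, 2, 3]


def test_packaged_primer_sets_parse():
    six = default_primer_set()
    assert [p.region_id for p in six] == [1, 2, 3, 4, 5, 6]
    assert six[0].forward == "TGGCGGACGGGTGAGTAA"
    v4 = v4_primer_pair()
    assert "M" in v4.forward and "W" in v4.reverse


# ---------------------------------------------------------------------------
# theoretical groups
# ---------------------------------------------------------------------------

def test_identical_footprints_form_one_group(primers3):
    # pools of size 2 in every region -> taxa {0,2,4} and {1,3,5} identical
    ref = toy_reference(6, primers3, seed=31,
                        region_pool_sizes={1: 2, 2: 2, 3: 2})
    db = build_region_kmer_db(ref, primers3, k=20)
    fp = compute_theoretical_groups(db)
    assert sorted(fp.group_sizes().tolist()) == [3, 3]
    assert fp.unique_fraction() == 0.0


def test_distinct_footprints_all_singletons(db10):
    fp = compute_theoretical_groups(db10)
    assert fp.n_groups == 10
    assert fp.unique_fraction() == 1.0


def test_adding_region_splits_groups(primers3):
    # region 1 shared between pairs, regions 2-3 unique
    ref = toy_reference(4, primers3, seed=33, region_pool_sizes={1: 2})
    db = build_region_kmer_db(ref, primers3, k=20)
    one = compute_theoretical_groups(db, [1])
    both = compute_theoretical_groups(db, [1, 2])
    assert sorted(one.group_sizes().tolist()) == [2, 2]
    assert sorted(both.group_sizes().tolist()) == [1, 1, 1, 1]


@pytest.mark.parametrize("seed", range(5))
def test_group_sizes_monotone_under_region_addition(seed):
    primers = toy_primer_set(3, seed=40 + seed)
    rng = np.random.default_rng(seed)
    pools = {r: int(rng.integers(1, 5)) for r in (1, 2, 3)}
    ref = toy_reference(12, primers, seed=50 + seed, region_pool_sizes=pools)
    db = build_region_kmer_db(ref, primers, k=20)
    subsets = [[1], [1, 2], [1, 2, 3]]
    prev_sizes = None
    prev_unique = -1.0
    for subset in subsets:
        fp = compute_theoretical_groups(db, subset)
        sizes = fp.group_size_of()
        if prev_sizes is not None:
            for j, s in sizes.items():
                assert s <= prev_sizes.get(j, np.inf)
        assert fp.unique_fraction() >= prev_unique
        prev_sizes, prev_unique = sizes, fp.unique_fraction()
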