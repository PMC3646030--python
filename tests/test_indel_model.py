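"""VCF ingestion, left-normalization (vs enumeration oracle), known filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msiseq import (
    DELETION,
    INSERTION,
    IndelCall,
    KnownVariantSet,
    ValidationError,
    filter_known,
    left_normalize,
    read_indels,
    write_vcf,
)

VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def make_vcf(tmp_path, body, name="calls.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


# ---------------------------------------------------------------------------
# normalization oracle


def leftmost_equivalent(call: IndelCall, ref: str) -> IndelCall:
    """Enumerate every representation producing the same edited sequence and
    return the one with the smallest interval start."""
    target = call.apply(ref)
    L = call.length
    if call.kind == DELETION:
        for s in range(0, len(ref) - L + 1):
            if ref[:s] + ref[s + L :] == target:
                return IndelCall(call.seq_id, DELETION, (s, s + L), ref[s : s + L])
    else:
        for s in range(0, len(ref) + 1):
            ins = target[s : s + L]
            if ref[:s] + ins + ref[s:] == target:
                return IndelCall(call.seq_id, INSERTION, (s, s), ins)
    raise AssertionError("no equivalent representation found")


@pytest.mark.parametrize(
    "ref,call,expected_start",
    [
        # deletion inside a homopolymer shifts to the run's left edge
        ("CAAAT", IndelCall("t", DELETION, (2, 3), "A"), 1),
        # insertion of AC in a dinucleotide context finds a single leftmost phase
        ("GACACT", IndelCall("t", INSERTION, (5, 5), "AC"), 1),
        # already leftmost: unchanged
        ("TGCAAT", IndelCall("t", DELETION, (3, 4), "A"), 3),
    ],
)
def test_left_normalize_matches_enumeration(ref, call, expected_start):
    norm = left_normalize(call, ref)
    oracle = leftmost_equivalent(call, ref)
    assert norm.affected_interval == oracle.affected_interval
    assert norm.seq == oracle.seq
    assert norm.affected_interval[0] == expected_start
    assert norm.apply(ref) == call.apply(ref)


def random_indel(rng, ref) -> IndelCall:
    length = int(rng.integers(1, 5))
    if rng.random() < 0.5 and len(ref) > length + 1:
        s = int(rng.integers(0, len(ref) - length))
        return IndelCall("t", DELETION, (s, s + length), ref[s : s + length])
    s = int(rng.integers(0, len(ref) + 1))
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return IndelCall("t", INSERTION, (s, s), ins)


def test_left_normalize_random_indels_idempotent_and_minimal():
    rng = np.random.default_rng(77)
    for _ in range(300):
        n = int(rng.integers(5, 40))
        ref = "".join("ACGT"[i] for i in rng.integers(0, 2 + 2 * (n % 2), size=n))
        call = random_indel(rng, ref)
        norm = left_normalize(call, ref)
        assert norm.apply(ref) == call.apply(ref)  # edit equivalence
        assert left_normalize(norm, ref) == norm  # idempotence
        oracle = leftmost_equivalent(call, ref)
        assert norm.affected_interval == oracle.affected_interval


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    ref=st.text(alphabet="AC", min_size=4, max_size=24),
    offset=st.integers(min_value=0, max_value=1000),
    length=st.integers(min_value=1, max_value=3),
    is_deletion=st.booleans(),
    ins=st.text(alphabet="ACGT", min_size=1, max_size=3),
)
def test_left_normalize_properties(ref, offset, length, is_deletion, ins):
    """Edit equivalence, idempotence and coordinate minimality hold for any
    indel on any (repeat-rich) reference."""
    if is_deletion:
        length = min(length, len(ref) - 1)
        s = offset % (len(ref) - length)
        call = IndelCall("t", DELETION, (s, s + length), ref[s : s + length])
    else:
        s = offset % (len(ref) + 1)
        call = IndelCall("t", INSERTION, (s, s), ins)
    norm = left_normalize(call, ref)
    assert norm.apply(ref) == call.apply(ref)
    assert left_normalize(norm, ref) == norm
    assert norm.affected_interval == leftmost_equivalent(call, ref).affected_interval


# ---------------------------------------------------------------------------
# VCF reading


def test_read_deletion_and_insertion(tmp_path):
    ref = {"T1": "TGCAAT"}
    vcf = make_vcf(
        tmp_path,
        "T1\t3\t.\tCA\tC\t.\tPASS\t.\n"  # 1 bp deletion
        "T1\t3\t.\tC\tCAG\t.\tPASS\t.\n",  # 2 bp insertion
    )
    calls, stats = read_indels(vcf, ref)
    assert stats["kept"] == 2 and stats["records"] == 2
    dele, ins = calls
    assert dele.kind == DELETION and dele.length == 1
    assert ins.kind == INSERTION and ins.length == 2 and ins.seq == "AG"


def test_substitution_skipped_and_counted(tmp_path):
    ref = {"T1": "TGCAAT"}
    vcf = make_vcf(tmp_path, "T1\t3\t.\tCA\tCG\t.\tPASS\t.\n")
    calls, stats = read_indels(vcf, ref)
    assert calls == [] and stats["skipped_non_indel"] == 1


def test_ref_mismatch_is_validation_error(tmp_path):
    vcf = make_vcf(tmp_path, "T1\t3\t.\tGG\tG\t.\tPASS\t.\n")
    with pytest.raises(ValidationError, match="T1:3"):
        read_indels(vcf, {"T1": "TGCAAT"})


def test_unknown_transcript_dropped_with_count(tmp_path):
    vcf = make_vcf(tmp_path, "NOPE\t3\t.\tCA\tC\t.\tPASS\t.\n")
    calls, stats = read_indels(vcf, {"T1": "TGCAAT"})
    assert calls == [] and stats["dropped_unknown_seq"] == 1


def test_filter_column_respected_unless_kept(tmp_path):
    body = "T1\t3\t.\tCA\tC\t.\tq10\t.\n"
    vcf = make_vcf(tmp_path, body)
    ref = {"T1": "TGCAAT"}
    assert read_indels(vcf, ref)[0] == []
    kept, _ = read_indels(vcf, ref, keep_filtered=True)
    assert len(kept) == 1


def test_reader_normalizes_repeat_indels(tmp_path):
    # deletion reported mid-run must come back at the run's left edge
    ref = {"T1": "CAAAAG"}
    vcf = make_vcf(tmp_path, "T1\t3\t.\tAA\tA\t.\tPASS\t.\n")
    calls, _ = read_indels(vcf, ref)
    assert calls[0].affected_interval == (1, 2)


def test_rsid_presence_mode_drops_annotated_records(tmp_path):
    ref = {"T1": "TGCAAT"}
    vcf = make_vcf(
        tmp_path,
        "T1\t3\t.\tCA\tC\t.\tPASS\t.\n"
        "T1\t3\trs12345\tC\tCAG\t.\tPASS\t.\n",
    )
    calls, stats = read_indels(vcf, ref, drop_annotated_ids=True)
    assert len(calls) == 1 and calls[0].kind == DELETION
    assert stats["skipped_known_id"] == 1


def test_max_indel_len_cap(tmp_path):
    ref = {"T1": "TGCAAT"}
    vcf = make_vcf(tmp_path, "T1\t2\t.\tGCAA\tG\t.\tPASS\t.\n")
    calls, stats = read_indels(vcf, ref, max_indel_len=2)
    assert calls == [] and stats["skipped_too_long"] == 1


def test_write_read_round_trip_including_sequence_start(tmp_path):
    ref = {"T1": "ACGTTTACGT", "T2": "GGGCCCAAAT"}
    calls = [
        IndelCall("T1", DELETION, (0, 2), "AC"),  # right-anchored VCF form
        IndelCall("T1", INSERTION, (4, 4), "T"),
        IndelCall("T2", DELETION, (3, 6), "CCC"),
        IndelCall("T2", INSERTION, (0, 0), "TT"),
    ]
    normalized = [left_normalize(c, ref[c.seq_id]) for c in calls]
    path = tmp_path / "rt.vcf"
    write_vcf(normalized, ref, path)
    back, _ = read_indels(path, ref)
    assert sorted(back, key=lambda c: (c.seq_id, c.affected_interval)) == sorted(
        normalized, key=lambda c: (c.seq_id, c.affected_interval)
    )


# ---------------------------------------------------------------------------
# known-variant filtering


def calls_fixture():
    return [
        IndelCall("T1", DELETION, (1, 2), "A"),
        IndelCall("T1", INSERTION, (4, 4), "GT"),
        IndelCall("T2", DELETION, (1, 2), "A"),
    ]


def test_empty_known_set_is_identity():
    calls = calls_fixture()
    kept, removed = filter_known(calls, KnownVariantSet())
    assert kept == calls and removed == 0
    kept, removed = filter_known(calls, None)
    assert kept == calls and removed == 0


def test_known_call_removed_order_preserved():
    calls = calls_fixture()
    known = KnownVariantSet([calls[1]])
    kept, removed = filter_known(calls, known)
    assert kept == [calls[0], calls[2]] and removed == 1
    assert len(kept) + removed == len(calls)


def test_same_position_different_allele_retained():
    calls = calls_fixture()
    known = KnownVariantSet([IndelCall("T1", INSERTION, (4, 4), "GG")])
    kept, removed = filter_known(calls, known)
    assert kept == calls and removed == 0


def test_known_set_from_vcf_matches_after_normalization(tmp_path):
    ref = {"T1": "CAAAAG"}
    # the known VCF reports the deletion mid-run; the sample call is leftmost
    known_vcf = make_vcf(tmp_path, "T1\t3\t.\tAA\tA\t.\tPASS\t.\n", name="known.vcf")
    known = KnownVariantSet.from_vcf(known_vcf, ref)
    sample_call = IndelCall("T1", DELETION, (1, 2), "A")
    kept, removed = filter_known([sample_call], known)
    assert kept == [] and removed == 1
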