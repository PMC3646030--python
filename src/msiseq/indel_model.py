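"""Indel ingestion, left-normalization and known-variant filtering.

Indels arrive as VCF records in transcript space.  Internally a call is
held as the 0-based half-open interval it affects on the reference plus the
inserted/deleted bases; the VCF anchor-base representation is produced only
at the I/O boundary.  Every retained call is *left-normalized*: shifted to
the representation with the smallest coordinate among all representations
yielding the same edited sequence.  This parks slippage indels at the left
edge of their repeat tract, which the annotator relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

from .errors import ValidationError
from .repeat_finder import SequenceRecord

logger = logging.getLogger(__name__)

INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class IndelCall:
    """One pure insertion or deletion.

    ``affected_interval`` is 0-based half-open on the reference: the deleted
    bases for a deletion, or the empty interval at the insertion point (the
    base index before which the new bases go) for an insertion.  ``pos`` is
    the anchor-base offset, one left of the interval start; it is -1 for an
    event at the very start of the sequence (written right-anchored in VCF).
    ``seq`` holds the deleted/inserted bases themselves.
    """

    seq_id: str
    kind: str  # INSERTION or DELETION
    affected_interval: tuple[int, int]
    seq: str
    known: bool = False

    def __post_init__(self) -> None:
        s, e = self.affected_interval
        if self.kind == DELETION:
            if e - s != len(self.seq) or not self.seq:
                raise ValidationError(f"inconsistent deletion interval {self.affected_interval}")
        elif self.kind == INSERTION:
            if e != s or not self.seq:
                raise ValidationError(f"inconsistent insertion interval {self.affected_interval}")
        else:
            raise ValidationError(f"unknown indel kind {self.kind!r}")

    @property
    def pos(self) -> int:
        return self.affected_interval[0] - 1

    @property
    def length(self) -> int:
        return len(self.seq)

    def vcf_alleles(self, reference_sequence: str) -> tuple[int, str, str]:
        """(1-based POS, REF, ALT) for this call against its reference."""
        s, _ = self.affected_interval
        ref = reference_sequence
        if s > 0:
            anchor = ref[s - 1]
            if self.kind == DELETION:
                return s, anchor + self.seq, anchor
            return s, anchor, anchor + self.seq
        # event at sequence start: anchor on the base after it
        if self.kind == DELETION:
            tail = ref[len(self.seq)]
            return 1, self.seq + tail, tail
        return 1, ref[0], self.seq + ref[0]

    def apply(self, reference_sequence: str) -> str:
        """The edited sequence this call produces (used for verification)."""
        s, e = self.affected_interval
        if self.kind == DELETION:
            return reference_sequence[:s] + reference_sequence[e:]
        return reference_sequence[:s] + self.seq + reference_sequence[s:]


def left_normalize(call: IndelCall, reference_sequence: str) -> IndelCall:
    """Shift ``call`` to its leftmost equivalent representation.

    Deletions shift left while the base preceding the deleted interval
    equals its last base; insertions shift left while the preceding
    reference base equals the last inserted base (rotating the inserted
    string).  The result is idempotent and produces the same edited
    sequence as the input.
    """
    s, e = call.affected_interval
    if call.kind == DELETION:
        length = e - s
        while s > 0 and reference_sequence[s - 1] == reference_sequence[s + length - 1]:
            s -= 1
        if s == call.affected_interval[0]:
            return call
        return replace(
            call,
            affected_interval=(s, s + length),
            seq=reference_sequence[s : s + length],
        )
    ins = call.seq
    while s > 0 and reference_sequence[s - 1] == ins[-1]:
        ins = ins[-1] + ins[:-1]
        s -= 1
    if s == call.affected_interval[0]:
        return call
    return replace(call, affected_interval=(s, s), seq=ins)


def _decompose(pos0: int, ref: str, alt: str) -> tuple[int, str, str] | None:
    """Reduce a (POS-1, REF, ALT) pair to a pure indel.

    Trims the shared suffix, then the shared prefix.  Returns
    ``(interval_start, kind, bases)`` or None when the record is a
    substitution/MNP/complex event.
    """
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    if ref and not alt:
        return pos0, DELETION, ref
    if alt and not ref:
        return pos0, INSERTION, alt
    return None


def read_indels(
    vcf_path,
    reference: Mapping[str, str] | Sequence[SequenceRecord],
    keep_filtered: bool = False,
    max_indel_len: int | None = None,
    drop_annotated_ids: bool = False,
) -> tuple[list[IndelCall], dict[str, int]]:
    """Read pure indels from a VCF and left-normalize them.

    ``reference`` maps transcript ids to sequences (a list of
    ``SequenceRecord`` is also accepted).  Multi-allelic records are split
    per ALT.  Substitutions/MNPs/complex records are skipped and counted;
    records on transcripts absent from the reference are dropped with a
    warning.  A REF allele that disagrees with the reference sequence is a
    validation error.  ``drop_annotated_ids`` enables rsID-presence mode:
    any record carrying an ID annotation is treated as a known polymorphism
    and dropped, an alternative to allele-level :func:`filter_known`.

    Returns ``(calls, stats)`` where stats counts kept/skipped records.
    """
    refs = as_reference(reference)
    calls: list[IndelCall] = []
    stats = {
        "records": 0,
        "kept": 0,
        "skipped_non_indel": 0,
        "skipped_filtered": 0,
        "dropped_unknown_seq": 0,
        "skipped_too_long": 0,
        "skipped_known_id": 0,
    }
    for variant in VCF(str(vcf_path)):
        stats["records"] += 1
        if variant.FILTER is not None and not keep_filtered:  # None == PASS or '.'
            stats["skipped_filtered"] += 1
            continue
        if drop_annotated_ids and variant.ID is not None:
            stats["skipped_known_id"] += 1
            continue
        chrom = variant.CHROM
        refseq = refs.get(chrom)
        if refseq is None:
            stats["dropped_unknown_seq"] += 1
            continue
        pos0 = variant.POS - 1
        vref = variant.REF.upper()
        if refseq[pos0 : pos0 + len(vref)] != vref:
            raise ValidationError(
                f"{vcf_path}: REF {vref!r} at {chrom}:{variant.POS} does not match "
                f"reference {refseq[pos0:pos0 + len(vref)]!r}"
            )
        for alt in variant.ALT:
            if not alt or not set(alt.upper()) <= set("ACGTN"):
                stats["skipped_non_indel"] += 1
                continue
            dec = _decompose(pos0, vref, alt.upper())
            if dec is None:
                stats["skipped_non_indel"] += 1
                continue
            start, kind, bases = dec
            if max_indel_len is not None and len(bases) > max_indel_len:
                stats["skipped_too_long"] += 1
                continue
            interval = (start, start + len(bases)) if kind == DELETION else (start, start)
            call = IndelCall(seq_id=chrom, kind=kind, affected_interval=interval, seq=bases)
            calls.append(left_normalize(call, refseq))
            stats["kept"] += 1
    if stats["skipped_non_indel"]:
        logger.info(
            "%s: skipped %d non-indel allele(s)", vcf_path, stats["skipped_non_indel"]
        )
    if stats["dropped_unknown_seq"]:
        logger.warning(
            "%s: dropped %d record(s) on transcripts absent from the reference",
            vcf_path,
            stats["dropped_unknown_seq"],
        )
    return calls, stats


def as_reference(
    reference: Mapping[str, str] | Sequence[SequenceRecord],
) -> dict[str, str]:
    if isinstance(reference, Mapping):
        return dict(reference)
    return {rec.seq_id: rec.sequence for rec in reference}


class KnownVariantSet:
    """Known (dbSNP-style) indels keyed by normalized (seq_id, pos, ref, alt).

    Matching is at allele level rather than by rsID so that records lacking
    ID annotation are still recognised; both sides must be normalized with
    the same left-alignment, which :meth:`from_vcf` guarantees.
    """

    def __init__(self, calls: Iterable[IndelCall] = ()):
        self._keys = {self.key(c) for c in calls}

    @staticmethod
    def key(call: IndelCall) -> tuple[str, int, str, str]:
        return (call.seq_id, call.affected_interval[0], call.kind, call.seq)

    @classmethod
    def from_vcf(
        cls, vcf_path, reference: Mapping[str, str] | Sequence[SequenceRecord]
    ) -> "KnownVariantSet":
        calls, _ = read_indels(vcf_path, reference, keep_filtered=True)
        return cls(calls)

    def __contains__(self, call: IndelCall) -> bool:
        return self.key(call) in self._keys

    def __len__(self) -> int:
        return len(self._keys)


def filter_known(
    calls: Sequence[IndelCall], known: KnownVariantSet | None
) -> tuple[list[IndelCall], int]:
    """Drop calls present in ``known``; returns (kept, n_removed), order kept."""
    if known is None or len(known) == 0:
        return list(calls), 0
    kept = [c for c in calls if c not in known]
    removed = len(calls) - len(kept)
    if removed:
        logger.info("filtered %d known indel(s)", removed)
    return kept, removed


def write_vcf(
    calls: Sequence[IndelCall],
    reference: Mapping[str, str] | Sequence[SequenceRecord],
    path,
    source: str = "msiseq",
) -> None:
    """Write calls as a minimal VCF 4.2 file sorted by (seq_id, position)."""
    refs = as_reference(reference)
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    for seq_id in sorted(refs):
        lines.append(f"##contig=<ID={seq_id},length={len(refs[seq_id])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in sorted(calls, key=lambda c: (c.seq_id, c.affected_interval[0])):
        refseq = refs.get(call.seq_id)
        if refseq is None:
            raise ValidationError(f"no reference sequence for {call.seq_id!r}")
        pos, ref, alt = call.vcf_alleles(refseq)
        lines.append(f"{call.seq_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
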