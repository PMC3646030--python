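"""Intersection of indels with the microsatellite catalogue and transcript
regions (5'UTR / CDS / 3'UTR / ncRNA).

Membership rules (calls must be left-normalized, intervals 0-based
half-open):

* a deletion lies in a tract iff its deleted interval overlaps the tract;
* an insertion lies in a tract iff its insertion point falls in
  ``[start - 1, end)``.  The extra position one base left of the tract is
  included because left-normalization can park a tract-lengthening
  insertion on the left flank (when the flanking base equals the last base
  of the repeat unit); without it, slippage insertions at the tract edge
  would be systematically missed.

When several tracts qualify the one with the smallest start (ties: the
longest) is assigned, so annotation is deterministic and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import ParseError, ValidationError
from .indel_model import DELETION, INSERTION, IndelCall
from .repeat_finder import Microsatellite

logger = logging.getLogger(__name__)

FIVE_PRIME_UTR = "five_prime_utr"
CDS = "cds"
THREE_PRIME_UTR = "three_prime_utr"
NC_RNA = "ncRNA"
REGIONS = (CDS, FIVE_PRIME_UTR, THREE_PRIME_UTR, NC_RNA)

MODEL_HEADER = "#seq_id\tlength\tcds_start\tcds_end"


@dataclass(frozen=True)
class TranscriptModel:
    """Per-transcript CDS boundaries; absent CDS means non-coding."""

    seq_id: str
    length: int
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"{self.seq_id}: cds_start/cds_end must both be set or absent")
        if self.cds_start is not None:
            if not 0 <= self.cds_start < self.cds_end <= self.length:
                raise ValidationError(
                    f"{self.seq_id}: invalid CDS [{self.cds_start}, {self.cds_end}) "
                    f"for length {self.length}"
                )

    @property
    def coding(self) -> bool:
        return self.cds_start is not None


@dataclass(frozen=True)
class AnnotatedIndel:
    call: IndelCall
    in_microsatellite: bool
    microsatellite: Microsatellite | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.in_microsatellite != (self.microsatellite is not None):
            raise ValidationError("microsatellite must be present iff in_microsatellite")


def intersect(
    calls: Sequence[IndelCall], catalogue: Sequence[Microsatellite]
) -> list[AnnotatedIndel]:
    """Annotate each call with the microsatellite it falls in, if any."""
    trees: dict[str, IntervalTree] = {}
    for ms in catalogue:
        trees.setdefault(ms.seq_id, IntervalTree())[ms.start : ms.end] = ms
    out: list[AnnotatedIndel] = []
    for call in calls:
        tree = trees.get(call.seq_id)
        hits = []
        if tree is not None:
            s, e = call.affected_interval
            if call.kind == DELETION:
                hits = list(tree.overlap(s, e))
            else:
                # insertion point s in [start - 1, end)  <=>  start < s + 2 and end > s
                hits = list(tree.overlap(s, s + 2))
                hits = [iv for iv in hits if iv.begin - 1 <= s < iv.end]
        if hits:
            best = min(hits, key=lambda iv: (iv.begin, -(iv.end - iv.begin)))
            out.append(AnnotatedIndel(call=call, in_microsatellite=True, microsatellite=best.data))
        else:
            out.append(AnnotatedIndel(call=call, in_microsatellite=False))
    return out


def assign_region(call: IndelCall, model: TranscriptModel) -> str:
    """Region of the call's anchor position.

    An indel spanning a region boundary is attributed to its anchor's
    region, keeping region labels a partition.  The anchor of an event at
    the sequence start is clamped to 0.
    """
    if call.seq_id != model.seq_id:
        raise ValidationError(f"call on {call.seq_id!r} vs model for {model.seq_id!r}")
    p = max(call.pos, 0)
    if not 0 <= p < model.length:
        raise ValidationError(
            f"{call.seq_id}: position {p} outside [0, {model.length})"
        )
    if not model.coding:
        return NC_RNA
    if p < model.cds_start:
        return FIVE_PRIME_UTR
    if p < model.cds_end:
        return CDS
    return THREE_PRIME_UTR


def annotate(
    calls: Sequence[IndelCall],
    catalogue: Sequence[Microsatellite],
    models: Mapping[str, TranscriptModel],
) -> list[AnnotatedIndel]:
    """Full annotation: microsatellite membership plus transcript region."""
    out = []
    for ann in intersect(calls, catalogue):
        model = models.get(ann.call.seq_id)
        region = assign_region(ann.call, model) if model is not None else None
        out.append(
            AnnotatedIndel(
                call=ann.call,
                in_microsatellite=ann.in_microsatellite,
                microsatellite=ann.microsatellite,
                region=region,
            )
        )
    return out


def altered_microsatellite_count(annotated: Iterable[AnnotatedIndel]) -> int:
    """Distinct tracts hit by at least one indel (several indels in one
    tract count once)."""
    return len({a.microsatellite.id for a in annotated if a.in_microsatellite})


def region_proportions(
    annotated: Iterable[AnnotatedIndel], per_tract: bool = False
) -> dict[str, float] | None:
    """Share of microsatellite indels per transcript region.

    With ``per_tract=True`` each altered tract contributes once (at the
    region of its first indel) instead of once per indel event.  Returns
    None — an explicit "undefined" flag — when there are no microsatellite
    indels, rather than a silent all-zero map.
    """
    counts = {r: 0 for r in REGIONS}
    seen_tracts: set[str] = set()
    for a in annotated:
        if not a.in_microsatellite or a.region is None:
            continue
        if per_tract:
            if a.microsatellite.id in seen_tracts:
                continue
            seen_tracts.add(a.microsatellite.id)
        counts[a.region] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    return {r: c / total for r, c in counts.items()}


# ---------------------------------------------------------------------------
# I/O


def read_transcript_models(path) -> dict[str, TranscriptModel]:
    """Read the 4-column transcript-model TSV (empty CDS fields => ncRNA)."""
    models: dict[str, TranscriptModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"model line {lineno}: expected 4 columns, got {len(fields)}")
            seq_id, length_s, cs, ce = fields
            try:
                model = TranscriptModel(
                    seq_id=seq_id,
                    length=int(length_s),
                    cds_start=int(cs) if cs else None,
                    cds_end=int(ce) if ce else None,
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"model line {lineno}: {exc}") from exc
            if seq_id in models:
                raise ParseError(f"model line {lineno}: duplicate transcript {seq_id!r}")
            models[seq_id] = model
    return models


def write_transcript_models(models: Mapping[str, TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(MODEL_HEADER + "\n")
        for seq_id in sorted(models):
            m = models[seq_id]
            cs = "" if m.cds_start is None else str(m.cds_start)
            ce = "" if m.cds_end is None else str(m.cds_end)
            fh.write(f"{m.seq_id}\t{m.length}\t{cs}\t{ce}\n")


def write_annotated(annotated: Sequence[AnnotatedIndel], sample_id: str, path) -> None:
    """One TSV row per indel: sample, seq_id, pos, kind, length, in_ms, ms_id, region."""
    with open(path, "w") as fh:
        fh.write("#sample\tseq_id\tpos\tkind\tlength\tin_ms\tms_id\tregion\n")
        for a in annotated:
            c = a.call
            ms_id = a.microsatellite.id if a.in_microsatellite else ""
            fh.write(
                f"{sample_id}\t{c.seq_id}\t{c.affected_interval[0]}\t{c.kind}\t"
                f"{c.length}\t{int(a.in_microsatellite)}\t{ms_id}\t{a.region or ''}\n"
            )
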