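"""Detection of perfect microsatellite tracts in transcript sequences.

A microsatellite is a tandem repeat of a short unit (1-6 bp).  The scanner
reports every *maximal perfect* tract: a run of exact unit repetitions
(possibly ending in a partial unit) that cannot be extended by one base on
either side without breaking the repeat phase.  Imperfect (interrupted)
repeats are deliberately not detected: perfect tracts make the catalogue
fully reproducible and amenable to exhaustive verification.

Coordinates are 0-based half-open throughout.  Units are canonicalised to
the lexicographically smallest rotation of the primitive motif; there is no
reverse-complement folding because transcripts are single-stranded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import InputError, ParseError

_VALID_CHARS = frozenset("ACGTN")
_ACGT = frozenset("ACGT")

CATALOGUE_HEADER = "#seq_id\tstart\tend\tunit\tcopies"


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase nucleotide sequence over the alphabet {A,C,G,T,N}."""

    seq_id: str
    sequence: str


@dataclass(frozen=True)
class Microsatellite:
    """One maximal perfect tandem-repeat tract.

    ``[start, end)`` are 0-based half-open offsets on the transcript,
    ``unit`` is the canonical primitive motif and ``copies`` the (possibly
    fractional) number of unit repetitions, ``(end - start) / len(unit)``.
    """

    seq_id: str
    start: int
    end: int
    unit: str
    copies: float

    @property
    def id(self) -> str:
        return f"{self.seq_id}:{self.start}-{self.end}:{self.unit}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScanParams:
    """Thresholds for tract detection.

    ``min_copies`` and ``min_tract_len`` jointly gate reporting: a tract
    must span at least ``min_tract_len`` bases *and* at least ``min_copies``
    unit repetitions.  Defaults (3 copies, 6 bp) keep mononucleotide runs
    of >= 6 while requiring three repetitions of longer units.
    """

    max_unit_len: int = 6
    min_copies: float = 3.0
    min_tract_len: int = 6

    def __post_init__(self) -> None:
        if not 1 <= self.max_unit_len <= 6:
            raise InputError(f"max_unit_len must be in [1, 6], got {self.max_unit_len}")
        if self.min_copies < 2:
            raise InputError(f"min_copies must be >= 2, got {self.min_copies}")
        if self.min_tract_len < self.max_unit_len:
            raise InputError(
                f"min_tract_len ({self.min_tract_len}) must be >= max_unit_len "
                f"({self.max_unit_len})"
            )

    def min_len_for_unit(self, unit_len: int) -> int:
        """Smallest tract length (bp) a unit of ``unit_len`` must reach."""
        return max(self.min_tract_len, math.ceil(self.min_copies * unit_len))


def primitive_unit(motif: str) -> str:
    """Canonical form of a repeat motif.

    Reduces ``motif`` to the shortest string whose tandem repetition equals
    it, then returns the lexicographically smallest rotation of that string.

    >>> primitive_unit("ATAT")
    'AT'
    >>> primitive_unit("CA")
    'AC'
    """
    if not motif:
        raise InputError("empty motif")
    n = len(motif)
    prim = motif
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            prim = motif[:d]
            break
    return min(prim[i:] + prim[:i] for i in range(len(prim)))


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif[:d] * (n // d) == motif for d in range(1, n))


def find_microsatellites(
    record: SequenceRecord, params: ScanParams | None = None
) -> list[Microsatellite]:
    """All maximal perfect tracts in ``record`` meeting ``params``.

    For each unit length k the sequence is scanned for maximal runs of the
    self-match condition ``seq[i] == seq[i-k]``; a run of m matches ending at
    position i corresponds to the tract ``[i-m-k+1, i+1)``.  Runs whose
    observed unit is non-primitive are skipped — the same tract is already
    reported at its smallest period — which collapses duplicate reports
    under unit multiples.  Positions holding ``N`` never participate.

    Returns tracts sorted by ``(start, end, unit)``.
    """
    params = params or ScanParams()
    seq = record.sequence
    for off, ch in enumerate(seq):
        if ch not in _VALID_CHARS:
            raise InputError(
                f"invalid character {ch!r} at offset {off} in sequence {record.seq_id!r}"
            )
    n = len(seq)
    found: list[Microsatellite] = []
    for k in range(1, min(params.max_unit_len, n) + 1):
        min_len = params.min_len_for_unit(k)
        run = 0  # length of current self-match streak ending at i-1
        for i in range(k, n + 1):
            if i < n and seq[i] == seq[i - k] and seq[i] in _ACGT:
                run += 1
                continue
            if run and run + k >= min_len:
                end = i
                start = end - run - k
                unit = seq[start : start + k]
                if _is_primitive(unit) and set(unit) <= _ACGT:
                    tract_len = end - start
                    if tract_len / k >= params.min_copies:
                        found.append(
                            Microsatellite(
                                seq_id=record.seq_id,
                                start=start,
                                end=end,
                                unit=primitive_unit(unit),
                                copies=tract_len / k,
                            )
                        )
            run = 0
    found.sort(key=lambda m: (m.start, m.end, m.unit))
    return found


def scan_catalogue(
    records: Iterable[SequenceRecord], params: ScanParams | None = None
) -> list[Microsatellite]:
    """Scan several records; catalogue sorted by (seq_id, start, end, unit)."""
    out: list[Microsatellite] = []
    for rec in records:
        out.extend(find_microsatellites(rec, params))
    out.sort(key=lambda m: (m.seq_id, m.start, m.end, m.unit))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-record, possibly line-wrapped) FASTA file, uppercased."""
    records = [
        SequenceRecord(seq_id=r.id, sequence=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for r in records:
        if r.seq_id in seen:
            raise ParseError(f"duplicate sequence id {r.seq_id!r} in {path}")
        seen.add(r.seq_id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_catalogue(microsatellites: Iterable[Microsatellite], path) -> None:
    """Write a BED-like catalogue (0-based half-open) with a header line."""
    with open(path, "w") as fh:
        fh.write(CATALOGUE_HEADER + "\n")
        for ms in microsatellites:
            fh.write(f"{ms.seq_id}\t{ms.start}\t{ms.end}\t{ms.unit}\t{ms.copies:g}\n")


def _parse_catalogue_lines(lines: Iterator[tuple[int, str]]) -> Iterator[Microsatellite]:
    for lineno, line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(f"catalogue line {lineno}: expected 5 columns, got {len(fields)}")
        seq_id, start_s, end_s, unit, copies_s = fields
        try:
            start, end, copies = int(start_s), int(end_s), float(copies_s)
        except ValueError as exc:
            raise ParseError(f"catalogue line {lineno}: {exc}") from exc
        if end <= start:
            raise ParseError(f"catalogue line {lineno}: end ({end}) <= start ({start})")
        if not 1 <= len(unit) <= 6:
            raise ParseError(f"catalogue line {lineno}: unit length {len(unit)} not in [1, 6]")
        yield Microsatellite(seq_id=seq_id, start=start, end=end, unit=unit, copies=copies)


def read_catalogue(path) -> list[Microsatellite]:
    with open(path) as fh:
        return list(_parse_catalogue_lines(enumerate(fh, start=1)))
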