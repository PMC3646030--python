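"""Seeded synthetic transcriptomes and indel cohorts.

The generator produces everything the scoring pipeline consumes — transcript
FASTA, microsatellite catalogue, transcript-model TSV and per-sample indel
VCFs — with a controlled statistical structure:

* transcripts are random ACGT sequences whose background is generated so it
  contains *no* tract meeting the default scan thresholds; microsatellites
  exist only where they were deliberately planted, so the planted list and
  the scanner output coincide exactly;
* each sample draws a fixed number of insertion and deletion events; each
  event lands inside a microsatellite with probability ``p_ms_ins`` /
  ``p_ms_del`` (so PI and PD are exact binomial proportions with those
  expectations) and otherwise falls uniformly outside all tracts;
* microsatellite indel lengths are whole multiples of the tract unit —
  replication-slippage style — with single-unit deletions up-weighted by
  ``msi_del_1bp_weight``.  Mismatch-repair-deficient (MSI) samples double
  the deletion count, double the microsatellite-deletion probability and
  push most microsatellite deletions to one unit, reproducing the excess of
  short (1 bp) microsatellite deletions that separates MSI from MSS
  transcriptomes; microsatellite-stable and normal samples share one
  balanced configuration;
* non-microsatellite indel lengths are geometric with mean 2 bp.

Microsatellite indels are planted at tract left edges already in normalized
form, so pipeline left-normalization must leave them unchanged — running the
pipeline on generated data doubles as a normalization check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, InputError
from .annotator import TranscriptModel, write_transcript_models
from .indel_model import DELETION, INSERTION, IndelCall, left_normalize, write_vcf
from .repeat_finder import (
    Microsatellite,
    ScanParams,
    SequenceRecord,
    find_microsatellites,
    primitive_unit,
    write_catalogue,
    write_fasta,
)

MSI_STATUS = "MSI"
MSS_STATUS = "MSS"
NORMAL_STATUS = "normal"
STATUSES = (NORMAL_STATUS, MSS_STATUS, MSI_STATUS)

# insertion sizes in repeat units, shared by every status so that insertion
# length distributions do not separate the groups
_INS_UNIT_WEIGHTS = {1: 0.7, 2: 0.2, 3: 0.1}

TRUTH_HEADER = (
    "#sample_id\tstatus\tn_ins_total\tn_del_total\tn_ins_ms\tn_del_ms\t"
    "expected_PI\texpected_PD\texpected_index"
)


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults describe one status via :meth:`for_status`."""

    seed: int = 0
    n_transcripts: int = 200
    transcript_len: int = 2000
    tracts_per_transcript: int = 3
    status: str = NORMAL_STATUS
    n_ins_total: int = 300
    n_del_total: int = 300
    p_ms_ins: float = 0.3
    p_ms_del: float = 0.3
    msi_del_1bp_weight: float = 0.4
    known_frac: float = 0.0
    scan: ScanParams = field(default_factory=ScanParams)

    def __post_init__(self) -> None:
        for name in ("p_ms_ins", "p_ms_del", "msi_del_1bp_weight", "known_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_ins_total", "n_del_total", "n_transcripts", "tracts_per_transcript"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.status not in STATUSES:
            raise InputError(f"status must be one of {STATUSES}, got {self.status!r}")

    @classmethod
    def for_status(cls, status: str, seed: int = 0, **overrides) -> "SimParams":
        """Status presets: MSI doubles deletions (600 vs 300), doubles the
        microsatellite-deletion probability (0.6 vs 0.3) and weights
        single-unit deletions at 0.8 (vs 0.4)."""
        base = dict(seed=seed, status=status)
        if status == MSI_STATUS:
            base.update(n_del_total=600, p_ms_del=0.6, msi_del_1bp_weight=0.8)
        elif status not in (MSS_STATUS, NORMAL_STATUS):
            raise InputError(f"unknown status {status!r}")
        base.update(overrides)
        return cls(**base)

    @property
    def expected_index(self) -> float:
        return self.p_ms_ins / self.p_ms_del


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one simulated sample."""

    sample_id: str
    status: str
    n_ins_total: int
    n_del_total: int
    n_ins_ms: int
    n_del_ms: int
    expected_pi: float
    expected_pd: float

    @property
    def expected_index(self) -> float:
        return self.expected_pi / self.expected_pd


@dataclass
class Transcriptome:
    """Generated transcripts plus their exact tract catalogue and models."""

    records: list[SequenceRecord]
    catalogue: list[Microsatellite]
    models: dict[str, TranscriptModel]

    @property
    def reference(self) -> dict[str, str]:
        return {r.seq_id: r.sequence for r in self.records}

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "transcripts.fa",
            "catalogue": out / "catalogue.bed",
            "model": out / "transcripts.model.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        write_catalogue(self.catalogue, paths["catalogue"])
        write_transcript_models(self.models, paths["model"])
        return paths


@dataclass
class SimulatedSample:
    sample_id: str
    calls: list[IndelCall]
    truth: TruthRecord
    known_calls: list[IndelCall] = field(default_factory=list)


# ---------------------------------------------------------------------------
# transcriptome generation

_BASES = "ACGT"


def _completes_tract(seq: list[str], base: str, params: ScanParams) -> bool:
    """Would appending ``base`` finish a tract meeting the scan thresholds?"""
    i = len(seq)
    for k in range(1, params.max_unit_len + 1):
        if i < k or seq[i - k] != base:
            continue
        m = 1
        j = i - 1
        while j >= k and seq[j] == seq[j - k]:
            m += 1
            j -= 1
        if m + k >= params.min_len_for_unit(k):
            return True
    return False


def _append_background(seq: list[str], n: int, rng: np.random.Generator, params: ScanParams,
                       forbid_first: str | None = None) -> None:
    """Extend ``seq`` by n bases that never complete a qualifying tract."""
    for j in range(n):
        order = rng.permutation(4)
        for idx in order:
            b = _BASES[idx]
            if j == 0 and forbid_first is not None and b == forbid_first:
                continue
            if not _completes_tract(seq, b, params):
                seq.append(b)
                break
        else:
            raise ConfigError("could not place a background base without forming a tract")


def _try_append_tract(seq: list[str], text: str, params: ScanParams) -> bool:
    """Append tract ``text``, rejecting cross-boundary artifacts.

    While appending, any qualifying run whose implied tract would start
    *left* of the planted tract (i.e. leaks into the background, like a
    background ``GTGT`` fused with a leading ``T`` of the tract) aborts the
    append and restores ``seq``.  Runs contained in the tract itself are its
    own periodicities and are fine.
    """
    tract_start = len(seq)
    for ch in text:
        i = len(seq)
        for k in range(1, params.max_unit_len + 1):
            if i < k or seq[i - k] != ch:
                continue
            m = 1
            j = i - 1
            while j >= k and seq[j] == seq[j - k]:
                m += 1
                j -= 1
            if m + k >= params.min_len_for_unit(k) and i - m - k + 1 < tract_start:
                del seq[tract_start:]
                return False
        seq.append(ch)
    return True


def _random_primitive_unit(k: int, rng: np.random.Generator) -> str:
    # canonical rotation, so the planted text starts with the catalogue unit
    while True:
        unit = "".join(_BASES[i] for i in rng.integers(0, 4, size=k))
        canon = primitive_unit(unit)
        if len(canon) == k:
            return canon


def _plan_tract(rng: np.random.Generator) -> tuple[str, int]:
    """Pick (unit, integer copies) for a planted tract (>= 8 bp, >= 3 copies)."""
    k = int(rng.integers(1, 7))
    unit = _random_primitive_unit(k, rng)
    min_copies = max(3, math.ceil(8 / k))
    span = 5 if k <= 2 else 2
    copies = int(rng.integers(min_copies, min_copies + span + 1))
    return unit, copies


def generate_transcriptome(params: SimParams, verify: bool = True) -> Transcriptome:
    """Build ``n_transcripts`` transcripts with exactly
    ``tracts_per_transcript`` planted tracts each.

    Tracts are spaced one per equal-width block with >= 30 bp margins so
    neighbouring tracts can never merge; boundary bases are constrained so
    every planted tract is maximal.  With ``verify=True`` each transcript is
    re-scanned and the scanner output is required to equal the planted list.
    """
    rng = np.random.default_rng(params.seed)
    margin = 30
    block = params.transcript_len // max(params.tracts_per_transcript, 1)
    if params.tracts_per_transcript and block < 2 * margin + 40:
        raise ConfigError(
            f"transcript_len {params.transcript_len} too short for "
            f"{params.tracts_per_transcript} tracts"
        )
    records: list[SequenceRecord] = []
    catalogue: list[Microsatellite] = []
    models: dict[str, TranscriptModel] = {}
    for t in range(params.n_transcripts):
        seq_id = f"TX{t:04d}"
        seq: list[str] = []
        for j in range(params.tracts_per_transcript):
            unit, copies = _plan_tract(rng)
            tract_len = len(unit) * copies
            lo = j * block + margin
            hi = (j + 1) * block - margin - tract_len
            start = int(rng.integers(lo, hi))
            _append_background(seq, start - len(seq), rng, params.scan)
            for attempt in range(30):
                # left maximality: the base before the tract must differ from
                # the unit's last base (else the repeat phase extends left)
                if seq and seq[-1] == unit[-1]:
                    seq.pop()
                    _append_background(seq, 1, rng, params.scan, forbid_first=unit[-1])
                if _try_append_tract(seq, unit * copies, params.scan):
                    break
                # junction artifact: regenerate the background tail and retry
                n_pop = min(2 + attempt, len(seq) - 1)
                del seq[len(seq) - n_pop :]
                _append_background(seq, n_pop - 1, rng, params.scan)
            else:
                raise ConfigError("could not plant a tract without junction artifacts")
            start = len(seq) - len(unit) * copies
            catalogue.append(
                Microsatellite(
                    seq_id=seq_id,
                    start=start,
                    end=start + tract_len,
                    unit=primitive_unit(unit),
                    copies=float(copies),
                )
            )
            # right maximality: next base must not continue the repeat phase
            _append_background(seq, 1, rng, params.scan, forbid_first=unit[0])
        _append_background(seq, params.transcript_len - len(seq), rng, params.scan)
        record = SequenceRecord(seq_id=seq_id, sequence="".join(seq))
        records.append(record)
        if rng.random() < 0.8:
            cds_start = int(rng.integers(50, params.transcript_len // 4))
            cds_end = int(
                rng.integers(params.transcript_len // 2, params.transcript_len - 50)
            )
            models[seq_id] = TranscriptModel(
                seq_id=seq_id, length=len(record.sequence),
                cds_start=cds_start, cds_end=cds_end,
            )
        else:
            models[seq_id] = TranscriptModel(seq_id=seq_id, length=len(record.sequence))
    if verify:
        planted = sorted(catalogue, key=lambda m: (m.seq_id, m.start))
        found = []
        for rec in records:
            found.extend(find_microsatellites(rec, params.scan))
        found.sort(key=lambda m: (m.seq_id, m.start))
        if planted != found:
            raise ConfigError(
                "generated transcriptome is not self-consistent: scanner output "
                "differs from the planted catalogue"
            )
    return Transcriptome(records=records, catalogue=catalogue, models=models)


# ---------------------------------------------------------------------------
# sample generation


def _unit_multiple(rng, one_unit_weight: float, max_units: int) -> int:
    """Number of whole repeat units gained/lost in a slippage event."""
    if rng.random() < one_unit_weight or max_units <= 1:
        return 1
    return min(int(rng.integers(2, 4)), max_units)


def _ms_insertion(ms: Microsatellite, rng) -> IndelCall:
    m = 1
    r = rng.random()
    acc = 0.0
    for units, w in _INS_UNIT_WEIGHTS.items():
        acc += w
        if r < acc:
            m = units
            break
    unit = ms.unit
    return IndelCall(
        seq_id=ms.seq_id,
        kind=INSERTION,
        affected_interval=(ms.start, ms.start),
        seq=unit * m,
    )


def _ms_deletion(ms: Microsatellite, rng, one_unit_weight: float) -> IndelCall:
    whole_copies = int(ms.copies)
    m = _unit_multiple(rng, one_unit_weight, max_units=min(3, whole_copies - 1))
    k = len(ms.unit)
    return IndelCall(
        seq_id=ms.seq_id,
        kind=DELETION,
        affected_interval=(ms.start, ms.start + m * k),
        seq=ms.unit * m,
    )


def _background_indel(
    kind: str,
    transcriptome: Transcriptome,
    rng,
    annotate_check,
) -> IndelCall:
    """A left-normalized indel that does not intersect any tract."""
    records = transcriptome.records
    for _ in range(200):
        rec = records[int(rng.integers(0, len(records)))]
        length = min(int(rng.geometric(0.5)), 10)
        pos = int(rng.integers(1, len(rec.sequence) - length - 1))
        if kind == DELETION:
            call = IndelCall(
                seq_id=rec.seq_id,
                kind=DELETION,
                affected_interval=(pos, pos + length),
                seq=rec.sequence[pos : pos + length],
            )
        else:
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
            call = IndelCall(
                seq_id=rec.seq_id, kind=INSERTION, affected_interval=(pos, pos), seq=ins
            )
        call = left_normalize(call, rec.sequence)
        if call.affected_interval[0] < 1:
            continue
        if not annotate_check(call):
            return call
    raise ConfigError("could not place a background indel outside all tracts")


def generate_sample(
    params: SimParams, transcriptome: Transcriptome, sample_id: str | None = None
) -> SimulatedSample:
    """Draw one sample's indel calls from ``transcriptome``.

    Each of the ``n_ins_total`` insertions (``n_del_total`` deletions) is a
    microsatellite event with probability ``p_ms_ins`` (``p_ms_del``), placed
    at the left edge of a uniformly chosen tract; otherwise it is placed
    uniformly outside all tracts.  All calls are emitted left-normalized.
    """
    rng = np.random.default_rng(params.seed)
    sample_id = sample_id or f"{params.status}_s{params.seed}"
    cat = transcriptome.catalogue
    if not cat:
        raise ConfigError("transcriptome has no microsatellites")
    del_eligible = [ms for ms in cat if int(ms.copies) >= 2]
    by_seq: dict[str, list[Microsatellite]] = {}
    for ms in cat:
        by_seq.setdefault(ms.seq_id, []).append(ms)

    def in_any_tract(call: IndelCall) -> bool:
        # same membership rule the annotator applies (insertions include the
        # position one base left of the tract)
        s, e = call.affected_interval
        for ms in by_seq.get(call.seq_id, ()):
            if call.kind == DELETION:
                if ms.start < e and ms.end > s:
                    return True
            elif ms.start - 1 <= s < ms.end:
                return True
        return False

    calls: list[IndelCall] = []
    background: list[IndelCall] = []
    n_ins_ms = n_del_ms = 0
    for _ in range(params.n_ins_total):
        if rng.random() < params.p_ms_ins:
            ms = cat[int(rng.integers(0, len(cat)))]
            calls.append(_ms_insertion(ms, rng))
            n_ins_ms += 1
        else:
            call = _background_indel(INSERTION, transcriptome, rng, in_any_tract)
            calls.append(call)
            background.append(call)
    for _ in range(params.n_del_total):
        if rng.random() < params.p_ms_del:
            ms = del_eligible[int(rng.integers(0, len(del_eligible)))]
            calls.append(_ms_deletion(ms, rng, params.msi_del_1bp_weight))
            n_del_ms += 1
        else:
            call = _background_indel(DELETION, transcriptome, rng, in_any_tract)
            calls.append(call)
            background.append(call)
    known_calls: list[IndelCall] = []
    if params.known_frac > 0 and background:
        n_known = int(round(params.known_frac * len(background)))
        if n_known:
            idx = rng.choice(len(background), size=n_known, replace=False)
            known_calls = [background[i] for i in sorted(idx)]
    truth = TruthRecord(
        sample_id=sample_id,
        status=params.status,
        n_ins_total=params.n_ins_total,
        n_del_total=params.n_del_total,
        n_ins_ms=n_ins_ms,
        n_del_ms=n_del_ms,
        expected_pi=params.p_ms_ins,
        expected_pd=params.p_ms_del,
    )
    return SimulatedSample(
        sample_id=sample_id, calls=calls, truth=truth, known_calls=known_calls
    )


# ---------------------------------------------------------------------------
# cohorts


def _jitter_count(n: int, rng) -> int:
    """Uniform +/-10% jitter on a planned event count."""
    lo = int(math.floor(n * 0.9))
    hi = int(math.ceil(n * 1.1))
    return int(rng.integers(lo, hi + 1))


def generate_cohort(
    n_per_group: int,
    base_params: SimParams,
    out_dir=None,
    groups: Sequence[str] = STATUSES,
) -> tuple[Transcriptome, list[SimulatedSample]]:
    """One shared transcriptome plus ``n_per_group`` samples per status.

    Per-sample seeds are derived deterministically from the master seed, and
    event counts are jittered +/-10% so cohort samples are not exact clones.
    When ``out_dir`` is given, writes FASTA/catalogue/model, one VCF per
    sample (plus known-variant VCFs when requested) and a truth TSV.
    """
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    transcriptome = generate_transcriptome(
        replace(base_params, status=NORMAL_STATUS)
    )
    samples: list[SimulatedSample] = []
    for group in groups:
        for i in range(n_per_group):
            sample_seed = int((base_params.seed * 1_000_003 + len(samples) + 1) % (2**31))
            jrng = np.random.default_rng(sample_seed)
            params = SimParams.for_status(group, seed=sample_seed)
            params = replace(
                params,
                n_ins_total=_jitter_count(params.n_ins_total, jrng),
                n_del_total=_jitter_count(params.n_del_total, jrng),
                known_frac=base_params.known_frac,
            )
            samples.append(
                generate_sample(params, transcriptome, sample_id=f"{group}_{i:02d}")
            )
    if out_dir is not None:
        write_cohort(transcriptome, samples, out_dir)
    return transcriptome, samples


def write_cohort(
    transcriptome: Transcriptome, samples: Sequence[SimulatedSample], out_dir
) -> dict[str, Path]:
    out = Path(out_dir)
    paths = transcriptome.write(out)
    ref = transcriptome.reference
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for s in samples:
            t = s.truth
            fh.write(
                f"{t.sample_id}\t{t.status}\t{t.n_ins_total}\t{t.n_del_total}\t"
                f"{t.n_ins_ms}\t{t.n_del_ms}\t{t.expected_pi:g}\t{t.expected_pd:g}\t"
                f"{t.expected_index:g}\n"
            )
            vcf_path = out / f"{t.sample_id}.vcf"
            write_vcf(s.calls, ref, vcf_path, source="msiseq-simulate")
            if s.known_calls:
                write_vcf(s.known_calls, ref, out / f"{t.sample_id}.known.vcf",
                          source="msiseq-simulate-known")
    paths["truth"] = truth_path
    return paths
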