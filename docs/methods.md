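# Methods

## Model and rationale

Replication slippage in tandem repeats is normally corrected by the DNA
mismatch-repair (MMR) system. When MMR is deficient, slippage indels
accumulate in microsatellites, and the excess is asymmetric: short
deletions — dominated by single-unit, typically 1 bp, events — increase far
more than insertions. `msiseq` turns this asymmetry into a per-sample
statistic. With all post-filter indel events in a sample classified as
inside/outside microsatellites,

    PI = n_ins_ms / n_ins_total,   PD = n_del_ms / n_del_total,
    index = PI / PD.

PD alone discriminates instability but depends on overall indel yield
(coverage, caller sensitivity); dividing by PI normalizes those
sample-level effects away, because both proportions share the same
detection pipeline. The index is a continuous measure of instability:
mismatch-repair-proficient samples sit near or above 1, deficient samples
fall clearly below it.

Assumptions: indel calls are in transcript coordinates against the same
FASTA used for repeat scanning; insertions and deletions are subject to the
same ascertainment; common population polymorphisms are removed (otherwise
they inflate both numerators independently of tumour state).

## Repeat scanner

Microsatellites are *maximal perfect* tandem repeats with primitive unit
length 1–6. The scanner finds, for each unit length k, maximal runs of the
self-match condition `seq[i] == seq[i-k]`; a run of m matches ending at i
is the tract `[i-m-k+1, i+1)` with `(m+k)/k` copies (fractional terminal
copies count). Runs whose observed unit is non-primitive are skipped, which
collapses duplicate reports of one tract under unit multiples; rotations
are canonicalised to the lexicographically smallest rotation (no
reverse-complement folding — transcripts are single-stranded). `N` bases
never participate in a tract.

Defaults: `min_copies = 3`, `min_tract_len = 6`, `max_unit_len = 6`. The
copy and length floors are deliberately permissive — mononucleotide runs of
6 qualify — because short repeats carry most of the slippage signal;
both are configurable. Interrupted (imperfect) repeats are not detected.
This is a deliberate design choice: perfect tracts make the catalogue a
pure function of the sequence, reproducible to the byte and verifiable by
exhaustive enumeration, at the cost of missing the minority of imperfect
repeats that alignment-scoring repeat finders would report.

## Indel handling

VCF records are reduced to pure indels by trimming the shared allele suffix
then prefix; substitutions, MNPs and complex records are skipped and
counted (the index is defined over insertions and deletions only). Every
retained call is left-normalized — shifted to the smallest coordinate among
all representations producing the same edited sequence — so slippage indels
land at the left edge of their tract. Known-variant filtering matches
normalized `(transcript, position, allele)` keys from a second VCF;
allele-level matching is robust to missing rsID annotation, and an
rsID-presence mode (`drop_annotated_ids`) is available where the sample VCF
is already dbSNP-annotated. FILTER-failed records are dropped unless
`--keep-filtered`; no indel length cap is applied unless `--max-indel-len`
is set.

Membership rules (0-based half-open): a deletion is in a tract iff its
deleted interval overlaps the tract; an insertion iff its insertion point
lies in `[start-1, end)`. The extra flank position exists because
left-normalization parks a tract-lengthening insertion one base left of the
tract whenever the preceding base equals the unit's last base; excluding it
would systematically miss in-phase slippage insertions. When several tracts
qualify, the smallest-start (tie: longest) tract is assigned. Region
attribution uses the indel's anchor position against per-transcript CDS
boundaries (no CDS ⇒ ncRNA); an indel spanning a boundary takes its
anchor's region so region labels partition the events.

Region proportions are computed over microsatellite indel *events*; the
altered-tract count (distinct tracts with ≥ 1 indel) is reported separately,
and tract-level PI/PD numerators are available via `tract_numerators=True`.
Event counting is primary because the index is a ratio of event
proportions; the tract view answers the different question of how many loci
are affected.

## Classification and supporting tests

Labels: `MSI` if index < threshold, `MSS` otherwise, `indeterminate` when
the index is undefined (zero denominators; no pseudocounts by default,
`--pseudocount` opts in) or when the sample has fewer than 20 insertions or
20 deletions — a ratio of proportions is unstable on tiny denominators.
The default threshold 0.9 comes from the clinical tumour/normal separation;
the cell-line separation supports 1.0, and both are exposed.

Distribution comparison uses the two-sample Kolmogorov–Smirnov test on
integer microsatellite indel lengths, one sample versus the concatenated
lengths of a control cohort, with the asymptotic two-sided p-value. With
heavy integer ties this p-value is approximate (slightly conservative);
that is accepted and documented rather than bootstrapped. Group comparison
uses the classic Student t-test (pooled variance) two-sided, with Welch and
paired variants behind flags; zero-variance configurations are flagged
degenerate instead of raising.

## Synthetic data generator

The simulator emulates the statistical skeleton of an MSI study, not raw
reads. One transcriptome (default 200 transcripts × 2000 bp) carries 3
planted tracts per transcript (unit 1–6 bp, ≥ 3 whole copies, ≥ 8 bp,
canonical rotation), spaced with ≥ 30 bp margins. Background bases are
drawn so that *no* tract meeting the default scan thresholds arises by
chance, and tract junctions are re-drawn when a background suffix fused
with tract bases would create an unplanned repeat; consequently the planted
list equals the scanner output exactly, which the generator verifies at
build time. ~80 % of transcripts receive CDS boundaries.

Per sample, a fixed number of insertion (300) and deletion events (300 for
normal/MSS, 600 for MSI) are drawn. Each event is a microsatellite event
with probability `p_ms_ins` / `p_ms_del` (0.3/0.3 for normal and MSS,
0.3/0.6 for MSI), so the realized PI and PD are exact binomial proportions
with those expectations and `E[index]` is 1.0 (MSS/normal) or 0.5 (MSI) up
to ratio bias of order 1/n. Microsatellite events sit at tract left edges,
pre-normalized (pipeline normalization must leave them fixed — a built-in
normalization check), and their lengths are whole unit multiples:
single-unit deletions with probability `msi_del_1bp_weight` (0.8 MSI, 0.4
otherwise; 2–3 units else), reproducing the MSI excess of 1 bp deletions;
insertion multiples (0.7/0.2/0.1 for 1/2/3 units) are identical across
statuses so insertion lengths carry no group signal. Background events fall
uniformly outside all tracts with geometric lengths (mean 2 bp). Cohorts
share one transcriptome, jitter per-sample counts ±10 %, and derive
per-sample seeds from the master seed. `known_frac` duplicates a fraction
of background calls into a synthetic known-variant VCF to exercise
filtering.

What the generator does *not* emulate — alignment artifacts, coverage- and
expression-dependent detectability, imperfect repeats, caller-specific
error modes, germline polymorphism structure. Tests passing on synthetic
cohorts therefore validate the bookkeeping and the statistical behaviour of
the index under its own model, not performance on real tumour RNA-seq.

## Numerical and scale choices

All coordinates are 0-based half-open internally; 1-based anchors exist
only at VCF boundaries (events at sequence start are written
right-anchored). Scoring is fully deterministic; all randomness is confined
to seeded `numpy` generators in the simulator. Reference checks compare
REF alleles to the FASTA and fail loudly on mismatch.

Reference problem sizes used by the test suite and the acceptance script:
scanner-vs-oracle equivalence on 200 random sequences ≤ 200 bp;
normalization on 1000 random indels against a full-enumeration oracle;
parameter recovery over 50 simulated samples (mean PI/PD within two
standard errors of the mean, `2·sqrt(p(1−p)/n)/sqrt(50)`); index bounds from
one MSI-like sample and the mean of ten MSS-like samples (a single
300/300-count MSS draw has index SD ≈ 0.125, so the balanced value is
asserted for the 10-seed mean within twice its analytic standard error);
KS signature against a pooled 10-sample control cohort; determinism and
count conservation on a 9-sample cohort. These sizes keep a full run in
seconds while leaving all bounds analytically grounded.

## Known limitations

- Transcript-space only: no splicing-aware genome-space annotation, no
  reverse-complement unit folding.
- Perfect repeats only; TRF-style imperfect tracts are out of scope.
- The KS p-value on tied integer data is asymptotic, not exact.
- No multiple-testing correction across samples (none is applied in the
  comparisons the report mirrors).
- The indeterminate guard (≥ 20/20 events) is a pragmatic floor, not a
  calibrated operating point; samples near it deserve manual review.
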