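"""The MSI-seq index and its supporting statistics.

For one sample, PI is the proportion of insertion events falling inside
microsatellites among all insertion events, and PD the analogous proportion
for deletions.  Mismatch-repair deficiency preferentially inflates short
microsatellite deletions, which raises PD while leaving PI comparatively
stable, so the ratio PI/PD — the MSI-seq index — drops below 1 in unstable
(MSI) samples and sits at or above 1 in stable (MSS) ones.  A sample is
called MSI when its index falls below the decision threshold (default 0.9,
from the clinical-sample separation; the cell-line separation supports 1.0).

Distributional support: per-sample two-sample Kolmogorov–Smirnov tests
compare a sample's microsatellite indel lengths against a pooled control
cohort, and Student t-tests compare index/region summaries between groups.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotator import (
    CDS,
    FIVE_PRIME_UTR,
    NC_RNA,
    THREE_PRIME_UTR,
    AnnotatedIndel,
    altered_microsatellite_count,
    region_proportions,
)
from .errors import ConfigError
from .indel_model import INSERTION

MSI = "MSI"
MSS = "MSS"
INDETERMINATE = "indeterminate"

DEFAULT_THRESHOLD = 0.9
DEFAULT_MIN_INS = 20
DEFAULT_MIN_DEL = 20

REPORT_COLUMNS = [
    "sample_id",
    "n_ins_total",
    "n_ins_ms",
    "n_del_total",
    "n_del_ms",
    "PI",
    "PD",
    "index",
    "label",
    "altered_ms",
    "prop_cds",
    "prop_5utr",
    "prop_3utr",
    "prop_nc",
    "ks_del_p",
    "ks_ins_p",
]

_PROP_KEYS = {
    "prop_cds": CDS,
    "prop_5utr": FIVE_PRIME_UTR,
    "prop_3utr": THREE_PRIME_UTR,
    "prop_nc": NC_RNA,
}


@dataclass
class SampleProfile:
    """Per-sample indel counts split by type and microsatellite membership."""

    sample_id: str
    n_ins_total: int = 0
    n_ins_ms: int = 0
    n_del_total: int = 0
    n_del_ms: int = 0
    del_lengths_ms: list[int] = field(default_factory=list)
    ins_lengths_ms: list[int] = field(default_factory=list)
    region_counts: Counter = field(default_factory=Counter)
    altered_ms: int = 0
    region_props: dict[str, float] | None = None
    # tract-level numerators: distinct tracts hit by >= 1 insertion/deletion
    n_ins_ms_tracts: int = 0
    n_del_ms_tracts: int = 0


@dataclass
class MSIResult:
    """PI, PD, the PI/PD index and the resulting status label.

    Undefined components (zero denominators) are held as None and always
    yield an ``indeterminate`` label rather than a fabricated ratio.
    """

    sample_id: str
    pi: float | None
    pd: float | None
    index: float | None
    label: str = INDETERMINATE
    threshold_used: float | None = None
    n_ins_total: int = 0
    n_del_total: int = 0


def compute_profile(annotated: Sequence[AnnotatedIndel], sample_id: str) -> SampleProfile:
    """Tally one sample's annotated indels into a :class:`SampleProfile`."""
    prof = SampleProfile(sample_id=sample_id)
    ins_tracts: set[str] = set()
    del_tracts: set[str] = set()
    for a in annotated:
        if a.call.kind == INSERTION:
            prof.n_ins_total += 1
            if a.in_microsatellite:
                prof.n_ins_ms += 1
                prof.ins_lengths_ms.append(a.call.length)
                ins_tracts.add(a.microsatellite.id)
        else:
            prof.n_del_total += 1
            if a.in_microsatellite:
                prof.n_del_ms += 1
                prof.del_lengths_ms.append(a.call.length)
                del_tracts.add(a.microsatellite.id)
        if a.in_microsatellite and a.region is not None:
            prof.region_counts[a.region] += 1
    prof.altered_ms = altered_microsatellite_count(annotated)
    prof.region_props = region_proportions(annotated)
    prof.n_ins_ms_tracts = len(ins_tracts)
    prof.n_del_ms_tracts = len(del_tracts)
    return prof


def msi_index(
    profile: SampleProfile, pseudocount: float = 0.0, tract_numerators: bool = False
) -> MSIResult:
    """PI, PD and PI/PD for one profile.

    With the default zero ``pseudocount``, a zero denominator leaves the
    corresponding proportion undefined (None) and the label indeterminate;
    a positive pseudocount is added to every numerator and denominator
    instead.  ``tract_numerators=True`` counts each altered tract once in
    the numerators instead of each indel event (events are the primary
    currency; both views are deterministic given one annotated sample).
    """
    n_ins_ms = profile.n_ins_ms_tracts if tract_numerators else profile.n_ins_ms
    n_del_ms = profile.n_del_ms_tracts if tract_numerators else profile.n_del_ms
    pi = _proportion(n_ins_ms, profile.n_ins_total, pseudocount)
    pdel = _proportion(n_del_ms, profile.n_del_total, pseudocount)
    index = pi / pdel if (pi is not None and pdel is not None and pdel > 0) else None
    return MSIResult(
        sample_id=profile.sample_id,
        pi=pi,
        pd=pdel,
        index=index,
        n_ins_total=profile.n_ins_total,
        n_del_total=profile.n_del_total,
    )


def _proportion(k: int, n: int, pseudocount: float) -> float | None:
    if n + pseudocount <= 0:
        return None
    return (k + pseudocount) / (n + pseudocount)


def classify(
    result: MSIResult,
    threshold: float = DEFAULT_THRESHOLD,
    min_ins: int = DEFAULT_MIN_INS,
    min_del: int = DEFAULT_MIN_DEL,
) -> MSIResult:
    """Attach an MSI/MSS/indeterminate label to ``result``.

    MSI when index < threshold, MSS when index >= threshold; indeterminate
    when the index is undefined or either total count falls below its
    minimum (the index is a ratio of proportions and unstable on tiny
    denominators).
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be positive, got {threshold}")
    if result.index is None or result.n_ins_total < min_ins or result.n_del_total < min_del:
        label = INDETERMINATE
    elif result.index < threshold:
        label = MSI
    else:
        label = MSS
    return replace(result, label=label, threshold_used=threshold)


def score_sample(
    annotated: Sequence[AnnotatedIndel],
    sample_id: str,
    threshold: float = DEFAULT_THRESHOLD,
    min_ins: int = DEFAULT_MIN_INS,
    min_del: int = DEFAULT_MIN_DEL,
    pseudocount: float = 0.0,
) -> tuple[SampleProfile, MSIResult]:
    """Profile, index and classify one sample's annotated indels."""
    profile = compute_profile(annotated, sample_id)
    result = classify(
        msi_index(profile, pseudocount=pseudocount),
        threshold=threshold,
        min_ins=min_ins,
        min_del=min_del,
    )
    return profile, result


class KSOutcome(NamedTuple):
    statistic: float
    pvalue: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.statistic)


def ks_length_test(
    sample_lengths: Sequence[int], control_lengths: Sequence[int]
) -> KSOutcome:
    """Two-sample Kolmogorov–Smirnov test on integer length multisets.

    Uses the asymptotic two-sided p-value; with heavily tied integer data
    this is the common practice and slightly conservative.  Either side
    empty yields NaNs (flagged undefined) instead of an exception.
    """
    if len(sample_lengths) == 0 or len(control_lengths) == 0:
        return KSOutcome(math.nan, math.nan)
    res = stats.ks_2samp(
        np.asarray(sample_lengths, dtype=float),
        np.asarray(control_lengths, dtype=float),
        method="asymp",
    )
    return KSOutcome(float(res.statistic), float(min(res.pvalue, 1.0)))


class TTestOutcome(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> TTestOutcome:
    """Two-sided t-test between two groups of per-sample summaries.

    Defaults to the classic Student test (pooled variance); ``welch=True``
    drops the equal-variance assumption, ``paired=True`` runs a paired test
    (equal lengths required).  A zero-variance configuration is flagged
    degenerate with NaN statistics rather than raising.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("need at least 2 values per group")
    if paired:
        if a.size != b.size:
            raise ConfigError(f"paired groups must have equal sizes ({a.size} vs {b.size})")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            t = 0.0 if np.allclose(d.mean(), 0.0) else math.inf
            return TTestOutcome(t, math.nan, True)
        res = stats.ttest_rel(a, b)
    else:
        pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        if np.allclose(pooled_var, 0.0) and not welch:
            t = 0.0 if np.allclose(a.mean(), b.mean()) else math.inf
            return TTestOutcome(t, math.nan, True)
        res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestOutcome(float(res.statistic), float(res.pvalue), False)


def cohort_report(
    results: Sequence[MSIResult],
    profiles: Mapping[str, SampleProfile],
    control_profiles: Sequence[SampleProfile] | None = None,
) -> pd.DataFrame:
    """Per-sample summary table.

    One row per scored sample: counts, PI, PD, index, label, altered-tract
    count, region proportions, and — when a control cohort is given — the
    per-sample KS p-values of its microsatellite deletion and insertion
    lengths against the pooled control lengths.
    """
    pooled_del: list[int] = []
    pooled_ins: list[int] = []
    if control_profiles:
        for cp in control_profiles:
            pooled_del.extend(cp.del_lengths_ms)
            pooled_ins.extend(cp.ins_lengths_ms)
    rows = []
    for res in results:
        prof = profiles[res.sample_id]
        row: dict[str, object] = {
            "sample_id": res.sample_id,
            "n_ins_total": prof.n_ins_total,
            "n_ins_ms": prof.n_ins_ms,
            "n_del_total": prof.n_del_total,
            "n_del_ms": prof.n_del_ms,
            "PI": _nan(res.pi),
            "PD": _nan(res.pd),
            "index": _nan(res.index),
            "label": res.label,
            "altered_ms": prof.altered_ms,
        }
        props = prof.region_props
        for col, region in _PROP_KEYS.items():
            row[col] = props[region] if props is not None else math.nan
        row["ks_del_p"] = (
            ks_length_test(prof.del_lengths_ms, pooled_del).pvalue if pooled_del else math.nan
        )
        row["ks_ins_p"] = (
            ks_length_test(prof.ins_lengths_ms, pooled_ins).pvalue if pooled_ins else math.nan
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _nan(x: float | None) -> float:
    return math.nan if x is None else x


def write_report(df: pd.DataFrame, tsv_path, json_path=None) -> None:
    """Write the report as TSV plus a full-precision JSON mirror."""
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    if json_path is not None:
        records = [
            {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]
        with open(json_path, "w") as fh:
            json.dump({"samples": records}, fh, indent=2)
            fh.write("\n")


def read_report(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")
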