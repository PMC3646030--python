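"""Pipeline orchestration: scan -> ingest -> filter -> annotate -> score.

Everything here is deterministic; randomness lives only in the simulator.
Each stage logs its input/output record counts and the same counts are
written to a machine-readable run manifest, so count conservation
(``records_in == records_out + records_dropped``) can be audited per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotator, indel_model, msi_stats, repeat_finder
from .errors import ConfigError
from .msi_stats import DEFAULT_MIN_DEL, DEFAULT_MIN_INS, DEFAULT_THRESHOLD

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one scoring run."""

    fasta: Path
    vcfs: list[Path]
    catalogue: Path | None = None  # scanned from fasta when absent
    model: Path | None = None
    known_vcf: Path | None = None
    control_dir: Path | None = None
    out_dir: Path = Path("msiseq_out")
    scan: repeat_finder.ScanParams = field(default_factory=repeat_finder.ScanParams)
    threshold: float = DEFAULT_THRESHOLD
    min_ins: int = DEFAULT_MIN_INS
    min_del: int = DEFAULT_MIN_DEL
    pseudocount: float = 0.0
    keep_filtered: bool = False
    max_indel_len: int | None = None

    def validate(self) -> None:
        required = [self.fasta, *self.vcfs]
        for opt in (self.catalogue, self.model, self.known_vcf, self.control_dir):
            if opt is not None:
                required.append(opt)
        for p in required:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not self.vcfs:
            raise ConfigError("at least one sample VCF is required")

    def to_jsonable(self) -> dict:
        d = {
            "fasta": str(self.fasta),
            "vcfs": [str(v) for v in self.vcfs],
            "catalogue": str(self.catalogue) if self.catalogue else None,
            "model": str(self.model) if self.model else None,
            "known_vcf": str(self.known_vcf) if self.known_vcf else None,
            "control_dir": str(self.control_dir) if self.control_dir else None,
            "out_dir": str(self.out_dir),
            "scan": {
                "max_unit_len": self.scan.max_unit_len,
                "min_copies": self.scan.min_copies,
                "min_tract_len": self.scan.min_tract_len,
            },
            "threshold": self.threshold,
            "min_ins": self.min_ins,
            "min_del": self.min_del,
            "pseudocount": self.pseudocount,
            "keep_filtered": self.keep_filtered,
            "max_indel_len": self.max_indel_len,
        }
        return d


def _stage(manifest: list[dict], name: str, n_in: int, n_out: int, sample: str | None = None):
    dropped = n_in - n_out
    logger.info("stage %-12s sample=%s in=%d out=%d dropped=%d", name, sample, n_in, n_out, dropped)
    manifest.append(
        {"stage": name, "sample": sample, "records_in": n_in, "records_out": n_out,
         "records_dropped": dropped}
    )


def _score_one_vcf(
    vcf_path: Path,
    reference: Mapping[str, str],
    catalogue,
    models,
    known,
    config: RunConfig,
    manifest: list[dict],
):
    sample_id = Path(vcf_path).stem
    calls, stats = indel_model.read_indels(
        vcf_path, reference,
        keep_filtered=config.keep_filtered, max_indel_len=config.max_indel_len,
    )
    _stage(manifest, "read", stats["records"], len(calls), sample_id)
    _stage(manifest, "normalize", len(calls), len(calls), sample_id)
    kept, removed = indel_model.filter_known(calls, known)
    _stage(manifest, "filter_known", len(calls), len(kept), sample_id)
    annotated = annotator.annotate(kept, catalogue, models)
    _stage(manifest, "annotate", len(kept), len(annotated), sample_id)
    profile, result = msi_stats.score_sample(
        annotated, sample_id,
        threshold=config.threshold, min_ins=config.min_ins, min_del=config.min_del,
        pseudocount=config.pseudocount,
    )
    _stage(manifest, "profile", len(annotated),
           profile.n_ins_total + profile.n_del_total, sample_id)
    return profile, result


def run_score(config: RunConfig) -> pd.DataFrame:
    """Execute the full scoring pipeline and write report + manifest.

    Stage order is fixed: read -> normalize -> filter -> intersect/annotate
    -> profile -> index -> classify -> report.  Returns the report frame;
    writes ``report.tsv``, ``report.json`` and ``manifest.json`` in
    ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    records = repeat_finder.read_fasta(config.fasta)
    reference = indel_model.as_reference(records)
    if config.catalogue is not None:
        catalogue = repeat_finder.read_catalogue(config.catalogue)
    else:
        catalogue = repeat_finder.scan_catalogue(records, config.scan)
    _stage(manifest, "scan", len(records), len(catalogue))
    models = annotator.read_transcript_models(config.model) if config.model else {
        r.seq_id: annotator.TranscriptModel(seq_id=r.seq_id, length=len(r.sequence))
        for r in records
    }
    known = (
        indel_model.KnownVariantSet.from_vcf(config.known_vcf, reference)
        if config.known_vcf
        else None
    )

    profiles: dict[str, msi_stats.SampleProfile] = {}
    results: list[msi_stats.MSIResult] = []
    for vcf in config.vcfs:
        profile, result = _score_one_vcf(
            vcf, reference, catalogue, models, known, config, manifest
        )
        profiles[profile.sample_id] = profile
        results.append(result)

    control_profiles: list[msi_stats.SampleProfile] = []
    if config.control_dir is not None:
        control_vcfs = sorted(Path(config.control_dir).glob("*.vcf"))
        for vcf in control_vcfs:
            profile, _ = _score_one_vcf(
                vcf, reference, catalogue, models, known, config, manifest
            )
            control_profiles.append(profile)

    report = msi_stats.cohort_report(results, profiles, control_profiles or None)
    msi_stats.write_report(report, out_dir / "report.tsv", out_dir / "report.json")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"config": config.to_jsonable(), "stages": manifest}, fh, indent=2)
        fh.write("\n")
    return report


COMPARE_METRICS = ["index", "PI", "PD", "prop_cds", "prop_5utr", "prop_3utr", "prop_nc"]


def run_compare(
    groups: Mapping[str, pd.DataFrame],
    paired: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise group comparisons of the index and region proportions.

    ``groups`` maps a label to that group's report frame.  For each pair of
    groups and each metric, reports group means and the two-sided t-test.
    Paired mode requires exactly two groups of equal size, compared in row
    order.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ConfigError("need at least two groups to compare")
    if paired and len(labels) != 2:
        raise ConfigError("paired comparison requires exactly two groups")
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            fa, fb = groups[la], groups[lb]
            for metric in COMPARE_METRICS:
                a = fa[metric].dropna().to_numpy()
                b = fb[metric].dropna().to_numpy()
                if paired:
                    a = fa[metric].to_numpy()
                    b = fb[metric].to_numpy()
                out = msi_stats.group_compare(a, b, paired=paired, welch=welch)
                rows.append(
                    {
                        "group_a": la,
                        "group_b": lb,
                        "metric": metric,
                        "n_a": len(a),
                        "n_b": len(b),
                        "mean_a": float(pd.Series(a).mean()),
                        "mean_b": float(pd.Series(b).mean()),
                        "t": out.statistic,
                        "p": out.pvalue,
                        "degenerate": out.degenerate,
                    }
                )
    return pd.DataFrame(rows)


def plot_index_strips(groups: Mapping[str, pd.DataFrame], path) -> None:
    """Strip chart of per-sample PI/PD indices by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(groups), 4))
    for x, (label, frame) in enumerate(groups.items()):
        vals = frame["index"].dropna()
        ax.plot([x] * len(vals), vals, "o", alpha=0.6, label=label)
    ax.axhline(DEFAULT_THRESHOLD, color="grey", linestyle="--", linewidth=1)
    ax.set_xticks(range(len(groups)), list(groups))
    ax.set_ylabel("PI/PD index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
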