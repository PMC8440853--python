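"""End-to-end orchestration: QC -> ROH -> inbreeding -> islands -> LD.

`run_pipeline` composes the analysis stages on a genotype matrix (or
PLINK files), writes every stage output as TSV under an output prefix
together with a JSON manifest of all parameters and input hashes, and
returns an in-memory :class:`SummaryReport`.  Reruns with identical
inputs and configuration reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import GenotypeMatrix
from .inbreeding import inbreeding_table, l_auto, pearson_correlations
from .islands import annotate_islands, island_threshold, merge_islands, snp_incidence
from .ld import (
    LDParams,
    adjacent_ld_summary,
    bin_decay,
    ld_extent,
    pairwise_r2,
    snp_panel_size,
)
from .plink import read_genotypes
from .qc import QCReport, QCThresholds, qc_filter
from .roh import ROHParams, detect_roh, summarize_roh

logger = logging.getLogger("rohscan")

#: Nominal pig genome length used for panel-size estimates (bp).
PIG_GENOME_BP = 2.5e9


@dataclass
class RunConfig:
    """Full-pipeline configuration; one block per stage."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    roh: ROHParams = field(default_factory=ROHParams)
    ld: LDParams = field(default_factory=LDParams)
    island_top_fraction: float = 0.01
    min_island_snps: int = 2
    ld_bin_kb: float = 100.0
    genome_bp: float = PIG_GENOME_BP
    features_path: str | None = None
    run_ld: bool = True

    def to_dict(self) -> dict:
        return {
            "qc": dataclasses.asdict(self.qc),
            "roh": dataclasses.asdict(self.roh),
            "ld": dataclasses.asdict(self.ld),
            "island_top_fraction": self.island_top_fraction,
            "min_island_snps": self.min_island_snps,
            "ld_bin_kb": self.ld_bin_kb,
            "genome_bp": self.genome_bp,
            "features_path": self.features_path,
            "run_ld": self.run_ld,
        }


@dataclass
class SummaryReport:
    """Aggregated results of a pipeline run."""

    qc_report: QCReport
    table1: pd.DataFrame
    per_chromosome: pd.DataFrame
    inbreeding: pd.DataFrame
    inbreeding_summary: pd.DataFrame
    correlations: pd.DataFrame
    islands: pd.DataFrame
    island_threshold: float
    ld_bins: pd.DataFrame
    ld_summary: dict
    segments: pd.DataFrame
    l_auto_bp: int


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def render_table1(per_class: pd.DataFrame) -> pd.DataFrame:
    """Length-class summary table with a cross-footed Total row.

    Input: per-class ``n_segments`` and ``mean_length_mb`` (as produced
    by :func:`rohscan.roh.summarize_roh`).  Percent is the class share of
    the segment count; genome coverage is the class share of total ROH
    length; the Total row's mean length is the count-weighted mean of
    the class means.  Values are rounded to 2 decimals.
    """
    counts = per_class["n_segments"].to_numpy(dtype=float)
    means = per_class["mean_length_mb"].to_numpy(dtype=float)
    totals = np.where(counts > 0, counts * means, 0.0)
    grand_n = counts.sum()
    grand_len = totals.sum()
    rows = []
    for cls, n, mean, tot in zip(per_class["length_class"], counts, means, totals):
        rows.append(
            (
                cls,
                int(n),
                round(100.0 * n / grand_n, 2) if grand_n else 0.0,
                round(mean, 2) if n else float("nan"),
                round(100.0 * tot / grand_len, 2) if grand_len else 0.0,
            )
        )
    rows.append(
        (
            "Total (>1)",
            int(grand_n),
            100.0 if grand_n else 0.0,
            round(grand_len / grand_n, 2) if grand_n else float("nan"),
            100.0 if grand_len else 0.0,
        )
    )
    return pd.DataFrame(
        rows,
        columns=[
            "roh_length_mb",
            "roh_number",
            "percent",
            "mean_length_mb",
            "genome_coverage_pct",
        ],
    )


def render_table2(islands: pd.DataFrame) -> pd.DataFrame:
    """Island table in CHR / Start / End / Length / SNPs / Genes layout."""
    out = pd.DataFrame(
        {
            "CHR": islands["chrom"],
            "Start (bp)": islands["start_bp"],
            "End (bp)": islands["end_bp"],
            "Length (bp)": islands["length_bp"],
            "SNPs": islands["n_snps"],
            "Genes": islands["n_features"] if "n_features" in islands else "",
        }
    )
    return out


def run_pipeline(
    gm_or_prefix,
    cfg: RunConfig = RunConfig(),
    out_prefix: str | None = None,
    input_paths: list[str] | None = None,
) -> SummaryReport:
    """Run QC, ROH detection, inbreeding, islands and LD in order.

    ``gm_or_prefix`` is a :class:`GenotypeMatrix` or a PLINK file prefix.
    With ``out_prefix`` set, every stage output is written as TSV plus a
    ``<prefix>.manifest.json`` capturing parameters, input hashes and the
    package version.  A stage failure raises :class:`PipelineError`
    naming the stage.
    """
    stage = "input"
    try:
        if isinstance(gm_or_prefix, GenotypeMatrix):
            gm = gm_or_prefix
        else:
            input_paths = input_paths or []
            gm = read_genotypes(gm_or_prefix)
        logger.info("input: %d samples x %d SNPs", gm.n_samples, gm.n_snps)

        stage = "qc"
        gm_qc, qc_report = qc_filter(gm, cfg.qc)
        logger.info(
            "qc: retained %d samples x %d SNPs",
            qc_report.n_samples_retained,
            qc_report.n_snps_retained,
        )
        if gm_qc.n_samples == 0 or gm_qc.n_snps == 0:
            raise PipelineError("stage 'qc': no samples or SNPs survive QC")

        stage = "roh"
        segments = detect_roh(gm_qc, cfg.roh)
        summary = summarize_roh(segments, gm_qc)
        table1 = render_table1(summary.per_class)

        stage = "inbreeding"
        span = l_auto(gm_qc)
        ftable = inbreeding_table(gm_qc, segments, l_auto_bp=span)
        fsummary = ftable.agg(["mean", "min", "max"]).T.reset_index(names="coefficient")
        corr = pearson_correlations(ftable) if len(ftable) >= 3 else pd.DataFrame()

        stage = "islands"
        incidence = snp_incidence(segments, gm_qc.variants, gm_qc.n_samples)
        thr = island_threshold(incidence, cfg.island_top_fraction)
        islands = merge_islands(incidence, thr, cfg.min_island_snps)
        if cfg.features_path:
            from .islands import read_features_bed, read_features_gff3

            if str(cfg.features_path).endswith((".gff", ".gff3")):
                feats = read_features_gff3(cfg.features_path)
            else:
                feats = read_features_bed(cfg.features_path)
            islands = annotate_islands(islands, feats)

        stage = "ld"
        if cfg.run_ld:
            pairs = pairwise_r2(gm_qc, cfg.ld)
            bins = bin_decay(pairs, cfg.ld_bin_kb)
            adj = adjacent_ld_summary(pairs, within_kb=cfg.ld_bin_kb)
            anchor = adj["consecutive_mean_r2"]
            ld_summary = {
                **adj,
                "extent_kb_at_0.3": ld_extent(bins, 0.3, anchor_r2=anchor),
                "extent_kb_at_0.2": ld_extent(bins, 0.2, anchor_r2=anchor),
            }
            for thr_r2 in (0.3, 0.2):
                ext = ld_summary[f"extent_kb_at_{thr_r2}"]
                ld_summary[f"panel_size_at_{thr_r2}"] = (
                    snp_panel_size(cfg.genome_bp, ext * 1000.0) if ext else None
                )
        else:
            pairs = pd.DataFrame()
            bins = pd.DataFrame()
            ld_summary = {}

        report = SummaryReport(
            qc_report=qc_report,
            table1=table1,
            per_chromosome=summary.per_chromosome,
            inbreeding=ftable,
            inbreeding_summary=fsummary,
            correlations=corr,
            islands=islands,
            island_threshold=thr,
            ld_bins=bins,
            ld_summary=ld_summary,
            segments=segments,
            l_auto_bp=span,
        )

        if out_prefix:
            stage = "write"
            _write_outputs(report, incidence, cfg, out_prefix, input_paths or [])
        return report
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _write_outputs(
    report: SummaryReport,
    incidence: pd.DataFrame,
    cfg: RunConfig,
    prefix: str,
    input_paths: list[str],
) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(str(prefix))), exist_ok=True)
    report.qc_report.to_frame().to_csv(f"{prefix}.qc_report.tsv", sep="\t", index=False)
    report.segments.to_csv(f"{prefix}.roh_segments.tsv", sep="\t", index=False)
    report.table1.to_csv(f"{prefix}.table1.tsv", sep="\t", index=False)
    report.per_chromosome.to_csv(f"{prefix}.per_chromosome.tsv", sep="\t", index=False)
    report.inbreeding.rename_axis("sample_id").to_csv(
        f"{prefix}.inbreeding.tsv", sep="\t"
    )
    if len(report.correlations):
        report.correlations.to_csv(f"{prefix}.inbreeding_correlations.tsv", sep="\t")
    incidence.to_csv(f"{prefix}.snp_incidence.tsv", sep="\t", index=False)
    report.islands.to_csv(f"{prefix}.islands.tsv", sep="\t", index=False)
    render_table2(report.islands).to_csv(f"{prefix}.table2.tsv", sep="\t", index=False)
    if len(report.ld_bins):
        report.ld_bins.to_csv(f"{prefix}.ld_decay.tsv", sep="\t", index=False)
    manifest = {
        "package": "rohscan",
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": {p: _sha256(p) for p in input_paths if os.path.exists(p)},
        "l_auto_bp": report.l_auto_bp,
        "island_threshold": report.island_threshold,
        "ld_summary": report.ld_summary,
    }
    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
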