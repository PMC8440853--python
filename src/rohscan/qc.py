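"""Quality control of SNP-array genotypes.

Filters follow the conventional array-QC order: restrict to autosomes,
drop low-call-rate samples, then drop SNPs by call rate (recomputed on the
retained samples) and by minor allele frequency.  The MAF filter is a
strict lower bound (maf == threshold is removed); the call-rate filters
are inclusive (rate == threshold is retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, PIG_AUTOSOMES, GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for :func:`qc_filter`.

    ``min_snp_call_rate`` / ``min_sample_call_rate`` are inclusive lower
    bounds; ``min_maf`` is a strict lower bound (SNPs with maf equal to it
    are removed).  ``autosomes`` lists the chromosome labels retained when
    ``autosomes_only`` is set (default: pig autosomes 1..18).
    """

    min_snp_call_rate: float = 0.9
    min_sample_call_rate: float = 0.9
    min_maf: float = 0.01
    autosomes_only: bool = True
    autosomes: tuple[str, ...] = PIG_AUTOSOMES

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_sample_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Counts of removed/retained samples and SNPs, in filter order."""

    n_samples_in: int = 0
    n_snps_in: int = 0
    n_snps_removed_nonautosomal: int = 0
    n_samples_removed_callrate: int = 0
    n_snps_removed_callrate: int = 0
    n_snps_removed_maf: int = 0
    n_samples_retained: int = 0
    n_snps_retained: int = 0
    filter_order: tuple[str, ...] = (
        "autosomes",
        "sample_call_rate",
        "snp_call_rate",
        "maf",
    )
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def reconcile(self) -> bool:
        """Input dimensions must equal retained + removed counts."""
        ok_snps = (
            self.n_snps_in
            == self.n_snps_removed_nonautosomal
            + self.n_snps_removed_callrate
            + self.n_snps_removed_maf
            + self.n_snps_retained
        )
        ok_samples = (
            self.n_samples_in
            == self.n_samples_removed_callrate + self.n_samples_retained
        )
        return ok_snps and ok_samples

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("snps_in", self.n_snps_in),
            ("snps_removed_nonautosomal", self.n_snps_removed_nonautosomal),
            ("samples_removed_callrate", self.n_samples_removed_callrate),
            ("snps_removed_callrate", self.n_snps_removed_callrate),
            ("snps_removed_maf", self.n_snps_removed_maf),
            ("samples_retained", self.n_samples_retained),
            ("snps_retained", self.n_snps_retained),
        ]
        return pd.DataFrame(rows, columns=["metric", "count"])


def allele_frequencies(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant allele-B frequency, MAF and call rate.

    Returns a DataFrame aligned with ``gm.variants`` with columns
    ``freq_b``, ``maf``, ``call_rate``.  SNPs with no non-missing
    genotypes get ``freq_b = maf = NaN`` and ``call_rate = 0``.
    """
    d = gm.dosage
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(obs, d, 0).sum(axis=0) / np.where(n_obs > 0, 2 * n_obs, 1)
    freq_b = np.where(n_obs > 0, freq_b, np.nan)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    call_rate = n_obs / gm.n_samples if gm.n_samples else np.zeros(gm.n_snps)
    return pd.DataFrame(
        {"freq_b": freq_b, "maf": maf, "call_rate": call_rate},
        index=gm.variants.index,
    )


def heterozygosity(gm: GenotypeMatrix) -> tuple[float, float]:
    """Mean observed (Ho) and expected (He) heterozygosity over SNPs.

    Ho per SNP is the heterozygote fraction among non-missing genotypes;
    He per SNP is 2p(1-p) with p the observed allele-B frequency
    (no small-sample correction).  SNPs with all genotypes missing are
    excluded from both averages.
    """
    d = gm.dosage
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    keep = n_obs > 0
    if not keep.any():
        return float("nan"), float("nan")
    het = (d == 1).sum(axis=0)
    ho = het[keep] / n_obs[keep]
    p = np.where(obs, d, 0).sum(axis=0)[keep] / (2 * n_obs[keep])
    he = 2.0 * p * (1.0 - p)
    return float(ho.mean()), float(he.mean())


def qc_filter(
    gm: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply autosome, call-rate and MAF filters; return (matrix, report).

    Filter order: non-autosomal SNPs -> samples by call rate -> SNPs by
    call rate (recomputed on retained samples) -> SNPs by MAF (strict
    lower bound).  A run that leaves zero samples or SNPs returns the
    empty matrix with a warning rather than raising.
    """
    rep = QCReport(
        n_samples_in=gm.n_samples, n_snps_in=gm.n_snps, thresholds=thresholds
    )

    cur = gm
    if thresholds.autosomes_only:
        keep = cur.variants["chrom"].isin(thresholds.autosomes).to_numpy()
        rep.n_snps_removed_nonautosomal = int((~keep).sum())
        cur = cur.subset(snp_idx=np.flatnonzero(keep))

    if cur.n_snps > 0:
        sample_cr = (cur.dosage != MISSING).mean(axis=1)
    else:
        sample_cr = np.zeros(cur.n_samples)
    keep_s = sample_cr >= thresholds.min_sample_call_rate
    rep.n_samples_removed_callrate = int((~keep_s).sum())
    cur = cur.subset(sample_idx=np.flatnonzero(keep_s))

    freqs = allele_frequencies(cur)
    keep_cr = freqs["call_rate"].to_numpy() >= thresholds.min_snp_call_rate
    rep.n_snps_removed_callrate = int((~keep_cr).sum())
    cur = cur.subset(snp_idx=np.flatnonzero(keep_cr))

    freqs = allele_frequencies(cur)
    maf = freqs["maf"].to_numpy()
    keep_maf = np.nan_to_num(maf, nan=-1.0) > thresholds.min_maf
    rep.n_snps_removed_maf = int((~keep_maf).sum())
    cur = cur.subset(snp_idx=np.flatnonzero(keep_maf))

    rep.n_samples_retained = cur.n_samples
    rep.n_snps_retained = cur.n_snps
    if cur.n_samples == 0 or cur.n_snps == 0:
        warnings.warn(
            "QC removed all samples or all SNPs; downstream results are empty",
            stacklevel=2,
        )
    return cur, rep
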