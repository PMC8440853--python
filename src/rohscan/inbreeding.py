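"""Genomic inbreeding coefficients from ROH and from homozygosity excess.

F_ROH for an individual is the summed length of its ROH segments divided
by L_auto, the autosomal length covered by the retained markers (sum over
chromosomes of last-minus-first SNP position + 1).  It is computed per
length class (1-5, 5-10, >10 Mb) and in total, with the same denominator,
so the class coefficients add up to the total exactly.

F_HOM is the method-of-moments excess-homozygosity estimator
(O - E) / (L - E): O observed homozygous genotypes, E expected under
Hardy-Weinberg from the sample allele frequencies with the 2N/(2N-1)
small-sample correction, L the individual's genotyped autosomal SNP
count.  Negative values indicate more heterozygosity than expected -
common in admixed or composite populations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .roh import LENGTH_CLASSES

F_COLUMNS = ["f_roh_1_5", "f_roh_5_10", "f_roh_gt10", "f_roh_total", "f_hom"]
_CLASS_TO_COLUMN = {"1-5": "f_roh_1_5", "5-10": "f_roh_5_10", ">10": "f_roh_gt10"}


def l_auto(gm: GenotypeMatrix) -> int:
    """Total bp covered by the retained SNPs: sum of per-chromosome spans.

    Each chromosome contributes (last SNP bp - first SNP bp + 1).  A
    chromosome holding a single SNP degenerately contributes 1 bp and
    triggers a warning.
    """
    total = 0
    v = gm.variants
    for chrom in gm.chromosomes():
        pos = v.loc[v["chrom"] == chrom, "pos_bp"]
        if len(pos) == 1:
            warnings.warn(
                f"chromosome {chrom} has a single SNP; contributes 1 bp to L_auto",
                stacklevel=2,
            )
        total += int(pos.max()) - int(pos.min()) + 1
    if total <= 0:
        raise ValueError("L_auto must be positive; no SNPs in matrix")
    return total


def f_roh(
    segments: pd.DataFrame, l_auto_bp: int, class_filter: str = "total"
) -> float:
    """Sum of segment lengths in a class divided by L_auto.

    ``class_filter`` is one of ``"1-5"``, ``"5-10"``, ``">10"`` or
    ``"total"``.  An empty segment table yields 0.0.
    """
    if class_filter != "total" and class_filter not in LENGTH_CLASSES:
        raise ValueError(f"unknown class filter {class_filter!r}")
    if len(segments) == 0:
        return 0.0
    sub = (
        segments
        if class_filter == "total"
        else segments[segments["length_class"] == class_filter]
    )
    return float(sub["length_bp"].sum()) / l_auto_bp


def f_hom(gm: GenotypeMatrix, per_sample_support: bool = True) -> pd.Series:
    """Excess-homozygosity inbreeding coefficient per sample.

    For each sample, over its non-missing SNPs (or over all SNPs when
    ``per_sample_support`` is False): O = observed homozygote count,
    E = sum over SNPs of 1 - 2 p q * 2N/(2N-1) with p the sample-based
    allele frequency and N the non-missing count at the SNP, L = SNP
    count on the same support.  Returns (O - E) / (L - E); NaN where
    L == E (degenerate, e.g. monomorphic-only support).
    """
    d = gm.dosage
    obs = d != MISSING
    n_obs = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)
    # expected homozygous probability per SNP, small-sample corrected
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_hom = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n_obs / (2.0 * n_obs - 1.0))
    exp_hom = np.where(n_obs > 0, exp_hom, np.nan)

    values = np.full(gm.n_samples, np.nan)
    hom = (d == 0) | (d == 2)
    for i in range(gm.n_samples):
        support = obs[i] if per_sample_support else np.ones(gm.n_snps, dtype=bool)
        support = support & ~np.isnan(exp_hom)
        L = int(support.sum())
        if L == 0:
            continue
        O = int((hom[i] & support).sum())
        E = float(exp_hom[support].sum())
        if np.isclose(L, E):
            continue  # undefined; leave NaN
        values[i] = (O - E) / (L - E)
    return pd.Series(values, index=gm.samples, name="f_hom")


def inbreeding_table(
    gm: GenotypeMatrix,
    segments: pd.DataFrame,
    l_auto_bp: int | None = None,
    per_sample_support: bool = True,
) -> pd.DataFrame:
    """Per-sample F_ROH by length class, total F_ROH, and F_HOM.

    ``l_auto_bp`` overrides the SNP-span denominator (e.g. to use a
    nominal chip genome length for cross-study comparability).
    """
    unknown = set(segments["sample_id"]) - set(gm.samples)
    if unknown:
        raise ValueError(f"segments reference samples absent from matrix: {sorted(unknown)[:5]}")
    denom = l_auto(gm) if l_auto_bp is None else int(l_auto_bp)

    by_class = (
        segments.groupby(["sample_id", "length_class"])["length_bp"].sum()
        if len(segments)
        else pd.Series(dtype=float)
    )
    table = pd.DataFrame(0.0, index=pd.Index(gm.samples, name="sample_id"),
                         columns=F_COLUMNS)
    for (sid, cls), bp in by_class.items():
        table.loc[sid, _CLASS_TO_COLUMN[cls]] = bp / denom
    table["f_roh_total"] = (
        table["f_roh_1_5"] + table["f_roh_5_10"] + table["f_roh_gt10"]
    )
    table["f_hom"] = f_hom(gm, per_sample_support=per_sample_support).to_numpy()
    return table


def pearson_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the five inbreeding coefficients.

    Pairwise-complete over samples with defined values; entries involving
    a constant column are NaN (undefined) rather than propagating into
    other cells.  Diagonal is 1 for non-constant columns.
    """
    cols = [c for c in F_COLUMNS if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 samples for correlations")
    corr = table[cols].corr(method="pearson", min_periods=3)
    for c in cols:
        col = table[c].dropna()
        if len(col) and col.nunique() > 1:
            corr.loc[c, c] = 1.0
    return corr
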