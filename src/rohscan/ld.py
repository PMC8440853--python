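"""Linkage-disequilibrium decay from genotype dosages.

r^2 between two SNPs is the squared Pearson correlation of their dosage
vectors over the samples non-missing at both (the composite, genotype-
level LD estimator; no phasing).  Pairs are restricted to the same
chromosome, to a maximum SNP-index separation and to a maximum physical
distance, mirroring the conventional whole-chromosome window settings of
array LD surveys.  Pair r^2 values are averaged within 100-kb distance
bins to summarise decay, and the distance at which mean r^2 crosses a
reference level (e.g. 0.3) is read off by linear interpolation between
bin midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class LDParams:
    """Pairing limits for :func:`pairwise_r2`.

    max_pair_snps: maximum index separation between paired SNPs.
    max_pair_kb: maximum physical separation (kb).
    min_r2_report: pairs below this r^2 are dropped from the output.
    """

    max_pair_snps: int = 99_999
    max_pair_kb: float = 1_000.0
    min_r2_report: float = 0.0

    def __post_init__(self) -> None:
        if self.max_pair_snps < 1 or self.max_pair_kb <= 0:
            raise ValueError("pair limits must be positive")
        if not 0.0 <= self.min_r2_report <= 1.0:
            raise ValueError("min_r2_report must be in [0, 1]")


def pairwise_r2(gm: GenotypeMatrix, params: LDParams = LDParams()) -> pd.DataFrame:
    """All within-chromosome SNP-pair r^2 values under the pairing limits.

    Returns a DataFrame (chrom, id_a, id_b, dist_bp, r2).  Pairs with a
    monomorphic SNP on the common non-missing support, or fewer than two
    common non-missing samples, are skipped.
    """
    if not gm.is_sorted():
        gm = gm.sort_variants()
    frames = []
    ids = gm.variants["id"].to_numpy()
    pos = gm.variants["pos_bp"].to_numpy()
    max_dist = params.max_pair_kb * 1000.0
    for chrom, sl in gm.chrom_slices().items():
        d = gm.dosage[:, sl].astype(np.float64)
        valid = gm.dosage[:, sl] != MISSING
        d[~valid] = 0.0
        v = valid.astype(np.float64)
        cpos = pos[sl]
        cids = ids[sl]
        m = d.shape[1]
        for k in range(1, min(params.max_pair_snps, m - 1) + 1):
            dist = cpos[k:] - cpos[:-k]
            if dist.min() > max_dist:
                break
            A, B = d[:, :-k], d[:, k:]
            VA, VB = v[:, :-k], v[:, k:]
            V = VA * VB
            n = V.sum(axis=0)
            sx = (A * V).sum(axis=0)
            sy = (B * V).sum(axis=0)
            sxx = (A * A * V).sum(axis=0)
            syy = (B * B * V).sum(axis=0)
            sxy = (A * B * V).sum(axis=0)
            cov = n * sxy - sx * sy
            varx = n * sxx - sx * sx
            vary = n * syy - sy * sy
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = (cov * cov) / (varx * vary)
            keep = (
                (dist <= max_dist)
                & (n >= 2)
                & (varx > 0)
                & (vary > 0)
                & (r2 >= params.min_r2_report)
            )
            if keep.any():
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "id_a": cids[:-k][keep],
                            "id_b": cids[k:][keep],
                            "idx_sep": k,
                            "dist_bp": dist[keep].astype(np.int64),
                            "r2": np.clip(r2[keep], 0.0, 1.0),
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "id_a", "id_b", "idx_sep", "dist_bp", "r2"]
        )
    return pd.concat(frames, ignore_index=True)


def bin_decay(pairs: pd.DataFrame, bin_kb: float = 100.0) -> pd.DataFrame:
    """Mean r^2 in contiguous half-open distance bins of width ``bin_kb``.

    A pair at distance d falls in bin ``floor(d / bin_bp)``; bins run
    from zero to the furthest occupied bin, with empty bins reported
    with ``n_pairs = 0`` and NaN mean.
    """
    bin_bp = bin_kb * 1000.0
    if len(pairs) == 0:
        return pd.DataFrame(columns=["dist_lo_kb", "dist_hi_kb", "mean_r2", "n_pairs"])
    which = np.floor(pairs["dist_bp"].to_numpy() / bin_bp).astype(int)
    n_bins = which.max() + 1
    sums = np.bincount(which, weights=pairs["r2"].to_numpy(), minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    lo = np.arange(n_bins) * bin_kb
    return pd.DataFrame(
        {
            "dist_lo_kb": lo,
            "dist_hi_kb": lo + bin_kb,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )


def ld_extent(
    bins: pd.DataFrame, r2_threshold: float, anchor_r2: float | None = None
) -> float | None:
    """Distance (kb) at which binned mean r^2 decays to ``r2_threshold``.

    Linear interpolation between the midpoints of the last bin at or
    above the threshold and the first below it.  When even the first bin
    is below the threshold, an anchor point at distance zero with value
    ``anchor_r2`` (e.g. the mean r^2 of consecutive-SNP pairs) is used to
    interpolate within (0, first midpoint]; without a usable anchor, or
    when the threshold is never crossed downward, returns None.
    """
    occupied = bins[bins["n_pairs"] > 0]
    if len(occupied) == 0:
        return None
    mids = ((occupied["dist_lo_kb"] + occupied["dist_hi_kb"]) / 2.0).to_numpy()
    means = occupied["mean_r2"].to_numpy()

    below = means < r2_threshold
    if below[0]:
        if anchor_r2 is None or anchor_r2 < r2_threshold:
            return None
        # interpolate from (0, anchor_r2) to the first bin midpoint
        frac = (anchor_r2 - r2_threshold) / (anchor_r2 - means[0])
        return float(frac * mids[0])
    i = int(np.argmax(below)) if below.any() else None
    if i is None:
        return None
    v_hi, v_lo = means[i - 1], means[i]
    if v_hi == v_lo:
        return float(mids[i - 1])
    frac = (v_hi - r2_threshold) / (v_hi - v_lo)
    return float(mids[i - 1] + frac * (mids[i] - mids[i - 1]))


def adjacent_ld_summary(pairs: pd.DataFrame, within_kb: float = 100.0) -> dict:
    """Mean +- SD of r^2 for short-range pairs, under both readings of
    "adjacent": strictly consecutive SNPs, and all pairs closer than
    ``within_kb``.

    Returns a dict with ``consecutive_mean/sd/n`` and
    ``within_100kb_mean/sd/n`` style keys.
    """
    out: dict[str, float] = {}
    close = pairs[pairs["dist_bp"] < within_kb * 1000.0]
    cons = close[close["idx_sep"] == 1] if "idx_sep" in close else close.iloc[0:0]
    for label, sub in (("all_pairs", close), ("consecutive", cons)):
        out[f"{label}_mean_r2"] = float(sub["r2"].mean()) if len(sub) else math.nan
        out[f"{label}_sd_r2"] = (
            float(sub["r2"].std(ddof=1)) if len(sub) > 1 else math.nan
        )
        out[f"{label}_n"] = int(len(sub))
    return out


def snp_panel_size(genome_bp: float, spacing_bp: float) -> int:
    """Markers needed to tile a genome at the given spacing: ceil(G / s)."""
    if spacing_bp <= 0 or genome_bp <= 0:
        raise ValueError("genome_bp and spacing_bp must be positive")
    return math.ceil(genome_bp / spacing_bp)
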