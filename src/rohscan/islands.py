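"""ROH islands: regions where an unusually high share of individuals are
homozygous.

Per-SNP ROH incidence is the number of individuals having a ROH segment
spanning the SNP position, divided by the number of individuals.  The
top percentile (default 1%) of SNPs by incidence defines a threshold;
maximal runs of adjacent qualifying SNPs are merged into island regions,
reported with 1-based inclusive coordinates.  Islands can be annotated
against user-supplied gene/feature intervals by simple 1-bp overlap.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

ISLAND_COLUMNS = ["chrom", "start_bp", "end_bp", "length_bp", "n_snps", "peak_fraction"]


def snp_incidence(
    segments: pd.DataFrame, variants: pd.DataFrame, n_individuals: int
) -> pd.DataFrame:
    """Per-SNP count and fraction of individuals whose ROH covers it.

    A SNP is "in ROH" for an individual iff ``start_bp <= pos <= end_bp``
    of any of that individual's segments; overlapping segments of one
    individual (not produced by the detector, but guarded against) count
    once.  Returns ``variants`` columns plus ``n_in_roh`` and
    ``fraction``.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    counts = np.zeros(len(variants), dtype=np.int64)
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos_bp"].to_numpy()
    # per chromosome, sorted position array for searchsorted
    for chrom, seg_chrom in segments.groupby("chrom"):
        mask = chroms == str(chrom)
        if not mask.any():
            continue
        cpos = pos[mask]
        cidx = np.flatnonzero(mask)
        delta = np.zeros(len(cpos) + 1, dtype=np.int64)
        for _, per_ind in seg_chrom.groupby("sample_id"):
            iv = _merge_intervals(per_ind[["start_bp", "end_bp"]].to_numpy())
            lo = np.searchsorted(cpos, iv[:, 0], side="left")
            hi = np.searchsorted(cpos, iv[:, 1], side="right")
            np.add.at(delta, lo, 1)
            np.add.at(delta, hi, -1)
        counts[cidx] += np.cumsum(delta[:-1])
    out = variants[["chrom", "id", "pos_bp"]].copy()
    out["n_in_roh"] = counts
    out["fraction"] = counts / n_individuals
    return out


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/touching 1-based inclusive intervals."""
    if len(iv) <= 1:
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged)


def island_threshold(incidence: pd.DataFrame, top_fraction: float = 0.01) -> float:
    """Incidence threshold selecting the top fraction of SNPs.

    The threshold is the fraction of the SNP at rank
    ``ceil(top_fraction * n_snps)`` from the top; SNPs at or above it
    qualify, so ties may push the qualifying set slightly past the
    nominal percentile.  With fewer than ``1/top_fraction`` SNPs the
    tail is meaningless: a warning is raised and the maximum incidence
    returned.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    fr = incidence["fraction"].to_numpy()
    n = len(fr)
    if n == 0:
        raise ValueError("empty incidence table")
    if n < 1.0 / top_fraction:
        warnings.warn(
            f"only {n} SNPs; top-{top_fraction:.0%} tail is degenerate, "
            "using the maximum incidence as threshold",
            stacklevel=2,
        )
        return float(fr.max())
    k = math.ceil(top_fraction * n)
    return float(np.sort(fr)[::-1][k - 1])


def merge_islands(
    incidence: pd.DataFrame,
    threshold: float,
    min_island_snps: int = 2,
    max_gap_bp: int | None = None,
) -> pd.DataFrame:
    """Merge adjacent qualifying SNPs (fraction >= threshold) into islands.

    Adjacent means consecutive in map order on the same chromosome with
    no intervening non-qualifying SNP; ``max_gap_bp``, when set, also
    splits runs at larger physical gaps.  Runs with fewer than
    ``min_island_snps`` SNPs are dropped.  Island coordinates are the
    first/last qualifying SNP positions (inclusive).
    """
    rows = []
    qual = incidence["fraction"].to_numpy() >= threshold
    chroms = incidence["chrom"].to_numpy()
    pos = incidence["pos_bp"].to_numpy()
    frac = incidence["fraction"].to_numpy()
    idx = np.flatnonzero(qual)
    if idx.size:
        same_chrom = chroms[idx[1:]] == chroms[idx[:-1]]
        adjacent = np.diff(idx) == 1
        ok = same_chrom & adjacent
        if max_gap_bp is not None:
            ok &= np.diff(pos[idx]) <= max_gap_bp
        breaks = np.flatnonzero(~ok)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s, e in zip(starts, ends):
            run = idx[s : e + 1]
            if len(run) < min_island_snps:
                continue
            start_bp, end_bp = int(pos[run[0]]), int(pos[run[-1]])
            rows.append(
                (
                    chroms[run[0]],
                    start_bp,
                    end_bp,
                    end_bp - start_bp + 1,
                    len(run),
                    float(frac[run].max()),
                )
            )
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def read_features_bed(path) -> pd.DataFrame:
    """Read a BED file of features into 1-based inclusive intervals.

    BED is 0-based half-open; start is shifted by +1.  Only the first
    four columns (chrom, start, end, optional name) are used.
    """
    try:
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "name"])
    out = pd.DataFrame(
        {
            "chrom": bed[0].astype(str),
            "start_bp": bed[1].astype(np.int64) + 1,
            "end_bp": bed[2].astype(np.int64),
            "name": bed[3].astype(str) if bed.shape[1] > 3 else "",
        }
    )
    return out


def read_features_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Read feature intervals (1-based inclusive) from a GFF3 file."""
    try:
        gff = pd.read_csv(path, sep="\t", header=None, comment="#",
                          names=["seqid", "source", "type", "start", "end",
                                 "score", "strand", "phase", "attributes"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "name"])
    if feature_types:
        gff = gff[gff["type"].isin(feature_types)]
    names = gff["attributes"].str.extract(r"Name=([^;]+)", expand=False)
    names = names.fillna(gff["attributes"].str.extract(r"ID=([^;]+)", expand=False))
    return pd.DataFrame(
        {
            "chrom": gff["seqid"].astype(str),
            "start_bp": gff["start"].astype(np.int64),
            "end_bp": gff["end"].astype(np.int64),
            "name": names.fillna(""),
        }
    ).reset_index(drop=True)


def annotate_islands(islands: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Count and list features overlapping each island by >= 1 bp.

    ``features`` must carry 1-based inclusive ``chrom/start_bp/end_bp``
    (see the BED/GFF3 readers).  Features on chromosome labels absent
    from the island table are skipped with a warning.  Returns the
    island table plus ``n_features`` and ``feature_names`` columns.
    """
    out = islands.copy()
    known = set(out["chrom"].astype(str))
    unknown = set(features["chrom"].astype(str)) - known
    if unknown and len(out):
        warnings.warn(
            f"features on chromosomes absent from islands skipped: {sorted(unknown)}",
            stacklevel=2,
        )
    n_feat, names = [], []
    for _, isl in out.iterrows():
        f = features[
            (features["chrom"].astype(str) == str(isl["chrom"]))
            & (features["start_bp"] <= isl["end_bp"])
            & (features["end_bp"] >= isl["start_bp"])
        ]
        n_feat.append(len(f))
        names.append(",".join(str(x) for x in f["name"] if str(x)))
    out["n_features"] = n_feat
    out["feature_names"] = names
    return out
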