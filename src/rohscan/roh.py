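"""Sliding-window detection of runs of homozygosity (ROH).

The detector follows the incremental scanning heuristic popularised by
PLINK's ``--homozyg``: a fixed-size window of consecutive SNPs slides one
SNP at a time along each chromosome and is judged "homozygous" when it
contains at most a small number of heterozygous and missing calls.  Each
SNP is then scored by the fraction of the windows overlapping it that were
homozygous, SNPs whose fraction reaches a threshold are flagged, and
maximal runs of flagged SNPs that satisfy length, SNP-count, density and
gap constraints are reported as ROH segments.

Defaults mirror common 50K-array practice: 50-SNP windows allowing one
heterozygote and five missing calls, a 5% window-hit threshold, minimum
segment length 1 Mb with at least 50 SNPs, at most 100 kb per SNP on
average and no gap above 1 Mb between consecutive SNPs in a segment.
Segment coordinates are 1-based and inclusive; ``length_bp`` is
``end_bp - start_bp + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, chrom_sort_key

#: Length classes (Mb) used to partition segments; left-closed bins.
LENGTH_CLASSES = ("1-5", "5-10", ">10")
_CLASS_EDGES_BP = (1_000_000, 5_000_000, 10_000_000)

SEGMENT_COLUMNS = [
    "sample_id",
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_bp",
    "length_class",
]


@dataclass(frozen=True)
class ROHParams:
    """Parameters of the sliding-window ROH scan.

    window_snps
        Number of consecutive SNPs per window.
    max_het_per_window / max_missing_per_window
        Heterozygous and missing calls tolerated in a homozygous window.
    window_hit_threshold
        Minimum fraction of a SNP's overlapping windows that must be
        homozygous for the SNP to be flagged as "in ROH".
    min_length_bp / min_snps
        Minimum inclusive segment length and SNP count.
    max_density_kb_per_snp
        Maximum average marker spacing inside a segment (kb per SNP).
    max_gap_kb
        Maximum gap (kb) between consecutive SNPs within one segment;
        larger gaps split the candidate run.
    """

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    window_hit_threshold: float = 0.05
    min_length_bp: int = 1_000_000
    min_snps: int = 50
    max_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 1_000.0

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps < 1 or self.min_length_bp < 1:
            raise ValueError("window_snps, min_snps and min_length_bp must be >= 1")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if self.max_het_per_window < 0 or self.max_missing_per_window < 0:
            raise ValueError("per-window allowances must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one individual (1-based inclusive bp)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_class(self) -> str:
        return classify_length(self.length_bp)


def classify_length(length_bp: int) -> str:
    """Length class of a segment: [1,5) -> "1-5", [5,10) -> "5-10", >=10 -> ">10" Mb.

    Raises ``ValueError`` below 1 Mb (segments that short are never emitted).
    """
    if length_bp < _CLASS_EDGES_BP[0]:
        raise ValueError(f"segment length {length_bp} bp is below the 1 Mb minimum")
    if length_bp < _CLASS_EDGES_BP[1]:
        return "1-5"
    if length_bp < _CLASS_EDGES_BP[2]:
        return "5-10"
    return ">10"


def scan_windows(
    dosage_row: np.ndarray, pos_bp: np.ndarray, params: ROHParams = ROHParams()
) -> np.ndarray:
    """Per-SNP window-hit fractions for one individual on one chromosome.

    A window is a run of ``window_snps`` consecutive SNPs; it is
    homozygous iff it contains at most ``max_het_per_window``
    heterozygotes and at most ``max_missing_per_window`` missing calls.
    The hit fraction of SNP *i* is the proportion of windows containing
    *i* that are homozygous.  Chromosomes with fewer SNPs than the window
    size are scanned with a single whole-chromosome window.
    """
    m = len(dosage_row)
    if m == 0:
        return np.zeros(0)
    het = (dosage_row == 1).astype(np.int64)
    mis = (dosage_row == MISSING).astype(np.int64)
    w = params.window_snps
    if m < w:
        ok = het.sum() <= params.max_het_per_window and (
            mis.sum() <= params.max_missing_per_window
        )
        return np.full(m, 1.0 if ok else 0.0)

    csum_het = np.concatenate([[0], np.cumsum(het)])
    csum_mis = np.concatenate([[0], np.cumsum(mis)])
    win_het = csum_het[w:] - csum_het[:-w]
    win_mis = csum_mis[w:] - csum_mis[:-w]
    win_ok = (
        (win_het <= params.max_het_per_window)
        & (win_mis <= params.max_missing_per_window)
    ).astype(np.int64)
    n_windows = m - w + 1

    idx = np.arange(m)
    lo = np.maximum(0, idx - w + 1)  # first window start covering SNP i
    hi = np.minimum(idx, n_windows - 1)  # last window start covering SNP i
    csum_ok = np.concatenate([[0], np.cumsum(win_ok)])
    hits = csum_ok[hi + 1] - csum_ok[lo]
    return hits / (hi - lo + 1)


def _flagged_runs_to_segments(
    flagged: np.ndarray,
    pos_bp: np.ndarray,
    chrom: str,
    sample_id: str,
    params: ROHParams,
) -> list[ROHSegment]:
    """Turn a boolean flag vector into filtered ROH segments."""
    segments: list[ROHSegment] = []
    idx = np.flatnonzero(flagged)
    if idx.size == 0:
        return segments
    # break at non-consecutive flags or gaps above max_gap_kb
    gap_bp = params.max_gap_kb * 1000.0
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos_bp[idx]) > gap_bp)
    )
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        i0, i1 = idx[s], idx[e]
        length = int(pos_bp[i1] - pos_bp[i0] + 1)
        n = int(i1 - i0 + 1)
        if length < params.min_length_bp or n < params.min_snps:
            continue
        if length / 1000.0 > params.max_density_kb_per_snp * n:
            continue
        segments.append(
            ROHSegment(
                sample_id=sample_id,
                chrom=chrom,
                start_bp=int(pos_bp[i0]),
                end_bp=int(pos_bp[i1]),
                n_snps=n,
            )
        )
    return segments


def call_roh_sample(
    dosage_row: np.ndarray,
    variants: pd.DataFrame,
    params: ROHParams = ROHParams(),
    sample_id: str = "sample",
) -> list[ROHSegment]:
    """Detect ROH segments for one individual across all chromosomes.

    ``variants`` must be sorted by (chrom, pos_bp); windows never span
    chromosomes.  SNPs whose window-hit fraction reaches
    ``window_hit_threshold`` are flagged; maximal runs of flagged SNPs,
    split at gaps above ``max_gap_kb``, become segments if they satisfy
    the length, SNP-count and density constraints.  Segment bounds are
    the outermost flagged SNP positions.
    """
    segments: list[ROHSegment] = []
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos_bp"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            sl = slice(start, i)
            frac = scan_windows(dosage_row[sl], pos[sl], params)
            flagged = frac >= params.window_hit_threshold
            segments.extend(
                _flagged_runs_to_segments(
                    flagged, pos[sl], chroms[start], sample_id, params
                )
            )
            start = i
    return segments


def naive_roh_oracle(
    dosage_row: np.ndarray,
    variants: pd.DataFrame,
    params: ROHParams = ROHParams(),
    sample_id: str = "sample",
) -> list[ROHSegment]:
    """Reference ROH caller: direct enumeration, no incremental sums.

    Contract-identical to :func:`call_roh_sample`; kept deliberately
    simple (pure-Python loops over every window position) to serve as an
    independent check of the vectorised scan.
    """
    segments: list[ROHSegment] = []
    chroms = list(variants["chrom"])
    pos = list(variants["pos_bp"])
    geno = list(dosage_row)
    # group indices per chromosome, preserving order
    groups: list[tuple[str, list[int]]] = []
    for i, c in enumerate(chroms):
        if groups and groups[-1][0] == c:
            groups[-1][1].append(i)
        else:
            groups.append((c, [i]))

    for chrom, idxs in groups:
        g = [geno[i] for i in idxs]
        p = [pos[i] for i in idxs]
        m = len(g)
        w = min(params.window_snps, m)
        window_starts = list(range(m - w + 1))
        window_ok = []
        for s in window_starts:
            win = g[s : s + w]
            n_het = sum(1 for x in win if x == 1)
            n_mis = sum(1 for x in win if x == MISSING)
            window_ok.append(
                n_het <= params.max_het_per_window
                and n_mis <= params.max_missing_per_window
            )
        flagged = []
        for i in range(m):
            covering = [s for s in window_starts if s <= i < s + w]
            n_hit = sum(1 for s in covering if window_ok[window_starts.index(s)])
            flagged.append(n_hit / len(covering) >= params.window_hit_threshold)

        # maximal flagged runs, split at large gaps
        run: list[int] = []
        runs: list[list[int]] = []
        for i in range(m):
            if flagged[i]:
                if run and p[i] - p[run[-1]] > params.max_gap_kb * 1000.0:
                    runs.append(run)
                    run = []
                run.append(i)
            else:
                if run:
                    runs.append(run)
                run = []
        if run:
            runs.append(run)
        for r in runs:
            length = p[r[-1]] - p[r[0]] + 1
            n = len(r)
            if length < params.min_length_bp or n < params.min_snps:
                continue
            if length / 1000.0 > params.max_density_kb_per_snp * n:
                continue
            segments.append(
                ROHSegment(sample_id, chrom, int(p[r[0]]), int(p[r[-1]]), n)
            )
    return segments


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Tabulate segments with derived length and class columns."""
    rows = [
        (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_bp,
         s.length_class)
        for s in segments
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def detect_roh(gm: GenotypeMatrix, params: ROHParams = ROHParams()) -> pd.DataFrame:
    """Detect ROH for every sample; returns the segment table.

    Rows are ordered by (sample, chrom, start_bp).  ``gm`` should be
    post-QC and sorted by (chrom, pos_bp).
    """
    if not gm.is_sorted():
        gm = gm.sort_variants()
    segments: list[ROHSegment] = []
    for i, sid in enumerate(gm.samples):
        segments.extend(call_roh_sample(gm.dosage[i], gm.variants, params, sid))
    df = segments_to_frame(segments)
    if len(df):
        df = df.sort_values(
            ["sample_id", "chrom", "start_bp"],
            key=lambda col: col.map(chrom_sort_key) if col.name == "chrom" else col,
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def classify_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """(Re)assign the ``length_class`` column from ``length_bp``."""
    out = segments.copy()
    out["length_class"] = [classify_length(x) for x in out["length_bp"]]
    return out


@dataclass
class ROHSummary:
    """Per-class, per-individual and per-chromosome ROH summaries."""

    per_class: pd.DataFrame  # class, n_segments, percent, mean_length_mb, share
    per_individual: pd.DataFrame  # sample_id, n_segments, total_length_bp
    per_chromosome: pd.DataFrame  # chrom, n_segments, coverage_fraction


def summarize_roh(segments: pd.DataFrame, gm: GenotypeMatrix) -> ROHSummary:
    """Summaries of a segment table against the genotyped map.

    Per class: count, percent of all segments, mean length (Mb) and share
    of total ROH length.  Per individual: segment count and total length
    over all samples in ``gm`` (zero rows included).  Per chromosome:
    segment count and coverage fraction, the mean over individuals of ROH
    bp on the chromosome divided by its SNP span
    (last - first position + 1).
    """
    per_class_rows = []
    total_n = len(segments)
    total_len = float(segments["length_bp"].sum()) if total_n else 0.0
    for cls in LENGTH_CLASSES:
        sub = segments[segments["length_class"] == cls] if total_n else segments
        n = len(sub)
        clen = float(sub["length_bp"].sum()) if n else 0.0
        per_class_rows.append(
            (
                cls,
                n,
                100.0 * n / total_n if total_n else 0.0,
                clen / n / 1e6 if n else float("nan"),
                100.0 * clen / total_len if total_len else 0.0,
            )
        )
    per_class = pd.DataFrame(
        per_class_rows,
        columns=["length_class", "n_segments", "percent", "mean_length_mb", "share"],
    )

    per_individual = (
        segments.groupby("sample_id")
        .agg(n_segments=("length_bp", "size"), total_length_bp=("length_bp", "sum"))
        .reindex(gm.samples, fill_value=0)
        .rename_axis("sample_id")
        .reset_index()
    )

    chrom_rows = []
    v = gm.variants
    n_ind = max(gm.n_samples, 1)
    for chrom in gm.chromosomes():
        span = int(v.loc[v["chrom"] == chrom, "pos_bp"].max()) - int(
            v.loc[v["chrom"] == chrom, "pos_bp"].min()
        ) + 1
        sub = segments[segments["chrom"] == chrom] if total_n else segments
        cov = float(sub["length_bp"].sum()) / span / n_ind if len(sub) else 0.0
        chrom_rows.append((chrom, len(sub), cov))
    per_chromosome = pd.DataFrame(
        chrom_rows, columns=["chrom", "n_segments", "coverage_fraction"]
    )
    return ROHSummary(per_class, per_individual, per_chromosome)


def with_params(params: ROHParams, **kwargs) -> ROHParams:
    """Copy ``params`` with the given fields replaced."""
    return replace(params, **kwargs)
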