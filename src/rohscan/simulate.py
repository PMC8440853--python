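"""Synthetic SNP-array genotypes with known ground truth.

The generator produces a multi-chromosome SNP map at array-like density,
Hardy-Weinberg background genotypes at configurable allele frequencies,
and planted autozygous tracts: per individual, intervals are placed
uniformly along the genome until the planted fraction reaches the target
genome-wide autozygosity F, and every SNP inside a tract is rendered
homozygous (a single allele drawn from the population frequency, copied
to both haplotypes).  Heterozygote "genotyping error" inside tracts and
genome-wide missingness are applied on top, and an optional shared tract
region can be forced into a chosen fraction of individuals to create a
ROH island with known coordinates.  Blockwise haplotype copying from a
founder pool induces LD that decays with distance when
``ld_block_snps > 1``.

This is a direct generative model of what the downstream analyses
consume - tract-induced homozygosity on an array map - not a coalescent
or pedigree simulation.  All randomness flows from a single seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .plink import write_plink_text


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults model a composite-pig SNP50-style study scaled to a compact
    genome: 18 autosomes x 2,000 SNPs at 25 kb mean spacing (so the
    canonical 1 Mb / 50 SNP ROH minimum is operative), 200 individuals,
    mean planted autozygosity 0.08, exponential tract lengths of mean
    4 Mb (minimum 1 Mb), 0.5% heterozygote error inside tracts and 1%
    missingness.
    """

    n_chromosomes: int = 18
    snps_per_chromosome: int = 2_000
    mean_spacing_bp: float = 25_000.0
    maf_min: float = 0.05
    n_individuals: int = 200
    target_f: float = 0.08
    tract_mean_bp: float = 4_000_000.0
    tract_min_bp: float = 1_000_000.0
    island_region: tuple[str, int, int, float] | None = None
    het_error_rate: float = 0.005
    missing_rate: float = 0.01
    ld_block_snps: int = 1
    n_founder_haplotypes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_error_rate", "missing_rate", "target_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must be in (0, 0.5]")
        if self.ld_block_snps < 1:
            raise ValueError("ld_block_snps must be >= 1")
        if self.island_region is not None:
            chrom, start, end, cf = self.island_region
            if end < start or not 0.0 <= cf <= 1.0:
                raise ValueError("invalid island_region")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated matrix.

    tracts: DataFrame (sample_id, chrom, start_bp, end_bp) of planted
    autozygous intervals, non-overlapping within an individual.
    true_f: per-individual planted autozygous fraction
    (tract bp / simulated L_auto).
    freq_b: per-SNP true allele-B frequency, aligned with the variant
    table.
    l_auto_bp: simulated marker-covered genome length.
    """

    tracts: pd.DataFrame
    true_f: pd.Series
    freq_b: pd.Series
    l_auto_bp: int = 0


def simulate_map(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the SNP map: exponential spacings, cumulative positions.

    Positions are 1-based; spacing is drawn per SNP from an exponential
    with mean ``mean_spacing_bp`` (minimum 1 bp).  Deterministic under
    the config seed.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    frames = []
    for c in range(1, cfg.n_chromosomes + 1):
        spacing = np.maximum(
            1, rng.exponential(cfg.mean_spacing_bp, cfg.snps_per_chromosome).astype(np.int64)
        )
        pos = np.cumsum(spacing)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": str(c),
                    "id": [f"snp{c}_{i + 1}" for i in range(cfg.snps_per_chromosome)],
                    "pos_bp": pos,
                    "allele_a": "A",
                    "allele_b": "B",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _background_dosage(
    cfg: SimConfig, freq: np.ndarray, chrom_bounds: list[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """HWE background genotypes; founder-copying blocks when ld_block_snps > 1."""
    n, m = cfg.n_individuals, len(freq)
    if cfg.ld_block_snps == 1:
        return rng.binomial(2, freq, size=(n, m)).astype(np.int8)
    # Founder-haplotype copying: each of the 2n haplotypes copies a founder,
    # switching to a fresh uniform founder with prob 1/ld_block_snps per SNP,
    # never across a chromosome boundary.  Shared founder segments between
    # two haplotypes create r^2 that decays with SNP distance.
    K = cfg.n_founder_haplotypes
    founders = (rng.random((K, m)) < freq).astype(np.int8)
    dosage = np.zeros((n, m), dtype=np.int8)
    switch_p = 1.0 / cfg.ld_block_snps
    for hap in range(2):
        choice = np.empty((n, m), dtype=np.int32)
        for lo, hi in chrom_bounds:
            width = hi - lo
            switches = rng.random((n, width)) < switch_p
            switches[:, 0] = True
            new_idx = rng.integers(0, K, size=(n, width))
            # forward-fill founder index within chromosome
            seg_id = np.cumsum(switches, axis=1) - 1
            filled = np.empty((n, width), dtype=np.int32)
            for i in range(n):
                picks = new_idx[i][switches[i]]
                filled[i] = picks[seg_id[i]]
            choice[:, lo:hi] = filled
        dosage += founders[choice, np.arange(m)[None, :]]
    return dosage


def _place_tracts(
    cfg: SimConfig,
    chrom_spans: dict[str, tuple[int, int]],
    forced: list[tuple[str, int, int]],
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping autozygous tracts for one individual.

    The tract count is Poisson with mean ``target_f * L / tract_mean_bp``
    so the expected autozygous fraction equals ``target_f`` while the
    realised fraction varies between individuals, as it does in real
    populations.  Tract lengths are shifted-exponential (minimum
    ``tract_min_bp``, mean ``tract_mean_bp``); placement is uniform along
    the genome with overlap rejection.
    """
    spans = list(chrom_spans.items())
    if cfg.target_f >= 1.0:
        # fully autozygous genome: one tract per chromosome
        return [(c, lo, hi) for c, (lo, hi) in spans]
    weights = np.array([hi - lo + 1 for _, (lo, hi) in spans], dtype=float)
    weights /= weights.sum()
    l_total = sum(hi - lo + 1 for _, (lo, hi) in spans)
    tracts: list[tuple[str, int, int]] = list(forced)
    n_tracts = rng.poisson(cfg.target_f * l_total / cfg.tract_mean_bp)
    placed_n = 0
    attempts = 0
    while placed_n < n_tracts and attempts < 100 * max(n_tracts, 1):
        attempts += 1
        ci = rng.choice(len(spans), p=weights)
        chrom, (lo, hi) = spans[ci]
        length = int(
            cfg.tract_min_bp
            + rng.exponential(max(cfg.tract_mean_bp - cfg.tract_min_bp, 1.0))
        )
        span = hi - lo + 1
        if length >= span:
            warnings.warn(
                f"tract longer than chromosome {chrom}; truncated", stacklevel=3
            )
            start, end = lo, hi
        else:
            start = int(rng.integers(lo, hi - length + 2))
            end = start + length - 1
        if any(c == chrom and s <= end and e >= start for c, s, e in tracts):
            continue  # overlap; resample
        tracts.append((chrom, start, end))
        placed_n += 1
    return tracts


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Simulate genotypes and ground truth under the configured conditions."""
    rng = np.random.default_rng(cfg.seed)
    variants = simulate_map(cfg, rng)
    m = len(variants)
    freq = rng.uniform(cfg.maf_min, 0.5, size=m)

    chroms = variants["chrom"].to_numpy()
    pos = variants["pos_bp"].to_numpy()
    chrom_bounds: list[tuple[int, int]] = []
    chrom_spans: dict[str, tuple[int, int]] = {}
    start = 0
    for i in range(1, m + 1):
        if i == m or chroms[i] != chroms[start]:
            chrom_bounds.append((start, i))
            chrom_spans[chroms[start]] = (int(pos[start]), int(pos[i - 1]))
            start = i
    l_auto_bp = sum(hi - lo + 1 for lo, hi in chrom_spans.values())

    dosage = _background_dosage(cfg, freq, chrom_bounds, rng)

    # island carriers decided once, before per-individual background tracts
    island_carriers: set[int] = set()
    forced_tract: list[tuple[str, int, int]] = []
    if cfg.island_region is not None:
        chrom, s, e, cf = cfg.island_region
        chrom = str(chrom)
        n_carriers = int(np.ceil(cf * cfg.n_individuals))
        island_carriers = set(
            rng.choice(cfg.n_individuals, size=n_carriers, replace=False).tolist()
        )
        forced_tract = [(chrom, int(s), int(e))]

    tract_rows = []
    true_f = np.zeros(cfg.n_individuals)
    sample_ids = [f"ind{i + 1:04d}" for i in range(cfg.n_individuals)]
    for i in range(cfg.n_individuals):
        forced = forced_tract if i in island_carriers else []
        tracts = _place_tracts(cfg, chrom_spans, forced, rng)
        tract_bp = 0
        for chrom, s, e in tracts:
            tract_rows.append((sample_ids[i], chrom, s, e))
            tract_bp += e - s + 1
            sel = (chroms == chrom) & (pos >= s) & (pos <= e)
            k = int(sel.sum())
            if k == 0:
                continue
            allele = (rng.random(k) < freq[sel]).astype(np.int8)
            g = 2 * allele
            if cfg.het_error_rate > 0:
                err = rng.random(k) < cfg.het_error_rate
                g[err] = 1
            dosage[i, sel] = g
        true_f[i] = tract_bp / l_auto_bp

    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = MISSING

    gm = GenotypeMatrix(
        variants=variants, samples=sample_ids, dosage=dosage
    ).canonicalize_alleles()
    # keep truth frequencies aligned with the (possibly flipped) allele_b
    flipped = gm.variants["allele_b"].to_numpy() == "A"
    freq = np.where(flipped, 1.0 - freq, freq)
    truth = GroundTruth(
        tracts=pd.DataFrame(
            tract_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"]
        ),
        true_f=pd.Series(true_f, index=sample_ids, name="true_f"),
        freq_b=pd.Series(freq, index=variants["id"], name="freq_b"),
        l_auto_bp=l_auto_bp,
    )
    return gm, truth


def write_fixture(gm: GenotypeMatrix, truth: GroundTruth, prefix) -> dict[str, str]:
    """Write PED/MAP plus truth tables; re-reading reproduces ``gm`` exactly."""
    ped, mp = write_plink_text(gm, prefix)
    tracts_path = f"{prefix}.truth_tracts.tsv"
    freqs_path = f"{prefix}.truth_freqs.tsv"
    truth.tracts.to_csv(tracts_path, sep="\t", index=False)
    truth.freq_b.rename_axis("id").reset_index().to_csv(freqs_path, sep="\t", index=False)
    return {"ped": ped, "map": mp, "tracts": tracts_path, "freqs": freqs_path}
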