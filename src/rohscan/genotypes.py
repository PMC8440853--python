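"""Core genotype container shared by every analysis stage.

Genotypes are stored as an allele-B dosage matrix (samples x SNPs) in
``int8`` with :data:`MISSING` (-1) marking no-calls.  All homozygosity-based
statistics downstream depend only on the {homozygous, heterozygous, missing}
partition, so the arbitrary choice of which allele is counted never affects
ROH, F_ROH, F_HOM or r^2 results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Columns every variant table must carry, in canonical order.
VARIANT_COLUMNS = ["chrom", "id", "pos_bp", "allele_a", "allele_b"]

#: Pig autosome labels (Sus scrofa 11.1 has 18 autosomes).
PIG_AUTOSOMES = tuple(str(c) for c in range(1, 19))


def chrom_sort_key(label: str) -> tuple[int, int, str]:
    """Sort key placing numeric chromosome labels first, in numeric order."""
    s = str(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with variant and sample metadata.

    Parameters
    ----------
    variants
        DataFrame with columns ``chrom`` (str), ``id``, ``pos_bp`` (1-based
        int), ``allele_a``, ``allele_b``; one row per SNP, in column order
        of ``dosage``.
    samples
        Sample identifiers, one per dosage row.
    dosage
        ``int8`` array of shape (n_samples, n_snps); entries in
        {0, 1, 2, MISSING} counting copies of ``allele_b``.
    fam
        Optional PLINK FAM-style metadata (fid, iid, pat, mat, sex, pheno),
        preserved through round trips.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    fam: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.variants["chrom"] = self.variants["chrom"].astype(str)
        self.variants["pos_bp"] = self.variants["pos_bp"].astype(np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.samples = [str(s) for s in self.samples]
        self.validate()

    # -- basic shape ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        if list(self.variants.columns[:5]) != VARIANT_COLUMNS:
            missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
            if missing:
                raise ValueError(f"variant table missing columns: {sorted(missing)}")
            self.variants = self.variants[VARIANT_COLUMNS]
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")
        if self.variants["id"].duplicated().any():
            dup = self.variants.loc[self.variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup!r}")
        if (self.variants["pos_bp"] < 1).any():
            raise ValueError("pos_bp must be >= 1 (1-based coordinates)")

    # -- ordering -------------------------------------------------------
    def sort_variants(self) -> "GenotypeMatrix":
        """Return a copy sorted by (chrom, pos_bp), dosage columns permuted."""
        order = sorted(
            range(self.n_snps),
            key=lambda i: (
                chrom_sort_key(self.variants["chrom"].iat[i]),
                int(self.variants["pos_bp"].iat[i]),
            ),
        )
        return GenotypeMatrix(
            variants=self.variants.iloc[order].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[:, order],
            fam=self.fam,
        )

    def is_sorted(self) -> bool:
        keys = [
            (chrom_sort_key(c), p)
            for c, p in zip(self.variants["chrom"], self.variants["pos_bp"])
        ]
        return all(keys[i] < keys[i + 1] for i in range(len(keys) - 1))

    def canonicalize_alleles(self) -> "GenotypeMatrix":
        """Return a copy in first-observed allele order.

        PED text files carry no allele metadata, so a text reader must
        take the first allele it encounters at each SNP as ``allele_a``.
        This method flips any column whose first non-missing genotype is
        homozygous for ``allele_b`` (dosage -> 2 - dosage, alleles
        swapped) so that writing to PED and reading back reproduces the
        dosage matrix exactly.  Homozygosity-based statistics are
        unaffected; allele-B frequencies flip to 1 - p on flipped
        columns.
        """
        d = self.dosage.copy()
        variants = self.variants.copy()
        for j in range(self.n_snps):
            col = d[:, j]
            obs = np.flatnonzero(col != MISSING)
            if obs.size and col[obs[0]] == 2:
                col[obs] = 2 - col[obs]
                variants.loc[j, ["allele_a", "allele_b"]] = (
                    variants.loc[j, "allele_b"],
                    variants.loc[j, "allele_a"],
                )
        return GenotypeMatrix(
            variants=variants, samples=list(self.samples), dosage=d, fam=self.fam
        )

    # -- subsetting -----------------------------------------------------
    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/SNP index arrays."""
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        fam = None
        if self.fam is not None:
            fam = self.fam.iloc[sample_idx].reset_index(drop=True)
        return GenotypeMatrix(
            variants=self.variants.iloc[snp_idx].reset_index(drop=True),
            samples=[self.samples[i] for i in sample_idx],
            dosage=self.dosage[np.ix_(sample_idx, snp_idx)],
            fam=fam,
        )

    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels in map order."""
        seen: dict[str, None] = {}
        for c in self.variants["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Column slice per chromosome (requires sorted variants)."""
        chroms = self.variants["chrom"].to_numpy()
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out
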