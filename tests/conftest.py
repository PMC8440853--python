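import numpy as np
import pandas as pd
import pytest

from rohscan.genotypes import GenotypeMatrix


def make_variants(positions_by_chrom: dict[str, list[int]]) -> pd.DataFrame:
    """Variant table from {chrom: [pos, ...]}, ids generated, alleles A/B."""
    rows = []
    for chrom, positions in positions_by_chrom.items():
        for i, pos in enumerate(positions):
            rows.append((str(chrom), f"snp{chrom}_{i}", pos, "A", "B"))
    return pd.DataFrame(
        rows, columns=["chrom", "id", "pos_bp", "allele_a", "allele_b"]
    )


def make_gm(dosage, positions_by_chrom=None, samples=None) -> GenotypeMatrix:
    """GenotypeMatrix from a dosage array; default map is chrom 1, 100 kb grid."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_snps = dosage.shape
    if positions_by_chrom is None:
        positions_by_chrom = {"1": [100_000 * (i + 1) for i in range(n_snps)]}
    variants = make_variants(positions_by_chrom)
    assert len(variants) == n_snps
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(variants=variants, samples=samples, dosage=dosage)


@pytest.fixture
def random_gm():
    """5 samples x 20 SNPs with missing calls, first-observed allele order."""
    rng = np.random.default_rng(1)
    dosage = rng.choice(
        np.array([0, 1, 2, -1], dtype=np.int8), size=(5, 20), p=[0.3, 0.3, 0.3, 0.1]
    )
    gm = make_gm(dosage, {"1": list(np.cumsum(rng.integers(1, 50_000, 10))),
                          "2": list(np.cumsum(rng.integers(1, 50_000, 10)))})
    return gm.canonicalize_alleles()
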