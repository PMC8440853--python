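"""Readers and writers for PLINK genotype formats.

Supports the whitespace-delimited text pair (PED/MAP) and the v1.0 binary
triple (BED/BIM/FAM, SNP-major).  Missing alleles are coded ``0`` in text
and ``01`` in the 2-bit binary encoding.  Coordinates are 1-based physical
bp as stored in MAP/BIM.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

BED_MAGIC = bytes((0x6C, 0x1B, 0x01))

FAM_COLUMNS = ["fid", "iid", "pat", "mat", "sex", "pheno"]


class PlinkFormatError(ValueError):
    """Malformed PLINK input (ragged rows, bad magic, >2 alleles, ...)."""


def read_map(map_path) -> pd.DataFrame:
    """Read a 4-column MAP file into a variant table (without alleles)."""
    try:
        mp = pd.read_csv(
            map_path,
            sep=r"\s+",
            header=None,
            names=["chrom", "id", "cm", "pos_bp"],
            dtype={"chrom": str, "id": str},
        )
    except pd.errors.EmptyDataError:
        mp = pd.DataFrame(columns=["chrom", "id", "cm", "pos_bp"])
    if mp["id"].duplicated().any():
        dup = mp.loc[mp["id"].duplicated(), "id"].iloc[0]
        raise PlinkFormatError(f"duplicate SNP id in MAP: {dup!r}")
    return mp


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    Allele coding: per SNP, ``allele_a`` is the first non-missing allele
    encountered in file order, ``allele_b`` the second; dosage counts
    copies of ``allele_b``.  ``0 0`` genotypes become missing.  Variants
    are returned sorted by (chrom, pos_bp) with dosage columns permuted
    to match.
    """
    mp = read_map(map_path)
    n_snps = len(mp)

    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PlinkFormatError(
                    f"PED line {lineno}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2x{n_snps} SNPs), found {len(fields)}"
                )
            rows.append(fields)

    fam = pd.DataFrame(
        [r[:6] for r in rows] if rows else None, columns=FAM_COLUMNS, dtype=str
    )
    samples = list(fam["iid"]) if rows else []
    alleles = (
        np.array([r[6:] for r in rows], dtype=object)
        if rows
        else np.empty((0, 2 * n_snps), dtype=object)
    )

    dosage = np.full((len(rows), n_snps), MISSING, dtype=np.int8)
    allele_a = np.empty(n_snps, dtype=object)
    allele_b = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        a1 = alleles[:, 2 * j]
        a2 = alleles[:, 2 * j + 1]
        seen: list[str] = []
        for a in np.concatenate([a1, a2]):
            if a != "0" and a not in seen:
                seen.append(a)
        if len(seen) > 2:
            raise PlinkFormatError(
                f"SNP {mp['id'].iat[j]!r}: more than two alleles observed {seen}"
            )
        aa = seen[0] if seen else "0"
        ab = seen[1] if len(seen) > 1 else "0"
        allele_a[j], allele_b[j] = aa, ab
        miss = (a1 == "0") | (a2 == "0")
        dosage[:, j] = np.where(miss, MISSING, (a1 == ab).astype(int) + (a2 == ab))

    variants = pd.DataFrame(
        {
            "chrom": mp["chrom"].astype(str),
            "id": mp["id"],
            "pos_bp": mp["pos_bp"].astype(np.int64) if n_snps else [],
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    gm = GenotypeMatrix(variants=variants, samples=samples, dosage=dosage, fam=fam)
    return gm.sort_variants()


def write_plink_text(gm: GenotypeMatrix, prefix) -> tuple[str, str]:
    """Write ``prefix.ped`` and ``prefix.map``; missing written as ``0 0``.

    Returns the (ped, map) paths.  Round trip with :func:`read_plink_text`
    reproduces (variants, samples, dosage) exactly provided ``allele_a``
    appears in the data before ``allele_b`` at every SNP, which holds for
    matrices produced by this package's readers and simulator.
    """
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    v = gm.variants
    with open(map_path, "w") as fh:
        for _, row in v.iterrows():
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos_bp}\n")

    fam = gm.fam
    if fam is None:
        fam = pd.DataFrame(
            {
                "fid": gm.samples,
                "iid": gm.samples,
                "pat": "0",
                "mat": "0",
                "sex": "0",
                "pheno": "-9",
            }
        )
    aa = v["allele_a"].to_numpy()
    ab = v["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i in range(gm.n_samples):
            d = gm.dosage[i]
            geno = np.empty((len(d), 2), dtype=object)
            geno[d == 0] = np.stack([aa, aa], axis=1)[d == 0]
            geno[d == 1] = np.stack([aa, ab], axis=1)[d == 1]
            geno[d == 2] = np.stack([ab, ab], axis=1)[d == 2]
            geno[d == MISSING] = ["0", "0"]
            fields = list(fam.iloc[i].astype(str)) + list(geno.ravel())
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a BED/BIM/FAM triple (PLINK 1, SNP-major) into a matrix.

    2-bit decoding per SNP-major byte, lowest bits first:
    ``00`` -> homozygous allele-1 (BIM col 5), ``01`` -> missing,
    ``10`` -> heterozygous, ``11`` -> homozygous allele-2 (BIM col 6).
    Dosage counts allele-2; BIM allele columns are recorded verbatim as
    (allele_a, allele_b) = (col5, col6), never re-inferred.
    """
    try:
        bim = pd.read_csv(
            bim_path,
            sep=r"\s+",
            header=None,
            names=["chrom", "id", "cm", "pos_bp", "a1", "a2"],
            dtype={"chrom": str, "id": str, "a1": str, "a2": str},
        )
    except pd.errors.EmptyDataError:
        bim = pd.DataFrame(columns=["chrom", "id", "cm", "pos_bp", "a1", "a2"])
    try:
        fam = pd.read_csv(
            fam_path, sep=r"\s+", header=None, names=FAM_COLUMNS, dtype=str
        )
    except pd.errors.EmptyDataError:
        fam = pd.DataFrame(columns=FAM_COLUMNS, dtype=str)

    n_snps, n_samples = len(bim), len(fam)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: not a SNP-major PLINK 1 BED file (bad magic bytes)"
        )
    body = raw[3:]
    bytes_per_snp = (n_samples + 3) // 4
    if len(body) != bytes_per_snp * n_snps:
        raise PlinkFormatError(
            f"{bed_path}: truncated or inconsistent BED body "
            f"({len(body)} bytes, expected {bytes_per_snp * n_snps})"
        )

    dosage = np.empty((n_samples, n_snps), dtype=np.int8)
    if n_snps and n_samples:
        mat = body.reshape(n_snps, bytes_per_snp)
        # 2-bit fields, lowest-order pair = first sample in the byte
        codes = np.stack(
            [(mat >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
        ).reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
        lut = np.array([0, MISSING, 1, 2], dtype=np.int8)
        dosage = lut[codes].T

    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"].astype(str),
            "id": bim["id"],
            "pos_bp": bim["pos_bp"].astype(np.int64) if n_snps else [],
            "allele_a": bim["a1"],
            "allele_b": bim["a2"],
        }
    )
    gm = GenotypeMatrix(
        variants=variants, samples=list(fam["iid"]), dosage=dosage, fam=fam
    )
    return gm.sort_variants()


def write_plink_binary(gm: GenotypeMatrix, prefix) -> tuple[str, str, str]:
    """Write ``prefix.bed/.bim/.fam`` (PLINK 1, SNP-major)."""
    bed_path, bim_path, fam_path = f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam"
    v = gm.variants
    with open(bim_path, "w") as fh:
        for _, row in v.iterrows():
            fh.write(
                f"{row.chrom}\t{row.id}\t0\t{row.pos_bp}\t{row.allele_a}\t{row.allele_b}\n"
            )
    fam = gm.fam
    if fam is None:
        fam = pd.DataFrame(
            {
                "fid": gm.samples,
                "iid": gm.samples,
                "pat": "0",
                "mat": "0",
                "sex": "0",
                "pheno": "-9",
            }
        )
    fam.to_csv(fam_path, sep="\t", header=False, index=False)

    n_samples, n_snps = gm.n_samples, gm.n_snps
    bytes_per_snp = (n_samples + 3) // 4
    inv = np.array([0b00, 0b10, 0b11], dtype=np.uint8)  # dosage 0/1/2 -> code
    codes = np.full((n_snps, bytes_per_snp * 4), 0, dtype=np.uint8)
    d = gm.dosage.T  # SNP-major
    c = np.where(d == MISSING, 0b01, inv[np.clip(d, 0, 2)]).astype(np.uint8)
    codes[:, :n_samples] = c
    packed = np.zeros((n_snps, bytes_per_snp), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        packed |= codes[:, k::4] << shift
    with open(bed_path, "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())
    return bed_path, bim_path, fam_path


def read_genotypes(prefix_or_ped, map_path=None) -> GenotypeMatrix:
    """Read genotypes given a file prefix, auto-detecting text vs binary."""
    if map_path is not None:
        return read_plink_text(prefix_or_ped, map_path)
    prefix = str(prefix_or_ped)
    for ext in (".ped", ".bed"):
        if prefix.endswith(ext):
            prefix = prefix[: -len(ext)]
    if os.path.exists(prefix + ".bed"):
        return read_plink_binary(prefix + ".bed", prefix + ".bim", prefix + ".fam")
    if os.path.exists(prefix + ".ped"):
        return read_plink_text(prefix + ".ped", prefix + ".map")
    raise FileNotFoundError(f"no PLINK files found at prefix {prefix!r}")
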