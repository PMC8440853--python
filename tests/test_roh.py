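"""Sliding-window ROH detection, classification and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohscan.roh import (
    ROHParams,
    call_roh_sample,
    classify_length,
    classify_segments,
    detect_roh,
    naive_roh_oracle,
    scan_windows,
    segments_to_frame,
    summarize_roh,
    with_params,
)

from conftest import make_gm, make_variants


def even_map(n, spacing=20_000, chrom="1"):
    return make_variants({chrom: [spacing * (i + 1) for i in range(n)]})


def random_instance(seed):
    """Random multi-chromosome genotype vector + parameters for the oracle."""
    rng = np.random.default_rng(seed)
    positions = {}
    for c in range(1, int(rng.integers(1, 4)) + 1):
        m = int(rng.integers(5, 201))
        positions[str(c)] = list(np.cumsum(rng.integers(1, 60_000, m)))
    variants = make_variants(positions)
    het_p, mis_p = rng.uniform(0, 0.3), rng.uniform(0, 0.15)
    hom_p = (1 - het_p - mis_p) / 2
    dosage = rng.choice(
        np.array([0, 1, 2, -1], dtype=np.int8),
        size=len(variants),
        p=[hom_p, het_p, hom_p, mis_p],
    )
    params = ROHParams(
        window_snps=int(rng.integers(2, 30)),
        max_het_per_window=int(rng.integers(0, 3)),
        max_missing_per_window=int(rng.integers(0, 4)),
        window_hit_threshold=float(rng.uniform(0.01, 1.0)),
        min_length_bp=int(rng.integers(1, 2_000_000)),
        min_snps=int(rng.integers(1, 30)),
        max_density_kb_per_snp=float(rng.uniform(20, 200)),
        max_gap_kb=float(rng.uniform(50, 2_000)),
    )
    return dosage, variants, params


class TestScanWindows:
    def test_all_homozygous_hits_everywhere(self):
        v = even_map(100)
        frac = scan_windows(np.zeros(100, dtype=np.int8), v["pos_bp"].to_numpy())
        assert (frac == 1.0).all()

    def test_alternating_het_kills_all_windows(self):
        v = even_map(100)
        d = np.tile([1, 0], 50).astype(np.int8)
        frac = scan_windows(d, v["pos_bp"].to_numpy())
        assert (frac == 0.0).all()

    def test_single_het_matches_exhaustive_enumeration(self):
        # 100 hom SNPs, one heterozygote at index 50; compare against a
        # direct enumeration of every 50-SNP window
        v = even_map(100)
        d = np.zeros(100, dtype=np.int8)
        d[50] = 1
        params = ROHParams()
        frac = scan_windows(d, v["pos_bp"].to_numpy(), params)
        w = params.window_snps
        n_windows = 100 - w + 1
        ok = [d[s : s + w].sum() <= params.max_het_per_window for s in range(n_windows)]
        for i in range(100):
            covering = [s for s in range(n_windows) if s <= i < s + w]
            expected = sum(ok[s] for s in covering) / len(covering)
            assert frac[i] == pytest.approx(expected)

    def test_short_chromosome_single_window(self):
        v = even_map(10)
        d = np.zeros(10, dtype=np.int8)
        assert (scan_windows(d, v["pos_bp"].to_numpy()) == 1.0).all()
        d[0] = d[1] = 1  # 2 hets > allowance of 1
        assert (scan_windows(d, v["pos_bp"].to_numpy()) == 0.0).all()

    def test_empty_chromosome(self):
        assert scan_windows(np.zeros(0, dtype=np.int8), np.zeros(0)).size == 0


class TestCallROH:
    def test_long_homozygous_run_single_segment(self):
        # 120 hom SNPs evenly spanning ~2 Mb
        v = make_variants({"1": [1 + round(i * 2_000_000 / 119) for i in range(120)]})
        segs = call_roh_sample(np.zeros(120, dtype=np.int8), v)
        assert len(segs) == 1
        assert segs[0].n_snps == 120
        assert segs[0].length_bp == pytest.approx(2_000_000, rel=0.01)

    def test_run_below_min_length_dropped(self):
        v = make_variants({"1": [1 + round(i * 900_000 / 119) for i in range(120)]})
        segs = call_roh_sample(np.zeros(120, dtype=np.int8), v)
        assert segs == []

    def test_all_missing_yields_nothing(self):
        v = even_map(100)
        segs = call_roh_sample(np.full(100, -1, dtype=np.int8), v)
        assert segs == []  # 50 missing per window > allowance of 5

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_naive_oracle(self, seed):
        dosage, variants, params = random_instance(seed)
        assert call_roh_sample(dosage, variants, params) == naive_roh_oracle(
            dosage, variants, params
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=10_000, max_value=99_999))
    def test_matches_naive_oracle_property(self, seed):
        dosage, variants, params = random_instance(seed)
        assert call_roh_sample(dosage, variants, params) == naive_roh_oracle(
            dosage, variants, params
        )

    def test_monotonicity_in_thresholds(self):
        dosage, variants, params = random_instance(424_242)
        base = with_params(params, min_length_bp=200_000, min_snps=5)
        n0 = len(call_roh_sample(dosage, variants, base))
        assert len(
            call_roh_sample(dosage, variants, with_params(base, min_snps=15))
        ) <= n0
        assert len(
            call_roh_sample(dosage, variants, with_params(base, min_length_bp=800_000))
        ) <= n0
        assert (
            len(
                call_roh_sample(
                    dosage,
                    variants,
                    with_params(base, max_het_per_window=base.max_het_per_window + 2),
                )
            )
            >= n0
        )

    def test_segments_sorted_and_disjoint(self):
        for seed in (7, 99, 1234):
            dosage, variants, params = random_instance(seed)
            segs = call_roh_sample(
                dosage, variants, with_params(params, min_length_bp=100_000, min_snps=3)
            )
            by_chrom: dict[str, list] = {}
            for s in segs:
                by_chrom.setdefault(s.chrom, []).append(s)
            for chrom_segs in by_chrom.values():
                for a, b in zip(chrom_segs, chrom_segs[1:]):
                    assert a.end_bp < b.start_bp


class TestClassify:
    @pytest.mark.parametrize(
        "length_bp,expected",
        [
            (3_490_000, "1-5"),
            (1_000_000, "1-5"),
            (5_000_000, "5-10"),
            (6_840_000, "5-10"),
            (10_000_000, ">10"),
            (16_320_000, ">10"),
        ],
    )
    def test_class_boundaries(self, length_bp, expected):
        assert classify_length(length_bp) == expected

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            classify_length(999_999)

    def test_classify_segments_column(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "a"],
                "chrom": ["1", "1"],
                "start_bp": [1, 1],
                "end_bp": [2_000_000, 12_000_000],
                "n_snps": [60, 600],
                "length_bp": [2_000_000, 12_000_000],
            }
        )
        out = classify_segments(df)
        assert list(out["length_class"]) == ["1-5", ">10"]


class TestDetectAndSummarize:
    def test_identical_samples_identical_segments(self):
        rng = np.random.default_rng(2)
        row = np.zeros(200, dtype=np.int8)
        row[::37] = 1
        gm = make_gm(
            np.vstack([row, row]),
            {"1": list(np.cumsum(rng.integers(5_000, 40_000, 200)))},
        )
        segs = detect_roh(gm)
        a = segs[segs.sample_id == "s0"].drop(columns="sample_id").reset_index(drop=True)
        b = segs[segs.sample_id == "s1"].drop(columns="sample_id").reset_index(drop=True)
        assert a.equals(b)

    def test_empty_matrix_empty_segments(self):
        gm = make_gm(np.zeros((0, 5), dtype=np.int8))
        assert len(detect_roh(gm)) == 0

    def test_single_segment_coverage(self):
        # one 2 Mb segment on a chromosome spanning 100 Mb -> coverage 0.02
        gm = make_gm(
            np.ones((1, 2), dtype=np.int8), {"1": [1, 100_000_000]}
        )
        segs = segments_to_frame([])
        segs = pd.DataFrame(
            {
                "sample_id": ["s0"],
                "chrom": ["1"],
                "start_bp": [1_000_001],
                "end_bp": [3_000_000],
                "n_snps": [80],
                "length_bp": [2_000_000],
                "length_class": ["1-5"],
            }
        )
        summary = summarize_roh(segs, gm)
        row = summary.per_chromosome.set_index("chrom").loc["1"]
        assert row["coverage_fraction"] == pytest.approx(0.02)

    def test_class_shares_sum_to_100(self):
        _, variants, _ = random_instance(31)
        gm = make_gm(
            np.zeros((1, len(variants)), dtype=np.int8),  # fully homozygous
            {
                c: list(variants.loc[variants.chrom == c, "pos_bp"])
                for c in variants["chrom"].unique()
            },
        )
        segs = detect_roh(gm)
        assert len(segs) > 0
        summary = summarize_roh(segs, gm)
        assert summary.per_class["percent"].sum() == pytest.approx(100.0, abs=0.01)
        assert summary.per_class["share"].sum() == pytest.approx(100.0, abs=0.01)

    def test_planted_tract_recovery_boundaries(self):
        # clean tract >= 2 Mb, no error/missingness: recovered within one
        # inter-SNP spacing at each boundary
        from rohscan.simulate import SimConfig, simulate_population

        cfg = SimConfig(
            n_chromosomes=2,
            snps_per_chromosome=1_500,
            n_individuals=8,
            target_f=0.10,
            tract_min_bp=2_000_000,
            tract_mean_bp=4_000_000,
            het_error_rate=0.0,
            missing_rate=0.0,
            seed=21,
        )
        gm, truth = simulate_population(cfg)
        segs = detect_roh(gm)
        pos = gm.variants["pos_bp"].to_numpy()
        chroms = gm.variants["chrom"].to_numpy()
        # With a 5% window-hit threshold over 50-SNP windows, the flagged
        # region starts at most ceil(0.05 * 50) = 3 SNPs inside the tract.
        max_edge_snps = 3
        for _, tract in truth.tracts.iterrows():
            sel = np.flatnonzero(
                (chroms == tract.chrom)
                & (pos >= tract.start_bp)
                & (pos <= tract.end_bp)
            )
            if sel.size < 50 + 2 * max_edge_snps:
                continue
            mine = segs[
                (segs.sample_id == tract.sample_id)
                & (segs.chrom == tract.chrom)
                & (segs.start_bp <= tract.end_bp)
                & (segs.end_bp >= tract.start_bp)
            ]
            assert len(mine) >= 1, "planted tract not recovered"
            start_idx = int(np.searchsorted(pos[sel], int(mine.start_bp.min())))
            end_idx = int(np.searchsorted(pos[sel], int(mine.end_bp.max())))
            assert start_idx <= max_edge_snps
            assert sel.size - 1 - end_idx <= max_edge_snps
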