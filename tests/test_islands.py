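"""Per-SNP ROH incidence, top-percentile islands and annotation."""

import numpy as np
import pandas as pd
import pytest

from rohscan.islands import (
    annotate_islands,
    island_threshold,
    merge_islands,
    read_features_bed,
    read_features_gff3,
    snp_incidence,
)

from conftest import make_variants


def seg(sample, chrom, start, end):
    return {
        "sample_id": sample,
        "chrom": str(chrom),
        "start_bp": start,
        "end_bp": end,
        "n_snps": 50,
        "length_bp": end - start + 1,
        "length_class": "1-5",
    }


def incidence_frame(fractions, chrom="1", spacing=10_000):
    v = make_variants({chrom: [spacing * (i + 1) for i in range(len(fractions))]})
    out = v[["chrom", "id", "pos_bp"]].copy()
    out["n_in_roh"] = (np.asarray(fractions) * 100).astype(int)
    out["fraction"] = fractions
    return out


class TestIncidence:
    def test_full_penetrance(self):
        v = make_variants({"1": [100, 200, 300]})
        segs = pd.DataFrame([seg(f"s{i}", 1, 150, 250) for i in range(10)])
        inc = snp_incidence(segs, v, 10)
        assert inc["fraction"].tolist() == [0.0, 1.0, 0.0]

    def test_individual_counted_once_with_overlapping_segments(self):
        v = make_variants({"1": [100, 200, 300]})
        segs = pd.DataFrame(
            [seg("a", 1, 100, 250), seg("a", 1, 150, 300)]
        )
        inc = snp_incidence(segs, v, 4)
        assert inc["n_in_roh"].tolist() == [1, 1, 1]

    def test_inclusive_boundaries(self):
        v = make_variants({"1": [99, 100, 300, 301]})
        segs = pd.DataFrame([seg("a", 1, 100, 300)])
        inc = snp_incidence(segs, v, 1)
        assert inc["n_in_roh"].tolist() == [0, 1, 1, 0]

    def test_requires_individuals(self):
        with pytest.raises(ValueError):
            snp_incidence(pd.DataFrame([seg("a", 1, 1, 2)]), make_variants({"1": [1]}), 0)

    def test_permutation_invariance(self):
        v = make_variants({"1": [100 * i for i in range(1, 30)]})
        segs = [seg(f"s{i}", 1, 300, 1200) for i in range(5)]
        a = snp_incidence(pd.DataFrame(segs), v, 5)
        b = snp_incidence(pd.DataFrame(segs[::-1]), v, 5)
        assert a.equals(b)


class TestThreshold:
    def test_rank_definition(self):
        fr = np.concatenate([[0.5, 0.4, 0.3], np.full(297, 0.1)])
        inc = incidence_frame(fr)
        # top 1% of 300 SNPs = 3 SNPs -> threshold is the 3rd-highest value
        assert island_threshold(inc, 0.01) == pytest.approx(0.3)

    def test_all_equal_all_qualify(self):
        inc = incidence_frame(np.full(200, 0.25))
        thr = island_threshold(inc, 0.01)
        assert thr == 0.25
        assert (inc["fraction"] >= thr).all()

    def test_few_snps_warns_and_uses_max(self):
        inc = incidence_frame([0.1, 0.9, 0.2])
        with pytest.warns(UserWarning):
            assert island_threshold(inc, 0.01) == 0.9


class TestMergeIslands:
    def test_inclusive_length_from_printed_coordinates(self):
        # runs of qualifying SNPs whose bounds are at known positions
        v = make_variants(
            {
                "2": [77_541_872, 78_000_000, 78_345_614],
                "11": [34_189_314, 35_000_000, 37_377_736],
            }
        )
        inc = v[["chrom", "id", "pos_bp"]].copy()
        inc["n_in_roh"] = 10
        inc["fraction"] = 0.9
        islands = merge_islands(inc, threshold=0.5, min_island_snps=2)
        got = dict(zip(islands["chrom"], islands["length_bp"]))
        assert got["2"] == 803_743
        assert got["11"] == 3_188_423

    def test_isolated_snp_no_island(self):
        inc = incidence_frame([0.1, 0.9, 0.1])
        assert len(merge_islands(inc, 0.5, min_island_snps=2)) == 0

    def test_runs_split_by_nonqualifying_snp(self):
        inc = incidence_frame([0.9, 0.9, 0.1, 0.9, 0.9])
        islands = merge_islands(inc, 0.5, min_island_snps=2)
        assert len(islands) == 2
        assert islands["n_snps"].tolist() == [2, 2]

    def test_runs_split_at_chromosome_boundary(self):
        v = make_variants({"1": [100, 200], "2": [250, 350]})
        inc = v[["chrom", "id", "pos_bp"]].copy()
        inc["n_in_roh"] = 5
        inc["fraction"] = 0.8
        islands = merge_islands(inc, 0.5)
        assert islands["chrom"].tolist() == ["1", "2"]

    def test_threshold_monotone_shrinkage(self):
        rng = np.random.default_rng(17)
        inc = incidence_frame(rng.random(500))
        prev = np.inf
        for thr in (0.2, 0.4, 0.6, 0.8):
            total = merge_islands(inc, thr, min_island_snps=1)["length_bp"].sum()
            assert total <= prev
            prev = total

    def test_qualifying_snp_conservation(self):
        rng = np.random.default_rng(23)
        inc = incidence_frame(rng.random(300))
        thr = 0.6
        islands = merge_islands(inc, thr, min_island_snps=1)
        assert islands["n_snps"].sum() == int((inc["fraction"] >= thr).sum())
        assert (
            merge_islands(inc, thr, min_island_snps=2)["n_snps"].sum()
            <= islands["n_snps"].sum()
        )


class TestAnnotate:
    def _islands(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "2"],
                "start_bp": [1_000, 5_000],
                "end_bp": [2_000, 6_000],
                "length_bp": [1_001, 1_001],
                "n_snps": [5, 5],
                "peak_fraction": [0.9, 0.8],
            }
        )

    def test_exact_interval_overlaps(self):
        feats = pd.DataFrame(
            {"chrom": ["1"], "start_bp": [1_000], "end_bp": [2_000], "name": ["g1"]}
        )
        out = annotate_islands(self._islands(), feats)
        assert out["n_features"].tolist() == [1, 0]

    def test_abutting_feature_does_not_overlap(self):
        feats = pd.DataFrame(
            {"chrom": ["1"], "start_bp": [2_001], "end_bp": [3_000], "name": ["g1"]}
        )
        out = annotate_islands(self._islands(), feats)
        assert out["n_features"].tolist() == [0, 0]

    def test_hand_enumerated_toy_bed(self, tmp_path):
        # 5 features vs 2 islands; expected counts by hand sweep:
        # island 1 [1000,2000]: f1 [900,1000] touches, f2 [1500,1600] inside,
        # f3 [2001,2100] abuts (no); island 2 [5000,6000]: f4 [4000,7000]
        # spans, f5 on chrom 3 skipped with warning
        bed = tmp_path / "genes.bed"
        bed.write_text(
            "1\t899\t1000\tf1\n"
            "1\t1499\t1600\tf2\n"
            "1\t2000\t2100\tf3\n"
            "2\t3999\t7000\tf4\n"
            "3\t1\t100\tf5\n"
        )
        feats = read_features_bed(bed)
        with pytest.warns(UserWarning, match="skipped"):
            out = annotate_islands(self._islands(), feats)
        assert out["n_features"].tolist() == [2, 1]
        assert out["feature_names"].tolist() == ["f1,f2", "f4"]

    def test_gff3_reader_intervals(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t1000\t1500\t.\t+\t.\tID=gene:g1;Name=G1\n"
            "1\tsrc\texon\t1000\t1200\t.\t+\t.\tID=exon:e1\n"
        )
        feats = read_features_gff3(gff)
        assert len(feats) == 1  # exon filtered out
        assert feats.loc[0, "start_bp"] == 1000 and feats.loc[0, "end_bp"] == 1500
        assert feats.loc[0, "name"] == "G1"
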