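"""Window partitioning, variant filtering, and summary statistics."""

import numpy as np
import pandas as pd
import pytest

from linksel import window_summaries as ws


class TestPartitionGenome:
    def test_exclusion_zones_leave_central_windows(self):
        # 25 Mb chromosome: 10 Mb cut from each end leaves [10, 15) Mb
        wins = ws.partition_genome({"chr1": 25_000_000})
        assert len(wins) == 50
        assert wins[0].start == 10_000_000
        assert wins[-1].end == 15_000_000

    def test_short_chromosome_fully_excluded(self):
        assert ws.partition_genome({"chr1": 20_000_000}) == []

    def test_trailing_partial_window_dropped(self):
        wins = ws.partition_genome(
            {"c": 1_050_000}, window_size=100_000, exclusion=0
        )
        assert len(wins) == 10 and wins[-1].end == 1_000_000

    def test_centromere_annotation_excludes_overlap(self):
        ann = pd.DataFrame(
            {"chrom": ["chr1"], "start": [20_000_000], "end": [20_100_000]}
        )
        wins = ws.partition_genome({"chr1": 45_000_000}, ann)
        starts = {w.start for w in wins}
        # anything within 10 Mb of the centromere interval is gone
        assert all(s >= 30_100_000 or s + 100_000 <= 10_000_000 for s in starts)
        assert len(wins) > 0

    def test_malformed_annotation_reports_line(self):
        ann = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [1]})
        with pytest.raises(ValueError, match="line 0"):
            ws.partition_genome({"chr1": 25_000_000}, ann)


class TestIngestVariants:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["pos", "ref", "alt"])

    def test_triallelic_removed(self):
        recs = self._records([(10, "A", "C"), (20, "A", "C,G")])
        out = ws.ingest_variants(recs)
        assert out["pos"].tolist() == [10]

    def test_sv_distance_boundary(self):
        recs = self._records([(99, "A", "C"), (102, "A", "C"), (150, "G", "T")])
        out = ws.ingest_variants(recs, sv_positions=np.array([100]))
        # 1 bp away removed, 2 bp away retained
        assert out["pos"].tolist() == [102, 150]

    def test_conserved_mask_removes_snp(self):
        recs = self._records([(10, "A", "C"), (60, "A", "C")])
        out = ws.ingest_variants(recs, conserved_mask=np.array([[50, 70]]))
        assert out["pos"].tolist() == [10]

    def test_unsorted_input_rejected(self):
        recs = self._records([(20, "A", "C"), (10, "A", "C")])
        with pytest.raises(ValueError, match="sorted"):
            ws.ingest_variants(recs)

    def test_reference_mismatch_removed(self):
        recs = self._records([(10, "A", "C"), (20, "A", "C")])
        recs["ref_matches"] = [True, False]
        out = ws.ingest_variants(recs)
        assert out["pos"].tolist() == [10]


class TestLoaders:
    def test_vcf_and_bed_loaders(self, tmp_path):
        vcf = tmp_path / "variants.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tA\tC\t50\tPASS\t.\n"
            "chr1\t201\t.\tG\tT,A\t50\tPASS\t.\n"
        )
        df = ws.load_vcf(vcf, chrom="chr1")
        assert df["pos"].tolist() == [100, 200]  # 0-based
        assert df["alt"].tolist() == ["C", "T,A"]
        filtered = ws.ingest_variants(df)
        assert filtered["pos"].tolist() == [100]  # triallelic dropped

        bed = tmp_path / "mask.bed"
        bed.write_text("chr1\t0\t500\nchr1\t400\t900\nchr2\t0\t10\n")
        ivals = ws.load_bed(bed, chrom="chr1")
        assert ivals.tolist() == [[0, 900]]


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        n, S = 10, 16
        a1 = sum(1 / i for i in range(1, n))
        assert ws.tajimas_d(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_constants_implementation(self):
        # second implementation of the constants, written from the
        # definitions independent of the library code path
        def oracle(S, pi, n):
            a1 = sum(1.0 / i for i in range(1, n))
            a2 = sum(1.0 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))

        for n, S, pi in [(10, 16, 3.888), (25, 40, 8.2), (200, 120, 22.0)]:
            assert ws.tajimas_d(S, pi, n) == pytest.approx(
                oracle(S, pi, n), abs=1e-10
            )

    def test_all_singletons_negative_in_large_sample(self):
        n, S = 100, 30
        # each singleton contributes 2(n-1)/(n(n-1)) ... pi = S * 2/n
        pi = S * 2 * (n - 1) / (n * (n - 1))
        assert ws.tajimas_d(S, pi, n) < 0

    def test_undefined_cases(self):
        assert np.isnan(ws.tajimas_d(0, 0.0, 10))
        assert np.isnan(ws.tajimas_d(5, 1.0, 2))


class TestCgsHetFilter:
    @pytest.mark.parametrize(
        "counts,drop",
        [
            ([3.4] * 12, True),  # >= 10 SNPs, mean het > 3
            ([6] * 9, False),  # too few SNPs
            ([3] * 15, False),  # mean exactly 3: strict inequality keeps
        ],
    )
    def test_rule(self, counts, drop):
        assert ws.cgs_het_filter(counts) is drop

    def test_range_validation(self):
        with pytest.raises(ValueError):
            ws.cgs_het_filter([7] * 12)


class TestClassifyWindow:
    @pytest.mark.parametrize(
        "frac,cls",
        [(0.0, "nongenic"), (0.5, "genic"), (1.0, "genic"), (0.3, "neither")],
    )
    def test_classes(self, frac, cls):
        assert ws.classify_window(frac) == cls


class TestSummarizeWindow:
    def _window(self):
        return ws.GenomicWindow("chr1", 0, 100_000, recomb_rate=1.0)

    def test_s_norm_direct_arithmetic(self):
        out = ws.summarize_window(
            self._window(),
            snp_pos=np.arange(10) * 100,
            snp_maf=np.full(10, 0.2),
            coverage=np.array([[0, 5000]]),
            hc_diff_pos=np.arange(50) * 10,
            aligned=np.array([[0, 5000]]),
        )
        assert out.S == 10 and out.covered == 5000
        assert out.S_norm == pytest.approx((10 / 5000) / (50 / 5000))
        assert out.mean_maf == pytest.approx(0.2)

    def test_no_snps_zero_s_norm_undefined_maf(self):
        out = ws.summarize_window(
            self._window(),
            snp_pos=np.array([], dtype=int),
            snp_maf=np.array([]),
            coverage=np.array([[0, 5000]]),
            hc_diff_pos=np.array([100, 200]),
            aligned=np.array([[0, 5000]]),
        )
        assert out.S_norm == 0.0 and np.isnan(out.mean_maf) and out.valid

    def test_fully_masked_window_flagged(self):
        out = ws.summarize_window(
            self._window(),
            snp_pos=np.array([], dtype=int),
            snp_maf=np.array([]),
            coverage=np.empty((0, 2), dtype=int),
            hc_diff_pos=np.array([], dtype=int),
            aligned=np.empty((0, 2), dtype=int),
        )
        assert not out.valid and np.isnan(out.S_norm)

    def test_mask_algebra_conservation(self):
        # covered bases over disjoint sub-intervals sum to the window total
        rng = np.random.default_rng(3)
        cuts = np.sort(rng.choice(np.arange(1, 100), size=6, replace=False))
        ivals = []
        prev = 0
        for c in list(cuts) + [100]:
            ivals.append((prev * 1000, c * 1000))
            prev = c
        total = ws.intervals_overlap_length(
            np.array([[0, 100_000]]), 0, 100_000
        )
        parts = sum(
            ws.intervals_overlap_length(np.array([iv]), 0, 100_000)
            for iv in ivals
        )
        assert parts == total == 100_000

    def test_order_independence_after_sorting(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(100_000, size=40, replace=False))
        maf = rng.uniform(0.05, 0.5, size=40)
        perm = rng.permutation(40)
        a = ws.summarize_window(
            self._window(), pos, maf,
            np.array([[0, 100_000]]), np.array([500]), np.array([[0, 100_000]]),
        )
        order = np.argsort(pos[perm], kind="stable")
        b = ws.summarize_window(
            self._window(), pos[perm][order], maf[perm][order],
            np.array([[0, 100_000]]), np.array([500]), np.array([[0, 100_000]]),
        )
        assert a.S == b.S and a.mean_maf == pytest.approx(b.mean_maf)
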