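"""Interval engine: BED I/O contracts, overlap arithmetic, annotation, profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episcore.errors import ArgumentError, BedParseError
from episcore.intervals import (
    Coverage,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    annotate_peaks,
    intersect,
    overlap_fraction,
    promoter_intervals,
    read_bed,
    tss_profile,
    write_bed,
)

from _oracles import bf_intersect, bf_overlap_fraction, random_intervals
from conftest import iset


class TestBedIO:
    def test_read_sorts_and_deduplicates(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\nchr1\t50\t80\nchr1\t100\t200\n")
        got = read_bed(p)
        assert [(i.chrom, i.start, i.end) for i in got] == [
            ("chr1", 50, 80),
            ("chr1", 100, 200),
        ]

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        with pytest.warns(UserWarning, match="no intervals"):
            assert len(read_bed(p)) == 0

    @pytest.mark.parametrize(
        "line, match",
        [
            ("chr1\t200\t100", "line|:1"),
            ("chr1\tabc\t300", "non-integer"),
            ("chr1\t100", "columns"),
        ],
    )
    def test_malformed_lines_cite_line_number(self, tmp_path, line, match):
        p = tmp_path / "bad.bed"
        p.write_text(line + "\n")
        with pytest.raises(BedParseError, match=":1"):
            read_bed(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            read_bed(tmp_path / "absent.bed")

    def test_score_column_roundtrip(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t10\t20\tpk1\t3.5\t.\n")
        got = read_bed(p)
        assert got.intervals[0].score == 3.5
        out = tmp_path / "o.bed"
        write_bed(got, out)
        assert read_bed(out) == got


class TestOverlapArithmetic:
    def test_identity_fraction_is_one(self):
        a = iset([("chr1", 0, 100), ("chr2", 5, 9)])
        assert overlap_fraction(a, a) == 1.0

    def test_disjoint_chromosomes(self):
        assert overlap_fraction(iset([("chr1", 0, 10)]), iset([("chr2", 0, 10)])) == 0.0

    def test_half_overlapping_query(self):
        q = iset([("chr1", 0, 100), ("chr1", 500, 600)])
        s = iset([("chr1", 90, 95)])
        assert overlap_fraction(q, s) == 0.5

    def test_min_bp_validation_and_empty_query(self):
        a = iset([("chr1", 0, 10)])
        with pytest.raises(ArgumentError):
            overlap_fraction(a, a, min_bp=0)
        with pytest.warns(UserWarning):
            assert overlap_fraction(iset([]), a) == 0.0

    def test_subject_monotonicity(self, rng):
        q = iset(random_intervals(rng, 50))
        raw_b = random_intervals(rng, 30)
        extra = raw_b + random_intervals(rng, 30)
        assert overlap_fraction(q, iset(extra)) >= overlap_fraction(q, iset(raw_b))

    def test_intersect_examples(self):
        a, b = iset([("chr1", 0, 100)]), iset([("chr1", 50, 150)])
        got = intersect(a, b)
        assert [(i.chrom, i.start, i.end) for i in got] == [("chr1", 50, 100)]
        assert len(intersect(a, iset([("chr1", 200, 300)]))) == 0

    def test_intersect_self_is_merge(self, rng):
        a = iset(random_intervals(rng, 100))
        assert intersect(a, a) == a.merge()

    def test_intersect_bp_bound_and_commutativity(self, rng):
        a = iset(random_intervals(rng, 80))
        b = iset(random_intervals(rng, 80))
        ab, ba = intersect(a, b), intersect(b, a)
        assert ab == ba
        assert ab.total_bp() <= min(a.total_bp(), b.total_bp())

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            raw_a = random_intervals(rng, int(rng.integers(1, 300)))
            raw_b = random_intervals(rng, int(rng.integers(1, 300)))
            got = intersect(iset(raw_a), iset(raw_b))
            assert [(i.chrom, i.start, i.end) for i in got] == bf_intersect(raw_a, raw_b)
            assert overlap_fraction(iset(raw_a), iset(raw_b)) == pytest.approx(
                bf_overlap_fraction(raw_a, raw_b)
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)),
            min_size=1,
            max_size=40,
        ),
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)),
            min_size=1,
            max_size=40,
        ),
    )
    def test_intersect_property_vs_oracle(self, raw_a, raw_b):
        ra = [("chr1", s, s + l) for s, l in raw_a]
        rb = [("chr1", s, s + l) for s, l in raw_b]
        got = intersect(iset(ra), iset(rb))
        assert [(i.chrom, i.start, i.end) for i in got] == bf_intersect(ra, rb)


class TestAnnotatePeaks:
    def test_promoter_and_distal(self, two_gene_models):
        peaks = iset(
            [
                ("chr1", 100_050, 100_150),  # midpoint 100 bp downstream of GP TSS
                ("chr1", 5_000_000, 5_000_200),  # 1 Mb+ from anything
            ]
        )
        anns, props = annotate_peaks(peaks, two_gene_models)
        by_start = {a.peak.start: a for a in anns}
        assert by_start[100_050].feature == "promoter"
        assert by_start[100_050].gene_id == "GP"
        assert by_start[100_050].distance_to_tss == 100
        assert by_start[5_000_000].feature == "distal_intergenic"
        assert props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_minus_strand_promoter_orientation(self, two_gene_models):
        # GM TSS = 519_999; 100 bp downstream on minus strand = 519_899
        peaks = iset([("chr1", 519_849, 519_949)])
        anns, _ = annotate_peaks(peaks, two_gene_models)
        assert anns[0].feature == "promoter"
        assert anns[0].distance_to_tss == 100

    def test_utr_exon_intron_downstream_priority(self):
        g = GeneModel("G", "chr1", 1, 100_000, 140_000)
        exons = {"G": [(100_000, 100_400), (110_000, 112_000), (139_000, 140_000)]}
        utr5 = {"G": [(100_000, 100_200)]}
        utr3 = {"G": [(139_800, 140_000)]}
        peaks = iset(
            [
                ("chr1", 110_500, 110_700),  # exon, beyond promoter window
                ("chr1", 120_000, 120_200),  # intron
                ("chr1", 139_850, 139_950),  # 3'UTR (inside last exon)
                ("chr1", 141_000, 141_200),  # downstream
                ("chr1", 100_050, 100_150),  # 5'UTR but promoter priority wins
            ]
        )
        anns, _ = annotate_peaks(
            peaks, [g], exon_table=exons, utr5_table=utr5, utr3_table=utr3
        )
        feats = {a.peak.start: a.feature for a in anns}
        assert feats[110_500] == "exon"
        assert feats[120_000] == "intron"
        assert feats[139_850] == "three_prime_utr"
        assert feats[141_000] == "downstream"
        assert feats[100_050] == "promoter"

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ArgumentError):
            annotate_peaks(iset([("chr1", 0, 10)]), [])

    def test_planted_proportions_recovered(self, small_genome):
        from episcore.synthetic_data import SimConfig, make_peaks

        cfg = SimConfig(
            seed=7,
            n_genes=60,
            n_chroms=1,
            n_peaks=10_000,
            n_samples=1,
            n_comark_genes=0,
            marks={
                "custom": {
                    "promoter": 0.42,
                    "distal_intergenic": 0.36,
                    "intron": 0.12,
                    "exon": 0.06,
                    "downstream": 0.04,
                }
            },
        )
        peaksets, truth = make_peaks(cfg, small_genome)
        anns, props = annotate_peaks(
            peaksets[("S00", "custom")],
            small_genome.genes,
            exon_table=small_genome.exons,
            utr5_table=small_genome.utr5,
            utr3_table=small_genome.utr3,
        )
        assert props["promoter"] == pytest.approx(0.42, abs=0.02)
        assert props["distal_intergenic"] == pytest.approx(0.36, abs=0.02)


class TestTssProfile:
    def _flat_cov(self, value, lo=0, hi=1_000_000):
        return Coverage({"chr1": (np.array([lo]), np.array([hi]), np.array([value]))})

    def test_equal_treat_input_gives_zero(self, two_gene_models):
        cov = self._flat_cov(3.0)
        mat = tss_profile(cov, cov, two_gene_models[:1])
        assert np.allclose(mat.to_numpy(), 0.0)

    def test_constant_ratio_two(self, two_gene_models):
        mat = tss_profile(
            self._flat_cov(2.0),
            self._flat_cov(1.0),
            two_gene_models[:1],
            pseudocount=1e-9,
        )
        assert np.allclose(mat.to_numpy(), 1.0, atol=1e-6)

    def test_minus_strand_bump_oriented_downstream(self):
        g = GeneModel("GM", "chr1", -1, 500_000, 520_000)
        # bump genomically UPSTREAM in coordinates = downstream for minus strand
        bump_lo, bump_hi = g.tss - 2_000, g.tss - 1_000
        cov = Coverage(
            {
                "chr1": (
                    np.array([0, bump_lo, bump_hi]),
                    np.array([bump_lo, bump_hi, 1_000_000]),
                    np.array([0.0, 50.0, 0.0]),
                )
            }
        )
        mat = tss_profile(cov, None, [g], flank=5000, bin_size=50)
        row = mat.iloc[0]
        downstream = row[row.index >= 0]
        upstream = row[row.index < 0]
        assert downstream.max() > 5
        assert upstream.max() < 0.1

    def test_chromosome_edge_padded_with_nan(self):
        g = GeneModel("GE", "chr1", 1, 1_000, 30_000)
        mat = tss_profile(self._flat_cov(1.0), None, [g], flank=5000, bin_size=50)
        row = mat.iloc[0].to_numpy()
        n_bad = (5000 - 1000) // 50  # bins starting before position 0
        assert np.isnan(row[:n_bad]).all()
        assert np.isfinite(row[n_bad:]).all()

    def test_flank_bin_validation(self, two_gene_models):
        with pytest.raises(ArgumentError):
            tss_profile(self._flat_cov(1.0), None, two_gene_models, flank=5000, bin_size=33)


class TestCoverage:
    def test_region_sums_match_bruteforce(self, rng):
        starts = np.arange(0, 10_000, 100)
        ends = starts + 100
        values = rng.random(len(starts)) * 5
        cov = Coverage({"chr1": (starts, ends, values)})
        per_bp = np.repeat(values, 100)
        for _ in range(50):
            a = int(rng.integers(0, 9_000))
            b = a + int(rng.integers(1, 1_000))
            assert cov.region_sum("chr1", a, b) == pytest.approx(per_bp[a:b].sum())

    def test_negative_values_rejected(self):
        with pytest.raises(Exception):
            Coverage({"chr1": (np.array([0]), np.array([10]), np.array([-1.0]))})
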