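"""Interval layer: merging, overlap arithmetic, and the genome partition.

Every operation is validated against a per-bp set-arithmetic oracle on toy
genomes, alongside the worked percentage examples from published
regulatory-track summaries.
"""

from __future__ import annotations

import numpy as np
import pytest

from conftest import bp_set, random_intervals, track_bp_set
from regvar.intervals import (
    BedParseError,
    GeneModel,
    GenomicInterval,
    RegulatoryTrack,
    build_genome_partition,
    complement_track,
    intersect_tracks,
    merge_track,
    normalize_chrom,
    overlap_length,
    percent_overlap,
    read_bed,
    read_chrom_sizes,
    read_gene_models,
)


class TestGenomicInterval:
    def test_rejects_degenerate_spans(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_length_is_half_open(self):
        assert len(GenomicInterval("chr1", 10, 20)) == 10


class TestMerge:
    @pytest.mark.parametrize(
        "spans, expected_total, expected_n",
        [
            ([], 0, 0),
            ([(0, 10)] * 3, 10, 1),  # idempotent on duplicates
            ([(0, 100), (50, 150)], 150, 1),  # overlap fuses
            ([(10, 20), (20, 30)], 20, 1),  # abutting spans fuse
            ([(0, 100), (200, 300)], 200, 2),  # disjoint stay apart
        ],
    )
    def test_merge_examples(self, spans, expected_total, expected_n):
        track = merge_track([GenomicInterval("chr1", s, e) for s, e in spans])
        assert track.total_length == expected_total
        assert len(track) == expected_n

    def test_disjoint_chroms_are_additive(self):
        track = merge_track(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100)]
        )
        assert track.total_length == 200

    def test_merge_idempotent(self, rng):
        ivs = random_intervals(rng, 100)
        once = merge_track(ivs)
        twice = merge_track(once.intervals)
        assert [(i.chrom, i.start, i.end) for i in once.intervals] == [
            (i.chrom, i.start, i.end) for i in twice.intervals
        ]

    def test_union_length_matches_per_bp_oracle(self, rng):
        for _ in range(20):
            ivs = random_intervals(rng, 100, chroms=("chr1", "chr2"))
            track = merge_track(ivs)
            assert track.total_length == len(bp_set(ivs))
            assert track_bp_set(track) == bp_set(ivs)

    def test_union_and_intersection_agree_with_pyranges(self, rng):
        # independent library cross-check on top of the per-bp oracle
        import pandas as pd
        import pyranges as pr

        def to_pr(ivs):
            return pr.PyRanges(pd.DataFrame({
                "Chromosome": [iv.chrom for iv in ivs],
                "Start": [iv.start for iv in ivs],
                "End": [iv.end for iv in ivs],
            }))

        ivs_a = random_intervals(rng, 60, chroms=("chr1", "chr2"))
        ivs_b = random_intervals(rng, 60, chroms=("chr1", "chr2"))
        a, b = merge_track(ivs_a), merge_track(ivs_b)
        ref_union = to_pr(ivs_a).merge()
        assert a.total_length == int((ref_union.End - ref_union.Start).sum())
        ref_inter = to_pr(a.intervals).intersect(to_pr(b.intervals))
        ref_bp = (int((ref_inter.End - ref_inter.Start).sum())
                  if len(ref_inter) else 0)
        assert overlap_length(a, b) == ref_bp

    def test_merged_invariant_no_overlap_or_abutment(self, rng):
        track = merge_track(random_intervals(rng, 200))
        starts, ends = track.arrays("chr1")
        assert np.all(starts[1:] > ends[:-1])  # strictly separated


class TestOverlap:
    def test_partial_overlap(self):
        a = merge_track([GenomicInterval("chr1", 0, 100)])
        b = merge_track([GenomicInterval("chr1", 50, 150)])
        assert overlap_length(a, b) == 50

    def test_disjoint_tracks(self):
        a = merge_track([GenomicInterval("chr1", 0, 100)])
        b = merge_track([GenomicInterval("chr1", 200, 300)])
        assert overlap_length(a, b) == 0
        assert overlap_length(a, merge_track([GenomicInterval("chr2", 0, 100)])) == 0

    def test_overlap_matches_per_bp_oracle_and_symmetry(self, rng):
        for _ in range(20):
            a = merge_track(random_intervals(rng, 10))
            b = merge_track(random_intervals(rng, 10))
            expected = len(track_bp_set(a) & track_bp_set(b))
            assert overlap_length(a, b) == expected
            assert overlap_length(b, a) == expected
            assert overlap_length(a, a) == a.total_length

    def test_intersection_track_equals_oracle(self, rng):
        a = merge_track(random_intervals(rng, 30, chroms=("chr1", "chr2")))
        b = merge_track(random_intervals(rng, 30, chroms=("chr1", "chr2")))
        inter = intersect_tracks(a, b)
        assert track_bp_set(inter) == track_bp_set(a) & track_bp_set(b)

    def test_complement_equals_oracle(self, rng):
        sizes = {"chr1": 5_000, "chr2": 3_000}
        track = merge_track(random_intervals(rng, 20, chroms=("chr1", "chr2"),
                                             chrom_size=3_000))
        comp = complement_track(track, sizes)
        genome = {(c, p) for c, n in sizes.items() for p in range(n)}
        assert track_bp_set(comp) == genome - track_bp_set(track)


class TestPercentOverlap:
    def test_published_promoter_coding_exon_cell(self):
        # 318,864 bp of promoter overlapping coding exons, of 3,833,500 bp
        assert percent_overlap(318_864, 3_833_500) == 8.32

    def test_three_decimal_mode_for_tiny_fractions(self):
        assert percent_overlap(275, 12_385_403, decimals=3) == 0.002

    def test_zero_overlap_and_zero_length(self):
        assert percent_overlap(0, 1_000) == 0.0
        with pytest.raises(ValueError):
            percent_overlap(10, 0)


class TestBedIO:
    def test_read_merges_and_sorts(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t100\nchr1\t50\t150\n")
        track = read_bed(p)
        assert track.total_length == 150
        assert len(track) == 1

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\tx\t200\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_end_not_after_start_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(BedParseError):
            read_bed(p)

    def test_roundtrip_through_bed3(self, tmp_path, rng):
        track = merge_track(random_intervals(rng, 50, chroms=("chr1", "chr2")))
        p = tmp_path / "out.bed"
        track.to_bed(p)
        back = read_bed(p)
        assert track_bp_set(back) == track_bp_set(track)

    def test_chrom_normalization(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("1\t0\t10\n")
        assert read_bed(p).chroms == ("chr1",)
        assert read_bed(p, add_chr_prefix=False).chroms == ("1",)
        assert normalize_chrom("chrX") == "chrX"

    def test_chrom_sizes_reader(self, tmp_path):
        p = tmp_path / "sizes.txt"
        p.write_text("chr1\t10000\n2\t5000\n")
        assert read_chrom_sizes(p) == {"chr1": 10_000, "chr2": 5_000}


def classify_bp_oracle(genes, sizes, flank=2000):
    """Brute-force per-bp classifier: the independent genome-partition oracle."""
    classes = {name: set() for name in
               ("coding_exon", "utr5", "utr3", "intron", "upstream",
                "downstream", "intergenic")}
    footprint = set()
    for g in genes:
        size = sizes[g.chrom]
        for s, e in g.cds:
            classes["coding_exon"].update((g.chrom, p) for p in range(s, e))
        exonic = set()
        for s, e in g.exons:
            exonic.update(range(s, e))
        for p in range(g.start, g.end):
            if p not in exonic:
                classes["intron"].add((g.chrom, p))
        if g.cds:
            lo = min(s for s, _ in g.cds)
            hi = max(e for _, e in g.cds)
            for p in exonic:
                if p < lo:
                    classes["utr5" if g.strand == "+" else "utr3"].add((g.chrom, p))
                elif p >= hi:
                    classes["utr3" if g.strand == "+" else "utr5"].add((g.chrom, p))
        up = (range(max(0, g.start - flank), g.start) if g.strand == "+"
              else range(g.end, min(size, g.end + flank)))
        down = (range(g.end, min(size, g.end + flank)) if g.strand == "+"
                else range(max(0, g.start - flank), g.start))
        classes["upstream"].update((g.chrom, p) for p in up)
        classes["downstream"].update((g.chrom, p) for p in down)
        footprint.update(
            (g.chrom, p)
            for p in range(max(0, g.start - flank), min(size, g.end + flank))
        )
    genome = {(c, p) for c, n in sizes.items() for p in range(n)}
    classes["intergenic"] = genome - footprint
    return classes


class TestGenomePartition:
    def test_single_plus_strand_gene_flanks_and_intergenic(self):
        sizes = {"chr1": 10_000}
        gene = GeneModel("g1", "chr1", 1_000, 2_000, "+",
                         exons=((1_000, 2_000),), cds=((1_200, 1_800),))
        part = build_genome_partition([gene], sizes, flank=2_000)
        assert track_bp_set(part["upstream"]) == {("chr1", p) for p in range(0, 1_000)}
        assert track_bp_set(part["downstream"]) == {
            ("chr1", p) for p in range(2_000, 4_000)
        }
        assert track_bp_set(part["intergenic"]) == {
            ("chr1", p) for p in range(4_000, 10_000)
        }
        assert track_bp_set(part["coding_exon"]) == {
            ("chr1", p) for p in range(1_200, 1_800)
        }
        assert track_bp_set(part["utr5"]) == {("chr1", p) for p in range(1_000, 1_200)}
        assert track_bp_set(part["utr3"]) == {("chr1", p) for p in range(1_800, 2_000)}

    def test_gene_spanning_whole_chrom_leaves_no_intergenic(self):
        sizes = {"chr1": 5_000}
        gene = GeneModel("g1", "chr1", 0, 5_000, "+", exons=((0, 5_000),))
        part = build_genome_partition([gene], sizes)
        assert part["intergenic"].total_length == 0

    def test_overlapping_opposite_strand_genes_match_oracle(self):
        sizes = {"chr1": 30_000}
        genes = [
            GeneModel("a", "chr1", 5_000, 12_000, "+",
                      exons=((5_000, 7_000), (9_000, 12_000)),
                      cds=((5_500, 7_000), (9_000, 11_000))),
            GeneModel("b", "chr1", 10_000, 20_000, "-",
                      exons=((10_000, 13_000), (15_000, 20_000)),
                      cds=((11_000, 13_000), (15_000, 19_000))),
        ]
        part = build_genome_partition(genes, sizes)
        oracle = classify_bp_oracle(genes, sizes)
        for name, expected in oracle.items():
            assert track_bp_set(part[name]) == expected, name

    def test_partition_union_covers_genome(self):
        sizes = {"chr1": 30_000}
        genes = [
            GeneModel("a", "chr1", 4_000, 9_000, "-",
                      exons=((4_000, 6_000), (7_000, 9_000)), cds=((5_000, 6_000),)),
        ]
        part = build_genome_partition(genes, sizes)
        union = set()
        for _, track in part.items():
            union |= track_bp_set(track)
        assert union == {("chr1", p) for p in range(30_000)}

    def test_gff3_roundtrip_partition(self, tmp_path):
        from regvar.simulate import write_gff3

        sizes = {"chr1": 30_000}
        genes = [
            GeneModel("g1", "chr1", 2_000, 8_000, "-",
                      exons=((2_000, 4_000), (5_000, 8_000)),
                      cds=((3_000, 4_000), (5_000, 7_000))),
        ]
        p = tmp_path / "g.gff3"
        write_gff3(genes, p)
        back = read_gene_models(p)
        assert len(back) == 1
        g = back[0]
        assert (g.chrom, g.start, g.end, g.strand) == ("chr1", 2_000, 8_000, "-")
        assert g.exons == genes[0].exons
        assert g.cds == genes[0].cds
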