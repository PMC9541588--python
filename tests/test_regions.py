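import numpy as np
import pytest

from tfbskit.regions import (
    GeneModel,
    RegionConfig,
    RegionError,
    build_region,
    build_regions,
    extract_sequences,
    read_bed,
    reverse_complement,
    select_representative,
    write_bed,
)


def gene(gene_id="g", chrom="chr1", strand="+", tic=10_000, tsc=11_000,
         exons=((10_000, 11_001),), gene_start=None, gene_end=None):
    exons = tuple(exons)
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.1",
        chrom=chrom,
        strand=strand,
        tic=tic,
        tsc=tsc,
        exons=exons,
        gene_start=min(s for s, _ in exons) if gene_start is None else gene_start,
        gene_end=max(e for _, e in exons) if gene_end is None else gene_end,
    )


class TestSelectRepresentative:
    def test_longest_wins(self):
        tid = select_representative(
            [
                {"transcript_id": "T1", "exons": [(0, 900)], "has_cds": True},
                {"transcript_id": "T2", "exons": [(0, 1200)], "has_cds": True},
            ]
        )
        assert tid == "T2"

    def test_tie_breaks_lexicographically(self):
        tid = select_representative(
            [
                {"transcript_id": "T2", "exons": [(0, 1000)], "has_cds": True},
                {"transcript_id": "T1", "exons": [(5, 1005)], "has_cds": True},
            ]
        )
        assert tid == "T1"

    def test_single_transcript_is_identity(self):
        tid = select_representative(
            [{"transcript_id": "only", "exons": [(0, 10)], "has_cds": True}]
        )
        assert tid == "only"

    def test_no_cds_raises(self):
        with pytest.raises(RegionError):
            select_representative(
                [{"transcript_id": "T", "exons": [(0, 10)], "has_cds": False}]
            )


class TestBuildRegion:
    def test_upstream_trimmed_at_neighbor(self):
        g = gene(tic=10_000)
        nb = gene("nb", tic=9_000, tsc=9_499, exons=((9_000, 9_500),))
        cfg = RegionConfig(upstream_len=5000)
        region = build_region(g, [nb], cfg)
        (label, _c, s, e, _st) = region.segments[0]
        assert label == "upstream"
        assert (s, e) == (9_500, 10_000)

    def test_no_trim_flag_keeps_full_window(self):
        g = gene(tic=10_000)
        nb = gene("nb", tic=9_000, tsc=9_499, exons=((9_000, 9_500),))
        cfg = RegionConfig(upstream_len=5000, trim_intergenic=False)
        region = build_region(g, [nb], cfg)
        assert region.segments[0][2:4] == (5_000, 10_000)

    def test_long_intron_skipped(self):
        g = gene(exons=((10_000, 10_300), (16_300, 17_000)), tsc=16_999)
        cfg = RegionConfig(upstream_len=1000, include_introns=True)
        region = build_region(g, [], cfg)
        assert [seg[0] for seg in region.segments] == ["upstream"]

    def test_short_intron_included(self):
        g = gene(exons=((10_000, 10_300), (10_500, 11_001)))
        cfg = RegionConfig(upstream_len=1000, include_introns=True)
        region = build_region(g, [], cfg)
        assert [seg[0] for seg in region.segments] == ["upstream", "intron_1"]
        assert region.segments[1][2:4] == (10_300, 10_500)

    def test_contig_edge_truncates_upstream(self):
        g = gene(tic=200, tsc=900, exons=((200, 901),))
        region = build_region(g, [], RegionConfig(upstream_len=1000), chrom_len=5000)
        assert region.segments[0][2:4] == (0, 200)

    def test_opposite_strand_overlap_keeps_full_windows(self):
        g = gene(tic=10_000, tsc=11_000)
        nb = gene("nb", strand="-", tic=11_200, tsc=10_800,
                  exons=((10_800, 11_201),))
        cfg = RegionConfig(upstream_len=5000)
        region = build_region(g, [nb], cfg)
        assert region.segments[0][2:4] == (5_000, 10_000)

    def test_same_strand_contained_gene_gets_zero_upstream(self):
        outer = gene("outer", tic=9_000, tsc=12_000, exons=((9_000, 12_001),))
        inner = gene("inner", tic=10_000, tsc=10_500, exons=((10_000, 10_501),))
        region = build_region(inner, [outer], RegionConfig(upstream_len=1000))
        assert region.segments == []

    def test_minus_strand_windows(self):
        g = gene(strand="-", tic=11_000, tsc=10_000, exons=((10_000, 11_001),))
        cfg = RegionConfig(upstream_len=1000, downstream_len=500)
        region = build_region(g, [], cfg)
        labels = {seg[0]: seg for seg in region.segments}
        assert labels["upstream"][2:4] == (11_001, 12_001)
        assert labels["downstream"][2:4] == (9_500, 10_000)

    def test_trimming_never_lengthens(self):
        rng = np.random.default_rng(3)
        cfg_trim = RegionConfig(upstream_len=3000)
        cfg_free = RegionConfig(upstream_len=3000, trim_intergenic=False)
        for _ in range(20):
            tic = int(rng.integers(5_000, 50_000))
            g = gene(tic=tic, tsc=tic + 500, exons=((tic, tic + 501),))
            nbs = []
            for _k in range(3):
                s = int(rng.integers(0, 60_000))
                nbs.append(gene(f"n{s}", tic=s, tsc=s + 400, exons=((s, s + 401),)))
            nbs = [n for n in nbs if not (n.gene_start < g.gene_end
                                          and n.gene_end > g.gene_start)]
            trimmed = build_region(g, nbs, cfg_trim)
            free = build_region(g, nbs, cfg_free)
            assert trimmed.length <= free.length

    def test_malformed_interval_raises_with_gene_name(self):
        with pytest.raises(RegionError, match="bad_gene"):
            GeneModel(
                gene_id="bad_gene", transcript_id="t", chrom="c", strand="+",
                tic=0, tsc=10, exons=((100, 50),),
            )


class TestOffsets:
    def test_upstream_offsets_end_at_minus_one(self):
        g = gene(tic=10_000)
        region = build_region(g, [], RegionConfig(upstream_len=1000))
        offs = region.offsets()
        assert offs[0] == -1000
        assert offs[-1] == -1
        assert (np.diff(offs) == 1).all()  # strictly monotonic

    def test_minus_strand_offsets_match_plus(self):
        g = gene(strand="-", tic=11_000, tsc=10_000, exons=((10_000, 11_001),))
        region = build_region(g, [], RegionConfig(upstream_len=1000))
        offs = region.offsets()
        assert offs[0] == -1000 and offs[-1] == -1

    def test_intron_offsets_are_positive(self):
        g = gene(exons=((10_000, 10_300), (10_500, 11_001)))
        region = build_region(g, [], RegionConfig(upstream_len=100, include_introns=True))
        offs = region.offsets()
        assert offs[100] == 300  # first intron base, 300 bp past the TIC


class TestSequenceExtraction:
    def test_plus_strand_exact_substring(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c1\n" + "ACGTACGTACGT" * 100 + "\n")
        g = gene(chrom="c1", tic=100, tsc=200, exons=((100, 201),))
        region = build_region(g, [], RegionConfig(upstream_len=10), chrom_len=1200)
        extract_sequences([region], fa)
        assert region.sequence == ("ACGTACGTACGT" * 100)[90:100]

    def test_minus_strand_reverse_complemented(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c1\n" + "A" * 50 + "ACGT" + "A" * 50 + "\n")
        g = gene(chrom="c1", strand="-", tic=49, tsc=10, exons=((10, 50),))
        region = build_region(g, [], RegionConfig(upstream_len=4), chrom_len=104)
        extract_sequences([region], fa)
        # reference [50, 54) = "ACGT"; minus-strand upstream reads its rc
        assert region.sequence == reverse_complement("ACGT")

    def test_missing_chromosome_raises(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c1\nACGT\n")
        g = gene(chrom="c2", tic=2, tsc=3, exons=((2, 4),))
        region = build_region(g, [], RegionConfig(upstream_len=2), chrom_len=4)
        with pytest.raises(KeyError):
            extract_sequences([region], fa)

    def test_empty_segment_list_gives_empty_sequence(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c1\nACGTACGT\n")
        outer = gene("outer", chrom="c1", tic=0, tsc=7, exons=((0, 8),))
        inner = gene("inner", chrom="c1", tic=2, tsc=5, exons=((2, 6),))
        region = build_region(inner, [outer], RegionConfig(upstream_len=2), chrom_len=8)
        extract_sequences([region], fa)
        assert region.sequence == ""


def test_bed_round_trip(small_regions, tmp_path):
    path = tmp_path / "regions.bed"
    write_bed(small_regions, path)
    back = read_bed(path)
    expected = [
        (r.gene_id, label, chrom, s, e, strand)
        for r in small_regions
        for (label, chrom, s, e, strand) in r.segments
    ]
    assert back == expected


def test_fixture_corner_cases_present(small_genome, small_regions):
    by_id = {r.gene_id: r for r in small_regions}
    truth = small_genome.truth.set_index("gene_id")
    edge = truth[truth["special"] == "edge"].index[0]
    assert by_id[edge].segments[0][2] == 0  # truncated at the contig start
    tight_b = truth[truth["special"] == "tight_b"].index[0]
    assert by_id[tight_b].length == 500  # trimmed at the tight neighbor
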