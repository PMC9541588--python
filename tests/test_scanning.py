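import itertools

import numpy as np
import pytest

from tfbskit.fixtures import consensus_pwm
from tfbskit.motifs import Pwm, to_log_odds
from tfbskit.regions import RegulatoryRegion, reverse_complement
from tfbskit.scanning import (
    MotifHit,
    ScanConfig,
    ScoreDistribution,
    _window_int_scores,
    encode_sequence,
    scan_cluster,
    scan_fimo,
    scan_regions,
)


def region_from(seq, gene_id="g"):
    """A bare upstream-only region ending at the TIC."""
    return RegulatoryRegion(
        gene_id=gene_id,
        segments=[("upstream", "chr1", 0, len(seq), "+")],
        tic=len(seq),
        strand="+",
        sequence=seq,
    )


def random_pwm(rng, width):
    return Pwm("rand", rng.dirichlet([1, 1, 1, 1], size=width))


class TestScoreDistribution:
    def test_single_column_enumeration(self):
        # one-column motif with one favoured base: P(score >= max) = 0.25
        pwm = Pwm("w1", np.array([[0.97, 0.01, 0.01, 0.01]]))
        lom = to_log_odds(pwm, None, 0.0)
        dist = ScoreDistribution(lom, precision=1000)
        assert dist.pvalue(dist.min_int_for_pvalue(0.25)) == pytest.approx(0.25)
        top = int(dist.int_matrix.max(axis=1).sum())
        assert float(dist.pvalue(top)) == pytest.approx(0.25)

    def test_dimer_tail_matches_enumeration(self):
        rng = np.random.default_rng(2)
        lom = to_log_odds(random_pwm(rng, 2), None, 0.1)
        dist = ScoreDistribution(lom, precision=1000)
        ints = []
        for w in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
            s, _v = _window_int_scores(encode_sequence(w), dist.int_matrix)
            ints.append(int(s[0]))
        ints = np.array(ints)
        for t in np.unique(ints):
            assert float(dist.pvalue(t)) == pytest.approx((ints >= t).mean(), abs=1e-12)

    def test_threshold_above_max_score_has_zero_tail(self):
        rng = np.random.default_rng(3)
        dist = ScoreDistribution(to_log_odds(random_pwm(rng, 3), None, 0.1))
        top = int(dist.int_matrix.max(axis=1).sum())
        assert float(dist.pvalue(top + 1)) == 0.0

    def test_nonuniform_background_tail(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        pwm = Pwm("w1", np.array([[0.97, 0.01, 0.01, 0.01]]))
        dist = ScoreDistribution(to_log_odds(pwm, bg, 0.0))
        top = int(dist.int_matrix.max(axis=1).sum())
        assert float(dist.pvalue(top)) == pytest.approx(0.4)

    def test_infinite_scores_rejected(self):
        pwm = Pwm("z", np.array([[0.0, 0.5, 0.25, 0.25]]))
        lom = to_log_odds(pwm, None, 0.0)
        with pytest.raises(ValueError, match="pseudocount"):
            ScoreDistribution(lom)


class TestScanFimo:
    def test_planted_consensus_recovered_at_offset(self):
        rng = np.random.default_rng(9)
        pwm = consensus_pwm("sharp", "TTGACCGGA", 0.97)
        seq = list("".join(rng.choice(list("ACGT"), size=2000)))
        seq[1500 : 1500 + 9] = "TTGACCGGA"
        region = region_from("".join(seq))
        lom = to_log_odds(pwm, None, 0.1)
        cfg = ScanConfig(fimo_score_threshold=4.0)
        hits = scan_fimo(region, lom, cfg)
        offsets = [h.offset for h in hits if h.strand == "+"]
        assert 1500 - 2000 in offsets  # TIC-relative: -500

    def test_hit_count_monotone_in_score_threshold(self):
        rng = np.random.default_rng(4)
        region = region_from("".join(rng.choice(list("ACGT"), size=5000)))
        lom = to_log_odds(random_pwm(rng, 6), None, 0.1)
        counts = []
        for s in (3, 4, 5, 6):
            cfg = ScanConfig(fimo_score_threshold=float(s))
            counts.append(len(scan_fimo(region, lom, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_palindrome_yields_single_hit_per_position(self):
        # TGCA reverse-complements to itself: both strands match everywhere
        pwm = consensus_pwm("pal", "TGCA", 0.97)
        region = region_from("AAAAATGCAAAAAA")
        lom = to_log_odds(pwm, None, 0.1)
        cfg = ScanConfig(fimo_score_threshold=2.0, max_strand=True)
        hits = scan_fimo(region, lom, cfg)
        positions = [h.offset for h in hits]
        assert len(positions) == len(set(positions))

    def test_strand_symmetry(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        lom = to_log_odds(random_pwm(rng, 5), None, 0.1)
        cfg = ScanConfig(fimo_score_threshold=2.0)
        fwd_hits = scan_fimo(region_from(seq), lom, cfg)
        rc_hits = scan_fimo(region_from(reverse_complement(seq)), lom, cfg)
        W = 5
        # position i on the forward sequence maps to len - W - i on the rc
        fwd_pos = sorted(h.offset + len(seq) for h in fwd_hits)
        rc_pos = sorted(len(seq) - W - (h.offset + len(seq)) for h in rc_hits)
        assert fwd_pos == rc_pos

    def test_windows_with_n_are_skipped(self):
        pwm = consensus_pwm("m", "ACGT", 0.97)
        region = region_from("AANGTACGTAA")
        lom = to_log_odds(pwm, None, 0.1)
        hits = scan_fimo(region, lom, ScanConfig(fimo_score_threshold=2.0))
        assert all(h.offset + 11 >= 3 for h in hits)  # no window covers the N

    def test_motif_wider_than_region_is_empty(self):
        pwm = consensus_pwm("wide", "ACGTACGTACGT", 0.97)
        region = region_from("ACGT")
        hits = scan_fimo(region, to_log_odds(pwm, None, 0.1), ScanConfig())
        assert hits == []


class TestScanCluster:
    def setup_method(self):
        self.pwm = consensus_pwm("M1", "TGACGTCA", 0.97)
        self.lom = to_log_odds(self.pwm, None, 0.0)
        self.rng = np.random.default_rng(0)

    def _seq_with_matches(self, gap, n=3, length=6000):
        s = list("".join(self.rng.choice(list("AC"), size=length)))
        pos = 100
        for _ in range(n):
            s[pos : pos + 8] = "TGACGTCA"
            pos += 8 + gap
        return "".join(s)

    def test_dense_matches_form_one_cluster(self):
        cfg = ScanConfig(
            algorithm="cluster",
            cluster_score_threshold=20.0,
            motif_score_threshold=5.0,
            pseudocount=0.0,
        )
        region = region_from(self._seq_with_matches(gap=20))
        clusters, hits = scan_cluster(region, [self.lom], cfg)
        assert len(clusters) == 1 and clusters[0].n_matches == 3
        assert len(hits) == 3
        # chain score: 3 matches minus two 20-bp gap costs
        expected = 3 * self.lom.max_score - 2 * 20 / cfg.gap_param
        assert clusters[0].score == pytest.approx(expected)

    def test_sparse_matches_form_no_cluster(self):
        cfg = ScanConfig(
            algorithm="cluster",
            cluster_score_threshold=20.0,
            motif_score_threshold=5.0,
            pseudocount=0.0,
        )
        region = region_from(self._seq_with_matches(gap=1500))
        clusters, hits = scan_cluster(region, [self.lom], cfg)
        # isolated singleton chains score one match (~15.6) < c=20
        assert clusters == [] and hits == []

    def test_empty_sequence_has_no_clusters(self):
        region = region_from("")
        clusters, hits = scan_cluster(
            region, [self.lom], ScanConfig(algorithm="cluster", pseudocount=0.0)
        )
        assert clusters == [] and hits == []

    def test_single_weak_match_yields_nothing(self):
        # one mismatch drops the score below m for a sharp 8-mer
        region = region_from("AAAAAAAATGACGTCCAAAAAAAA".replace("TGACGTCC", "TGACGACC"))
        cfg = ScanConfig(
            algorithm="cluster",
            cluster_score_threshold=1.0,
            motif_score_threshold=15.0,
            pseudocount=0.0,
        )
        clusters, hits = scan_cluster(region, [self.lom], cfg)
        assert hits == []

    def test_no_motifs_rejected(self):
        with pytest.raises(ValueError):
            scan_cluster(region_from("ACGT"), [], ScanConfig(algorithm="cluster"))


def test_scan_regions_matches_per_region_scan(small_genome, small_regions):
    from tfbskit.motifs import estimate_background

    regions = small_regions[:30]
    bg = estimate_background(r.sequence for r in regions)
    loms = [to_log_odds(p, bg, 0.1) for p in small_genome.pwms[:3]]
    cfg = ScanConfig(fimo_score_threshold=3.0)
    combined = scan_regions(regions, loms, cfg)
    singles = []
    for lom in loms:
        dist = ScoreDistribution(lom, cfg.precision)
        for r in regions:
            singles.extend(scan_fimo(r, lom, cfg, dist))
    from tfbskit.scanning import hits_to_frame

    expected = hits_to_frame(singles)
    assert combined.reset_index(drop=True).equals(expected.reset_index(drop=True))
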