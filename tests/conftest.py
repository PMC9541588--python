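import numpy as np
import pytest

from tfbskit.fixtures import FixtureSpec, make_genome
from tfbskit import regions as reg
from tfbskit.hit_index import build_index
from tfbskit.motifs import estimate_background, to_log_odds
from tfbskit.scanning import ScanConfig, scan_regions


@pytest.fixture(scope="session")
def small_genome():
    """300-gene planted fixture shared across the suite."""
    return make_genome(FixtureSpec(n_genes=300, target_set_size=50, rng_seed=7))


@pytest.fixture(scope="session")
def small_genome_dir(small_genome, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    paths = small_genome.write(outdir)
    return paths


@pytest.fixture(scope="session")
def small_regions(small_genome, small_genome_dir):
    from pyfaidx import Fasta

    genes = reg.read_gene_models(small_genome_dir["gff"])
    cfg = reg.RegionConfig(upstream_len=1000)
    regions = reg.build_regions(
        genes, cfg, {small_genome.chrom: len(small_genome.sequence)}
    )
    reg.extract_sequences(regions, Fasta(str(small_genome_dir["fasta"])))
    return regions


@pytest.fixture(scope="session")
def small_index(small_genome, small_regions):
    bg = estimate_background(r.sequence for r in small_regions)
    loms = [to_log_odds(p, bg, 0.1) for p in small_genome.pwms]
    cfg = ScanConfig(algorithm="fimo", fimo_score_threshold=4.0)
    hits = scan_regions(small_regions, loms, cfg)
    index = build_index(
        hits,
        [r.gene_id for r in small_regions],
        setting="up1000|fimo4",
        motif_ids=[p.motif_id for p in small_genome.pwms],
    )
    return index, hits
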