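import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import windmr as w

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_genome() -> w.GenomeSequence:
    return w.GenomeSequence(
        {
            "chr1": "ACGTCAGCCGGNACCTAGGT",
            "chr2": "CGCGCGTTTT",
        }
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated experiment shared by read-only tests."""
    config = w.SimConfig(
        seed=7,
        n_chrom=1,
        chrom_len=120_000,
        mean_depth=12,
        dmr_spec=[w.DmrSpec("CG", -0.4, 600, 3), w.DmrSpec("CHG", 0.4, 600, 2)],
    )
    genome, genes, tes = w.simulate_genome_and_annotation(config)
    track_a, track_b, truth = w.simulate_methylome_pair(genome, genes, tes, config)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "tes": tes,
        "track_a": track_a,
        "track_b": track_b,
        "truth": truth,
    }


def make_track(rows, sample_id="t") -> w.MethylomeTrack:
    """Build a track from (chrom, pos, strand, context, m, t) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "m", "t"])
    return w.MethylomeTrack(sample_id, df)


def pixel_metrics(called, truth, chrom_len):
    """Nucleotide-level precision/recall of called vs truth (chrom,start,end) lists."""
    cov_c, cov_t = {}, {}
    for c, s, e in called:
        cov_c.setdefault(c, np.zeros(chrom_len, bool))[s:e] = True
    for c, s, e in truth:
        cov_t.setdefault(c, np.zeros(chrom_len, bool))[s:e] = True
    chroms = set(cov_c) | set(cov_t)
    z = np.zeros(chrom_len, bool)
    tp = sum((cov_c.get(c, z) & cov_t.get(c, z)).sum() for c in chroms)
    n_called = sum(a.sum() for a in cov_c.values())
    n_true = sum(a.sum() for a in cov_t.values())
    precision = tp / n_called if n_called else 1.0
    recall = tp / n_true if n_true else 1.0
    return precision, recall
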