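"""Calibration and recovery benchmarks run entirely on simulated data.

These drivers quantify the caller's behaviour under known conditions:
false-positive behaviour when no differential region exists, nucleotide-level
recovery of spiked regions, conversion-rate estimator coverage, and the
null behaviour of the enrichment test.  They are used by the test suite and
the reproduction script, and are available to users who want to re-check
calibration under their own parameter choices.
"""

from __future__ import annotations

import numpy as np

from .dmr import DmrParams, call_all_dmrs, call_context_dmrs
from .enrichment import TermAnnotation, enrich_terms
from .methylome import estimate_conversion_rate
from .simulate import (
    DmrSpec,
    SimConfig,
    simulate_genome_and_annotation,
    simulate_methylome_pair,
    simulate_unmethylated_control,
)


def _simulate_pair(config: SimConfig):
    genome, genes, tes = simulate_genome_and_annotation(config)
    track_a, track_b, truth = simulate_methylome_pair(genome, genes, tes, config)
    return genome, track_a, track_b, truth


def null_dmr_counts(
    n_replicates: int = 20,
    base_seed: int = 1,
    n_chrom: int = 2,
    chrom_len: int = 500_000,
    mean_depth: float = 12.0,
    non_conversion: float = 0.008,
    params: DmrParams = DmrParams(),
) -> list[int]:
    """Total DMRs (all contexts) called per replicate when no true DMR exists.

    Each replicate simulates an independent identically-distributed sample
    pair; any DMR called is a false positive of the full pipeline.
    """
    counts = []
    for rep in range(n_replicates):
        config = SimConfig(
            seed=base_seed + rep, n_chrom=n_chrom, chrom_len=chrom_len,
            mean_depth=mean_depth, non_conversion=non_conversion, dmr_spec=[],
        )
        genome, track_a, track_b, _ = _simulate_pair(config)
        dmrs = call_all_dmrs(track_a, track_b, genome, params)
        counts.append(sum(len(v) for v in dmrs.values()))
    return counts


def nucleotide_precision_recall(
    called: list[tuple[str, int, int]],
    truth: list[tuple[str, int, int]],
    chrom_len: int,
) -> tuple[float, float]:
    """Base-pair-level precision and recall of called regions vs truth."""
    cov_c: dict[str, np.ndarray] = {}
    cov_t: dict[str, np.ndarray] = {}
    for chrom, s, e in called:
        cov_c.setdefault(chrom, np.zeros(chrom_len, bool))[s:e] = True
    for chrom, s, e in truth:
        cov_t.setdefault(chrom, np.zeros(chrom_len, bool))[s:e] = True
    zero = np.zeros(chrom_len, bool)
    chroms = set(cov_c) | set(cov_t)
    tp = sum(int((cov_c.get(c, zero) & cov_t.get(c, zero)).sum()) for c in chroms)
    n_called = sum(int(a.sum()) for a in cov_c.values())
    n_truth = sum(int(a.sum()) for a in cov_t.values())
    precision = tp / n_called if n_called else 1.0
    recall = tp / n_truth if n_truth else 1.0
    return precision, recall


def spike_recovery(
    seeds=(1, 2, 3, 4, 5),
    context: str = "CG",
    delta: float = -0.4,
    region_len: int = 600,
    n_regions: int = 20,
    n_chrom: int = 2,
    chrom_len: int = 500_000,
    mean_depth: float = 15.0,
    params: DmrParams = DmrParams(),
) -> tuple[float, float]:
    """Mean nucleotide precision/recall of spiked-region recovery over seeds.

    The spike lowers the level inside each region by |delta| from the
    intergenic base (the hypomethylation direction keeps the fold change
    above the caller's 2.5-fold gate; a +0.4 shift from the same base would
    be filtered by design).
    """
    precisions, recalls = [], []
    for seed in seeds:
        config = SimConfig(
            seed=seed, n_chrom=n_chrom, chrom_len=chrom_len, mean_depth=mean_depth,
            dmr_spec=[DmrSpec(context, delta, region_len, n_regions)],
        )
        genome, track_a, track_b, truth = _simulate_pair(config)
        dmrs, _ = call_context_dmrs(track_a, track_b, genome, context, params)
        p, r = nucleotide_precision_recall(
            [(d.chrom, d.start, d.end) for d in dmrs],
            [(t.chrom, t.start, t.end) for t in truth.regions.itertuples(index=False)],
            chrom_len,
        )
        precisions.append(p)
        recalls.append(r)
    return float(np.mean(precisions)), float(np.mean(recalls))


def conversion_rate_estimates(
    n_seeds: int = 100,
    base_seed: int = 1,
    length: int = 50_000,
    mean_depth: float = 15.0,
    non_conversion: float = 0.008,
) -> np.ndarray:
    """Conversion-rate estimates from independent unmethylated controls."""
    rates = []
    for s in range(n_seeds):
        config = SimConfig(
            seed=base_seed + s, mean_depth=mean_depth, non_conversion=non_conversion
        )
        track = simulate_unmethylated_control(length, config)
        rates.append(estimate_conversion_rate(track))
    return np.asarray(rates)


def enrichment_null_any_significant_rate(
    n_replicates: int = 200,
    base_seed: int = 1,
    universe_size: int = 1000,
    n_terms: int = 50,
    list_size: int = 50,
    fdr_max: float = 0.01,
) -> float:
    """Fraction of random gene lists with any term flagged at the FDR cutoff."""
    rng = np.random.default_rng(base_seed)
    universe = [f"g{i:05d}" for i in range(universe_size)]
    annotations = [
        TermAnnotation(
            f"T{t:03d}", f"term {t}",
            frozenset(rng.choice(universe, size=int(rng.integers(10, 100)), replace=False)),
        )
        for t in range(n_terms)
    ]
    hits = 0
    for _ in range(n_replicates):
        gene_list = rng.choice(universe, size=list_size, replace=False)
        result = enrich_terms(gene_list, annotations, universe, fdr_max)
        if len(result) and result["significant"].any():
            hits += 1
    return hits / n_replicates
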