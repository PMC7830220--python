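"""DMR-to-gene assignment: differentially methylated genes (DMGs).

A gene whose functional regions — promoter (2 kb upstream of the TSS by
default), UTR, exon or intron — overlap a DMR by at least one base pair is
a differentially methylated gene.  Genes are deduplicated per (context,
direction); a gene may legitimately appear in both the hyper and hypo
tallies, but only once in a "non-repeat" total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .dmr import Dmr
from .genome import GeneModel, build_functional_regions

REGION_LABELS = ("promoter", "utr", "exon", "intron")


@dataclass
class DmgRecord:
    """One gene × context × direction hit, with every region label touched."""

    gene_id: str
    context: str
    direction: str
    regions_hit: set[str] = field(default_factory=set)
    dmr_ids: list[int] = field(default_factory=list)


def _region_trees(
    genes: list[GeneModel], promoter_len: int, chrom_len: dict[str, int] | None
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        clen = None if chrom_len is None else chrom_len.get(gene.body.chrom)
        for label, iv in build_functional_regions(gene, promoter_len, clen):
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (gene.gene_id, label)
            )
    return trees


def assign_dmrs_to_genes(
    dmrs: list[Dmr],
    genes: list[GeneModel],
    promoter_len: int = 2000,
    chrom_len: dict[str, int] | None = None,
    min_overlap: int = 1,
) -> list[DmgRecord]:
    """Genes whose functional regions overlap a DMR (≥ min_overlap bp).

    Every overlapping gene is recorded; per gene, every overlapped region
    label is recorded; records are unique per (gene, context, direction).
    """
    trees = _region_trees(genes, promoter_len, chrom_len)
    records: dict[tuple[str, str, str], DmgRecord] = {}
    for dmr_id, dmr in enumerate(dmrs):
        tree = trees.get(dmr.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(dmr.start, dmr.end):
            overlap = min(hit.end, dmr.end) - max(hit.begin, dmr.start)
            if overlap < min_overlap:
                continue
            gene_id, label = hit.data
            key = (gene_id, dmr.context, dmr.direction)
            rec = records.setdefault(key, DmgRecord(gene_id, dmr.context, dmr.direction))
            rec.regions_hit.add(label)
            if dmr_id not in rec.dmr_ids:
                rec.dmr_ids.append(dmr_id)
    return sorted(records.values(), key=lambda r: (r.context, r.direction, r.gene_id))


def genomic_composition(
    dmrs: list[Dmr],
    genes: list[GeneModel],
    promoter_len: int = 2000,
    chrom_len: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-context DMR fractions over {genic, promoter, intergenic}.

    Each DMR is assigned exactly one compartment with precedence
    genic > promoter > intergenic (a DMR touching both an exon and a
    promoter counts as genic), so fractions sum to 1 per context.
    """
    body_trees: dict[str, IntervalTree] = {}
    prom_trees: dict[str, IntervalTree] = {}
    for gene in genes:
        b = gene.body
        body_trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end)
        clen = None if chrom_len is None else chrom_len.get(b.chrom)
        for label, iv in build_functional_regions(gene, promoter_len, clen):
            if label == "promoter":
                prom_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    rows = []
    contexts = sorted({d.context for d in dmrs})
    for ctx in contexts:
        sub = [d for d in dmrs if d.context == ctx]
        counts = {"genic": 0, "promoter": 0, "intergenic": 0}
        for d in sub:
            if d.chrom in body_trees and body_trees[d.chrom].overlap(d.start, d.end):
                counts["genic"] += 1
            elif d.chrom in prom_trees and prom_trees[d.chrom].overlap(d.start, d.end):
                counts["promoter"] += 1
            else:
                counts["intergenic"] += 1
        total = len(sub)
        rows.append(
            {
                "context": ctx,
                "n_dmrs": total,
                **{f"frac_{k}": v / total if total else 0.0 for k, v in counts.items()},
            }
        )
    return pd.DataFrame(rows)


def region_distribution(records: list[DmgRecord]) -> pd.DataFrame:
    """Counts of genes per context × direction × functional region.

    A gene counts once per region label it hits, so region columns can sum
    to more than the (non-repeat) gene total.
    """
    rows = []
    contexts = sorted({r.context for r in records}) or []
    for ctx in contexts:
        for direction in ("hyper", "hypo"):
            sub = [r for r in records if r.context == ctx and r.direction == direction]
            row = {
                "context": ctx,
                "direction": direction,
                "total": len({r.gene_id for r in sub}),
            }
            for label in REGION_LABELS:
                row[label] = sum(label in r.regions_hit for r in sub)
            rows.append(row)
    cols = ["context", "direction", "total", *REGION_LABELS]
    return pd.DataFrame(rows, columns=cols)


def nonrepeat_gene_count(records: list[DmgRecord], context: str | None = None) -> int:
    """Distinct genes across directions (a both-direction gene counts once)."""
    sub = records if context is None else [r for r in records if r.context == context]
    return len({r.gene_id for r in sub})


def expression_filter(
    records: list[DmgRecord], tpm_table: dict[str, float], min_tpm: float = 10.0
) -> list[DmgRecord]:
    """Drop DMGs expressed below ``min_tpm`` (TPM < threshold removed).

    Genes absent from the expression table are dropped with a warning.
    """
    missing = sorted({r.gene_id for r in records if r.gene_id not in tpm_table})
    if missing:
        warnings.warn(
            f"{len(missing)} DMG(s) absent from the TPM table were dropped "
            f"(first: {missing[0]})",
            stacklevel=2,
        )
    return [
        r for r in records
        if r.gene_id in tpm_table and tpm_table[r.gene_id] >= min_tpm
    ]


def records_to_frame(
    records: list[DmgRecord], tpm_table: dict[str, float] | None = None
) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "context": r.context,
            "direction": r.direction,
            "regions_hit": ",".join(sorted(r.regions_hit)),
            "dmr_ids": ",".join(map(str, r.dmr_ids)),
            "tpm": tpm_table.get(r.gene_id) if tpm_table else None,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "context", "direction", "regions_hit", "dmr_ids", "tpm"]
    )


def read_tpm_table(path) -> dict[str, float]:
    """Two-column TSV (gene_id, TPM), with or without a header line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "tpm"], comment="#")
    if df.iloc[0]["gene_id"].lower() in ("gene", "gene_id"):
        df = df.iloc[1:]
    return dict(zip(df["gene_id"], df["tpm"].astype(float)))
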