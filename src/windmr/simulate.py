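"""Synthetic two-sample plant methylome generator with known ground truth.

Emulates the salient structure of a plant WGBS experiment at desk scale: a
random genome carrying non-overlapping genes and transposable elements (TEs
concentrated in a pericentromeric zone), per-cytosine true methylation
probabilities that depend on sequence context and genomic compartment
(CG > CHG > CHH within each compartment; TEs hypermethylated; gene bodies
carrying CG but little CHG/CHH methylation), read counts drawn as
Poisson coverage with binomial methylated-read counts, and bisulfite
non-conversion noise.  Differential regions of known location, context and
effect size are spiked into sample B only, and returned as ground truth.

Read-level detail (FASTQ, alignment) is deliberately not modelled: the
caller's true input is the per-site count table, and that is what is
generated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    GenomeSequence,
    GenomicInterval,
    GeneModel,
    TeFeature,
    enumerate_cytosines,
    write_fasta,
    write_gff3,
)
from .methylome import MethylomeTrack

_CTX_CODE = {"CG": 0, "CHG": 1, "CHH": 2}
_CLASS_CODE = {"intergenic": 0, "gene": 1, "TE": 2}

#: Default true methylation probabilities per (compartment, context).
#: Chosen to mirror a TE-rich plant genome: CG > CHG > CHH everywhere,
#: TEs heavily methylated in CG/CHG, gene bodies carrying CG methylation
#: but depleted CHG/CHH relative to flanking intergenic sequence.
DEFAULT_BASE_LEVELS: dict[tuple[str, str], float] = {
    ("intergenic", "CG"): 0.55,
    ("intergenic", "CHG"): 0.35,
    ("intergenic", "CHH"): 0.08,
    ("gene", "CG"): 0.35,
    ("gene", "CHG"): 0.08,
    ("gene", "CHH"): 0.03,
    ("TE", "CG"): 0.90,
    ("TE", "CHG"): 0.70,
    ("TE", "CHH"): 0.12,
}


class SimulationError(RuntimeError):
    """Raised when the requested feature densities cannot be placed."""


@dataclass(frozen=True)
class DmrSpec:
    """One batch of spiked differential regions.

    ``delta`` is the signed level change in sample B relative to A
    (positive = hypermethylated in B).  ``base_level`` overrides the level
    in sample A inside the regions; by default the intergenic base level of
    the context is used, so ``base_level + delta`` must stay in [0, 1].
    """

    context: str
    delta: float
    length: int
    count: int
    base_level: float | None = None


@dataclass
class SimConfig:
    """All generative parameters of one simulated experiment."""

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 500_000
    gene_density: float = 50.0  # genes per Mb
    te_density: float = 80.0  # TEs per Mb
    base_levels: dict = field(default_factory=lambda: dict(DEFAULT_BASE_LEVELS))
    mean_depth: tuple[float, float] = (12.64, 13.42)  # reads/site, samples A and B
    non_conversion: float = 0.008  # unmethylated C read as methylated
    over_conversion: float = 0.0  # methylated C read as unmethylated
    dmr_spec: list[DmrSpec] = field(default_factory=list)
    pericentromere_frac: float = 0.3  # central fraction of each chromosome
    te_pericentromere_weight: float = 0.7  # fraction of TEs placed centrally

    def __post_init__(self) -> None:
        if np.isscalar(self.mean_depth):
            self.mean_depth = (float(self.mean_depth), float(self.mean_depth))
        else:
            self.mean_depth = (float(self.mean_depth[0]), float(self.mean_depth[1]))
        if min(self.mean_depth) <= 0:
            raise ValueError("mean_depth must be positive")
        for prob in (self.non_conversion, self.over_conversion):
            if not 0 <= prob < 1:
                raise ValueError("conversion probabilities must lie in [0, 1)")
        for key, val in self.base_levels.items():
            if not 0 <= val <= 1:
                raise ValueError(f"base level {key} outside [0, 1]")
        for spec in self.dmr_spec:
            base = spec.base_level
            if base is None:
                base = self.base_levels[("intergenic", spec.context)]
            if not 0 <= base + spec.delta <= 1 or not 0 <= base <= 1:
                raise ValueError(f"dmr_spec {spec} pushes levels outside [0, 1]")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["base_levels"] = sorted(
            (f"{a}:{b}", v) for (a, b), v in self.base_levels.items()
        )
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated sample pair."""

    regions: pd.DataFrame  # chrom, start, end, context, direction, level_a, level_b
    site_params: pd.DataFrame  # chrom, pos, strand, context, p_a, p_b
    config_hash: str


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genome_and_annotation(
    config: SimConfig,
) -> tuple[GenomeSequence, list[GeneModel], list[TeFeature]]:
    """A random genome with non-overlapping genes and TEs.

    Gene and TE counts per chromosome are Poisson at the configured per-Mb
    densities.  TEs are preferentially placed in the central
    (pericentromere-like) zone of each chromosome, genes outside it, so the
    simulated genome shows the TE-dense hypermethylated interior that real
    plant chromosomes do.
    """
    rng = _rng(config, 0)
    sequences = {}
    genes: list[GeneModel] = []
    tes: list[TeFeature] = []
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        length = config.chrom_len
        sequences[chrom] = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
        )
        occupied = np.zeros(length, dtype=bool)
        peri_lo = int(length * (0.5 - config.pericentromere_frac / 2))
        peri_hi = int(length * (0.5 + config.pericentromere_frac / 2))

        def place(feat_len: int, central: bool, max_tries: int = 300) -> int | None:
            for _ in range(max_tries):
                if central:
                    lo, hi = peri_lo, max(peri_lo + 1, peri_hi - feat_len)
                else:
                    lo, hi = 0, length - feat_len
                if hi <= lo:
                    return None
                start = int(rng.integers(lo, hi))
                if not occupied[start : start + feat_len].any():
                    occupied[start : start + feat_len] = True
                    return start
            return None

        n_genes = rng.poisson(config.gene_density * length / 1e6)
        for gi in range(n_genes):
            glen = int(rng.integers(1000, 4001))
            central = rng.random() > 0.8  # most genes sit outside the TE zone
            start = place(glen, central)
            if start is None:
                start = place(glen, not central)
            if start is None:
                raise SimulationError(
                    f"cannot place gene of {glen} bp on {chrom}; densities too high"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, start, start + glen, strand)
            genes.append(_random_gene_structure(f"{chrom}g{gi + 1:04d}", body, rng))

        n_tes = rng.poisson(config.te_density * length / 1e6)
        for ti in range(n_tes):
            tlen = int(rng.integers(300, 3001))
            central = rng.random() < config.te_pericentromere_weight
            start = place(tlen, central)
            if start is None and central:
                # central zone congested: fall back to anywhere on the chromosome
                start = place(tlen, False)
            if start is None:
                raise SimulationError(
                    f"cannot place TE of {tlen} bp on {chrom}; densities too high"
                )
            family = rng.choice(["Gypsy", "Copia", "MULE", "CACTA"])
            tes.append(
                TeFeature(f"{chrom}te{ti + 1:04d}", GenomicInterval(chrom, start, start + tlen), str(family))
            )
    genes.sort(key=lambda g: (g.body.chrom, g.body.start))
    tes.sort(key=lambda t: (t.location.chrom, t.location.start))
    return GenomeSequence(sequences), genes, tes


def _random_gene_structure(gene_id: str, body: GenomicInterval, rng) -> GeneModel:
    """Exon/intron/UTR structure: 1–5 exons, terminal UTRs inside terminal exons."""
    glen = len(body)
    n_exons = int(rng.integers(1, 6))
    n_parts = 2 * n_exons - 1  # exon, intron, exon, ...
    weights = rng.dirichlet(np.ones(n_parts)) * glen
    sizes = np.maximum(weights.astype(int), 40)
    sizes[-1] += glen - sizes.sum()  # absorb rounding in the last exon
    if sizes[-1] < 40:  # redistribute if the correction broke the minimum
        sizes = np.full(n_parts, glen // n_parts)
        sizes[-1] += glen - sizes.sum()
    bounds = np.concatenate([[0], np.cumsum(sizes)]) + body.start
    exons = [
        GenomicInterval(body.chrom, int(bounds[i]), int(bounds[i + 1]), body.strand)
        for i in range(0, n_parts, 2)
    ]
    first, last = exons[0], exons[-1]
    utr_a = GenomicInterval(
        body.chrom, first.start, min(first.end, first.start + max(30, len(first) // 6)), body.strand
    )
    utr_b = GenomicInterval(
        body.chrom, max(last.start, last.end - max(30, len(last) // 6)), last.end, body.strand
    )
    if body.strand == "+":
        utr5, utr3 = [utr_a], [utr_b]
    else:
        utr5, utr3 = [utr_b], [utr_a]
    return GeneModel(gene_id, body, exons, utr5, utr3)


def _compartment_arrays(
    genome: GenomeSequence, genes: list[GeneModel], tes: list[TeFeature]
) -> dict[str, np.ndarray]:
    comp = {c: np.zeros(genome.chrom_len[c], dtype=np.int8) for c in genome.chrom_names}
    for gene in genes:
        b = gene.body
        comp[b.chrom][b.start : b.end] = _CLASS_CODE["gene"]
    for te in tes:
        loc = te.location
        comp[loc.chrom][loc.start : loc.end] = _CLASS_CODE["TE"]
    return comp


def _place_truth_regions(
    config: SimConfig,
    genome: GenomeSequence,
    comp: dict[str, np.ndarray],
    sites: pd.DataFrame,
    rng,
) -> pd.DataFrame:
    """Place spiked regions in intergenic space with enough matching cytosines.

    Regions require at least 10 context-matching cytosines so the ≥7-DMC
    assembly rule is attainable in principle, and never overlap each other.
    """
    rows = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    pos_by = {
        (chrom, ctx): grp["pos"].to_numpy()
        for (chrom, ctx), grp in sites.groupby(["chrom", "context"], observed=True)
    }
    for spec in config.dmr_spec:
        base = spec.base_level
        if base is None:
            base = config.base_levels[("intergenic", spec.context)]
        placed = 0
        tries = 0
        while placed < spec.count:
            tries += 1
            if tries > 2000 * spec.count:
                raise SimulationError(
                    f"cannot place {spec.count} truth regions of {spec.length} bp "
                    f"({spec.context}); genome too small or too feature-dense"
                )
            chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
            length = genome.chrom_len[chrom]
            if spec.length >= length:
                continue
            start = int(rng.integers(0, length - spec.length))
            end = start + spec.length
            if comp[chrom][start:end].any():  # intergenic only
                continue
            if any(start < e and s < end for s, e in taken[chrom]):
                continue
            pos = pos_by.get((chrom, spec.context))
            if pos is None:
                continue
            n_ctx = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            if n_ctx < 10:
                continue
            taken[chrom].append((start, end))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "context": spec.context,
                    "direction": "hyper" if spec.delta > 0 else "hypo",
                    "level_a": base,
                    "level_b": base + spec.delta,
                }
            )
            placed += 1
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "direction", "level_a", "level_b"]
    )
    return regions.sort_values(["chrom", "start"]).reset_index(drop=True)


def _draw_track(
    sample_id: str,
    sites: pd.DataFrame,
    p_true: np.ndarray,
    depth: float,
    config: SimConfig,
    rng,
) -> MethylomeTrack:
    cov = rng.poisson(depth, size=len(sites))
    p_obs = p_true * (1 - config.over_conversion) + (1 - p_true) * config.non_conversion
    m = rng.binomial(cov, p_obs)
    keep = cov > 0
    df = sites.loc[keep, ["chrom", "pos", "strand", "context"]].reset_index(drop=True)
    df["m"] = m[keep]
    df["t"] = cov[keep]
    return MethylomeTrack(sample_id, df, provenance={"config_hash": config.config_hash()})


def simulate_methylome_pair(
    genome: GenomeSequence,
    genes: list[GeneModel],
    tes: list[TeFeature],
    config: SimConfig,
) -> tuple[MethylomeTrack, MethylomeTrack, SimTruth]:
    """Two per-cytosine call tracks differing only inside the spiked regions.

    Per site, coverage ~ Poisson(mean_depth) and methylated count ~
    Binomial(coverage, p_obs), with p_obs folding in non-conversion (an
    unmethylated cytosine reads methylated with the configured probability).
    Sample B's true level differs from A's only inside truth regions, by the
    spec's signed delta.
    """
    sites = enumerate_cytosines(genome)
    comp = _compartment_arrays(genome, genes, tes)
    ctx_codes = sites["context"].cat.codes.to_numpy()

    base_table = np.zeros((3, 3))
    for (cls, ctx), val in config.base_levels.items():
        base_table[_CLASS_CODE[cls], _CTX_CODE[ctx]] = val
    comp_codes = np.concatenate(
        [comp[c][sites.loc[sites["chrom"] == c, "pos"].to_numpy()] for c in genome.chrom_names]
    )
    p_a = base_table[comp_codes, ctx_codes]

    rng = _rng(config, 1)
    regions = _place_truth_regions(config, genome, comp, sites, rng)
    p_b = p_a.copy()
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for reg in regions.itertuples(index=False):
        sel = (
            (chrom_arr == reg.chrom)
            & (pos_arr >= reg.start)
            & (pos_arr < reg.end)
            & (ctx_codes == _CTX_CODE[reg.context])
        )
        p_a[sel] = reg.level_a
        p_b[sel] = reg.level_b

    track_a = _draw_track("sample_A", sites, p_a, config.mean_depth[0], config, _rng(config, 2))
    track_b = _draw_track("sample_B", sites, p_b, config.mean_depth[1], config, _rng(config, 3))

    site_params = sites.copy()
    site_params["p_a"] = p_a
    site_params["p_b"] = p_b
    truth = SimTruth(regions=regions, site_params=site_params, config_hash=config.config_hash())
    return track_a, track_b, truth


def simulate_unmethylated_control(length: int, config: SimConfig) -> MethylomeTrack:
    """A call track over a biologically unmethylated control sequence.

    Mirrors the use of an unmethylated organellar genome to estimate the
    bisulfite non-conversion rate: every methylated read here is a
    conversion failure.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = _rng(config, 4)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    control = GenomeSequence({"control": seq})
    sites = enumerate_cytosines(control)
    p_true = np.zeros(len(sites))
    return _draw_track("control", sites, p_true, config.mean_depth[0], config, rng)


def truth_to_bed(truth: SimTruth, path) -> None:
    """Write truth regions as BED with name field ``context|direction|delta``."""
    with open(path, "w") as fh:
        for reg in truth.regions.itertuples(index=False):
            delta = reg.level_b - reg.level_a
            fh.write(
                f"{reg.chrom}\t{reg.start}\t{reg.end}\t"
                f"{reg.context}|{reg.direction}|{delta:+.3f}\n"
            )


def write_simulation(
    outdir,
    genome: GenomeSequence,
    genes: list[GeneModel],
    tes: list[TeFeature],
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    truth: SimTruth,
    config: SimConfig,
) -> dict[str, Path]:
    """Write FASTA, GFF3, two call TSVs, truth BED and the resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "annotation.gff3",
        "calls_a": outdir / "calls_A.tsv",
        "calls_b": outdir / "calls_B.tsv",
        "truth": outdir / "truth.bed",
        "config": outdir / "sim_config.json",
    }
    write_fasta(genome, paths["fasta"])
    write_gff3(genes, tes, paths["gff3"])
    track_a.to_tsv(paths["calls_a"])
    track_b.to_tsv(paths["calls_b"])
    truth_to_bed(truth, paths["truth"])
    payload = asdict(config)
    payload["base_levels"] = {f"{a}:{b}": v for (a, b), v in config.base_levels.items()}
    payload["config_hash"] = config.config_hash()
    paths["config"].write_text(json.dumps(payload, indent=2, default=str))
    return paths
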