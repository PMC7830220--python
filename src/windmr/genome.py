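"""Genome representation, cytosine-context classification, and feature models.

Plant cytosine methylation occurs in three sequence contexts — CG, CHG and
CHH, where H is any base but G — read 5'→3' on the strand carrying the
cytosine.  This module owns the genome container, the strand-aware context
classifier, and the gene/TE feature models whose functional regions
(promoter, UTR, exon, intron) anchor all downstream region assignment.

All coordinates are 0-based, half-open internally; GFF3 I/O converts from
the 1-based inclusive convention of that format.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

CONTEXTS = ("CG", "CHG", "CHH")

_A, _C, _G, _T = ord("A"), ord("C"), ord("G"), ord("T")
_VALID = np.zeros(256, dtype=bool)
_VALID[[_A, _C, _G, _T]] = True

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (bad header, bad alphabet, duplicates)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeSequence:
    """An ordered collection of named chromosome sequences over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise FastaFormatError("genome contains no sequences")
        self.chrom_names: list[str] = list(sequences)
        self.chrom_seq: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FastaFormatError(
                    f"sequence {name!r} contains non-nucleotide characters "
                    f"{sorted(bad)}"
                )
            self.chrom_seq[name] = seq
        self.chrom_len: dict[str, int] = {n: len(s) for n, s in self.chrom_seq.items()}
        self._arrays: dict[str, np.ndarray] = {}

    def array(self, chrom: str) -> np.ndarray:
        """Chromosome sequence as a uint8 array of ASCII codes (cached)."""
        if chrom not in self._arrays:
            self._arrays[chrom] = np.frombuffer(
                self.chrom_seq[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[chrom]

    def reverse_complement(self) -> "GenomeSequence":
        """A genome with every chromosome reverse-complemented (for symmetry checks)."""
        rc = {}
        for name, seq in self.chrom_seq.items():
            rc[name] = "".join(_COMPLEMENT[b] for b in reversed(seq))
        return GenomeSequence(rc)


def load_fasta(path) -> GenomeSequence:
    """Read a (possibly gzipped) multi-FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; record order is preserved.  Duplicate record
    names, an empty file, or non-nucleotide characters raise
    :class:`FastaFormatError`.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    sequences: dict[str, str] = {}
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise FastaFormatError(f"duplicate FASTA record {record.id!r}")
            sequences[record.id] = str(record.seq)
    if not sequences:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.chrom_seq[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def classify_context(
    genome: GenomeSequence, chrom: str, pos: int, strand: str
) -> str | None:
    """Classify the methylation context of the cytosine at (chrom, pos, strand).

    On the minus strand the reference base must be G (the cytosine sits on
    the complement).  CG requires only one downstream base; CHG/CHH require
    two.  Returns ``None`` when the needed downstream bases run off the
    chromosome or contain N.  Raises ``ValueError`` if the base at the
    position is not a cytosine on the given strand.
    """
    seq = genome.chrom_seq[chrom]
    length = len(seq)
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"base at {chrom}:{pos}(+) is {seq[pos]!r}, not C")
        if pos + 1 >= length:
            return None
        b1 = seq[pos + 1]
        if b1 == "G":
            return "CG"
        if b1 == "N" or pos + 2 >= length:
            return None
        b2 = seq[pos + 2]
        if b2 == "N":
            return None
        return "CHG" if b2 == "G" else "CHH"
    if strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"base at {chrom}:{pos}(-) is {seq[pos]!r}, not G (no C on -)")
        if pos - 1 < 0:
            return None
        b1 = seq[pos - 1]  # complements to the first downstream base on -
        if b1 == "C":
            return "CG"
        if b1 == "N" or pos - 2 < 0:
            return None
        b2 = seq[pos - 2]
        if b2 == "N":
            return None
        return "CHG" if b2 == "C" else "CHH"
    raise ValueError(f"strand must be + or -, got {strand!r}")


def enumerate_cytosines(genome: GenomeSequence) -> pd.DataFrame:
    """Table of every context-resolvable cytosine on both strands.

    Returns a DataFrame with columns ``chrom, pos, strand, context``, sorted
    by (chrom order, pos).  Cytosines whose context spans an N or a
    chromosome edge are omitted.
    """
    frames = []
    for chrom in genome.chrom_names:
        arr = genome.array(chrom)
        length = len(arr)

        # plus strand: reference C
        p = np.flatnonzero(arr == _C)
        p = p[p < length - 1]
        ctx_p = np.full(p.shape, -1, dtype=np.int8)
        n1 = arr[p + 1]
        ctx_p[n1 == _G] = 0  # CG from the dinucleotide alone
        rest = (n1 != _G) & _VALID[n1] & (p < length - 2)
        idx = np.flatnonzero(rest)
        if idx.size:
            n2 = arr[p[idx] + 2]
            ok = _VALID[n2]
            idx = idx[ok]
            n2 = n2[ok]
            ctx_p[idx] = np.where(n2 == _G, 1, 2)
        keep = ctx_p >= 0
        pos_p, ctx_p = p[keep], ctx_p[keep]

        # minus strand: reference G, downstream bases run 3'-ward (leftward)
        g = np.flatnonzero(arr == _G)
        g = g[g >= 1]
        ctx_m = np.full(g.shape, -1, dtype=np.int8)
        b1 = arr[g - 1]
        ctx_m[b1 == _C] = 0
        rest = (b1 != _C) & _VALID[b1] & (g >= 2)
        idx = np.flatnonzero(rest)
        if idx.size:
            b2 = arr[g[idx] - 2]
            ok = _VALID[b2]
            idx = idx[ok]
            b2 = b2[ok]
            ctx_m[idx] = np.where(b2 == _C, 1, 2)
        keep = ctx_m >= 0
        pos_m, ctx_m = g[keep], ctx_m[keep]

        pos = np.concatenate([pos_p, pos_m])
        strand = np.concatenate(
            [np.zeros(pos_p.size, dtype=np.int8), np.ones(pos_m.size, dtype=np.int8)]
        )
        ctx = np.concatenate([ctx_p, ctx_m])
        order = np.argsort(pos, kind="stable")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[order],
                    "strand": np.array(["+", "-"])[strand[order]],
                    "context": pd.Categorical.from_codes(
                        ctx[order], categories=list(CONTEXTS)
                    ),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    return pd.concat(frames, ignore_index=True)


def iter_cytosines(genome: GenomeSequence) -> Iterator[tuple[str, int, str, str]]:
    """Stream (chrom, pos, strand, context) tuples in coordinate order."""
    df = enumerate_cytosines(genome)
    for row in df.itertuples(index=False):
        yield row.chrom, int(row.pos), row.strand, str(row.context)


# --------------------------------------------------------------------------
# Gene / TE feature models


@dataclass
class GeneModel:
    """A gene with exon structure and UTRs; introns are the body minus exons.

    ``exons`` must tile part of ``body`` without overlap; UTR intervals lie
    within exons.  The promoter is derived on demand by
    :func:`build_functional_regions`.
    """

    gene_id: str
    body: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: body must be stranded")
        exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for ex in exons:
            if ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(f"gene {self.gene_id}: exon outside body")
        self.exons = exons

    @property
    def introns(self) -> list[GenomicInterval]:
        ivs = []
        exons = self.exons or [self.body]
        if exons[0].start > self.body.start:
            ivs.append(
                GenomicInterval(self.body.chrom, self.body.start, exons[0].start, self.body.strand)
            )
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                ivs.append(GenomicInterval(self.body.chrom, a.end, b.start, self.body.strand))
        if exons[-1].end < self.body.end:
            ivs.append(
                GenomicInterval(self.body.chrom, exons[-1].end, self.body.end, self.body.strand)
            )
        return ivs

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end


@dataclass
class TeFeature:
    """A transposable-element annotation."""

    te_id: str
    location: GenomicInterval
    family: str = "unknown"


def _subtract(iv: GenomicInterval, cuts: list[GenomicInterval]) -> list[GenomicInterval]:
    """Interval minus a list of intervals (same chrom), returned sorted."""
    pieces = [(iv.start, iv.end)]
    for cut in cuts:
        new = []
        for s, e in pieces:
            if cut.end <= s or cut.start >= e:
                new.append((s, e))
                continue
            if cut.start > s:
                new.append((s, cut.start))
            if cut.end < e:
                new.append((cut.end, e))
        pieces = new
    return [GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in sorted(pieces) if e > s]


def build_functional_regions(
    gene: GeneModel, promoter_len: int = 2000, chrom_len: int | None = None
) -> list[tuple[str, GenomicInterval]]:
    """Labeled functional regions of a gene: promoter, utr, exon, intron.

    The promoter is ``promoter_len`` bp upstream of the TSS on the gene's
    strand, clipped at the chromosome edge.  UTRs take precedence over the
    exons that contain them, so the returned intervals are pairwise disjoint
    and their union covers promoter ∪ body.
    """
    if promoter_len <= 0:
        raise ValueError("promoter_len must be positive")
    regions: list[tuple[str, GenomicInterval]] = []
    body = gene.body
    if body.strand == "+":
        pstart, pend = max(0, body.start - promoter_len), body.start
    else:
        pstart = body.end
        pend = body.end + promoter_len
        if chrom_len is not None:
            pend = min(pend, chrom_len)
    if pend > pstart:
        regions.append(("promoter", GenomicInterval(body.chrom, pstart, pend, body.strand)))

    utrs = sorted(gene.utr5 + gene.utr3, key=lambda iv: iv.start)
    for utr in utrs:
        regions.append(("utr", utr))
    for exon in gene.exons or [body]:
        for piece in _subtract(exon, utrs):
            regions.append(("exon", piece))
    for intron in gene.introns:
        regions.append(("intron", intron))
    return regions


# --------------------------------------------------------------------------
# GFF3 I/O

GFF_TE_TYPE = "transposable_element"


def write_gff3(genes: list[GeneModel], tes: list[TeFeature], path, te_type: str = GFF_TE_TYPE) -> None:
    """Write gene models and TEs as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            b = gene.body
            fh.write(
                f"{b.chrom}\twindmr\tgene\t{b.start + 1}\t{b.end}\t.\t{b.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for i, ex in enumerate(gene.exons, 1):
                fh.write(
                    f"{b.chrom}\twindmr\texon\t{ex.start + 1}\t{ex.end}\t.\t{b.strand}\t.\t"
                    f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )
            for label, lst in (("five_prime_UTR", gene.utr5), ("three_prime_UTR", gene.utr3)):
                for i, utr in enumerate(lst, 1):
                    fh.write(
                        f"{b.chrom}\twindmr\t{label}\t{utr.start + 1}\t{utr.end}\t.\t"
                        f"{b.strand}\t.\tID={gene.gene_id}.{label}{i};Parent={gene.gene_id}\n"
                    )
        for te in tes:
            loc = te.location
            fh.write(
                f"{loc.chrom}\twindmr\t{te_type}\t{loc.start + 1}\t{loc.end}\t.\t.\t.\t"
                f"ID={te.te_id};family={te.family}\n"
            )


def read_gff3(path, te_type: str = GFF_TE_TYPE) -> tuple[list[GeneModel], list[TeFeature]]:
    """Read gene models and TE features from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        body = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        exons, utr5, utr3 = [], [], []
        for child in db.children(g, featuretype=("exon", "five_prime_UTR", "three_prime_UTR")):
            iv = GenomicInterval(child.seqid, child.start - 1, child.end, child.strand)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            else:
                utr3.append(iv)
        genes.append(GeneModel(g.id, body, exons, utr5, utr3))
    tes = [
        TeFeature(t.id, GenomicInterval(t.seqid, t.start - 1, t.end), t.attributes.get("family", ["unknown"])[0])
        for t in db.features_of_type(te_type)
    ]
    genes.sort(key=lambda g: (g.body.chrom, g.body.start))
    tes.sort(key=lambda t: (t.location.chrom, t.location.start))
    return genes, tes
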