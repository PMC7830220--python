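"""Per-cytosine methylation call tables and genome-wide summaries.

A methylome here is a table of per-cytosine read counts: at each covered
cytosine, how many aligned reads reported it methylated (``m``) out of how
many covered it (``t``).  The methylation level of a site or region is the
read-weighted fraction Σm/Σt, the standard convention for bisulfite data.

Methylated-site *calling* is a separate, statistical notion: a site is
called methylated when its methylated-read count exceeds what bisulfite
non-conversion alone would explain, via a one-sided binomial test with BH
correction across sites.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import CONTEXTS, GenomeSequence, GenomicInterval
from .stats import bh_adjust

_CALL_COLUMNS = ["chrom", "pos", "strand", "context", "m", "t"]


class CallTableError(ValueError):
    """Raised for malformed per-cytosine call tables."""


@dataclass
class MethylomeTrack:
    """A coordinate-sorted per-cytosine call table for one sample.

    ``df`` holds columns chrom, pos (0-based), strand, context, m, t with at
    most one row per (chrom, pos, strand).
    """

    sample_id: str
    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _CALL_COLUMNS if c not in df.columns]
        if missing:
            raise CallTableError(f"call table missing columns {missing}")
        if np.any(df["m"].to_numpy() > df["t"].to_numpy()):
            raise CallTableError("m_count exceeds t_count")
        if np.any(df["m"].to_numpy() < 0):
            raise CallTableError("negative counts")
        df = df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise CallTableError("duplicate (chrom, pos, strand) entries")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, region: GenomicInterval, context: str | None = None) -> pd.DataFrame:
        df = self.df
        sel = (
            (df["chrom"] == region.chrom)
            & (df["pos"] >= region.start)
            & (df["pos"] < region.end)
        )
        if context is not None:
            sel &= df["context"] == context
        return df[sel]

    def to_tsv(self, path) -> None:
        """Write the 6-column call TSV (1-based positions, gzip by suffix)."""
        out = self.df.copy()
        out["pos"] = out["pos"] + 1
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            out.to_csv(fh, sep="\t", index=False, header=False)


def read_calls(path, min_coverage: int = 4, sample_id: str | None = None) -> MethylomeTrack:
    """Load a per-cytosine call TSV, dropping sites below ``min_coverage``.

    The dialect is 6 tab-separated columns — chrom, pos (1-based), strand,
    context, methylated count, total count — with no header; gzip transparent.
    Rows with ``m > t`` raise :class:`CallTableError` naming the line.
    """
    path = str(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=_CALL_COLUMNS,
        dtype={"chrom": str, "pos": np.int64, "strand": str, "context": str,
               "m": np.int64, "t": np.int64},
    )
    bad = np.flatnonzero(df["m"].to_numpy() > df["t"].to_numpy())
    if bad.size:
        raise CallTableError(f"{path}: m_count > t_count at line {bad[0] + 1}")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        raise CallTableError(
            f"{path}: unknown context at line {int(np.flatnonzero(bad_ctx)[0]) + 1}"
        )
    df["pos"] = df["pos"] - 1
    if df.duplicated(["chrom", "pos", "strand"]).any():
        raise CallTableError(f"{path}: duplicate (chrom, pos, strand) entries")
    df = df[df["t"] >= min_coverage].reset_index(drop=True)
    df["context"] = pd.Categorical(df["context"], categories=list(CONTEXTS))
    if sample_id is None:
        sample_id = path
    return MethylomeTrack(sample_id, df, provenance={"path": path, "min_coverage": min_coverage})


def site_level(m_count: int, t_count: int) -> float:
    """Methylation level of one site: m/t.  Errors when the site has no reads."""
    if t_count <= 0:
        raise ValueError("site level undefined for t_count == 0")
    if not 0 <= m_count <= t_count:
        raise ValueError("need 0 <= m_count <= t_count")
    return m_count / t_count


def region_level(
    track: MethylomeTrack,
    region: GenomicInterval,
    context: str | None = None,
    weight: str = "reads",
) -> float:
    """Methylation level of a region: Σm/Σt over covered matching sites.

    ``weight='reads'`` is the standard read-weighted convention;
    ``weight='sites'`` averages per-site levels instead.  Raises
    ``ValueError`` when no covered site matches.
    """
    sub = track.subset(region, context)
    if len(sub) == 0:
        raise ValueError(
            f"no covered {context or 'C'} sites in {region.chrom}:{region.start}-{region.end}"
        )
    if weight == "reads":
        return float(sub["m"].sum() / sub["t"].sum())
    if weight == "sites":
        return float((sub["m"] / sub["t"]).mean())
    raise ValueError(f"unknown weighting {weight!r}")


def call_methylated_sites(
    track: MethylomeTrack, non_conversion: float, q_threshold: float = 0.05
) -> np.ndarray:
    """Boolean mask over ``track.df``: sites whose methylated-read count
    exceeds the bisulfite non-conversion background.

    One-sided binomial test of m successes in t trials at success probability
    ``non_conversion``, BH-adjusted across all sites; methylated iff adjusted
    p < ``q_threshold``.
    """
    if not 0 <= non_conversion < 1:
        raise ValueError("non_conversion must lie in [0, 1)")
    m = track.df["m"].to_numpy()
    t = track.df["t"].to_numpy()
    if m.size == 0:
        return np.zeros(0, dtype=bool)
    # P(X >= m) for X ~ Binomial(t, nc); sf(m-1) == 1 for m == 0
    p = sps.binom.sf(m - 1, t, non_conversion)
    q = bh_adjust(p)
    return q < q_threshold


@dataclass
class GenomeSummary:
    """Genome-wide methylation roll-up for one sample."""

    n_sites: dict[str, int]
    n_methylated: dict[str, int]
    weighted_level: dict[str, float]  # NaN where a context has no covered site
    composition: dict[str, float]  # fraction of called mCs per context
    fraction_methylated: float  # called mCs over all covered cytosines
    has_methylated: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "context": list(CONTEXTS),
                "n_sites": [self.n_sites[c] for c in CONTEXTS],
                "n_methylated": [self.n_methylated[c] for c in CONTEXTS],
                "weighted_level": [self.weighted_level[c] for c in CONTEXTS],
                "composition": [self.composition[c] for c in CONTEXTS],
            }
        )


def genome_summary(
    track: MethylomeTrack, non_conversion: float = 0.0, q_threshold: float = 0.05
) -> GenomeSummary:
    """Per-context weighted levels and the context composition of called mCs.

    Composition fractions sum to 1 whenever any site is called methylated;
    with none, they are reported as zeros and ``has_methylated`` is False.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    df = track.df
    called = call_methylated_sites(track, non_conversion, q_threshold)
    n_sites, n_meth, level = {}, {}, {}
    for ctx in CONTEXTS:
        sel = (df["context"] == ctx).to_numpy()
        n_sites[ctx] = int(sel.sum())
        n_meth[ctx] = int(called[sel].sum())
        tsum = df.loc[sel, "t"].sum()
        level[ctx] = float(df.loc[sel, "m"].sum() / tsum) if tsum > 0 else float("nan")
    total_meth = sum(n_meth.values())
    if total_meth > 0:
        comp = {c: n_meth[c] / total_meth for c in CONTEXTS}
    else:
        comp = {c: 0.0 for c in CONTEXTS}
    return GenomeSummary(
        n_sites=n_sites,
        n_methylated=n_meth,
        weighted_level=level,
        composition=comp,
        fraction_methylated=total_meth / len(df),
        has_methylated=total_meth > 0,
    )


def chromosome_windows(
    track: MethylomeTrack, genome: GenomeSequence, window: int = 5_000_000
) -> pd.DataFrame:
    """Per-context levels in fixed windows tiling each chromosome.

    Consecutive windows of ``window`` bp; the last window may be short.
    Windows without covered sites for a context get NaN.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    df = track.df
    for chrom in genome.chrom_names:
        length = genome.chrom_len[chrom]
        sub = df[df["chrom"] == chrom]
        starts = np.arange(0, length, window)
        for s in starts:
            e = min(s + window, length)
            row = {"chrom": chrom, "start": int(s), "end": int(e)}
            inwin = sub[(sub["pos"] >= s) & (sub["pos"] < e)]
            for ctx in CONTEXTS:
                cs = inwin[inwin["context"] == ctx]
                tsum = cs["t"].sum()
                row[f"level_{ctx}"] = float(cs["m"].sum() / tsum) if tsum > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def estimate_conversion_rate(control_track: MethylomeTrack) -> float:
    """Bisulfite conversion rate from a biologically unmethylated control.

    In a genuinely unmethylated genome (e.g. the chloroplast) every
    methylated read call is a conversion failure, so the conversion rate is
    1 − Σm/Σt over all control sites.
    """
    t = control_track.df["t"].sum()
    if t == 0:
        raise ValueError("control track has no covered sites")
    return float(1.0 - control_track.df["m"].sum() / t)
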